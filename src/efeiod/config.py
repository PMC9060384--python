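"""Config parsing and validation for parameter sets and runs.

Configs are flat YAML (JSON being a YAML subset, both load).  A parameter
set looks like::

    n: 3
    ell: 2
    lambda: [1, 1, 1, 1]      # n+1 rates, entry first
    alpha: [0.01, 0.01, 0.01]  # n rates, site 1 first
    q: 1.0
    r: 1.0

Interactions may instead be given as an energy ``E`` (then ``q = exp(E/2)``,
``r = exp(-E/2)``); explicit ``q``/``r`` win if both are present.  Unknown
keys are rejected with the offending key named.
"""

from __future__ import annotations

import math

import numpy as np
import yaml

from .core import LatticeParams
from .periodic import Modulation, PeriodicSchedule
from .rfmeod import FeedbackParams

__all__ = ["ConfigError", "load_config", "params_from_dict",
           "schedule_from_dict", "feedback_from_dict", "params_to_dict"]


class ConfigError(ValueError):
    """Raised for malformed or incomplete configuration files."""


_PARAM_KEYS = {"n", "ell", "lambda", "alpha", "q", "r", "E",
               "entry_interaction"}
_SCHEDULE_KEYS = {"T", "delta1", "delta2", "modulations"}
_FEEDBACK_KEYS = {"k1", "k2"}


def _require_number(cfg, key, kind=float):
    if key not in cfg:
        raise ConfigError(f"missing required key {key!r}")
    try:
        return kind(cfg[key])
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"key {key!r} must be a {kind.__name__}: {exc}") from exc


def params_from_dict(cfg: dict) -> LatticeParams:
    """Validate a flat mapping into a :class:`~efeiod.core.LatticeParams`."""
    if not isinstance(cfg, dict):
        raise ConfigError("parameter config must be a mapping")
    extra = set(cfg) - _PARAM_KEYS - _SCHEDULE_KEYS - _FEEDBACK_KEYS
    if extra:
        raise ConfigError(f"unknown config keys: {sorted(extra)}")
    n = _require_number(cfg, "n", int)
    ell = _require_number(cfg, "ell", int)
    for key, length in (("lambda", n + 1), ("alpha", n)):
        if key not in cfg:
            raise ConfigError(f"missing required key {key!r}")
        if not isinstance(cfg[key], (list, tuple)) or len(cfg[key]) != length:
            raise ConfigError(
                f"key {key!r} must be a list of {length} rates "
                f"(got {cfg.get(key)!r})")
    lam = np.asarray(cfg["lambda"], dtype=float)
    alpha = np.asarray(cfg["alpha"], dtype=float)
    entry = bool(cfg.get("entry_interaction", True))
    if "q" in cfg or "r" in cfg:
        if not ("q" in cfg and "r" in cfg):
            raise ConfigError("q and r must be given together")
        q, r = float(cfg["q"]), float(cfg["r"])
    elif "E" in cfg:
        E = float(cfg["E"])
        q, r = math.exp(E / 2.0), math.exp(-E / 2.0)
    else:
        q = r = 1.0
    try:
        return LatticeParams(n=n, ell=ell, lam=lam, alpha=alpha, q=q, r=r,
                             entry_interaction=entry)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def schedule_from_dict(cfg: dict) -> PeriodicSchedule:
    """Build a periodic schedule; ``modulations`` maps parameter name to
    ``{offset, amplitude, phase}``."""
    base = params_from_dict({k: v for k, v in cfg.items()
                             if k in _PARAM_KEYS})
    T = _require_number(cfg, "T", float)
    mods = {}
    for name, spec in (cfg.get("modulations") or {}).items():
        if not isinstance(spec, dict) or "offset" not in spec:
            raise ConfigError(
                f"modulation {name!r} must be a mapping with an 'offset'")
        unknown = set(spec) - {"offset", "amplitude", "phase"}
        if unknown:
            raise ConfigError(f"modulation {name!r} has unknown keys {sorted(unknown)}")
        mods[name] = Modulation(offset=float(spec["offset"]),
                                amplitude=float(spec.get("amplitude", 0.0)),
                                phase=float(spec.get("phase", 0.0)))
    kw = {}
    if "delta1" in cfg:
        kw["delta1"] = float(cfg["delta1"])
    if "delta2" in cfg:
        kw["delta2"] = float(cfg["delta2"])
    return PeriodicSchedule(base=base, T=T, modulations=mods, **kw)


def feedback_from_dict(cfg: dict) -> FeedbackParams:
    return FeedbackParams(k1=_require_number(cfg, "k1", float),
                          k2=float(cfg.get("k2", 0.0)))


def load_config(path) -> dict:
    """Load and structurally validate a YAML/JSON config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"config {path} must contain a mapping")
    return cfg


def params_to_dict(p: LatticeParams) -> dict:
    """Serializable form of a parameter set (round-trips exactly)."""
    d = {"n": p.n, "ell": p.ell, "lambda": [float(v) for v in p.lam],
         "alpha": [float(v) for v in p.alpha], "q": p.q, "r": p.r}
    if not p.entry_interaction:
        d["entry_interaction"] = False
    return d
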