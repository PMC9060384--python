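"""Result serialization: deterministic CSV/JSON writers with metadata.

Site indices are 1-based in every output.  Each artifact embeds the
parameter set, the package version, the seed (when randomness was involved)
and the solver tolerances, so a run can be reproduced from its output alone.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from . import __version__
from .config import params_to_dict
from .core import LatticeParams
from .steady_state import SteadyState
from .tasep import MCResult

__all__ = ["steady_state_frame", "mc_frame", "write_results"]


def steady_state_frame(ss: SteadyState) -> pd.DataFrame:
    """Tidy per-site table: site, reader density e, coverage y."""
    return pd.DataFrame({
        "site": np.arange(1, ss.e.size + 1),
        "e": ss.e,
        "y": ss.y,
    })


def mc_frame(mc: MCResult) -> pd.DataFrame:
    """Per-site table of MC reader density with standard errors."""
    return pd.DataFrame({
        "site": np.arange(1, mc.reader_density.size + 1),
        "reader_density": mc.reader_density,
        "se": mc.occupancy_se,
    })


def _summary(result):
    if isinstance(result, SteadyState):
        return {"R": result.R, "rho": result.rho, "residual": result.residual}
    if isinstance(result, MCResult):
        return {"flux": result.flux, "seed": result.seed,
                "n_replicates": result.n_replicates}
    raise TypeError(f"unsupported result type {type(result).__name__}")


def write_results(result, path, fmt="csv", params: LatticeParams | None = None,
                  extra_metadata: dict | None = None):
    """Write a result artifact to ``path`` as ``csv`` or ``json``.

    CSV output carries the metadata as leading ``#`` comment lines followed
    by the per-site table and a trailing summary block; JSON output nests
    ``metadata``, ``per_site`` and ``summary`` (numbers round-trip exactly
    through ``json``'s repr-based float encoding).
    """
    meta = {"version": __version__}
    if params is not None:
        meta["params"] = params_to_dict(params)
    if extra_metadata:
        meta.update(extra_metadata)
    if isinstance(result, SteadyState):
        frame = steady_state_frame(result)
    elif isinstance(result, MCResult):
        frame = mc_frame(result)
    else:
        raise TypeError(f"unsupported result type {type(result).__name__}")
    summary = _summary(result)

    if fmt == "json":
        payload = {
            "metadata": meta,
            "per_site": {c: [float(v) for v in frame[c]] if c != "site"
                         else [int(v) for v in frame[c]] for c in frame.columns},
            "summary": summary,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")
    elif fmt == "csv":
        with open(path, "w") as fh:
            fh.write(f"# {json.dumps(meta)}\n")
            frame.to_csv(fh, index=False)
            for k, v in summary.items():
                fh.write(f"# {k},{v}\n")
    else:
        raise ValueError(f"format must be 'csv' or 'json', got {fmt!r}")
    return path


def read_results_json(path) -> dict:
    """Round-trip loader for :func:`write_results`'s JSON flavour."""
    with open(path) as fh:
        return json.load(fh)
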