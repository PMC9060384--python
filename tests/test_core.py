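"""Vector field, coverage operator and state-space membership."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from efeiod import (
    LatticeParams,
    coverage,
    coverage_matrix,
    efeiod_rhs,
    in_state_space,
    output_rate,
    simulate,
)
from efeiod.fixtures import generate_fixture


def naive_coverage(x, ell):
    """Direct double-loop transcription of the window sum (test oracle)."""
    n = len(x)
    return np.array([sum(x[j] for j in range(max(0, i - ell + 1), i + 1))
                     for i in range(n)])


class TestCoverage:
    def test_width_one_window_is_identity(self):
        x = np.array([0.2, 0.7, 0.1])
        assert np.array_equal(coverage(x, 1), x)

    @pytest.mark.parametrize("ell", [1, 2, 3, 5, 8])
    def test_matches_naive_double_loop(self, ell, rng):
        x = rng.uniform(0, 1, 8)
        np.testing.assert_allclose(coverage(x, ell), naive_coverage(x, ell),
                                   atol=1e-14)

    def test_printed_three_site_example(self):
        y = coverage(np.array([0.4959, 0.2483, 0.2459]), 2)
        np.testing.assert_allclose(y, [0.4959, 0.7442, 0.4942], atol=1e-12)

    def test_full_footprint_empty_lattice(self):
        assert np.all(coverage(np.zeros(6), 6) == 0)

    @pytest.mark.parametrize("n,ell", [(5, 1), (5, 3), (7, 7)])
    def test_agrees_with_banded_matrix(self, n, ell, rng):
        x = rng.uniform(0, 1, n)
        np.testing.assert_allclose(coverage(x, ell),
                                   coverage_matrix(n, ell) @ x, atol=1e-14)

    def test_bad_footprint_rejected(self):
        with pytest.raises(ValueError):
            coverage(np.zeros(3), 4)


class TestCoverageProperties:
    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(data=st.data(),
           n=st.integers(min_value=1, max_value=12))
    def test_linearity_window_bounds_and_matrix_agreement(self, data, n):
        """Coverage is linear in the state, each y_i sums at most ell
        readers, and the operator equals its banded-matrix form."""
        ell = data.draw(st.integers(min_value=1, max_value=n))
        x = np.array(data.draw(st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=n, max_size=n)))
        y = coverage(x, ell)
        np.testing.assert_allclose(y, naive_coverage(x, ell), atol=1e-12)
        np.testing.assert_allclose(coverage(2.0 * x, ell), 2.0 * y, atol=1e-12)
        assert np.all(y <= x.sum() + 1e-12)
        assert np.all(y >= x - 1e-12)  # own reader always contributes
        np.testing.assert_allclose(y, coverage_matrix(n, ell) @ x, atol=1e-12)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(n=st.integers(min_value=1, max_value=10), seed=st.integers(0, 999))
    def test_mass_balance_of_field(self, n, seed):
        """Total density changes only through entry, exit and drop-off:
        sum(dx/dt) = f_0 - f_n - sum(g)."""
        rng_local = np.random.default_rng(seed)
        ell = int(rng_local.integers(1, n + 1))
        p, x = generate_fixture(n, ell, seed=seed)
        from efeiod.core import _fluxes
        f, g = _fluxes(x, p)
        assert efeiod_rhs(x, p).sum() == pytest.approx(
            f[0] - f[-1] - g.sum(), abs=1e-12)


class TestParams:
    def test_rate_sign_validation(self):
        with pytest.raises(ValueError):
            LatticeParams(3, 1, np.array([1.0, 0.0, 1, 1]), np.zeros(3))
        with pytest.raises(ValueError):
            LatticeParams(3, 1, np.ones(4), np.array([-0.1, 0, 0]))
        with pytest.raises(ValueError):
            LatticeParams(3, 4, np.ones(4), np.zeros(3))

    def test_energy_parameterization_splits_equally(self):
        p = LatticeParams.from_energy(4, 2, np.ones(5), np.zeros(4), E=3.0)
        assert p.q == pytest.approx(np.exp(1.5))
        assert p.r == pytest.approx(np.exp(-1.5))
        assert p.q * p.r == pytest.approx(1.0)
        assert p.energy == pytest.approx(3.0)


class TestVectorField:
    def test_empty_lattice_fills_first_site_only(self):
        p = LatticeParams.homogeneous(5, 2, lam=1.3, alpha=0.2, q=0.5, r=2.0)
        xdot = efeiod_rhs(np.zeros(5), p)
        assert xdot[0] == pytest.approx(1.3)
        assert np.all(xdot[1:] == 0)

    def test_vanishes_at_printed_equilibrium(self, example3_params):
        e = np.array([0.4959, 0.2483, 0.2459])
        # the printed densities are 4-digit roundings, so the field is only
        # zero to about that resolution
        assert np.max(np.abs(efeiod_rhs(e, example3_params))) < 5e-4

    def test_fully_repelling_three_site_transcription(self):
        """q = r = 0, ell = 1: hand-transcribed product form of the field."""
        lam = np.array([0.7, 1.1, 0.9, 1.3])
        al = np.array([0.2, 0.3, 0.1])
        p = LatticeParams(3, 1, lam, al, q=0.0, r=0.0)
        x = np.array([0.5, 0.5, 0.5])
        x1, x2, x3 = x
        expected = np.array([
            lam[0] * (1 - x1) * (1 - x2)
            - lam[1] * x1 * (1 - x2) * (1 - x3)
            - al[0] * x1 * (1 - x2),
            lam[1] * x1 * (1 - x2) * (1 - x3)
            - lam[2] * x2 * (1 - x1) * (1 - x3)
            - al[1] * x2 * (1 - x1) * (1 - x3),
            lam[2] * x2 * (1 - x1) * (1 - x3)
            - lam[3] * x3 * (1 - x2)
            - al[2] * x3 * (1 - x2),
        ])
        np.testing.assert_allclose(efeiod_rhs(x, p), expected, atol=1e-14)

    def test_reduces_to_classical_rfm(self, rng):
        """q=r=1, ell=1, alpha=0 collapses to the hopping-chain field."""
        n = 7
        lam = rng.uniform(0.2, 2.0, n + 1)
        p = LatticeParams(n, 1, lam, np.zeros(n))
        for _ in range(5):
            x = rng.uniform(0, 1, n)
            xp = np.concatenate([[1.0], x, [0.0]])  # virtual boundary sites
            rfm = np.array([
                lam[i - 1] * (xp[i - 1] if i > 1 else 1.0) * (1 - x[i - 1])
                - lam[i] * x[i - 1] * (1 - (x[i] if i < n else 0.0))
                for i in range(1, n + 1)])
            np.testing.assert_allclose(efeiod_rhs(x, p), rfm, atol=1e-13)

    def test_shape_mismatch_rejected(self, example3_params):
        with pytest.raises(ValueError):
            efeiod_rhs(np.zeros(4), example3_params)


class TestOutputRate:
    def test_empty_exit_site_gives_zero(self, example3_params):
        assert output_rate(np.zeros(3), example3_params) == 0.0

    def test_printed_equilibrium_arithmetic(self, example3_params):
        e = np.array([0.4959, 0.2483, 0.2459])
        assert output_rate(e, example3_params) == pytest.approx(
            1.01 * 0.2459, abs=1e-12)

    def test_no_existing_bond_factor_when_r_is_one(self, rng):
        p = LatticeParams.homogeneous(6, 2, lam=1.4, alpha=0.3)
        x = rng.uniform(0, 0.4, 6)
        assert output_rate(x, p) == pytest.approx((1.4 + 0.3) * x[-1])

    def test_full_footprint_interaction_factor_is_unity(self, rng):
        p = LatticeParams.homogeneous(4, 4, lam=1.0, alpha=0.0, q=2.0, r=0.5)
        x = np.zeros(4)
        x[-1] = 0.2
        assert output_rate(x, p) == pytest.approx(0.2)


class TestStateSpace:
    def test_origin_is_member(self):
        assert in_state_space(np.zeros(6), 2)

    def test_coverage_overflow_excluded(self):
        # box-feasible but the width-2 window at site 2 sums to 1.9
        x = np.array([1, 0.9, 0.5, 1, 1, 1.0])
        assert not in_state_space(x, 2)
        assert in_state_space(x, 1)

    def test_box_alone_suffices_for_unit_footprint(self, rng):
        assert in_state_space(rng.uniform(0, 1, 10), 1)


class TestDynamicsInvariants:
    def test_state_space_is_forward_invariant(self):
        """Randomly parameterised trajectories never leave H."""
        for seed in range(20):
            p, x0 = generate_fixture(n=6, ell=2, seed=seed)
            traj = simulate(p, x0, t_end=30.0)
            for state in traj.x:
                assert in_state_space(state, p.ell, tol=1e-9)

    def test_boundary_is_repelling(self):
        """From the empty lattice every density moves strictly inside."""
        p, _ = generate_fixture(n=5, ell=2, seed=3)
        traj = simulate(p, np.zeros(5), t_end=5.0,
                        t_eval=np.linspace(0.5, 5.0, 10))
        for state in traj.x:
            y = coverage(state, p.ell)
            assert np.all(state > 0) and np.all(state < 1)
            assert np.all(y > 0) and np.all(y < 1)

    def test_unit_cube_alone_is_not_invariant(self):
        """A box-feasible start with infeasible coverage escapes the box."""
        lam = np.ones(7)
        lam[0] = 0.01
        p = LatticeParams(6, 2, lam, np.full(6, 0.1), q=0.5, r=2.0)
        x0 = np.array([1, 0.9, 0.5, 1, 1, 1.0])
        assert not in_state_space(x0, 2)
        traj = simulate(p, x0, t_end=2.0, require_feasible=False,
                        t_eval=np.linspace(0, 2, 400))
        assert traj.x.max() > 1.0 + 1e-6

    def test_l1_distance_contracts(self, rng):
        """Trajectories from two feasible starts approach in L1."""
        for seed in (0, 1, 2):
            p, a = generate_fixture(n=6, ell=2, seed=seed)
            _, b = generate_fixture(n=6, ell=2, seed=seed + 100)
            grid = np.linspace(2.0, 80.0, 25)
            ta = simulate(p, a, t_end=80.0, t_eval=grid)
            tb = simulate(p, b, t_end=80.0, t_eval=grid)
            d = np.abs(ta.x - tb.x).sum(axis=1)
            assert np.all(np.diff(d) <= 1e-9)
            assert d[-1] < 1e-3
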