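"""Worm-like-chain sampler and closed-form theory."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rufflekit.errors import InsufficientDataError, InvalidParameterError
from rufflekit.wlc_sim import (
    ChainConformation,
    WLCParams,
    chain_measurements,
    sample_chain,
    sample_ensemble,
    sample_uniform_length_ensemble,
    theoretical_ree_sq,
)


class TestTheory:
    def test_zero_length_chain_has_zero_extension(self):
        assert theoretical_ree_sq(0.0, 5.0) == 0.0

    def test_direct_evaluation_at_L10_lp5(self):
        # 8 * 25 * (1 - 1 + e^-1) = 200/e
        assert theoretical_ree_sq(10.0, 5.0) == pytest.approx(200.0 / math.e, rel=1e-12)

    def test_rigid_rod_limit_small_L(self):
        # L << l_p: chain behaves as a rigid rod, <Ree^2> -> L^2
        val = theoretical_ree_sq(0.01, 5.0)
        assert val == pytest.approx(1.0e-4, rel=1e-3)

    def test_long_chain_asymptote(self):
        # L >> l_p: <Ree^2> -> 4 l_p L - 8 l_p^2
        l_p = 0.7
        L = 100.0 * l_p
        asymptote = 4.0 * l_p * L - 8.0 * l_p**2
        assert theoretical_ree_sq(L, l_p) == pytest.approx(asymptote, rel=1e-3)

    @given(st.floats(0.01, 50.0), st.floats(0.1, 20.0))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_in_L(self, L, l_p):
        assert theoretical_ree_sq(L * 1.01, l_p) > theoretical_ree_sq(L, l_p)

    def test_rejects_non_positive_persistence_length(self):
        with pytest.raises(InvalidParameterError):
            theoretical_ree_sq(1.0, 0.0)


class TestSampling:
    def test_rigid_rod_is_straight(self):
        chain = sample_chain(
            WLCParams(l_p=1e9, contour_length=10.0, step=0.05), seed=1
        )
        _, r_ee = chain_measurements(chain)
        assert r_ee == pytest.approx(10.0, abs=1e-6)

    def test_deterministic_under_fixed_seed(self):
        params = WLCParams(l_p=2.0, contour_length=5.0, step=0.05)
        a = sample_chain(params, seed=42)
        b = sample_chain(params, seed=42)
        assert np.array_equal(a.points, b.points)

    def test_segment_lengths_equal_step(self):
        chain = sample_chain(WLCParams(l_p=1.0, contour_length=3.0, step=0.05), seed=3)
        seg = np.linalg.norm(np.diff(chain.points, axis=0), axis=1)
        np.testing.assert_allclose(seg, 0.05, rtol=1e-9)

    def test_ensemble_mean_matches_theory(self):
        # 2000 chains at L=10, l_p=5: <Ree^2> within 3 standard errors of Eq. theory
        params = WLCParams(l_p=5.0, contour_length=10.0, step=0.05)
        ree_sq = np.array(
            [
                chain_measurements(sample_chain(params, seed=s))[1] ** 2
                for s in range(2000)
            ]
        )
        expected = theoretical_ree_sq(10.0, 5.0)
        se = ree_sq.std(ddof=1) / math.sqrt(len(ree_sq))
        assert abs(ree_sq.mean() - expected) < 3 * se

    def test_quenched_disorder_reciprocal_additivity(self):
        # 1/l_p_obs = 1/l_p + 1/l_p_int: disordered ensemble behaves as a WLC
        # with the combined persistence length, within Monte-Carlo error
        l_p, l_p_int = 5.0, 1.0
        l_obs = 1.0 / (1.0 / l_p + 1.0 / l_p_int)
        params = WLCParams(l_p=l_p, contour_length=6.0, step=0.05, l_p_int=l_p_int)
        ree_sq = np.array(
            [
                chain_measurements(sample_chain(params, seed=s))[1] ** 2
                for s in range(800)
            ]
        )
        expected = theoretical_ree_sq(6.0, l_obs)
        assert ree_sq.mean() == pytest.approx(expected, rel=0.10)

    def test_ree_never_exceeds_contour_length(self):
        params = WLCParams(l_p=0.8, contour_length=4.0, step=0.05)
        for s in range(1000):
            L, r_ee = chain_measurements(sample_chain(params, seed=s))
            assert r_ee <= L

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"l_p": -1.0, "contour_length": 5.0},
            {"l_p": 5.0, "contour_length": 0.0},
            {"l_p": 5.0, "contour_length": 0.01, "step": 0.05},
            {"l_p": 0.1, "contour_length": 5.0, "step": 0.05},  # step > l_p/5
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            WLCParams(**kwargs)


class TestMeasurements:
    def test_straight_three_point_chain(self):
        chain = ChainConformation(points=[[0, 0], [1, 0], [2, 0]], step=1.0)
        assert chain_measurements(chain) == (2.0, 2.0)

    def test_near_closed_loop_has_small_ree(self):
        n = 100
        theta = np.linspace(0, 2 * math.pi, n, endpoint=False)
        radius = 1.0
        pts = radius * np.column_stack((np.cos(theta), np.sin(theta)))
        step = float(np.linalg.norm(pts[1] - pts[0]))
        loop = np.concatenate((pts, pts[:1]))
        chain = ChainConformation(points=loop, step=step)
        L, r_ee = chain_measurements(chain)
        assert r_ee < 1e-9
        assert L == pytest.approx(n * step)

    def test_single_point_rejected_at_construction(self):
        with pytest.raises(InvalidParameterError):
            ChainConformation(points=[[0.0, 0.0]], step=1.0)


class TestEnsembles:
    def test_single_entry_gives_one_row(self):
        table = sample_ensemble(
            [WLCParams(l_p=5.0, contour_length=2.0, step=0.05)], 1, seed=0
        )
        assert len(table) == 1
        assert list(table.columns) == ["chain_id", "L_um", "Ree_um"]

    def test_reproducible_under_master_seed(self):
        params = [
            WLCParams(l_p=5.0, contour_length=L, step=0.05) for L in (2.0, 5.0, 8.0)
        ]
        a = sample_ensemble(params, 4, seed=9)
        b = sample_ensemble(params, 4, seed=9)
        assert a.equals(b)
        assert len(a) == 12

    def test_empty_params_list_rejected(self):
        with pytest.raises(InvalidParameterError):
            sample_ensemble([], 1, seed=0)

    def test_fitting_grid_ensemble_recovers_lp(self):
        from rufflekit.wlc_fit import fit_persistence_length

        params = [
            WLCParams(l_p=5.0, contour_length=float(L), step=0.05)
            for L in range(2, 21)
        ]
        table = sample_ensemble(params, 100, seed=7)
        result = fit_persistence_length(table)
        assert result.l_p_obs == pytest.approx(5.0, rel=0.10)

    def test_uniform_length_ensemble_bounds_and_determinism(self):
        a = sample_uniform_length_ensemble(50, 2.0, 20.0, l_p=5.0, seed=3)
        b = sample_uniform_length_ensemble(50, 2.0, 20.0, l_p=5.0, seed=3)
        assert a.equals(b)
        assert a["L_um"].between(1.9, 20.1).all()
        assert (a["Ree_um"] <= a["L_um"]).all()
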