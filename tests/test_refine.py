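"""Regularized refinement: objective, multi-start, series, uncertainties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trixs import ParameterVector, chi2, regularization_penalty
from trixs.refine import (
    RefinementConfig,
    parameter_uncertainty,
    refine_series,
    refine_timepoint,
)
from trixs.simulate import ReactionSchemeParams, simulate_dataset, simulate_trajectory


def _noiseless_data(fm, x, rel_err=1e-5):
    d0 = fm.iso(x)
    d2 = fm.aniso(x)
    sigma = rel_err * np.max(np.abs(d0))
    return (d0, d2, np.full_like(d0, sigma), np.full_like(d2, sigma))


class TestChi2:
    def test_model_equals_data_is_zero(self, fm_coarse):
        x = ParameterVector(3.1, 4.5, 1.2, 0.08, 0.6, 0.5, 0.2)
        d = _noiseless_data(fm_coarse, x)
        assert chi2(d[0], fm_coarse.iso(x), d[2], d[1], fm_coarse.aniso(x), d[3]) == 0.0

    def test_constant_residual_closed_form(self):
        n0, n2 = 11, 7
        c = chi2(
            np.ones(n0), np.zeros(n0), np.ones(n0),
            np.ones(n2), np.zeros(n2), np.ones(n2),
        )
        assert c == pytest.approx(n0 + n2)

    def test_matches_independent_sum(self):
        rng = np.random.default_rng(8)
        d0, m0, e0 = rng.normal(size=20), rng.normal(size=20), rng.uniform(0.5, 2, 20)
        d2, m2, e2 = rng.normal(size=15), rng.normal(size=15), rng.uniform(0.5, 2, 15)
        expected = sum(((a - b) / e) ** 2 for a, b, e in zip(d0, m0, e0))
        expected += sum(((a - b) / e) ** 2 for a, b, e in zip(d2, m2, e2))
        assert chi2(d0, m0, e0, d2, m2, e2) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            chi2(np.ones(3), np.zeros(3), np.array([1.0, 0.0, 1.0]))


class TestPenalty:
    def test_zero_cases(self):
        x = np.arange(7.0)
        assert regularization_penalty(x, x, 5.0) == 0.0
        assert regularization_penalty(x, x + 3, 0.0) == 0.0
        assert regularization_penalty(x, None, 5.0) == 0.0

    def test_closed_form(self):
        x = np.zeros(7)
        xp = np.zeros(7)
        xp[1] = 1.0
        xp[4] = 1.0
        assert regularization_penalty(x, xp, 3.0) == pytest.approx(6.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        lam=st.floats(0, 100),
        jump=st.floats(-2, 2),
        w=st.floats(0.1, 10),
    )
    def test_quadratic_scaling(self, lam, jump, w):
        x = np.zeros(7)
        xp = np.zeros(7)
        xp[2] = jump
        weights = np.ones(7)
        weights[2] = w
        got = regularization_penalty(x, xp, lam, weights)
        assert got == pytest.approx(lam * w * jump**2, rel=1e-10, abs=1e-12)


class TestTimepoint:
    def test_noiseless_recovery(self, fm_coarse):
        truth = ParameterVector(3.15, 4.7, 1.1, 0.09, 0.55, 0.6, 0.25)
        data = _noiseless_data(fm_coarse, truth)
        cfg = RefinementConfig(lam=0.0, restarts=8, seed=14)
        res = refine_timepoint(fm_coarse, data, None, cfg)
        assert abs(res.x[0] - truth.r12) < 0.02
        assert abs(res.x[1] - truth.r23) < 0.02
        assert abs(res.x[2] - truth.alpha) < 0.02
        assert np.all(np.abs(res.x[3:] - truth.to_array()[3:]) < 0.01)

    def test_more_restarts_never_worse(self, fm_coarse):
        truth = ParameterVector(3.15, 4.7, 1.1, 0.09, 0.55, 0.6, 0.25)
        d0 = fm_coarse.iso(truth)
        rng = np.random.default_rng(3)
        sigma = 0.05 * np.max(np.abs(d0))
        data = (
            d0 + rng.normal(0, sigma, d0.shape),
            fm_coarse.aniso(truth) + rng.normal(0, sigma, d0.shape),
            np.full_like(d0, sigma),
            np.full_like(d0, sigma),
        )
        few = refine_timepoint(
            fm_coarse, data, None, RefinementConfig(lam=0, restarts=1, seed=4)
        )
        many = refine_timepoint(
            fm_coarse, data, None, RefinementConfig(lam=0, restarts=6, seed=4)
        )
        assert many.objective <= few.objective + 1e-9
        # same seed: the single start is the first of the six
        assert many.restart_objectives[0] == pytest.approx(
            few.restart_objectives[0]
        )

    def test_pure_heating_identified(self, fm_coarse):
        heat_only = ParameterVector(3.1, 4.5, 1.2, 0.0, 0.5, 0.7, 0.0)
        data = _noiseless_data(fm_coarse, heat_only, rel_err=1e-4)
        cfg = RefinementConfig(lam=0.0, restarts=6, seed=1)
        res = refine_timepoint(fm_coarse, data, None, cfg)
        assert res.x[3] < 0.01  # A_iso ~ 0
        assert abs(res.x[5] - 0.7) < 0.01  # A_heat recovered


def _tiny_dataset(fm, noise=0.01, seed=0, t=None):
    if t is None:
        t = np.array([0.1, 0.3, 1.0])
    truth = simulate_trajectory(ReactionSchemeParams(), t, fm.gs)
    return t, truth, simulate_dataset(truth, t, fm, noise_level=noise, seed=seed)


class TestSeries:
    def test_unregularized_series_equals_independent(self, fm_coarse):
        t, truth, ds = _tiny_dataset(fm_coarse)
        cfg = RefinementConfig(lam=0.0, restarts=3, seed=6)
        series = refine_series(ds, fm_coarse, cfg)
        for i in range(len(t)):
            data_t = (ds.dS0[i], ds.dS2[i], ds.err0[i], ds.err2[i])
            rng = np.random.default_rng([cfg.seed, i])
            indep = refine_timepoint(fm_coarse, data_t, None, cfg, rng)
            assert np.allclose(series.x[i], indep.x)

    def test_strong_regularization_smooths_r23(self, fm_coarse):
        t = np.array([0.1, 0.2, 0.3, 0.5, 1.0])
        truth = simulate_trajectory(ReactionSchemeParams(), t, fm_coarse.gs)
        ds = simulate_dataset(truth, t, fm_coarse, noise_level=0.08, seed=12)
        free = refine_series(ds, fm_coarse, RefinementConfig(lam=0.0, restarts=3, seed=7))
        tied = refine_series(
            ds, fm_coarse, RefinementConfig(lam=1e5, restarts=3, seed=7)
        )
        tv = lambda y: np.sum(np.abs(np.diff(y)))
        assert tv(tied.column("r23")) <= tv(free.column("r23")) + 1e-9

    def test_q_permutation_invariance(self, fm_coarse):
        """chi2 is a sum over q, so permuting data and model together
        cannot change the refined parameters."""
        t, truth, ds = _tiny_dataset(fm_coarse)
        i = 1
        data_t = (ds.dS0[i], ds.dS2[i], ds.err0[i], ds.err2[i])
        x0 = truth[i].to_array()
        from trixs.refine import _objective_factory

        cfg = RefinementConfig(lam=0.0)
        obj = _objective_factory(fm_coarse, data_t, cfg, None)
        perm = np.random.default_rng(0).permutation(len(ds.q))
        data_p = (
            ds.dS0[i][perm], ds.dS2[i][perm], ds.err0[i][perm], ds.err2[i][perm]
        )

        class PermFM:
            def iso_array(self, x):
                return fm_coarse.iso_array(x)[perm]

            def aniso_array(self, x):
                return fm_coarse.aniso_array(x)[perm]

        obj_p = _objective_factory(PermFM(), data_p, cfg, None)
        assert obj(x0) == pytest.approx(obj_p(x0), rel=1e-12)


class TestUncertainty:
    def test_bounds_bracket_truth_and_hit_target_increase(self, fm_coarse):
        truth = ParameterVector(3.15, 4.7, 1.1, 0.09, 0.55, 0.6, 0.25)
        data = _noiseless_data(fm_coarse, truth, rel_err=1e-3)
        cfg = RefinementConfig(lam=0.0, restarts=6, seed=2)
        res = refine_timepoint(fm_coarse, data, None, cfg)
        bounds, flat = parameter_uncertainty(fm_coarse, data, res.x, cfg)
        from trixs.refine import _objective_factory

        obj = _objective_factory(fm_coarse, data, cfg, None)
        f0 = obj(res.x)
        for k in (1, 4):  # r23 and A_GP are well constrained here
            lo, hi = bounds[k]
            assert lo < truth.to_array()[k] < hi
            for edge in (lo, hi):
                x = res.x.copy()
                x[k] = edge
                assert obj(x) - f0 == pytest.approx(cfg.delta_objective, abs=1e-3)

    def test_absent_species_flags_flat_directions(self, fm_coarse):
        heat_only = ParameterVector(3.1, 4.5, 1.2, 0.0, 0.5, 0.7, 0.0)
        data = _noiseless_data(fm_coarse, heat_only, rel_err=1e-3)
        cfg = RefinementConfig(lam=0.0, restarts=4, seed=3)
        res = refine_timepoint(fm_coarse, data, None, cfg)
        _, flat = parameter_uncertainty(fm_coarse, data, res.x, cfg)
        flat_params = {name for name, _ in flat}
        assert "A_GP" in flat_params or "alpha" in flat_params
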