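"""Diffusion primitives: first-passage density, absorption, simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from sceneddm.ddm import (
    DDMParams,
    ParameterError,
    absorption_probability,
    dataset_loglik,
    simulate_trials,
    wfpt_density,
)

PAR = DDMParams(v=1.2, a=1.6, t0=0.3)
SYM = DDMParams(v=0.0, a=2.0, t0=0.3)  # driftless, symmetric start


class TestDensity:
    def test_zero_before_nondecision_time(self):
        assert wfpt_density(PAR.t0, "upper", PAR) == 0.0
        assert wfpt_density(0.1, "lower", PAR) == 0.0

    def test_nonnegative_and_continuous(self):
        t = np.linspace(0.301, 5.0, 2000)
        d = wfpt_density(t, "upper", PAR)
        assert np.all(d >= 0)
        assert np.max(np.abs(np.diff(d))) < 0.05  # no jumps on a fine grid

    def test_conservation_symmetric(self):
        """Total absorption mass is 1 for the driftless symmetric process."""
        total, _ = integrate.quad(
            lambda t: wfpt_density(t, "upper", SYM) + wfpt_density(t, "lower", SYM),
            SYM.t0, 90.0, limit=300,
        )
        assert total == pytest.approx(1.0, abs=1e-4)

    @pytest.mark.parametrize("boundary", ["upper", "lower"])
    def test_density_integrates_to_absorption_probability(self, boundary):
        p_upper = absorption_probability(PAR)
        expected = p_upper if boundary == "upper" else 1 - p_upper
        mass, _ = integrate.quad(
            lambda t: wfpt_density(t, boundary, PAR), PAR.t0, 60.0, limit=300
        )
        assert mass == pytest.approx(expected, abs=1e-4)

    def test_truncation_error_bounded_by_eps(self):
        """Halving eps changes the density by less than the coarser eps."""
        t = np.linspace(0.31, 3.0, 500)
        for eps in (1e-4, 1e-6):
            d1 = wfpt_density(t, "upper", PAR, eps=eps)
            d2 = wfpt_density(t, "upper", PAR, eps=eps / 2)
            assert np.max(np.abs(d1 - d2)) <= 2 * eps

    def test_invalid_inputs(self):
        with pytest.raises(ParameterError):
            wfpt_density(1.0, "upper", PAR, eps=1e-2)
        with pytest.raises(ParameterError):
            wfpt_density(1.0, "sideways", PAR)
        with pytest.raises(ParameterError):
            DDMParams(v=1.0, a=-1.0)
        with pytest.raises(ParameterError):
            DDMParams(v=1.0, a=1.0, z=1.5)


class TestAbsorption:
    def test_symmetric_is_half(self):
        assert absorption_probability(SYM) == pytest.approx(0.5)

    def test_closed_form_value(self):
        p = absorption_probability(DDMParams(v=1.0, a=2.0, z=1.0))
        expected = (1 - np.exp(-2.0)) / (1 - np.exp(-4.0))
        assert p == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(v=st.floats(min_value=-4, max_value=4))
    def test_monotone_in_drift(self, v):
        p1 = absorption_probability(DDMParams(v=v, a=1.5, t0=0.0))
        p2 = absorption_probability(DDMParams(v=v + 0.5, a=1.5, t0=0.0))
        assert p2 > p1

    def test_strong_drift_limit(self):
        assert absorption_probability(DDMParams(v=50.0, a=1.5)) == pytest.approx(1.0, abs=1e-6)

    def test_matches_simulation(self, _warm_numba):
        par = DDMParams(v=1.0, a=2.0, z=1.0, t0=0.0)
        n = 200_000
        _, choice = simulate_trials(
            (np.full(n, par.v), np.full(n, par.a), np.full(n, par.start),
             np.zeros(n)), seed=42,
        )
        p_hat = (choice == 1).mean()
        p = absorption_probability(par)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(p_hat - p) < 3 * se


class TestSimulator:
    def test_symmetric_choice_half(self, _warm_numba):
        n = 100_000
        rt, choice = simulate_trials(
            (np.zeros(n), np.full(n, 2.0), np.ones(n), np.full(n, 0.3)), seed=7
        )
        se = 0.5 / np.sqrt(n)
        assert abs((choice == 1).mean() - 0.5) < 3 * se

    def test_driftless_mean_decision_time(self, _warm_numba):
        """E[T] = z (a - z) = a^2/4 for the symmetric driftless process."""
        n = 100_000
        a = 2.0
        rt, choice = simulate_trials(
            (np.zeros(n), np.full(n, a), np.full(n, a / 2), np.full(n, 0.3)), seed=11
        )
        assert np.all(choice >= 0)
        mean_dec = (rt - 0.3).mean()
        assert mean_dec == pytest.approx(a**2 / 4, rel=0.02)

    def test_rt_exceeds_nondecision_time(self, _warm_numba):
        plist = [DDMParams(v=0.5, a=1.0, t0=0.25)] * 500
        rt, choice = simulate_trials(plist, seed=3)
        ok = choice >= 0
        assert np.all(rt[ok] > 0.25)

    def test_runaway_flagged_as_miss(self, _warm_numba):
        # tiny time cap forces unabsorbed paths
        rt, choice = simulate_trials(
            (np.zeros(50), np.full(50, 5.0), np.full(50, 2.5), np.zeros(50)),
            seed=1, t_max=0.01,
        )
        assert np.all(choice == -1)
        assert np.all(np.isnan(rt))

    def test_reproducible_under_seed(self, _warm_numba):
        args = (np.ones(100), np.full(100, 1.5), np.full(100, 0.75), np.zeros(100))
        rt1, c1 = simulate_trials(args, seed=9)
        rt2, c2 = simulate_trials(args, seed=9)
        assert np.array_equal(rt1, rt2) and np.array_equal(c1, c2)

    def test_dt_validation(self):
        with pytest.raises(ParameterError):
            simulate_trials((np.ones(2), np.ones(2), np.full(2, 0.5), np.zeros(2)),
                            seed=0, dt=0.01)


class TestDatasetLoglik:
    def test_single_trial_equals_log_density(self):
        rt, resp = np.array([0.8]), np.array([1])
        par = (np.array([1.0]), np.array([1.5]), np.array([0.75]), np.array([0.3]))
        ll = dataset_loglik(rt, resp, par)
        d = wfpt_density(0.8, "upper", DDMParams(v=1.0, a=1.5, t0=0.3))
        assert ll == pytest.approx(np.log(d), rel=1e-10)

    def test_additivity_on_duplication(self):
        rng = np.random.default_rng(0)
        n = 50
        rt = rng.uniform(0.4, 2.0, n)
        resp = rng.integers(0, 2, n)
        par = (rng.normal(1, 0.3, n), rng.uniform(1, 2, n), None, np.full(n, 0.3))
        par = (par[0], par[1], par[1] / 2, par[3])
        ll1 = dataset_loglik(rt, resp, par)
        ll2 = dataset_loglik(np.tile(rt, 2), np.tile(resp, 2),
                             tuple(np.tile(x, 2) for x in par))
        assert ll2 == pytest.approx(2 * ll1, rel=1e-12)

    def test_matches_naive_loop_oracle(self):
        rng = np.random.default_rng(5)
        n = 100
        rt = rng.uniform(0.35, 3.0, n)
        resp = rng.integers(0, 2, n)
        v = rng.normal(1, 0.5, n)
        a = rng.uniform(0.8, 2.5, n)
        t0 = rng.uniform(0.1, 0.3, n)
        ll = dataset_loglik(rt, resp, (v, a, a / 2, t0))
        naive = 0.0
        for i in range(n):
            par = DDMParams(v=v[i], a=a[i], t0=t0[i])
            side = "upper" if resp[i] == 1 else "lower"
            naive += np.log(max(wfpt_density(rt[i], side, par), 1e-300))
        assert ll == pytest.approx(naive, abs=1e-10)

    def test_rt_below_t0_hits_floor(self):
        ll, n_floored = dataset_loglik(
            np.array([0.1]), np.array([1]),
            (np.array([1.0]), np.array([1.5]), np.array([0.75]), np.array([0.3])),
            return_floored=True,
        )
        assert n_floored == 1
        assert ll == pytest.approx(np.log(1e-300))
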