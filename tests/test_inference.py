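"""Hierarchical estimation: model building, sampling, diagnostics, DIC."""

import math

import numpy as np
import pandas as pd
import pytest

from sceneddm.inference import (
    HierarchyError,
    ModelSpec,
    ModelSpecError,
    PosteriorTrace,
    Regression,
    build_model,
    compare,
    compute_dic,
    fit,
    gelman_rubin,
    model_grid,
    posterior_p,
    posterior_predictive,
)

from conftest import make_behaviour


@pytest.fixture(scope="module")
def tiny_fit(small_behaviour):
    """One small but real fit shared by the diagnostic tests."""
    spec = ModelSpec(name="v~SC", regressions={"v": Regression("SC")})
    model = build_model(small_behaviour, spec)
    trace = fit(model, chains=2, iterations=900, burn=100, seed=3, tune=300)
    return model, trace


class TestModelSpec:
    def test_both_covariates_rejected(self):
        with pytest.raises(ModelSpecError):
            ModelSpec(regressions={"v": Regression("SC"), "a": Regression("CE")})

    def test_unknown_target_rejected(self):
        with pytest.raises(ModelSpecError):
            ModelSpec(regressions={"t0": Regression("SC")})

    def test_condition_and_regression_exclusive(self):
        with pytest.raises(ModelSpecError):
            ModelSpec(v_by_condition=True, regressions={"v": Regression("SC")})


class TestBuildModel:
    def test_null_spec_structure(self, small_behaviour):
        spec = ModelSpec(name="null", a_by_instruction=False)
        m = build_model(small_behaviour, spec)
        S = m.n_subjects
        assert set(m.group_level) == {
            "mu_v", "sigma_v", "mu_log_a", "sigma_log_a", "mu_t0", "sigma_t0"
        }
        assert len(m.param_names) == 6 + 3 * S

    def test_quadratic_regression_structure(self, small_behaviour):
        spec = ModelSpec(
            regressions={"v": Regression("SC", "linear+quadratic")},
            a_by_instruction=True,
        )
        m = build_model(small_behaviour, spec)
        assert "beta_v_lin" in m.group_level and "beta_v_quad" in m.group_level
        assert "mu_log_a[speed]" in m.group_level
        assert "mu_log_a[accurate]" in m.group_level
        # covariate centred over included trials
        assert abs(m.x.mean()) < 1e-12

    def test_trial_drift_is_quadratic_in_covariate(self, small_behaviour):
        spec = ModelSpec(regressions={"v": Regression("SC", "linear+quadratic")})
        m = build_model(small_behaviour, spec)
        theta = np.zeros(m.n_params)
        # every subject's (beta_lin, beta_quad) = (0.5, -1.0); the squared
        # regressor is centred, so the prediction differs from 0.5x - x^2
        # only by a constant absorbed into the intercept
        theta[m.sl_Cs] = np.tile([0.5, -1.0], m.n_subjects)
        v, a, t0 = m.trial_params(theta)
        expected = 0.5 * m.x - 1.0 * (m.x**2 - (m.x**2).mean())
        assert np.allclose(v, expected)
        assert np.allclose(np.diff(v - expected), 0.0)

    def test_single_subject_rejected(self, small_behaviour):
        solo = small_behaviour[small_behaviour["subj_idx"] == 0]
        with pytest.raises(HierarchyError):
            build_model(solo, ModelSpec())


class TestFit:
    def test_retained_sample_arithmetic(self, tiny_fit):
        _, trace = tiny_fit
        assert trace.samples.shape[:2] == (2, 800)
        assert trace.n_retained == 2 * (900 - 100)

    def test_empty_trace_rejected(self, small_behaviour):
        model = build_model(small_behaviour, ModelSpec())
        with pytest.raises(ValueError):
            fit(model, chains=1, iterations=100, burn=100, seed=0)

    def test_reproducible_under_seed(self, small_behaviour):
        model = build_model(small_behaviour, ModelSpec())
        t1 = fit(model, chains=2, iterations=60, burn=20, seed=5, tune=20)
        t2 = fit(model, chains=2, iterations=60, burn=20, seed=5, tune=20)
        assert np.array_equal(t1.samples, t2.samples)


class TestGelmanRubin:
    def _trace(self, chains):
        chains = np.asarray(chains, float)[:, :, None]
        return PosteriorTrace(
            samples=chains, param_names=["theta"], group_level=["theta"],
            chains=chains.shape[0], iterations=chains.shape[1], burn=0,
        )

    def test_identical_chains(self):
        x = np.random.default_rng(0).normal(size=200)
        rhat = gelman_rubin(self._trace([x, x]))["theta"]
        n = x.size
        assert rhat == pytest.approx(math.sqrt((n - 1) / n), rel=1e-12)

    def test_offset_chains_inflate_rhat(self):
        """Two chains 10 SD apart: closed-form between-chain inflation."""
        rng = np.random.default_rng(1)
        n = 500
        a = rng.normal(0, 1, n)
        b = rng.normal(10, 1, n)
        rhat = gelman_rubin(self._trace([a, b]))["theta"]
        W = (a.var(ddof=1) + b.var(ddof=1)) / 2
        B_over_n = np.var([a.mean(), b.mean()], ddof=1)
        expected = math.sqrt(((n - 1) / n * W + B_over_n) / W)
        assert rhat == pytest.approx(expected, rel=1e-12)
        assert rhat > 1.5

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(self._trace([np.zeros(10)]))

    def test_well_mixed_fit_in_paper_band(self, tiny_fit):
        _, trace = tiny_fit
        rhat = gelman_rubin(trace)
        assert all(0.98 <= v <= 1.02 for v in rhat.values()), rhat


class TestPosteriorP:
    def _trace(self, values):
        return PosteriorTrace(
            samples=np.asarray(values, float)[None, :, None],
            param_names=["beta"], group_level=["beta"], chains=1,
            iterations=len(values), burn=0,
        )

    def test_all_negative(self):
        P, direction, p_below, p_above = posterior_p(self._trace([-1.0] * 100), "beta")
        assert (P, direction, p_below, p_above) == (0.0, "negative", 1.0, 0.0)

    def test_symmetric_about_zero(self):
        x = np.concatenate([np.linspace(-1, -0.01, 500), np.linspace(0.01, 1, 500)])
        P, _, p_below, p_above = posterior_p(self._trace(x), "beta")
        assert P == pytest.approx(0.5, abs=0.01)
        assert p_below + p_above == pytest.approx(1.0)

    def test_strong_negative_coefficient(self):
        """Posterior mean -3, SD 0.5: the opposite-tail mass is < 0.001."""
        x = np.random.default_rng(0).normal(-3, 0.5, 19_200)
        P, direction, _, _ = posterior_p(self._trace(x), "beta")
        assert direction == "negative"
        assert P < 0.001

    def test_tail_masses_sum_to_one_minus_point_mass(self):
        x = np.array([-1.0, 0.0, 1.0, 2.0])
        _, _, p_below, p_above = posterior_p(self._trace(x), "beta")
        assert p_below + p_above == pytest.approx(1 - 0.25)


class TestDIC:
    def test_point_mass_posterior_has_zero_pd(self):
        theta0 = np.array([1.3])
        trace = PosteriorTrace(
            samples=np.tile(theta0, (1, 50, 1)), param_names=["mu"],
            group_level=["mu"], chains=1, iterations=50, burn=0,
        )
        loglik = lambda th: -0.5 * float((th[0] - 2.0) ** 2)
        dic = compute_dic(trace, loglik_fn=loglik)
        assert dic == pytest.approx(-2 * loglik(theta0), rel=1e-12)  # pD = 0

    def test_conjugate_normal_mean_pd_is_one(self):
        """Flat-prior normal mean: effective parameter count pD ~ 1."""
        rng = np.random.default_rng(8)
        n, sigma = 50, 1.0
        y = rng.normal(0.7, sigma, n)
        post = rng.normal(y.mean(), sigma / np.sqrt(n), 20_000)
        trace = PosteriorTrace(
            samples=post[None, :, None], param_names=["mu"], group_level=["mu"],
            chains=1, iterations=post.size, burn=0,
        )
        loglik = lambda th: float(-0.5 * np.sum((y - th[0]) ** 2) / sigma**2)
        dic = compute_dic(trace, loglik_fn=loglik)
        d_at_mean = -2 * loglik(np.array([post.mean()]))
        p_d = dic - d_at_mean - (dic - d_at_mean) / 2  # recover pD = D_bar - D(mean)
        # direct computation instead of the algebra above
        devs = np.array([-2 * loglik(np.array([m])) for m in post])
        p_d = devs.mean() - d_at_mean
        assert p_d == pytest.approx(1.0, abs=0.1)
        assert dic == pytest.approx(devs.mean() + p_d, rel=1e-12)


class TestModelGrid:
    def test_condition_ladder_has_five_models(self):
        assert len(model_grid("condition_ladder")) == 5

    def test_regression_grid_default_and_extended(self):
        default = model_grid("regression_grid")
        assert len(default) == 12 + 1  # + null
        extended = model_grid("regression_grid", include_quadratic_only=True)
        assert len(extended) == 18 + 1

    def test_no_spec_mixes_covariates(self):
        for spec in model_grid("regression_grid", include_quadratic_only=True):
            covs = {r.covariate for r in spec.regressions.values()}
            assert len(covs) <= 1


class TestCompare:
    def test_delta_dic_subtraction(self):
        s1, s2 = ModelSpec(name="better"), ModelSpec(name="worse")
        table = compare([(s2, 171.0), (s1, 100.0)])
        assert list(table["model"]) == ["better", "worse"]
        assert table["ddic_vs_best"].iloc[1] == pytest.approx(-71.0)

    def test_single_fit_rejected(self):
        with pytest.raises(ValueError):
            compare([(ModelSpec(), 100.0)])

    def test_ranking_invariant_to_order(self):
        specs = [(ModelSpec(name=f"m{i}"), d) for i, d in enumerate([30.0, 10.0, 20.0])]
        t1 = compare(specs)
        t2 = compare(specs[::-1])
        assert list(t1["model"]) == list(t2["model"]) == ["m1", "m2", "m0"]

    def test_different_data_rejected(self):
        with pytest.raises(ValueError):
            compare([(ModelSpec(name="a"), 1.0), (ModelSpec(name="b"), 2.0)],
                    n_trials=[100, 200])


class TestPosteriorPredictive:
    def test_n_sims_rows_and_columns(self, tiny_fit, small_behaviour):
        model, trace = tiny_fit
        ppc = posterior_predictive(trace, model, small_behaviour, n_sims=20, seed=0)
        assert ppc.sims["sim"].nunique() == 20
        assert {"observed", "predicted", "lo95", "hi95"} <= set(ppc.table.columns)

    def test_observed_summaries_covered(self, tiny_fit, small_behaviour):
        """Model fitted to its own data reproduces accuracy and RT deciles.

        At least 90% of the observed per-cell summaries fall inside the
        central 95% of the predictive distribution.
        """
        model, trace = tiny_fit
        ppc = posterior_predictive(trace, model, small_behaviour, n_sims=60, seed=1)
        t = ppc.table.dropna(subset=["lo95"])
        covered = (t["observed"] >= t["lo95"]) & (t["observed"] <= t["hi95"])
        assert covered.mean() >= 0.9

    def test_zero_trials_rejected(self, tiny_fit):
        model, trace = tiny_fit
        empty = pd.DataFrame(columns=["rt", "response", "instruction"])
        n_orig = model.n_trials
        try:
            model.n_trials = 0
            with pytest.raises(ValueError):
                posterior_predictive(trace, model, empty, n_sims=2, seed=0)
        finally:
            model.n_trials = n_orig


class TestParameterRecovery:
    def test_quadratic_coefficient_recovered(self):
        """Posterior concentrates near the generating inverted-U coefficients."""
        data = make_behaviour(n_subjects=5, n_trials=240, seed=21, beta1=0.3, beta2=-1.0)
        spec = ModelSpec(regressions={"v": Regression("SC", "linear+quadratic")})
        model = build_model(data, spec)
        trace = fit(model, chains=2, iterations=600, burn=100, seed=4, tune=300)
        b2 = trace.get("beta_v_quad")
        assert b2.mean() < 0
        lo, hi = np.percentile(b2, [2.5, 97.5])
        assert lo < -1.0 < hi
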