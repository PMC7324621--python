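"""Hierarchical Bayesian estimation of drift-diffusion parameters.

The model mirrors the standard hierarchical DDM setup for speeded binary
decisions: every subject has their own drift intercept(s), (log) boundary
separation(s) and non-decision time, drawn from group-level normal
distributions, and trial-level drift/boundary can additionally be regressed
on a centred scene statistic (SC or CE) with linear and quadratic terms.
Boundary separation is modelled on the log scale so that arbitrary covariate
values keep ``a > 0``.  The starting point is fixed at ``a/2`` (accuracy
coding: the upper boundary is the correct response).

Sampling uses Metropolis-within-Gibbs: conjugate Gibbs draws for the group
means of drift and log-boundary, and adaptive random-walk Metropolis for
everything else.  Proposal step sizes adapt only during the tuning/burn-in
phase, so the retained trace is a valid Markov chain.

Model assessment follows the usual toolkit: DIC (``D_bar + pD`` with
``pD = D_bar - D(theta_bar)``), the classic Gelman–Rubin potential scale
reduction factor per group-level parameter, posterior tail masses for
coefficient tests, and posterior predictive checks that average summaries of
datasets simulated from posterior draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .ddm import LOGLIK_FLOOR, _loglik_vec, _simulate_core

__all__ = [
    "Regression",
    "ModelSpec",
    "Priors",
    "HierarchicalDDM",
    "PosteriorTrace",
    "build_model",
    "fit",
    "compute_dic",
    "gelman_rubin",
    "posterior_p",
    "posterior_predictive",
    "model_grid",
    "compare",
]

CONDITIONS = ("low", "medium", "high")
INSTRUCTIONS = ("speed", "accurate")
_FORMS = ("linear", "quadratic", "linear+quadratic")


class ModelSpecError(ValueError):
    """Invalid model specification."""


class HierarchyError(ValueError):
    """Data cannot support the hierarchical structure."""


@dataclass(frozen=True)
class Regression:
    """Trial-level regression of a DDM parameter on a scene statistic.

    ``form`` is "linear" (centred covariate), "quadratic" (squared centred
    covariate only) or "linear+quadratic".
    """

    covariate: str  # "SC" or "CE"
    form: str = "linear+quadratic"
    center: bool = True

    def __post_init__(self) -> None:
        if self.covariate not in ("SC", "CE"):
            raise ModelSpecError(f"covariate must be 'SC' or 'CE', got {self.covariate!r}")
        if self.form not in _FORMS:
            raise ModelSpecError(f"form must be one of {_FORMS}, got {self.form!r}")

    @property
    def has_linear(self) -> bool:
        return self.form in ("linear", "linear+quadratic")

    @property
    def has_quadratic(self) -> bool:
        return self.form in ("quadratic", "linear+quadratic")


@dataclass(frozen=True)
class ModelSpec:
    """Which DDM parameters vary, and how.

    ``v_by_condition`` / ``a_by_condition`` give each complexity condition its
    own subject- and group-level parameter; ``a_by_instruction`` estimates two
    boundary intercepts (speed, accurate).  ``regressions`` maps "v" and/or
    "a" to a :class:`Regression`.  A model never mixes SC and CE covariates.
    """

    name: str = "model"
    v_by_condition: bool = False
    a_by_condition: bool = False
    a_by_instruction: bool = True
    regressions: Mapping[str, Regression] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key in self.regressions:
            if key not in ("v", "a"):
                raise ModelSpecError(f"regression target must be 'v' or 'a', got {key!r}")
        covs = {r.covariate for r in self.regressions.values()}
        if len(covs) > 1:
            raise ModelSpecError(
                "a model must never include both SC and CE simultaneously "
                f"(got {sorted(covs)}); their collinearity destabilises the coefficients"
            )
        if "v" in self.regressions and self.v_by_condition:
            raise ModelSpecError("drift cannot both vary by condition and be regressed")
        if "a" in self.regressions and self.a_by_condition:
            raise ModelSpecError("boundary cannot both vary by condition and be regressed")

    @property
    def covariate(self) -> str | None:
        for r in self.regressions.values():
            return r.covariate
        return None


@dataclass(frozen=True)
class Priors:
    """Weakly-informative group-level priors (documented and configurable).

    Group drift mean ~ N(0, 5); group log-boundary mean ~ N(log 1.5, 1);
    group t0 mean ~ N(0.3, 0.25); group SDs half-normal; regression
    coefficients ~ N(0, 5).  Subject t0 is truncated to be positive.
    """

    mu_v_loc: float = 0.0
    mu_v_scale: float = 5.0
    sigma_v_scale: float = 1.0
    mu_loga_loc: float = math.log(1.5)
    mu_loga_scale: float = 1.0
    sigma_loga_scale: float = 0.5
    mu_t0_loc: float = 0.3
    mu_t0_scale: float = 0.25
    sigma_t0_scale: float = 0.25
    beta_scale: float = 5.0
    sigma_beta_scale: float = 0.5
    t0_floor: float = 1e-3


@dataclass
class PosteriorTrace:
    """MCMC trace: ``samples[chain, iteration, parameter]`` after burn-in."""

    samples: np.ndarray
    param_names: list[str]
    group_level: list[str]
    chains: int
    iterations: int
    burn: int
    seed: int | None = None

    @property
    def n_retained(self) -> int:
        return self.samples.shape[0] * self.samples.shape[1]

    def index(self, name: str) -> int:
        try:
            return self.param_names.index(name)
        except ValueError:
            raise KeyError(f"parameter {name!r} not in trace") from None

    def get(self, name: str, flat: bool = True) -> np.ndarray:
        col = self.samples[:, :, self.index(name)]
        return col.ravel() if flat else col

    def posterior_mean(self) -> np.ndarray:
        return self.samples.reshape(-1, self.samples.shape[2]).mean(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        c, n, p = self.samples.shape
        df = pd.DataFrame(self.samples.reshape(c * n, p), columns=self.param_names)
        df.insert(0, "chain", np.repeat(np.arange(c), n))
        df.insert(1, "iter", np.tile(np.arange(n) + self.burn, c))
        return df


# ---------------------------------------------------------------------------
# model object
# ---------------------------------------------------------------------------


class HierarchicalDDM:
    """Hierarchical DDM bound to a trial table.

    Expects columns ``subj_idx, rt, response, instruction`` plus ``condition``
    (for condition models) and ``SC``/``CE`` (for regression models).
    ``response`` is 1 for the upper (correct) boundary, 0 for the lower.
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec, priors: Priors | None = None):
        self.spec = spec
        self.priors = priors or Priors()
        required = {"subj_idx", "rt", "response", "instruction"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"data is missing columns {sorted(missing)}")
        data = data.reset_index(drop=True)
        self.subjects = np.array(sorted(data["subj_idx"].unique()))
        self.n_subjects = len(self.subjects)
        if self.n_subjects < 2:
            raise HierarchyError(
                f"hierarchical estimation needs at least 2 subjects, got {self.n_subjects}"
            )
        subj_map = {s: i for i, s in enumerate(self.subjects)}
        self.subj = data["subj_idx"].map(subj_map).to_numpy(np.int64)
        self.rt = np.ascontiguousarray(data["rt"].to_numpy(float))
        if np.any(~np.isfinite(self.rt)) or np.any(self.rt <= 0):
            raise ValueError("rt must be finite and positive (drop misses before fitting)")
        self.response = np.ascontiguousarray(data["response"].to_numpy(np.int64))
        if not np.isin(self.response, (0, 1)).all():
            raise ValueError("response must be coded 0/1")
        self.n_trials = len(data)

        # grouping structures ------------------------------------------------
        if spec.v_by_condition or spec.a_by_condition:
            if "condition" not in data.columns:
                raise ValueError("condition column required for condition models")
            cond = data["condition"].astype(str).to_numpy()
            bad = set(cond) - set(CONDITIONS)
            if bad:
                raise ValueError(f"unknown condition labels {sorted(bad)}")
            cond_idx = np.array([CONDITIONS.index(c) for c in cond])
        else:
            cond_idx = np.zeros(self.n_trials, dtype=np.int64)

        instr = data["instruction"].astype(str).to_numpy()
        bad = set(instr) - set(INSTRUCTIONS)
        if bad:
            raise ValueError(f"unknown instruction labels {sorted(bad)}")
        instr_idx = np.array([INSTRUCTIONS.index(i) for i in instr])

        self.v_group_names = list(CONDITIONS) if spec.v_by_condition else ["0"]
        self.v_group = cond_idx if spec.v_by_condition else np.zeros(self.n_trials, np.int64)

        a_names: list[str] = []
        a_group = np.zeros(self.n_trials, dtype=np.int64)
        if spec.a_by_instruction and spec.a_by_condition:
            for i, ins in enumerate(INSTRUCTIONS):
                for c, con in enumerate(CONDITIONS):
                    a_names.append(f"{ins},{con}")
            a_group = instr_idx * len(CONDITIONS) + cond_idx
        elif spec.a_by_instruction:
            a_names = list(INSTRUCTIONS)
            a_group = instr_idx
        elif spec.a_by_condition:
            a_names = list(CONDITIONS)
            a_group = cond_idx
        else:
            a_names = ["0"]
        self.a_group_names = a_names
        self.a_group = a_group

        # covariate ----------------------------------------------------------
        cov = spec.covariate
        if cov is not None:
            if cov not in data.columns:
                raise ValueError(f"covariate column {cov!r} missing from data")
            x = data[cov].to_numpy(float)
            if np.any(~np.isfinite(x)):
                raise ValueError(f"covariate {cov} contains non-finite values")
            center = any(r.center for r in spec.regressions.values())
            self.x = x - x.mean() if center else x.copy()
        else:
            self.x = np.zeros(self.n_trials)
        # the squared regressor is itself centred so the quadratic
        # coefficient decorrelates from the intercept (the intercept then
        # refers to the average-complexity trial); pure reparameterization,
        # the coefficients are unchanged
        self.x2 = self.x**2 - (self.x**2).mean()

        # active regression coefficients, in a fixed order; each one is
        # hierarchical (group mean/SD + one value per subject)
        self.coef_names: list[str] = []
        self.coef_target: list[str] = []   # "v" or "a" per coefficient
        self.coef_power: list[int] = []    # 1 (linear) or 2 (quadratic)
        for target in ("v", "a"):
            reg = spec.regressions.get(target)
            if reg is None:
                continue
            if reg.has_linear:
                self.coef_names.append(f"beta_{target}_lin")
                self.coef_target.append(target)
                self.coef_power.append(1)
            if reg.has_quadratic:
                self.coef_names.append(f"beta_{target}_quad")
                self.coef_target.append(target)
                self.coef_power.append(2)
        self.K = len(self.coef_names)

        # parameter vector layout -------------------------------------------
        Gv, Ga, S = len(self.v_group_names), len(self.a_group_names), self.n_subjects
        K = self.K
        names: list[str] = []
        names += [f"mu_v[{g}]" if Gv > 1 else "mu_v" for g in self.v_group_names]
        names += ["sigma_v"]
        names += [f"mu_log_a[{g}]" if Ga > 1 else "mu_log_a" for g in self.a_group_names]
        names += ["sigma_log_a", "mu_t0", "sigma_t0"]
        for name in self.coef_names:  # group mean keeps the plain beta name
            names += [name, f"sigma_{name}"]
        self.group_level = list(names)
        for s in range(S):
            for g in self.v_group_names:
                names.append(f"v[s{s},{g}]" if Gv > 1 else f"v[s{s}]")
        for s in range(S):
            for g in self.a_group_names:
                names.append(f"log_a[s{s},{g}]" if Ga > 1 else f"log_a[s{s}]")
        names += [f"t0[s{s}]" for s in range(S)]
        for s in range(S):
            names += [f"{n}[s{s}]" for n in self.coef_names]
        self.param_names = names
        self.Gv, self.Ga, self.S = Gv, Ga, S

        # index slices into the flat vector
        i = 0
        self.sl_mu_v = slice(i, i + Gv); i += Gv
        self.i_sigma_v = i; i += 1
        self.sl_mu_la = slice(i, i + Ga); i += Ga
        self.i_sigma_la = i; i += 1
        self.i_mu_t0 = i; i += 1
        self.i_sigma_t0 = i; i += 1
        self.sl_coef = slice(i, i + 2 * K); i += 2 * K  # (mu, sigma) per coefficient
        self.sl_Vs = slice(i, i + S * Gv); i += S * Gv
        self.sl_LAs = slice(i, i + S * Ga); i += S * Ga
        self.sl_T0s = slice(i, i + S); i += S
        self.sl_Cs = slice(i, i + S * K); i += S * K
        self.n_params = i

        # per-update trial index lists
        self.idx_subj = [np.flatnonzero(self.subj == s) for s in range(S)]
        self.idx_v = [
            [np.flatnonzero((self.subj == s) & (self.v_group == g)) for g in range(Gv)]
            for s in range(S)
        ]
        self.idx_a = [
            [np.flatnonzero((self.subj == s) & (self.a_group == g)) for g in range(Ga)]
            for s in range(S)
        ]
        self.min_rt_subj = np.array([self.rt[self.idx_subj[s]].min() for s in range(S)])
        self.w = np.full(self.n_trials, 0.5)
        self.eps = 1e-8

    def coef_column(self, j: int) -> np.ndarray:
        """Covariate column (centred x or x^2) for coefficient j."""
        return self.x if self.coef_power[j] == 1 else self.x2

    # -- vector <-> structured views ---------------------------------------
    def unpack(self, theta: np.ndarray):
        S, Gv, Ga, K = self.S, self.Gv, self.Ga, self.K
        return {
            "mu_v": theta[self.sl_mu_v],
            "sigma_v": theta[self.i_sigma_v],
            "mu_la": theta[self.sl_mu_la],
            "sigma_la": theta[self.i_sigma_la],
            "mu_t0": theta[self.i_mu_t0],
            "sigma_t0": theta[self.i_sigma_t0],
            "coef_group": theta[self.sl_coef].reshape(K, 2) if K else np.empty((0, 2)),
            "Vs": theta[self.sl_Vs].reshape(S, Gv),
            "LAs": theta[self.sl_LAs].reshape(S, Ga),
            "T0s": theta[self.sl_T0s],
            "Cs": theta[self.sl_Cs].reshape(S, K) if K else np.empty((S, 0)),
        }

    def trial_params(self, theta: np.ndarray):
        """Per-trial (v, a, t0) arrays implied by a flat parameter vector."""
        p = self.unpack(theta)
        v = p["Vs"][self.subj, self.v_group].copy()
        log_a = p["LAs"][self.subj, self.a_group].copy()
        for j in range(self.K):
            contrib = p["Cs"][self.subj, j] * self.coef_column(j)
            if self.coef_target[j] == "v":
                v += contrib
            else:
                log_a += contrib
        t0 = p["T0s"][self.subj]
        return v, np.exp(log_a), t0

    def loglik(self, theta: np.ndarray) -> float:
        v, a, t0 = self.trial_params(theta)
        ll = _loglik_vec(self.rt, self.response, v, a, self.w, t0, self.eps, LOGLIK_FLOOR)
        return float(ll.sum())


def build_model(
    data: pd.DataFrame, spec: ModelSpec, priors: Priors | None = None
) -> HierarchicalDDM:
    """Construct a hierarchical DDM bound to a trial table (see class docs)."""
    return HierarchicalDDM(data, spec, priors)


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------


def _log_halfnormal(x: float, scale: float) -> float:
    if x <= 0:
        return -np.inf
    return -0.5 * (x / scale) ** 2


def _log_truncnorm0(x: np.ndarray, mu: float, sigma: float) -> float:
    """Sum of log-density of N(mu, sigma) truncated to x > 0."""
    if sigma <= 0 or np.any(x <= 0):
        return -np.inf
    z = (x - mu) / sigma
    lognorm = math.log(max(norm.cdf(mu / sigma), 1e-300))
    return float(np.sum(-0.5 * z**2) - x.size * (math.log(sigma) + lognorm))


class _ChainState:
    """Mutable per-chain sampler state with cached trial-level arrays."""

    def __init__(self, model: HierarchicalDDM, rng: np.random.Generator):
        m, pr = model, model.priors
        S, Gv, Ga = m.S, m.Gv, m.Ga
        self.Vs = rng.normal(1.0, 0.3, size=(S, Gv))
        self.LAs = rng.normal(math.log(1.5), 0.15, size=(S, Ga))
        t0_init = np.minimum(0.5 * m.min_rt_subj, 0.35)
        self.T0s = np.clip(t0_init * rng.uniform(0.7, 1.0, size=S), pr.t0_floor, None)
        self.mu_v = self.Vs.mean(axis=0)
        self.sigma_v = 0.3
        self.mu_la = self.LAs.mean(axis=0)
        self.sigma_la = 0.2
        self.mu_t0 = float(np.mean(self.T0s))
        self.sigma_t0 = 0.05
        self.mu_c = rng.normal(0.0, 0.05, size=m.K)
        self.sigma_c = np.full(m.K, 0.1)
        self.Cs = self.mu_c[None, :] + rng.normal(0.0, 0.05, size=(S, m.K))
        self.refresh_trials(m)

    def refresh_trials(self, m: HierarchicalDDM) -> None:
        self.v_tr = self.Vs[m.subj, m.v_group].copy()
        self.la_tr = self.LAs[m.subj, m.a_group].copy()
        for j in range(m.K):
            contrib = self.Cs[m.subj, j] * m.coef_column(j)
            if m.coef_target[j] == "v":
                self.v_tr += contrib
            else:
                self.la_tr += contrib
        self.t0_tr = self.T0s[m.subj]
        self.ll_tr = _loglik_vec(
            m.rt, m.response, self.v_tr, np.exp(self.la_tr), m.w, self.t0_tr,
            m.eps, LOGLIK_FLOOR,
        )

    def pack(self, m: HierarchicalDDM) -> np.ndarray:
        out = np.empty(m.n_params)
        out[m.sl_mu_v] = self.mu_v
        out[m.i_sigma_v] = self.sigma_v
        out[m.sl_mu_la] = self.mu_la
        out[m.i_sigma_la] = self.sigma_la
        out[m.i_mu_t0] = self.mu_t0
        out[m.i_sigma_t0] = self.sigma_t0
        out[m.sl_coef] = np.column_stack([self.mu_c, self.sigma_c]).ravel()
        out[m.sl_Vs] = self.Vs.ravel()
        out[m.sl_LAs] = self.LAs.ravel()
        out[m.sl_T0s] = self.T0s
        out[m.sl_Cs] = self.Cs.ravel()
        return out


def _subset_ll(m: HierarchicalDDM, idx, v, la, t0):
    return _loglik_vec(
        m.rt[idx], m.response[idx], v, np.exp(la), m.w[: idx.size], t0,
        m.eps, LOGLIK_FLOOR,
    )


def _run_chain(model, iterations, burn, tune, rng, progress=False):
    m, pr = model, model.priors
    st = _ChainState(m, rng)
    for _ in range(20):
        if np.isfinite(st.ll_tr.sum()):
            break
        st = _ChainState(m, rng)
    else:
        raise RuntimeError("could not find finite initial likelihood after 20 redraws")

    S, Gv, Ga = m.S, m.Gv, m.Ga
    # adaptive log step sizes, one per scalar update
    ls = {
        "sigma_v": math.log(0.3), "sigma_la": math.log(0.3),
        "mu_t0": math.log(0.02), "sigma_t0": math.log(0.3),
    }
    for j in range(m.K):
        ls[f"sigma_c{j}"] = math.log(0.5)
        ls[f"rescale_c{j}"] = math.log(0.3)
    ls_V = np.full((S, Gv), math.log(0.25))
    ls_LA = np.full((S, Ga), math.log(0.08))
    ls_T0 = np.full(S, math.log(0.015))
    ls_C = np.full((S, m.K), math.log(0.15))

    kept = np.empty((iterations - burn, m.n_params))
    n_adapt_total = tune + burn
    t_step = 0

    def adapt(key_scale: float, alpha: float, store, key=None) -> float:
        gamma = 6.0 / (60.0 + t_step)
        new = key_scale + gamma * (alpha - 0.44)
        return min(max(new, -12.0), 4.0)

    total_iters = tune + iterations
    for it in range(total_iters):
        adapting = it < n_adapt_total
        t_step = it + 1

        # --- group level: conjugate means + RW scales -----------------------
        # These updates cost no likelihood evaluations, so several sweeps per
        # iteration buy faster hyperparameter mixing essentially for free.
        for _sweep in range(3):
            for g in range(Gv):
                vals = st.Vs[:, g]
                prec = S / st.sigma_v**2 + 1.0 / pr.mu_v_scale**2
                mean = (vals.sum() / st.sigma_v**2 + pr.mu_v_loc / pr.mu_v_scale**2) / prec
                st.mu_v[g] = rng.normal(mean, 1.0 / math.sqrt(prec))
            for g in range(Ga):
                vals = st.LAs[:, g]
                prec = S / st.sigma_la**2 + 1.0 / pr.mu_loga_scale**2
                mean = (vals.sum() / st.sigma_la**2
                        + pr.mu_loga_loc / pr.mu_loga_scale**2) / prec
                st.mu_la[g] = rng.normal(mean, 1.0 / math.sqrt(prec))

            for key, get, set_, vals_fn, mu_fn, hn_scale in (
                ("sigma_v", lambda: st.sigma_v, lambda x: setattr(st, "sigma_v", x),
                 lambda: st.Vs, lambda: st.mu_v, pr.sigma_v_scale),
                ("sigma_la", lambda: st.sigma_la, lambda x: setattr(st, "sigma_la", x),
                 lambda: st.LAs, lambda: st.mu_la, pr.sigma_loga_scale),
            ):
                cur = get()
                prop = cur * math.exp(math.exp(ls[key]) * rng.standard_normal())
                vals, mus = vals_fn(), mu_fn()
                n_v = vals.size

                def _lp(s):
                    return (
                        _log_halfnormal(s, hn_scale) + math.log(s)  # prior + Jacobian
                        - n_v * math.log(s)
                        - 0.5 * float(np.sum((vals - mus[None, :]) ** 2)) / s**2
                    )

                alpha = math.exp(min(0.0, _lp(prop) - _lp(cur)))
                if rng.random() < alpha:
                    set_(prop)
                if adapting:
                    ls[key] = adapt(ls[key], alpha, ls)

            # t0 group mean and SD (truncated-normal subject prior)
            cur = st.mu_t0
            prop = cur + math.exp(ls["mu_t0"]) * rng.standard_normal()
            lp_cur = (-0.5 * ((cur - pr.mu_t0_loc) / pr.mu_t0_scale) ** 2
                      + _log_truncnorm0(st.T0s, cur, st.sigma_t0))
            lp_prop = (-0.5 * ((prop - pr.mu_t0_loc) / pr.mu_t0_scale) ** 2
                       + _log_truncnorm0(st.T0s, prop, st.sigma_t0))
            alpha = math.exp(min(0.0, lp_prop - lp_cur))
            if rng.random() < alpha:
                st.mu_t0 = prop
            if adapting:
                ls["mu_t0"] = adapt(ls["mu_t0"], alpha, ls)

            cur = st.sigma_t0
            prop = cur * math.exp(math.exp(ls["sigma_t0"]) * rng.standard_normal())
            lp_cur = (_log_halfnormal(cur, pr.sigma_t0_scale) + math.log(cur)
                      + _log_truncnorm0(st.T0s, st.mu_t0, cur))
            lp_prop = (_log_halfnormal(prop, pr.sigma_t0_scale) + math.log(prop)
                       + _log_truncnorm0(st.T0s, st.mu_t0, prop))
            alpha = math.exp(min(0.0, lp_prop - lp_cur))
            if rng.random() < alpha:
                st.sigma_t0 = prop
            if adapting:
                ls["sigma_t0"] = adapt(ls["sigma_t0"], alpha, ls)

            for j in range(m.K):
                # Gibbs: group mean of coefficient j
                prec = S / st.sigma_c[j] ** 2 + 1.0 / pr.beta_scale**2
                mean = (st.Cs[:, j].sum() / st.sigma_c[j] ** 2) / prec
                st.mu_c[j] = rng.normal(mean, 1.0 / math.sqrt(prec))

                # RW: group SD of coefficient j
                key = f"sigma_c{j}"
                cur = st.sigma_c[j]
                prop = cur * math.exp(math.exp(ls[key]) * rng.standard_normal())
                dev2 = float(np.sum((st.Cs[:, j] - st.mu_c[j]) ** 2))

                def _lp_sc(s):
                    return (_log_halfnormal(s, pr.sigma_beta_scale) + math.log(s)
                            - S * math.log(s) - 0.5 * dev2 / s**2)

                alpha = math.exp(min(0.0, _lp_sc(prop) - _lp_sc(cur)))
                if rng.random() < alpha:
                    st.sigma_c[j] = prop
                if adapting:
                    ls[key] = adapt(ls[key], alpha, ls)

        # --- RW: subject drift intercepts -----------------------------------
        for s in range(S):
            for g in range(Gv):
                idx = m.idx_v[s][g]
                if idx.size == 0:
                    # no data: draw from the group distribution
                    st.Vs[s, g] = rng.normal(st.mu_v[g], st.sigma_v)
                    continue
                cur = st.Vs[s, g]
                prop = cur + math.exp(ls_V[s, g]) * rng.standard_normal()
                delta = prop - cur
                ll_new = _subset_ll(m, idx, st.v_tr[idx] + delta, st.la_tr[idx], st.t0_tr[idx])
                dprior = (-0.5 * ((prop - st.mu_v[g]) / st.sigma_v) ** 2
                          + 0.5 * ((cur - st.mu_v[g]) / st.sigma_v) ** 2)
                alpha = math.exp(min(0.0, dprior + float(ll_new.sum() - st.ll_tr[idx].sum())))
                if rng.random() < alpha:
                    st.Vs[s, g] = prop
                    st.v_tr[idx] += delta
                    st.ll_tr[idx] = ll_new
                if adapting:
                    ls_V[s, g] = adapt(ls_V[s, g], alpha, ls_V)

        # --- RW: subject log-boundaries --------------------------------------
        for s in range(S):
            for g in range(Ga):
                idx = m.idx_a[s][g]
                if idx.size == 0:
                    st.LAs[s, g] = rng.normal(st.mu_la[g], st.sigma_la)
                    continue
                cur = st.LAs[s, g]
                prop = cur + math.exp(ls_LA[s, g]) * rng.standard_normal()
                delta = prop - cur
                ll_new = _subset_ll(m, idx, st.v_tr[idx], st.la_tr[idx] + delta, st.t0_tr[idx])
                dprior = (-0.5 * ((prop - st.mu_la[g]) / st.sigma_la) ** 2
                          + 0.5 * ((cur - st.mu_la[g]) / st.sigma_la) ** 2)
                alpha = math.exp(min(0.0, dprior + float(ll_new.sum() - st.ll_tr[idx].sum())))
                if rng.random() < alpha:
                    st.LAs[s, g] = prop
                    st.la_tr[idx] += delta
                    st.ll_tr[idx] = ll_new
                if adapting:
                    ls_LA[s, g] = adapt(ls_LA[s, g], alpha, ls_LA)

        # --- RW: subject non-decision times ----------------------------------
        for s in range(S):
            idx = m.idx_subj[s]
            cur = st.T0s[s]
            prop = cur + math.exp(ls_T0[s]) * rng.standard_normal()
            if prop <= pr.t0_floor:
                alpha = 0.0
            else:
                ll_new = _subset_ll(m, idx, st.v_tr[idx], st.la_tr[idx],
                                    np.full(idx.size, prop))
                dprior = (-0.5 * ((prop - st.mu_t0) / st.sigma_t0) ** 2
                          + 0.5 * ((cur - st.mu_t0) / st.sigma_t0) ** 2)
                alpha = math.exp(min(0.0, dprior + float(ll_new.sum() - st.ll_tr[idx].sum())))
                if rng.random() < alpha:
                    st.T0s[s] = prop
                    st.t0_tr[idx] = prop
                    st.ll_tr[idx] = ll_new
            if adapting:
                ls_T0[s] = adapt(ls_T0[s], alpha, ls_T0)

        # --- hierarchical regression coefficients (subject level) -----------
        for j in range(m.K):
            xcol = m.coef_column(j)
            on_v = m.coef_target[j] == "v"

            # RW: subject-level coefficients (touch that subject's trials)
            for s in range(S):
                idx = m.idx_subj[s]
                cur = st.Cs[s, j]
                prop = cur + math.exp(ls_C[s, j]) * rng.standard_normal()
                delta = prop - cur
                if on_v:
                    ll_new = _subset_ll(m, idx, st.v_tr[idx] + delta * xcol[idx],
                                        st.la_tr[idx], st.t0_tr[idx])
                else:
                    ll_new = _subset_ll(m, idx, st.v_tr[idx],
                                        st.la_tr[idx] + delta * xcol[idx], st.t0_tr[idx])
                dprior = (-0.5 * ((prop - st.mu_c[j]) / st.sigma_c[j]) ** 2
                          + 0.5 * ((cur - st.mu_c[j]) / st.sigma_c[j]) ** 2)
                alpha = math.exp(min(0.0, dprior + float(ll_new.sum() - st.ll_tr[idx].sum())))
                if rng.random() < alpha:
                    st.Cs[s, j] = prop
                    if on_v:
                        st.v_tr[idx] += delta * xcol[idx]
                    else:
                        st.la_tr[idx] += delta * xcol[idx]
                    st.ll_tr[idx] = ll_new
                if adapting:
                    ls_C[s, j] = adapt(ls_C[s, j], alpha, ls_C)

            # parameter-expansion rescale: move along the (sigma, deviations)
            # funnel axis jointly so the group SD mixes even when the subject
            # coefficients are nearly identical
            key = f"rescale_c{j}"
            c = math.exp(math.exp(ls[key]) * rng.standard_normal())
            sig_new = st.sigma_c[j] * c
            cs_new = st.mu_c[j] + c * (st.Cs[:, j] - st.mu_c[j])
            delta_cs = cs_new - st.Cs[:, j]
            if on_v:
                v_new = st.v_tr + delta_cs[m.subj] * xcol
                ll_new = _loglik_vec(m.rt, m.response, v_new, np.exp(st.la_tr),
                                     m.w, st.t0_tr, m.eps, LOGLIK_FLOOR)
            else:
                la_new = st.la_tr + delta_cs[m.subj] * xcol
                ll_new = _loglik_vec(m.rt, m.response, st.v_tr, np.exp(la_new),
                                     m.w, st.t0_tr, m.eps, LOGLIK_FLOOR)
            # subject-prior deviations rescale exactly with sigma, leaving the
            # quadratic form invariant; the density picks up -S log c, the
            # transform Jacobian is (S + 1) log c, and the half-normal prior
            # on sigma changes too
            dlog = (_log_halfnormal(sig_new, pr.sigma_beta_scale)
                    - _log_halfnormal(st.sigma_c[j], pr.sigma_beta_scale)
                    - S * math.log(c) + (S + 1) * math.log(c)
                    + float(ll_new.sum() - st.ll_tr.sum()))
            alpha = math.exp(min(0.0, dlog))
            if rng.random() < alpha:
                st.sigma_c[j] = sig_new
                st.Cs[:, j] = cs_new
                if on_v:
                    st.v_tr = v_new
                else:
                    st.la_tr = la_new
                st.ll_tr = ll_new
            if adapting:
                ls[key] = adapt(ls[key], alpha, ls)

        rec = it - tune
        if rec >= burn:
            kept[rec - burn] = st.pack(m)
    return kept


def fit(
    model: HierarchicalDDM,
    chains: int = 4,
    iterations: int = 5000,
    burn: int = 200,
    seed: int = 0,
    tune: int = 400,
) -> PosteriorTrace:
    """Sample the joint posterior with ``chains`` independent MCMC runs.

    Each chain records ``iterations`` samples after a discarded tuning phase
    (``tune`` iterations, proposal adaptation only there and during the
    burn-in) and drops the first ``burn``; the retained trace therefore holds
    ``chains * (iterations - burn)`` samples.
    """
    if iterations <= burn:
        raise ValueError(
            f"empty trace: iterations ({iterations}) must exceed burn ({burn})"
        )
    if chains < 1:
        raise ValueError("need at least one chain")
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(chains)
    all_kept = []
    for c in range(chains):
        rng = np.random.default_rng(child[c])
        all_kept.append(_run_chain(model, iterations, burn, tune, rng))
    samples = np.stack(all_kept)
    return PosteriorTrace(
        samples=samples,
        param_names=list(model.param_names),
        group_level=list(model.group_level),
        chains=chains,
        iterations=iterations,
        burn=burn,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# diagnostics and model comparison
# ---------------------------------------------------------------------------


def compute_dic(
    trace: PosteriorTrace,
    model: HierarchicalDDM | None = None,
    loglik_fn: Callable[[np.ndarray], float] | None = None,
    thin: int = 1,
) -> float:
    """Deviance information criterion: ``DIC = D_bar + pD``.

    ``D = -2 log L``; ``pD = D_bar - D(theta_bar)`` with ``theta_bar`` the
    posterior mean of every sampled parameter (subject- and group-level).
    Either a fitted ``model`` or an explicit ``loglik_fn(theta_vector)`` must
    be supplied (the latter enables DIC for arbitrary likelihoods).
    """
    if loglik_fn is None:
        if model is None:
            raise ValueError("need a model or an explicit loglik_fn")
        loglik_fn = model.loglik
    draws = trace.samples.reshape(-1, trace.samples.shape[2])[::thin]
    devs = np.array([-2.0 * loglik_fn(theta) for theta in draws])
    if not np.all(np.isfinite(devs)):
        bad = np.flatnonzero(~np.isfinite(devs))
        raise ValueError(f"non-finite deviance at posterior draws {bad[:5]}...")
    d_bar = float(devs.mean())
    d_at_mean = -2.0 * loglik_fn(draws.mean(axis=0))
    p_d = d_bar - d_at_mean
    return d_bar + p_d


def gelman_rubin(trace: PosteriorTrace, parameters: Sequence[str] | None = None):
    """Classic Gelman–Rubin potential scale reduction factor per parameter.

    ``Rhat = sqrt(((n-1)/n * W + B/n) / W)`` with W the mean within-chain
    variance and B/n the variance of chain means; values near 1 indicate the
    chains sample the same distribution.  (Identical chains give
    ``sqrt((n-1)/n)``, slightly below 1, which is why well-converged fits are
    reported in a band like 0.98–1.02.)
    """
    if trace.chains < 2:
        raise ValueError("Gelman-Rubin requires at least 2 chains")
    if parameters is None:
        parameters = trace.group_level
    n = trace.samples.shape[1]
    out = {}
    for name in parameters:
        x = trace.get(name, flat=False)  # chains x n
        W = float(x.var(axis=1, ddof=1).mean())
        B_over_n = float(x.mean(axis=1).var(ddof=1))
        if W == 0:
            out[name] = 1.0 if B_over_n == 0 else np.inf
            continue
        var_hat = (n - 1) / n * W + B_over_n
        out[name] = math.sqrt(var_hat / W)
    return out


def posterior_p(trace: PosteriorTrace, parameter: str):
    """Posterior tail masses of a parameter around zero.

    Returns ``(P, direction, p_below, p_above)``: ``p_below = Pr(theta < 0)``,
    ``p_above = Pr(theta > 0)``, and the reported ``P`` is the mass on the
    side *opposite* the sign of the posterior mean — i.e. the probability that
    the effect has the other sign, the usual reporting convention for "a
    negative shift in the posterior distribution, P < 0.001".
    """
    x = trace.get(parameter)
    p_below = float(np.mean(x < 0))
    p_above = float(np.mean(x > 0))
    direction = "negative" if x.mean() < 0 else "positive"
    reported = p_above if direction == "negative" else p_below
    return reported, direction, p_below, p_above


@dataclass
class PPCResult:
    """Observed-vs-predicted summary table and the per-simulation summaries."""

    table: pd.DataFrame
    sims: pd.DataFrame  # one row per simulation x cell


def _ppc_summaries(rt, resp, cond, instr):
    """Per-cell accuracy and RT quantiles for one (observed or simulated) dataset."""
    rows = []
    qs = (10, 30, 50, 70, 90)
    df = pd.DataFrame({"rt": rt, "resp": resp, "cond": cond, "instr": instr})
    df = df[np.isfinite(df["rt"])]
    for (c, i), cell in df.groupby(["cond", "instr"], sort=True):
        rows.append({"cond": c, "instr": i, "stat": "accuracy", "value": cell["resp"].mean()})
        for correct, sub in cell.groupby(cell["resp"] == 1):
            lab = "correct" if correct else "error"
            if len(sub) == 0:
                continue
            for q, val in zip(qs, np.percentile(sub["rt"], qs)):
                rows.append({"cond": c, "instr": i, "stat": f"rt_q{q}_{lab}", "value": val})
    return pd.DataFrame(rows)


def posterior_predictive(
    trace: PosteriorTrace,
    model: HierarchicalDDM,
    data: pd.DataFrame,
    n_sims: int = 500,
    seed: int = 0,
    dt: float = 1e-3,
) -> PPCResult:
    """Posterior predictive check: average ``n_sims`` simulated datasets.

    For each of ``n_sims`` posterior draws the full trial table is
    re-simulated from the model; per-cell summaries (accuracy and RT deciles
    by condition x instruction x correctness) are averaged across simulations
    and reported next to the observed summaries with central 95% predictive
    intervals.
    """
    if model.n_trials == 0:
        raise ValueError("cannot run a posterior predictive check on zero trials")
    rng = np.random.default_rng(seed)
    flat = trace.samples.reshape(-1, trace.samples.shape[2])
    pick = rng.integers(0, flat.shape[0], size=n_sims)
    cond = (data["condition"].astype(str).to_numpy()
            if "condition" in data.columns else np.full(model.n_trials, "all"))
    instr = data["instruction"].astype(str).to_numpy()
    obs = _ppc_summaries(model.rt, model.response, cond, instr)

    sim_tables = []
    for j, k in enumerate(pick):
        v, a, t0 = model.trial_params(flat[k])
        z = a / 2.0
        rt_s, ch_s = _simulate_core(
            v, a, z, t0, dt, 20.0, int(rng.integers(0, 2**31 - 1)), True
        )
        tab = _ppc_summaries(rt_s, ch_s, cond, instr)
        tab["sim"] = j
        sim_tables.append(tab)
    sims = pd.concat(sim_tables, ignore_index=True)
    pred = sims.groupby(["cond", "instr", "stat"])["value"].agg(
        predicted="mean",
        lo95=lambda s: np.nanpercentile(s, 2.5),
        hi95=lambda s: np.nanpercentile(s, 97.5),
    ).reset_index()
    table = obs.rename(columns={"value": "observed"}).merge(
        pred, on=["cond", "instr", "stat"], how="left"
    )
    return PPCResult(table=table, sims=sims)


# ---------------------------------------------------------------------------
# model grids
# ---------------------------------------------------------------------------


def model_grid(
    stage: str,
    covariates: Sequence[str] = ("SC", "CE"),
    include_quadratic_only: bool = False,
) -> list[ModelSpec]:
    """Enumerate the model ladder or the trial-level regression grid.

    ``condition_ladder`` returns the five condition models: everything fixed;
    boundary split by instruction; plus drift and/or boundary split by
    complexity condition.  ``regression_grid`` crosses affected parameter
    {v, a, both} x covariate x form {linear, linear+quadratic} — 12 models —
    plus the null model; ``include_quadratic_only=True`` adds the
    quadratic-only form, giving the full 18 (+ null).  No spec ever contains
    both SC and CE.
    """
    if stage == "condition_ladder":
        return [
            ModelSpec(name="fixed", a_by_instruction=False),
            ModelSpec(name="a~instr"),
            ModelSpec(name="a~instr,v~cond", v_by_condition=True),
            ModelSpec(name="a~instr+cond", a_by_condition=True),
            ModelSpec(name="a~instr+cond,v~cond", v_by_condition=True, a_by_condition=True),
        ]
    if stage == "regression_grid":
        forms = ["linear", "linear+quadratic"]
        if include_quadratic_only:
            forms.insert(1, "quadratic")
        specs = [ModelSpec(name="null")]
        for cov in covariates:
            for form in forms:
                specs.append(ModelSpec(
                    name=f"v~{cov}:{form}",
                    regressions={"v": Regression(cov, form)},
                ))
                specs.append(ModelSpec(
                    name=f"a~{cov}:{form}",
                    regressions={"a": Regression(cov, form)},
                ))
                specs.append(ModelSpec(
                    name=f"v,a~{cov}:{form}",
                    regressions={"v": Regression(cov, form), "a": Regression(cov, form)},
                ))
        return specs
    raise ValueError(f"unknown stage {stage!r}")


def compare(fits: Sequence[tuple[ModelSpec, float]], n_trials: Sequence[int] | None = None):
    """Rank fitted models by DIC (ascending; lower is better).

    ``fits`` is a list of ``(spec, dic)``; ``n_trials`` optionally carries the
    dataset size of each fit and must be identical across fits.  The best
    model's ``delta_dic`` is 0; others report their (positive) excess, and the
    conventional signed difference best-minus-model is in ``ddic_vs_best``.
    """
    if len(fits) < 2:
        raise ValueError("model comparison requires at least 2 fits")
    if n_trials is not None and len(set(n_trials)) > 1:
        raise ValueError(f"fits were run on different data sizes: {sorted(set(n_trials))}")
    rows = [{"model": s.name, "dic": float(d)} for s, d in fits]
    df = pd.DataFrame(rows).sort_values("dic", kind="mergesort").reset_index(drop=True)
    best = df["dic"].iloc[0]
    df["delta_dic"] = df["dic"] - best
    df["ddic_vs_best"] = best - df["dic"]
    return df
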