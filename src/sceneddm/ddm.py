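"""Drift-diffusion model primitives.

Evidence accumulates as a Wiener process with drift ``v`` and unit diffusion
between absorbing boundaries at 0 and ``a``, starting at ``z`` (default
``a/2``); the observed response time is the first-passage time plus a
non-decision time ``t0`` (response execution, encoding).  The first-passage
density is evaluated with the dual series representation — a small-time and a
large-time expansion with an accuracy-driven automatic switch — which is the
standard fast/accurate scheme for this density.

All heavy loops (density over a trial table, Euler–Maruyama simulation) are
numba-compiled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "DDMParams",
    "wfpt_density",
    "absorption_probability",
    "simulate_trials",
    "dataset_loglik",
    "LOGLIK_FLOOR",
]

#: Per-trial likelihood floor keeping MCMC finite on outlier RTs.
LOGLIK_FLOOR = 1e-300


class ParameterError(ValueError):
    """Invalid diffusion-model parameters."""


@dataclass(frozen=True)
class DDMParams:
    """Parameters of a single-trial drift-diffusion process (sigma = 1)."""

    v: float
    a: float
    z: float | None = None  # default a/2
    t0: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.v):
            raise ParameterError("drift v must be finite")
        if not (np.isfinite(self.a) and self.a > 0):
            raise ParameterError(f"boundary separation a must be > 0, got {self.a}")
        z = self.a / 2 if self.z is None else self.z
        if not (0 < z < self.a):
            raise ParameterError(f"starting point z must lie in (0, a), got {z}")
        if not (np.isfinite(self.t0) and self.t0 >= 0):
            raise ParameterError(f"non-decision time t0 must be >= 0, got {self.t0}")

    @property
    def start(self) -> float:
        return self.a / 2 if self.z is None else self.z


@njit(cache=True)
def _fpt_lower_norm(u: float, w: float, eps: float) -> float:
    """Normalized (a=1, v=0) lower-boundary FPT density at scaled time u.

    Chooses between the small-time and large-time series by the number of
    terms each needs for absolute accuracy eps.
    """
    if u <= 0.0:
        return 0.0
    # terms needed by the small-time expansion
    if 2.0 * math.sqrt(2.0 * math.pi * u) * eps < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * u * math.log(2.0 * eps * math.sqrt(2.0 * math.pi * u)))
        if ks < math.sqrt(u) + 1.0:
            ks = math.sqrt(u) + 1.0
    else:
        ks = 2.0
    # terms needed by the large-time expansion
    if math.pi * u * eps < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * u * eps) / (math.pi * math.pi * u))
        if kl < 1.0 / (math.pi * math.sqrt(u)):
            kl = 1.0 / (math.pi * math.sqrt(u))
    else:
        kl = 1.0 / (math.pi * math.sqrt(u))

    if ks < kl:  # small-time series
        K = int(math.ceil(ks))
        lo = -((K - 1) // 2)
        hi = (K - 1) // 2 + (K - 1) % 2
        s = 0.0
        for k in range(lo, hi + 1):
            wk = w + 2.0 * k
            s += wk * math.exp(-wk * wk / (2.0 * u))
        return s / math.sqrt(2.0 * math.pi * u * u * u)
    # large-time series
    K = int(math.ceil(kl))
    s = 0.0
    for k in range(1, K + 1):
        s += k * math.exp(-k * k * math.pi * math.pi * u / 2.0) * math.sin(k * math.pi * w)
    return math.pi * s


@njit(cache=True)
def _wfpt_pdf(t_dec: float, v: float, a: float, w: float, eps: float) -> float:
    """Density of absorption at the LOWER boundary after decision time t_dec.

    w = z / a is the relative starting point.  eps bounds the truncation
    error of the normalized series; the drift/scale envelope is exact.
    """
    if t_dec <= 0.0:
        return 0.0
    u = t_dec / (a * a)
    p = _fpt_lower_norm(u, w, eps)
    if p <= 0.0:
        return 0.0
    return p * math.exp(-v * a * w - v * v * t_dec / 2.0) / (a * a)


def wfpt_density(
    t: float | np.ndarray,
    boundary_hit: str,
    params: DDMParams,
    eps: float = 1e-10,
) -> float | np.ndarray:
    """First-passage-time density of the named boundary at clock time ``t``.

    ``t`` includes the non-decision time: the returned value is the density of
    ``rt = t`` given absorption at ``boundary_hit`` ("upper" or "lower");
    zero for ``t <= t0``.  Absolute accuracy of the series truncation is
    bounded by ``eps``.
    """
    if not (0 < eps <= 1e-3):
        raise ParameterError(f"eps must be in (0, 1e-3], got {eps}")
    if boundary_hit not in ("upper", "lower"):
        raise ParameterError(f"boundary_hit must be 'upper' or 'lower', got {boundary_hit!r}")
    w = params.start / params.a
    v = params.v
    if boundary_hit == "upper":  # reflect: upper hit of (v, w) = lower hit of (-v, 1-w)
        v, w = -v, 1.0 - w
    tt = np.asarray(t, dtype=float)
    out = np.empty(tt.shape, dtype=float)
    flat_t = np.atleast_1d(tt).ravel()
    flat_o = np.atleast_1d(out).ravel()
    for i in range(flat_t.size):
        flat_o[i] = _wfpt_pdf(flat_t[i] - params.t0, v, params.a, w, eps)
    if np.isscalar(t) or tt.ndim == 0:
        return float(flat_o[0])
    return out


def absorption_probability(params: DDMParams) -> float:
    """Probability that the process is absorbed at the upper boundary.

    Closed form for Brownian motion with drift between two absorbing
    boundaries (sigma = 1): ``(1 - exp(-2 v z)) / (1 - exp(-2 v a))``, with
    the drift-free limit ``z / a``.
    """
    v, a, z = params.v, params.a, params.start
    if abs(v) < 1e-9:
        return z / a
    # guard overflow for strongly negative drift
    x = -2.0 * v * z
    y = -2.0 * v * a
    if y > 700 or x > 700:
        return float(np.expm1(min(x, 700)) / np.expm1(min(y, 700)))
    return float(np.expm1(x) / np.expm1(y))


@njit(cache=True)
def _simulate_core(v, a, z, t0, dt, t_max, seed, bridge):
    n = v.shape[0]
    rt = np.empty(n)
    choice = np.empty(n, dtype=np.int64)
    np.random.seed(seed)
    sdt = math.sqrt(dt)
    buf = np.random.standard_normal(4096)
    ptr = 0
    for i in range(n):
        x = z[i]
        t = 0.0
        ai = a[i]
        vi_dt = v[i] * dt
        done = False
        hit_upper = False
        while t <= t_max:
            if ptr >= 4096:
                buf = np.random.standard_normal(4096)
                ptr = 0
            x_new = x + vi_dt + sdt * buf[ptr]
            ptr += 1
            t += dt
            if x_new >= ai:
                done = True
                hit_upper = True
            elif x_new <= 0.0:
                done = True
                hit_upper = False
            elif bridge:
                # Brownian-bridge probability that the path crossed a boundary
                # inside the step even though both endpoints are interior;
                # removes the O(sqrt(dt)) discrete-monitoring bias.  The test
                # is skipped when the crossing probability is below exp(-34)
                # (product of distances > 17*dt), which covers almost every
                # interior step.
                d_up = (ai - x) * (ai - x_new)
                if d_up < 17.0 * dt and np.random.random() < math.exp(-2.0 * d_up / dt):
                    done = True
                    hit_upper = True
                else:
                    d_lo = x * x_new
                    if d_lo < 17.0 * dt and np.random.random() < math.exp(-2.0 * d_lo / dt):
                        done = True
                        hit_upper = False
            if done:
                break
            x = x_new
        if not done:
            rt[i] = np.nan
            choice[i] = -1  # miss: not absorbed within the time cap
        else:
            rt[i] = t + t0[i]
            choice[i] = 1 if hit_upper else 0
    return rt, choice


def simulate_trials(
    params_per_trial,
    seed: int,
    dt: float = 1e-3,
    t_max: float = 20.0,
    bridge: bool = True,
):
    """Euler–Maruyama simulation of one trial per parameter set.

    ``params_per_trial`` is a sequence of :class:`DDMParams` or a tuple of
    arrays ``(v, a, z, t0)``.  Returns ``(rt, choice)`` with choice 1 for the
    upper boundary, 0 for the lower, and -1 (rt = NaN) for trials not
    absorbed within ``t_max`` seconds of decision time (misses).

    With ``bridge=True`` (default) each Euler step additionally tests for an
    intra-step boundary crossing with the exact Brownian-bridge crossing
    probability, which removes the O(sqrt(dt)) bias of discretely monitored
    absorption.
    """
    if dt > 1e-3 or dt <= 0:
        raise ParameterError(f"dt must be in (0, 1e-3], got {dt}")
    if isinstance(params_per_trial, tuple) and len(params_per_trial) == 4:
        v, a, z, t0 = (np.ascontiguousarray(x, dtype=float) for x in params_per_trial)
    else:
        plist = list(params_per_trial)
        v = np.array([p.v for p in plist])
        a = np.array([p.a for p in plist])
        z = np.array([p.start for p in plist])
        t0 = np.array([p.t0 for p in plist])
    if np.any(a <= 0) or np.any((z <= 0) | (z >= a)) or np.any(t0 < 0):
        raise ParameterError("invalid trial parameters (need a > 0, 0 < z < a, t0 >= 0)")
    return _simulate_core(
        v, a, z, t0, float(dt), float(t_max), int(seed) & 0x7FFFFFFF, bridge
    )


@njit(cache=True)
def _loglik_vec(rt, choice, v, a, w, t0, eps, floor):
    """Per-trial log-density vector (floored); used by the MCMC sampler."""
    n = rt.shape[0]
    out = np.empty(n)
    for i in range(n):
        t_dec = rt[i] - t0[i]
        if choice[i] == 1:
            d = _wfpt_pdf(t_dec, -v[i], a[i], 1.0 - w[i], eps)
        else:
            d = _wfpt_pdf(t_dec, v[i], a[i], w[i], eps)
        if d < floor or not np.isfinite(d):
            d = floor
        out[i] = math.log(d)
    return out


@njit(cache=True)
def _loglik_core(rt, choice, v, a, w, t0, eps, floor):
    total = 0.0
    n_floored = 0
    for i in range(rt.shape[0]):
        t_dec = rt[i] - t0[i]
        if choice[i] == 1:
            d = _wfpt_pdf(t_dec, -v[i], a[i], 1.0 - w[i], eps)
        else:
            d = _wfpt_pdf(t_dec, v[i], a[i], w[i], eps)
        if d < floor or not np.isfinite(d):
            d = floor
            n_floored += 1
        total += math.log(d)
    return total, n_floored


def dataset_loglik(
    rt: np.ndarray,
    choice: np.ndarray,
    params_per_trial,
    eps: float = 1e-10,
    return_floored: bool = False,
):
    """Total log-likelihood of a trial table under per-trial DDM parameters.

    ``choice`` is 1 (upper) or 0 (lower); trials whose density underflows
    (e.g. rt <= t0) contribute ``log(1e-300)`` via the likelihood floor.
    """
    rt = np.ascontiguousarray(rt, dtype=float)
    choice = np.ascontiguousarray(choice, dtype=np.int64)
    if isinstance(params_per_trial, tuple) and len(params_per_trial) == 4:
        v, a, z, t0 = (np.ascontiguousarray(x, dtype=float) for x in params_per_trial)
    else:
        plist = list(params_per_trial)
        v = np.array([p.v for p in plist])
        a = np.array([p.a for p in plist])
        z = np.array([p.start for p in plist])
        t0 = np.array([p.t0 for p in plist])
    if not (rt.shape == choice.shape == v.shape == a.shape == z.shape == t0.shape):
        raise ParameterError("rt, choice and parameter arrays must share one length")
    w = z / a
    total, n_floored = _loglik_core(rt, choice, v, a, w, t0, eps, LOGLIK_FLOOR)
    if return_floored:
        return total, n_floored
    return total
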