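"""Synthetic images and behaviour for exercising the full pipeline.

The texture generator emulates the sparse-to-cluttered axis of natural
scenes with a single clutter knob: a mid-grey canvas receives ``n_elements``
randomly placed oriented edge/blob elements whose amplitudes are drawn from
a heavy-tailed lognormal.  Sparse compositions give power-law-like local
contrast histograms (Weibull shape well below 1); thousands of overlapping
elements converge to a Gaussian random field whose contrast modulus is
Rayleigh (shape near 2), spanning the empirical range of natural scenes.

The behaviour generator draws subject-level DDM parameters from group
distributions and simulates every trial of a schedule with a drift that is a
quadratic (inverted-U for ``beta2 < 0``) function of the centred spatial
coherence and an instruction-dependent boundary, the generative structure
assumed by the hierarchical model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import scene_stats as ss
from .ddm import simulate_trials

__all__ = [
    "TextureParams",
    "BehaviourGenSpec",
    "generate_texture",
    "generate_scene_pool",
    "generate_stat_pool",
    "generate_behaviour",
]


class GenerationError(ValueError):
    """Raised for infeasible generator parameters."""


@dataclass(frozen=True)
class TextureParams:
    """Controls for one synthetic texture; deterministic under fixed fields."""

    n_elements: int = 100
    amplitude_scale: float = 0.08
    kind: str = "mixed"  # "edge", "blob" or "mixed"
    size_range: tuple[float, float] = (4.0, 16.0)
    shape: tuple[int, int] = (128, 128)
    noise_sd: float = 0.0  # optional sensor-noise floor
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_elements < 0:
            raise GenerationError("n_elements must be >= 0")
        if self.amplitude_scale <= 0:
            raise GenerationError("amplitude_scale must be > 0")
        if self.kind not in ("edge", "blob", "mixed"):
            raise GenerationError(f"unknown element kind {self.kind!r}")
        if self.size_range[1] >= min(self.shape):
            raise GenerationError(
                f"element size {self.size_range[1]} exceeds image extent {self.shape}"
            )


def generate_texture(params: TextureParams) -> np.ndarray:
    """Render one synthetic texture as a luminance image in [0, 1]."""
    rng = np.random.default_rng(params.seed)
    h, w = params.shape
    img = np.zeros((h, w))
    yy, xx = np.mgrid[0:h, 0:w]
    # keep the summed-texture variance bounded as elements pile up: real
    # cluttered scenes stay within the luminance range instead of saturating
    mean_size = 0.5 * (params.size_range[0] + params.size_range[1])
    cover = params.n_elements * (1.5 * mean_size) ** 2 / (h * w)
    overlap_norm = 1.0 / np.sqrt(max(1.0, cover))
    # amplitude heterogeneity shrinks as elements pile up: sparse scenes have
    # a few dominant edges (heavy tail), dense textures are homogeneous and
    # converge to a Gaussian field (Rayleigh contrast moduli, shape near 2).
    # The sparse-end spread is capped so that shape parameters stay in the
    # range observed for natural scenes rather than collapsing towards 0.
    amp_sigma = min(0.6, 1.0 / np.sqrt(max(1.0, cover)))
    for _ in range(params.n_elements):
        # heavy-tailed signed amplitude: sparse scenes get occasional very
        # strong edges, producing power-law-like contrast histograms
        amp = rng.lognormal(np.log(params.amplitude_scale), amp_sigma) * overlap_norm
        amp *= rng.choice((-1.0, 1.0))
        size = rng.uniform(*params.size_range)
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        kind = params.kind
        if kind == "mixed":
            kind = "edge" if rng.random() < 0.5 else "blob"
        y0, y1 = int(max(0, cy - size - 2)), int(min(h, cy + size + 3))
        x0, x1 = int(max(0, cx - size - 2)), int(min(w, cx + size + 3))
        py, px = yy[y0:y1, x0:x1] - cy, xx[y0:y1, x0:x1] - cx
        if kind == "blob":
            sig = size / 3.0
            img[y0:y1, x0:x1] += amp * np.exp(-(px**2 + py**2) / (2 * sig**2))
        else:
            theta = rng.uniform(0, np.pi)
            u = px * np.cos(theta) + py * np.sin(theta)   # across the edge
            t = -px * np.sin(theta) + py * np.cos(theta)  # along the edge
            profile = np.tanh(u / 1.0)                    # sharp luminance step
            taper = np.exp(-(t / (size / 2.0)) ** 2) * np.exp(-(u / (size / 2.0)) ** 2)
            img[y0:y1, x0:x1] += amp * profile * taper
    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, size=img.shape)
    return np.clip(0.5 + img, 0.0, 1.0)


def generate_scene_pool(
    n_scenes: int,
    clutter_range: tuple[int, int] = (10, 5000),
    amplitude_range: tuple[float, float] = (0.04, 0.16),
    animal_fraction: float = 0.5,
    seed: int = 0,
    shape: tuple[int, int] = (96, 96),
    scales: tuple[float, ...] = (1.0, 2.0, 4.0),
    animal_sc_association: float = 0.0,
) -> pd.DataFrame:
    """Render a pool of textures and score them with the contrast-statistics model.

    Clutter counts are drawn log-uniformly over ``clutter_range`` so the pool
    spans the sparse (SC well below 1) to cluttered (SC near 2) axis; CE is
    additionally varied through the element amplitude.  Animal labels are
    Bernoulli(``animal_fraction``) and independent of the statistics by
    default, so condition-wise matching is achievable;
    ``animal_sc_association`` in [0, 1) probabilistically ties the label to
    above-median SC for bias experiments.

    Returns a data frame with columns ``image_id, CE, SC, n_samples, route,
    animal, clutter``.
    """
    if n_scenes < 3:
        raise GenerationError("pool must contain at least 3 scenes")
    if not (0 <= animal_fraction <= 1):
        raise GenerationError("animal_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    lo, hi = clutter_range
    if not (0 < lo < hi):
        raise GenerationError(f"invalid clutter_range {clutter_range}")
    clutter = np.exp(rng.uniform(np.log(lo), np.log(hi), n_scenes)).astype(int)
    amps = rng.uniform(*amplitude_range, n_scenes)
    rows = []
    for i in range(n_scenes):
        img = generate_texture(TextureParams(
            n_elements=int(clutter[i]), amplitude_scale=float(amps[i]),
            shape=shape, seed=int(rng.integers(2**31 - 1)),
        ))
        stats = ss.compute_scene_stats(img, scales=scales)
        rows.append({
            "image_id": f"synth_{i:05d}", "CE": stats.CE, "SC": stats.SC,
            "n_samples": stats.n_samples, "route": stats.route,
            "clutter": int(clutter[i]),
        })
    pool = pd.DataFrame(rows)
    if animal_sc_association > 0:
        high_sc = (pool["SC"] > pool["SC"].median()).to_numpy()
        p = animal_fraction + animal_sc_association * (high_sc - 0.5)
        pool["animal"] = rng.random(n_scenes) < np.clip(p, 0, 1)
    else:
        pool["animal"] = rng.random(n_scenes) < animal_fraction
    return pool


def generate_stat_pool(
    n_scenes: int,
    seed: int = 0,
    animal_fraction: float = 0.5,
    sc_range: tuple[float, float] = (0.4, 2.2),
    ce_given_sc_sd: float = 0.35,
) -> pd.DataFrame:
    """Draw a pool of (CE, SC) values directly, without rendering images.

    A fast stand-in for :func:`generate_scene_pool` when only the statistics
    matter (stimulus sampling, schedules): SC is uniform over its natural
    range and CE is lognormal around a level increasing with SC.  The default
    conditional scatter gives an SC-CE correlation near 0.8, the order
    reported for natural image databases — high, but with enough overlap
    that one statistic can be clamped while the other is manipulated.
    """
    if n_scenes < 3:
        raise GenerationError("pool must contain at least 3 scenes")
    rng = np.random.default_rng(seed)
    sc = rng.uniform(*sc_range, n_scenes)
    # CE increases with SC on average (correlated statistics), with scatter
    ce = np.exp(np.log(0.02) + 0.8 * (sc - np.mean(sc_range)) +
                rng.normal(0, ce_given_sc_sd, n_scenes))
    return pd.DataFrame({
        "image_id": [f"stat_{i:05d}" for i in range(n_scenes)],
        "CE": ce, "SC": sc,
        "n_samples": 0, "route": "synthetic",
        "animal": rng.random(n_scenes) < animal_fraction,
    })


@dataclass(frozen=True)
class BehaviourGenSpec:
    """True group-level parameters of the behaviour generator.

    Drift on trial i of subject s is
    ``v = v0_s + beta1 * SC_c + beta2 * SC_c**2`` with SC centred over the
    schedule; ``beta2 <= 0`` encodes the inverted-U.  Boundary is the
    subject's instruction-specific value, lower under speed emphasis by
    default.  All parameters are in the sigma = 1 convention, times in
    seconds.
    """

    mu_v: float = 1.5
    sigma_v: float = 0.3
    beta1: float = 0.0
    beta2: float = -1.0
    a_speed: float = 1.2
    a_accurate: float = 1.8
    sigma_log_a: float = 0.12
    beta1_a: float = 0.0
    beta2_a: float = 0.0
    mu_t0: float = 0.3
    sigma_t0: float = 0.04
    n_subjects: int = 6
    fast_guess_rate: float = 0.0
    miss_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta2 > 0:
            raise GenerationError("beta2 must be <= 0 (inverted-U drift)")
        if self.a_speed <= 0 or self.a_accurate <= 0:
            raise GenerationError("boundaries must be positive")
        if self.n_subjects < 1:
            raise GenerationError("need at least one subject")
        if not (0 <= self.fast_guess_rate < 1 and 0 <= self.miss_rate < 1):
            raise GenerationError("contaminant rates must be in [0, 1)")


def generate_behaviour(
    spec: BehaviourGenSpec,
    schedule: pd.DataFrame,
    sc_values: pd.Series | dict | None = None,
    dt: float = 1e-3,
) -> pd.DataFrame:
    """Simulate every subject through a trial schedule.

    ``schedule`` needs columns ``scene_id`` and ``instruction`` (a
    ``condition`` column, if present, is carried through); ``sc_values`` maps
    scene_id to SC (omit it if the schedule already has an ``SC`` column).
    Returns the standard trial table: ``subj_idx, rt, response, instruction,
    condition, SC`` (+ CE if available).  ``response`` is accuracy-coded
    (1 = correct); misses have ``response = -1`` and ``rt = NaN``.
    """
    sched = schedule.copy().reset_index(drop=True)
    if sc_values is not None:
        mapping = sc_values if isinstance(sc_values, dict) else sc_values.to_dict()
        sched["SC"] = sched["scene_id"].map(mapping)
    if "SC" not in sched.columns or sched["SC"].isna().any():
        raise GenerationError("schedule and SC values are not aligned")
    rng = np.random.default_rng(spec.seed)
    sc_c = sched["SC"].to_numpy(float)
    sc_c = sc_c - sc_c.mean()
    instr = sched["instruction"].astype(str).to_numpy()
    if not set(instr) <= {"speed", "accurate"}:
        raise GenerationError(f"unknown instruction labels {sorted(set(instr))}")
    is_speed = instr == "speed"
    n = len(sched)
    out = []
    for s in range(spec.n_subjects):
        v0 = rng.normal(spec.mu_v, spec.sigma_v)
        la_sp = rng.normal(np.log(spec.a_speed), spec.sigma_log_a)
        la_ac = rng.normal(np.log(spec.a_accurate), spec.sigma_log_a)
        t0 = max(rng.normal(spec.mu_t0, spec.sigma_t0), 0.05)
        v = v0 + spec.beta1 * sc_c + spec.beta2 * sc_c**2
        log_a = np.where(is_speed, la_sp, la_ac) \
            + spec.beta1_a * sc_c + spec.beta2_a * sc_c**2
        a = np.exp(log_a)
        rt, choice = simulate_trials(
            (v, a, a / 2, np.full(n, t0)), seed=int(rng.integers(2**31 - 1)), dt=dt
        )
        df = pd.DataFrame({
            "subj_idx": s,
            "rt": rt,
            "response": choice,
            "instruction": instr,
            "SC": sched["SC"].to_numpy(float),
        })
        for extra in ("condition", "scene_id", "CE"):
            if extra in sched.columns:
                df[extra] = sched[extra].to_numpy()
        # contaminants (off by default): fast guesses and misses
        if spec.fast_guess_rate > 0:
            hit = rng.random(n) < spec.fast_guess_rate
            df.loc[hit, "rt"] = rng.uniform(0.02, 0.0999, hit.sum())
            df.loc[hit, "response"] = rng.integers(0, 2, hit.sum())
        if spec.miss_rate > 0:
            hit = rng.random(n) < spec.miss_rate
            df.loc[hit, "rt"] = np.nan
            df.loc[hit, "response"] = -1
        out.append(df)
    return pd.concat(out, ignore_index=True)
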