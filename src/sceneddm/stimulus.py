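"""Stimulus sampling and trial schedules for the animal-detection task.

Scenes from a scored pool are sampled into three complexity conditions —
low, medium and high — either jointly along the correlated SC-CE axis or in
one statistic with the other clamped to intermediate values.  Within each
condition, animal and non-animal scenes are matched in both statistics (the
categories must not differ in mean or median), which is verified with a
two-sample t-test and a Mann–Whitney z-test and enforced by resampling.

Trial schedules present every selected scene once under each instruction
(speed, accurate), in randomly alternating blocks of 20 trials, with
fixation durations drawn uniformly from {350, 400, 450, 500, 550} ms
(mean 450 ms) and a 100 ms stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MatchReport",
    "StimulusSet",
    "assign_conditions",
    "check_matching",
    "build_trial_schedule",
    "FIXATION_MS",
    "STIMULUS_MS",
    "BLOCK_SIZE",
]

CONDITIONS = ("low", "medium", "high")
FIXATION_MS = (350, 400, 450, 500, 550)
STIMULUS_MS = 100
BLOCK_SIZE = 20


class SamplingError(RuntimeError):
    """Pool exhausted or matching unattainable."""


@dataclass(frozen=True)
class MatchTest:
    """Mean (t) and median (Mann–Whitney z) comparison of two groups."""

    t: float
    df: int
    p_mean: float
    z: float
    p_median: float
    degenerate: bool = False


@dataclass
class MatchReport:
    """Per condition and per statistic: the animal vs non-animal match tests."""

    entries: dict[tuple[str, str], MatchTest] = field(default_factory=dict)

    def passes(self, p_threshold: float = 0.25) -> bool:
        return all(
            e.degenerate or (e.p_mean > p_threshold and e.p_median > p_threshold)
            for e in self.entries.values()
        )


@dataclass
class StimulusSet:
    """Scenes per condition with animal flags; `mode` records the sampling axis."""

    frames: dict[str, pd.DataFrame]  # condition -> (image_id, SC, CE, animal)
    mode: str
    match_report: MatchReport
    #: per condition, (min, max) of the manipulated axis (z(SC)+z(CE) for
    #: joint mode, the raw statistic otherwise); bands must not interleave
    band_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    def scenes(self) -> pd.DataFrame:
        out = []
        for cond in CONDITIONS:
            df = self.frames[cond].copy()
            df["condition"] = cond
            out.append(df)
        return pd.concat(out, ignore_index=True)


def check_matching(values_a, values_b) -> MatchTest:
    """Compare two samples in mean (Welch-free pooled t) and median (MW z).

    The mean test is the classic two-sample t-test with pooled variance
    (df = n_a + n_b - 2); the median test is the Mann–Whitney U with normal
    approximation and tie correction, reported as a z-statistic.  Samples
    with zero variance in both groups are flagged degenerate and skipped.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    df = a.size + b.size - 2
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a.size > 1 and b.size > 1 and a[0] == b[0]:
        return MatchTest(t=0.0, df=df, p_mean=1.0, z=0.0, p_median=1.0, degenerate=True)
    t_res = stats.ttest_ind(a, b, equal_var=True)
    # Mann-Whitney z from the normal approximation with tie correction
    u_res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    n1, n2 = a.size, b.size
    combined = np.concatenate([a, b])
    _, counts = np.unique(combined, return_counts=True)
    n = n1 + n2
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1)) if n > 1 else 0.0
    sigma_u = np.sqrt(n1 * n2 / 12.0 * (n + 1 - tie_term))
    mu_u = n1 * n2 / 2.0
    if sigma_u == 0:
        z, p_med = 0.0, 1.0
    else:
        z = (u_res.statistic - mu_u) / sigma_u
        p_med = 2 * stats.norm.sf(abs(z))
    return MatchTest(
        t=float(t_res.statistic), df=df, p_mean=float(t_res.pvalue),
        z=float(z), p_median=float(p_med),
    )


def _band_masks(values: np.ndarray, guard: float):
    """Tertile bands with a guard gap (fraction of a band width) dropped between them."""
    q1, q2 = np.quantile(values, [1 / 3, 2 / 3])
    width = (values.max() - values.min()) / 3.0
    g = guard / 2 * width
    low = values <= q1 - g
    med = (values > q1 + g) & (values <= q2 - g)
    high = values > q2 + g
    return {"low": low, "medium": med, "high": high}


def assign_conditions(
    pool: pd.DataFrame,
    n_per_condition: int = 160,
    mode: str = "joint",
    seed: int = 0,
    guard: float = 0.10,
    p_threshold: float = 0.25,
    max_retries: int = 1000,
) -> StimulusSet:
    """Sample low/medium/high conditions from a scored scene pool.

    ``mode="joint"`` bands the scenes along the correlated SC-CE axis (the
    sum of the two z-scored statistics); ``"sc_only"`` bands SC with CE
    restricted to its middle band; ``"ce_only"`` the converse.  Each condition
    receives ``n_per_condition`` scenes, exactly half with an animal, and the
    animal/non-animal groups are resampled (up to ``max_retries``) until the
    mean and median tests on both statistics all have p > ``p_threshold``.
    """
    required = {"image_id", "SC", "CE", "animal"}
    if not required <= set(pool.columns):
        raise ValueError(f"pool must have columns {sorted(required)}")
    if pool["image_id"].duplicated().any():
        raise ValueError("pool has duplicate image_ids")
    if n_per_condition % 2:
        raise SamplingError("n_per_condition must be even (half animal, half not)")
    if mode not in ("joint", "sc_only", "ce_only"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    pool = pool.reset_index(drop=True)
    sc = pool["SC"].to_numpy(float)
    ce = pool["CE"].to_numpy(float)
    if not (np.all(np.isfinite(sc)) and np.all(np.isfinite(ce))):
        raise ValueError("pool statistics must be finite")

    zsc = (sc - sc.mean()) / sc.std()
    zce = (ce - ce.mean()) / ce.std()
    if mode == "joint":
        axis = zsc + zce
        masks = _band_masks(axis, guard)
    elif mode == "sc_only":
        masks = _band_masks(sc, guard)
        mid_ce = _band_masks(ce, 0.0)["medium"]
        masks = {k: m & mid_ce for k, m in masks.items()}
    else:
        masks = _band_masks(ce, guard)
        mid_sc = _band_masks(sc, 0.0)["medium"]
        masks = {k: m & mid_sc for k, m in masks.items()}

    half = n_per_condition // 2
    frames: dict[str, pd.DataFrame] = {}
    report = MatchReport()

    # In isolation modes the clamped statistic still varies inside its middle
    # band and correlates with the manipulated one, so the conditions would
    # drift apart in it.  Stratify: equal per-bin quotas of the clamped
    # statistic for every condition x animal group.
    quotas = None
    if mode in ("sc_only", "ce_only"):
        clamped = "CE" if mode == "sc_only" else "SC"
        all_cand = pd.concat([pool[masks[c]] for c in CONDITIONS])
        edges = np.quantile(all_cand[clamped], np.linspace(0, 1, 9))
        edges[0] -= 1e-9
        edges[-1] += 1e-9
        groups = {}
        for cond in CONDITIONS:
            cand = pool[masks[cond]]
            for flag in (True, False):
                sub = cand[cand["animal"].astype(bool) == flag]
                groups[(cond, flag)] = np.histogram(sub[clamped], bins=edges)[0]
        cap = np.minimum.reduce(list(groups.values()))
        if cap.sum() < half:
            raise SamplingError(
                f"{mode} infeasible: stratified capacity {int(cap.sum())} scenes per "
                f"group < required {half} (clamped statistic {clamped})"
            )
        quotas = np.floor(cap * half / cap.sum()).astype(int)
        order = np.argsort(-(cap - quotas))
        for b in order:  # distribute the rounding remainder where capacity remains
            if quotas.sum() >= half:
                break
            if quotas[b] < cap[b]:
                quotas[b] += 1
        if quotas.sum() != half:
            raise SamplingError(f"{mode} infeasible: cannot fill {half} scenes per group")

    def _draw(sub: pd.DataFrame) -> pd.DataFrame:
        if quotas is None:
            return sub.sample(half, random_state=rng.integers(2**31 - 1))
        parts = []
        col = sub[clamped].to_numpy()
        for b in range(len(quotas)):
            if quotas[b] == 0:
                continue
            in_bin = sub[(col > edges[b]) & (col <= edges[b + 1])]
            parts.append(in_bin.sample(int(quotas[b]), random_state=rng.integers(2**31 - 1)))
        return pd.concat(parts)

    for cond in CONDITIONS:
        cand = pool[masks[cond]]
        animals = cand[cand["animal"].astype(bool)]
        others = cand[~cand["animal"].astype(bool)]
        if len(animals) < half or len(others) < half:
            raise SamplingError(
                f"condition {cond!r} infeasible: need {half} animal and {half} "
                f"non-animal scenes, pool band has {len(animals)}/{len(others)}"
            )
        chosen = None
        for _ in range(max_retries):
            ai = _draw(animals)
            ni = _draw(others)
            tests = {
                (cond, "SC"): check_matching(ai["SC"], ni["SC"]),
                (cond, "CE"): check_matching(ai["CE"], ni["CE"]),
            }
            if all(
                t.degenerate or (t.p_mean > p_threshold and t.p_median > p_threshold)
                for t in tests.values()
            ):
                chosen = (ai, ni, tests)
                break
        if chosen is None:
            raise SamplingError(
                f"could not match animal/non-animal statistics in condition {cond!r} "
                f"within {max_retries} resampling attempts (p > {p_threshold} required)"
            )
        ai, ni, tests = chosen
        report.entries.update(tests)
        frames[cond] = pd.concat([ai, ni], ignore_index=True)[
            ["image_id", "SC", "CE", "animal"]
        ]

    band_ranges = {}
    for cond, df_c in frames.items():
        if mode == "joint":
            ax = ((df_c["SC"] - sc.mean()) / sc.std()
                  + (df_c["CE"] - ce.mean()) / ce.std()).to_numpy()
        elif mode == "sc_only":
            ax = df_c["SC"].to_numpy()
        else:
            ax = df_c["CE"].to_numpy()
        band_ranges[cond] = (float(ax.min()), float(ax.max()))
    return StimulusSet(frames=frames, mode=mode, match_report=report,
                       band_ranges=band_ranges)


def build_trial_schedule(stimulus_set: StimulusSet, seed: int = 0) -> pd.DataFrame:
    """Build a per-subject trial schedule from a stimulus set.

    Every scene appears exactly once under each instruction; instruction is
    constant within blocks of 20 trials whose order randomly alternates;
    fixation durations are sampled uniformly from the five standard values.
    Returns columns ``trial_index, scene_id, condition, animal, SC, CE,
    instruction, fixation_ms, stimulus_ms``.
    """
    rng = np.random.default_rng(seed)
    scenes = stimulus_set.scenes()
    n_scenes = len(scenes)
    if n_scenes % BLOCK_SIZE:
        raise SamplingError(
            f"scene count {n_scenes} must be a multiple of the block size {BLOCK_SIZE}"
        )
    blocks = []
    for instruction in ("speed", "accurate"):
        order = scenes.sample(frac=1.0, random_state=rng.integers(2**31 - 1))
        for start in range(0, n_scenes, BLOCK_SIZE):
            chunk = order.iloc[start:start + BLOCK_SIZE].copy()
            chunk["instruction"] = instruction
            blocks.append(chunk)
    rng.shuffle(blocks)
    sched = pd.concat(blocks, ignore_index=True)
    sched["fixation_ms"] = rng.choice(FIXATION_MS, size=len(sched))
    sched["stimulus_ms"] = STIMULUS_MS
    sched.insert(0, "trial_index", np.arange(len(sched)))
    sched = sched.rename(columns={"image_id": "scene_id"})
    # metadata mirrored from the task script; no computational role
    sched.attrs["feedback"] = {
        "speed": "on time / too slow at 500 ms", "accurate": "correct / incorrect",
        "no_response": "miss", "keyboard_switch": "halfway",
    }
    return sched
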