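"""End-to-end analysis pipeline: preprocessing, model ladders, reporting.

Mirrors the analysis flow of a speed/accuracy animal-detection experiment:
raw trial tables are cleaned (fast guesses below 100 ms removed, participants
with excessive errors or omissions excluded), behaviour is summarised per
complexity condition and instruction, a ladder of condition models and a
grid of trial-level regression models are fitted and compared by DIC, and
the best model's diagnostics (Rhat, posterior coefficient tests, posterior
predictive checks) are bundled into a report with a reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import inference, stimulus, synth

__all__ = [
    "PreprocessConfig",
    "preprocess",
    "summarize_behaviour",
    "run_full_analysis",
    "AnalysisReport",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class PreprocessConfig:
    """Trial- and participant-level exclusion rules.

    Trials faster than ``fast_guess_ms`` are removed as fast guesses.
    Participants are excluded when their error rate exceeds
    ``max_error_rate`` (absolute rule), exceeds the group mean by
    ``error_sd_rule`` standard deviations (SD rule; either rule may be
    disabled with None), or when their omission rate exceeds
    ``max_omission_rate``.  Error rates are computed on responded trials
    (misses excluded from the denominator); misses count toward omissions
    only.
    """

    fast_guess_ms: float = 100.0
    max_error_rate: float | None = 0.25
    error_sd_rule: float | None = 2.8
    max_omission_rate: float | None = 0.40

    def __post_init__(self) -> None:
        if self.fast_guess_ms < 0:
            raise ValueError("fast_guess_ms must be >= 0")
        for name in ("max_error_rate", "max_omission_rate"):
            val = getattr(self, name)
            if val is not None and not (0 < val <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {val}")
        if self.error_sd_rule is not None and self.error_sd_rule <= 0:
            raise ValueError("error_sd_rule must be positive")


def preprocess(
    raw: pd.DataFrame, config: PreprocessConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Clean a raw trial table; returns ``(clean_trials, exclusion_report)``.

    The report has one row per exclusion event (fast-guess trials per
    subject, misses, excluded participants) with counts and reasons;
    excluded + retained counts always add up to the input count.
    """
    config = config or PreprocessConfig()
    required = {"subj_idx", "rt", "response"}
    if not required <= set(raw.columns):
        raise ValueError(f"raw trials must have columns {sorted(required)}")
    df = raw.reset_index(drop=True)
    n_input = len(df)
    report_rows = []

    is_miss = df["response"].eq(-1) | df["rt"].isna()
    responded = df[~is_miss]
    fast = responded["rt"] < config.fast_guess_ms / 1000.0
    for subj, cnt in responded.loc[fast, "subj_idx"].value_counts().items():
        report_rows.append({"subj_idx": subj, "reason": "fast_guess_trials",
                            "n_trials": int(cnt)})

    # participant-level rates, computed before trial removal
    stats = []
    for subj, grp in df.groupby("subj_idx"):
        miss_g = grp["response"].eq(-1) | grp["rt"].isna()
        resp = grp[~miss_g]
        err_rate = float((resp["response"] == 0).mean()) if len(resp) else np.nan
        stats.append({"subj_idx": subj, "error_rate": err_rate,
                      "omission_rate": float(miss_g.mean()), "n": len(grp)})
    pstats = pd.DataFrame(stats)
    excluded = set()
    if config.max_error_rate is not None:
        for _, row in pstats[pstats["error_rate"] > config.max_error_rate].iterrows():
            excluded.add(row["subj_idx"])
            report_rows.append({
                "subj_idx": row["subj_idx"], "reason": "excessive_errors_absolute",
                "n_trials": int(row["n"]),
                "detail": f"error rate {row['error_rate']:.3f} > {config.max_error_rate}",
            })
    if config.error_sd_rule is not None and len(pstats) > 1:
        m, s = pstats["error_rate"].mean(), pstats["error_rate"].std(ddof=1)
        if s > 0:
            bad = pstats[pstats["error_rate"] > m + config.error_sd_rule * s]
            for _, row in bad.iterrows():
                if row["subj_idx"] in excluded:
                    continue
                excluded.add(row["subj_idx"])
                report_rows.append({
                    "subj_idx": row["subj_idx"], "reason": "excessive_errors_sd_rule",
                    "n_trials": int(row["n"]),
                    "detail": f"error rate {row['error_rate']:.3f} > mean + "
                              f"{config.error_sd_rule} SD ({m + config.error_sd_rule * s:.3f})",
                })
    if config.max_omission_rate is not None:
        bad = pstats[pstats["omission_rate"] > config.max_omission_rate]
        for _, row in bad.iterrows():
            if row["subj_idx"] in excluded:
                continue
            excluded.add(row["subj_idx"])
            report_rows.append({
                "subj_idx": row["subj_idx"], "reason": "excessive_omissions",
                "n_trials": int(row["n"]),
                "detail": f"omission rate {row['omission_rate']:.3f} > "
                          f"{config.max_omission_rate}",
            })

    keep = ~df["subj_idx"].isin(excluded)
    clean = df[keep & ~is_miss].copy()
    clean = clean[clean["rt"] >= config.fast_guess_ms / 1000.0]
    n_miss_dropped = int((is_miss & keep).sum())
    if n_miss_dropped:
        report_rows.append({"subj_idx": None, "reason": "misses_dropped",
                            "n_trials": n_miss_dropped})
    if clean.empty:
        raise PipelineError("preprocess: no trials survive the exclusion rules")
    report = pd.DataFrame(report_rows, columns=["subj_idx", "reason", "n_trials", "detail"])
    report.attrs["n_input"] = n_input
    report.attrs["n_retained"] = len(clean)
    report.attrs["n_excluded"] = n_input - len(clean)
    return clean.reset_index(drop=True), report


def summarize_behaviour(clean: pd.DataFrame, collapse_instruction: bool = False):
    """Mean correct RT (with SEM) and error rate per condition x instruction.

    RT statistics use correct trials only; error rates use all responded
    trials.  Cells with a single RT have an undefined SEM and are flagged.
    Pass ``collapse_instruction=True`` for the view pooled over instructions.
    """
    if clean.empty:
        raise PipelineError("summarize_behaviour: empty trial table")
    df = clean.copy()
    if "condition" not in df.columns:
        df["condition"] = "all"
    keys = ["condition"] if collapse_instruction else ["condition", "instruction"]
    rows = []
    for key_vals, cell in df.groupby(keys):
        if not isinstance(key_vals, tuple):
            key_vals = (key_vals,)
        correct = cell[cell["response"] == 1]
        n_rt = len(correct)
        rows.append({
            **dict(zip(keys, key_vals)),
            "n_trials": len(cell),
            "error_rate": float((cell["response"] == 0).mean()),
            "mean_rt_correct": float(correct["rt"].mean()) if n_rt else np.nan,
            "sem_rt_correct": (float(correct["rt"].std(ddof=1) / np.sqrt(n_rt))
                               if n_rt > 1 else np.nan),
            "sem_undefined": n_rt <= 1,
        })
    return pd.DataFrame(rows)


@dataclass
class AnalysisReport:
    """Output bundle of :func:`run_full_analysis`."""

    behaviour_summary: pd.DataFrame
    exclusion_report: pd.DataFrame
    ladder_comparison: pd.DataFrame | None
    grid_comparison: pd.DataFrame | None
    best_model: str
    posterior_summary: pd.DataFrame
    rhat: pd.DataFrame
    ppc: pd.DataFrame | None
    manifest: dict
    traces: dict = field(default_factory=dict)


_DEFAULT_CONFIG = {
    "seed": 0,
    "synthetic": {
        "n_scenes": 3000,
        "n_per_condition": 160,
        "mode": "joint",
        "behaviour": {},
    },
    "preprocess": {},
    "fit": {"chains": 2, "iterations": 800, "burn": 100, "tune": 300},
    "stages": {"condition_ladder": False, "regression_grid": True},
    "grid": {"covariates": ["SC"], "include_quadratic_only": False},
    "ppc": {"n_sims": 100},
    "out_dir": None,
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _validate_config(cfg: dict) -> None:
    covs = cfg["grid"]["covariates"]
    regs = cfg.get("model", {}).get("regressions", {})
    model_covs = {r.get("covariate") for r in regs.values()} if regs else set()
    if len(model_covs) > 1:
        raise inference.ModelSpecError(
            "config requests both SC and CE in one model; never include both "
            "scene statistics simultaneously"
        )
    for c in covs:
        if c not in ("SC", "CE"):
            raise ValueError(f"unknown covariate {c!r} in grid config")


def run_full_analysis(config: dict | str | Path | None = None) -> AnalysisReport:
    """Run the full analysis chain on synthetic (or supplied) behaviour.

    ``config`` is a nested dict or a YAML path; see the packaged defaults.
    Stages: generate or load trials -> preprocess -> optional condition
    ladder -> regression grid -> best model (lowest DIC) diagnostics ->
    posterior predictive check -> report bundle with manifest (seed, config
    hash, versions).  Any stage failure raises :class:`PipelineError` naming
    the stage; partial outputs are preserved on the raised exception.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = _merge(_DEFAULT_CONFIG, config or {})
    _validate_config(cfg)
    seed = int(cfg["seed"])
    rng = np.random.default_rng(seed)
    partial: dict = {}

    try:
        if "data" in cfg and cfg["data"]:
            raw = pd.read_csv(cfg["data"])
        else:
            syn = cfg["synthetic"]
            pool = synth.generate_stat_pool(int(syn["n_scenes"]),
                                            seed=int(rng.integers(2**31 - 1)))
            sset = stimulus.assign_conditions(
                pool, n_per_condition=int(syn["n_per_condition"]),
                mode=syn["mode"], seed=int(rng.integers(2**31 - 1)),
            )
            sched = stimulus.build_trial_schedule(sset, seed=int(rng.integers(2**31 - 1)))
            bspec = synth.BehaviourGenSpec(
                **syn["behaviour"], seed=int(rng.integers(2**31 - 1))
            )
            raw = synth.generate_behaviour(bspec, sched)
    except Exception as exc:
        raise PipelineError(f"stage 'data': {exc}") from exc

    try:
        clean, excl = preprocess(raw, PreprocessConfig(**cfg["preprocess"]))
        partial["exclusions"] = excl
        summary = summarize_behaviour(clean)
        partial["behaviour_summary"] = summary
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'preprocess': {exc}") from exc

    fit_kw = {k: int(v) for k, v in cfg["fit"].items()}
    fits: list[tuple[inference.ModelSpec, float]] = []
    traces: dict = {}

    def _fit_specs(specs, stage_name):
        rows = []
        for spec in specs:
            try:
                model = inference.build_model(clean, spec)
                trace = inference.fit(model, seed=int(rng.integers(2**31 - 1)), **fit_kw)
                dic = inference.compute_dic(trace, model)
            except Exception as exc:
                raise PipelineError(f"stage '{stage_name}' ({spec.name}): {exc}") from exc
            rows.append((spec, dic))
            traces[spec.name] = (model, trace)
        return rows

    ladder_cmp = None
    if cfg["stages"].get("condition_ladder"):
        ladder = _fit_specs(inference.model_grid("condition_ladder"), "condition_ladder")
        ladder_cmp = inference.compare(ladder)
        partial["ladder_comparison"] = ladder_cmp

    grid_cmp = None
    if cfg["stages"].get("regression_grid"):
        specs = inference.model_grid(
            "regression_grid",
            covariates=tuple(cfg["grid"]["covariates"]),
            include_quadratic_only=bool(cfg["grid"]["include_quadratic_only"]),
        )
        fits = _fit_specs(specs, "regression_grid")
        grid_cmp = inference.compare(fits)
        partial["grid_comparison"] = grid_cmp

    if not traces:
        raise PipelineError("stage 'fit': no stage enabled in config")

    # best model = lowest DIC across everything fitted
    all_cmp = pd.concat([c for c in (ladder_cmp, grid_cmp) if c is not None])
    best_name = all_cmp.sort_values("dic").iloc[0]["model"]
    best_model, best_trace = traces[best_name]

    rhat = inference.gelman_rubin(best_trace)
    rhat_df = pd.DataFrame(
        [{"parameter": k, "rhat": v} for k, v in rhat.items()]
    )
    post_rows = []
    for name in best_trace.group_level:
        x = best_trace.get(name)
        P, direction, p_below, p_above = inference.posterior_p(best_trace, name)
        post_rows.append({
            "parameter": name, "mean": x.mean(), "sd": x.std(ddof=1),
            "hdi_2.5": np.percentile(x, 2.5), "hdi_97.5": np.percentile(x, 97.5),
            "P": P, "direction": direction,
            "p_below_0": p_below, "p_above_0": p_above,
        })
    post_df = pd.DataFrame(post_rows)

    ppc_table = None
    n_sims = int(cfg["ppc"].get("n_sims", 0))
    if n_sims:
        try:
            ppc = inference.posterior_predictive(
                best_trace, best_model, clean, n_sims=n_sims,
                seed=int(rng.integers(2**31 - 1)),
            )
            ppc_table = ppc.table
        except Exception as exc:
            raise PipelineError(f"stage 'ppc': {exc}") from exc

    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    manifest = {
        "seed": seed,
        "config_hash": cfg_hash,
        "package_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "python": platform.python_version(),
        "n_trials_clean": int(len(clean)),
        "best_model": str(best_name),
    }

    report = AnalysisReport(
        behaviour_summary=summary,
        exclusion_report=excl,
        ladder_comparison=ladder_cmp,
        grid_comparison=grid_cmp,
        best_model=str(best_name),
        posterior_summary=post_df,
        rhat=rhat_df,
        ppc=ppc_table,
        manifest=manifest,
        traces=traces,
    )

    out_dir = cfg.get("out_dir")
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "behaviour_summary.csv", index=False)
        excl.to_csv(out / "exclusions.csv", index=False)
        if ladder_cmp is not None:
            ladder_cmp.to_csv(out / "ladder_comparison.csv", index=False)
        if grid_cmp is not None:
            grid_cmp.to_csv(out / "grid_comparison.csv", index=False)
        post_df.to_csv(out / "posterior_summary.csv", index=False)
        rhat_df.to_csv(out / "rhat.csv", index=False)
        if ppc_table is not None:
            ppc_table.to_csv(out / "ppc.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return report
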