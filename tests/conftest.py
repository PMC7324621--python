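"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pandas as pd
import pytest

from sceneddm.ddm import simulate_trials
from sceneddm.synth import BehaviourGenSpec, generate_behaviour, generate_stat_pool


def make_schedule(n_trials: int, seed: int, sc_range=(0.4, 2.2)) -> pd.DataFrame:
    """Minimal schedule: SC values and alternating instruction blocks."""
    rng = np.random.default_rng(seed)
    sc = rng.uniform(*sc_range, n_trials)
    ce = np.exp(np.log(0.02) + 0.8 * (sc - np.mean(sc_range))
                + rng.normal(0, 0.35, n_trials))
    instr = np.repeat(
        rng.permutation(np.tile(["speed", "accurate"], n_trials // 40 + 1)), 20
    )[:n_trials]
    return pd.DataFrame({
        "scene_id": [f"s{i}" for i in range(n_trials)],
        "SC": sc,
        "CE": ce,
        "instruction": instr,
    })


def make_behaviour(
    n_subjects=4, n_trials=200, seed=0, beta1=0.3, beta2=-1.0, **kw
) -> pd.DataFrame:
    """Inverted-U behavioural dataset from known group-level parameters."""
    spec = BehaviourGenSpec(
        n_subjects=n_subjects, beta1=beta1, beta2=beta2, seed=seed, **kw
    )
    sched = make_schedule(n_trials, seed=seed + 1)
    data = generate_behaviour(spec, sched)
    return data[data["response"] >= 0].reset_index(drop=True)


@pytest.fixture(scope="session")
def small_behaviour() -> pd.DataFrame:
    return make_behaviour(n_subjects=4, n_trials=200, seed=5)


@pytest.fixture(scope="session")
def stat_pool() -> pd.DataFrame:
    return generate_stat_pool(7200, seed=3)


@pytest.fixture(scope="session")
def _warm_numba():
    """Compile the numba kernels once per session."""
    simulate_trials((np.ones(4), np.full(4, 1.5), np.full(4, 0.75), np.zeros(4)), seed=0)
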