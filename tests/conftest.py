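import numpy as np
import pandas as pd
import pytest

import calfplay as cp
from calfplay.synthetic import simulate_calves


def build_feature_table(
    n_calves=4,
    study_days=2,
    active_hours=1.0,
    play_fraction=0.01,
    seed=5,
    **overrides,
):
    """Simulate, clean, smooth and featurise a small cohort."""
    cfg = cp.SimulationConfig(
        n_calves=n_calves,
        study_days=study_days,
        active_hours_per_day=active_hours,
        play_time_fraction=play_fraction,
        seed=seed,
        **overrides,
    )
    rng = np.random.default_rng(seed)
    calves, meta = simulate_calves(cfg, rng)
    frames = []
    for calf in calves:
        for day in range(1, study_days + 1):
            traj, labels = cp.simulate_trajectory(cfg, calf, day)
            traj, _ = cp.filter_pen_bounds(traj)
            traj = cp.smooth_moving_average(traj, 10)
            frames.append(cp.feature_table(traj, labels))
    return pd.concat(frames, ignore_index=True), cfg, calves, meta


@pytest.fixture(scope="session")
def small_cohort():
    """A small labelled cohort shared by classification-level tests."""
    table, cfg, calves, meta = build_feature_table()
    return {"table": table, "config": cfg, "calves": calves, "meta": meta}


def random_window(rng, stationary=False):
    """A random 4-sample window on the 1 Hz grid."""
    t = np.arange(4, dtype=float)
    if stationary:
        x = np.full(4, rng.uniform(0, 6))
        y = np.full(4, rng.uniform(0, 10))
    else:
        x = rng.uniform(0, 6, 4)
        y = rng.uniform(0, 10, 4)
    return t, x, y
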