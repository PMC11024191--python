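"""Generator tests: husbandry schedules, metadata invariants, trajectory
kinematics, localization noise and the daily outcome model."""

import numpy as np
import pandas as pd
import pytest

import calfplay as cp
from calfplay.errors import ConfigError, InputError
from calfplay.synthetic import (
    health_category,
    milk_allowance,
    simulate_calves,
    weaning_stage,
)


@pytest.mark.parametrize(
    "day, litres",
    [(1, 10.0), (35, 10.0), (36, 9.6), (50, 4.0), (60, 0.0), (200, 0.0)],
)
def test_milk_allowance_schedule(day, litres):
    assert milk_allowance(day) == pytest.approx(litres)


def test_milk_allowance_rejects_bad_days():
    for bad in (0, -3, 1.5):
        with pytest.raises(InputError):
            milk_allowance(bad)


def test_weaning_stage_boundaries():
    assert weaning_stage(1) == "pre_weaned"
    assert weaning_stage(35) == "pre_weaned"
    assert weaning_stage(36) == "step_down"
    assert weaning_stage(60) == "step_down"
    assert weaning_stage(61) == "weaned"


@pytest.mark.parametrize(
    "score, cat",
    [(0, "healthy"), (2, "healthy"), (3, "moderate"), (4, "moderate"), (5, "sick"), (9, "sick")],
)
def test_wisconsin_health_mapping(score, cat):
    assert health_category(score) == cat


def test_config_rejects_inverted_speed_range():
    with pytest.raises(ConfigError):
        cp.SimulationConfig(walk_speed_min=1.0, walk_speed_max=0.2).validate()
    with pytest.raises(ConfigError):
        cp.SimulationConfig(play_min_bout_s=2.0).validate()


def _one_calf(cfg, seed=0):
    rng = np.random.default_rng(seed)
    calves, _ = simulate_calves(cfg, rng)
    return calves[0]


def test_trajectory_is_seed_deterministic():
    cfg = cp.SimulationConfig(n_calves=1, study_days=1, active_hours_per_day=0.2)
    calf = _one_calf(cfg)
    t1, l1 = cp.simulate_trajectory(cfg, calf, 1, seed=9)
    t2, l2 = cp.simulate_trajectory(cfg, calf, 1, seed=9)
    assert np.array_equal(t1.t, t2.t)
    assert np.array_equal(t1.x, t2.x)
    assert np.array_equal(t1.y, t2.y)
    pd.testing.assert_frame_equal(l1, l2)


def test_rest_only_noise_free_trajectory_is_constant():
    cfg = cp.SimulationConfig(
        n_calves=1,
        study_days=1,
        active_hours_per_day=0.1,
        walk_mean_s=0.0,
        feeder_visit_mean_s=0.0,
        rest_jitter_m=0.0,
        play_time_fraction=0.0,
        dash_time_fraction=0.0,
        cep_m=0.0,
        missing_fraction=0.0,
        outlier_fraction=0.0,
    )
    calf = _one_calf(cfg)
    traj, labels = cp.simulate_trajectory(cfg, calf, 1, seed=3)
    assert labels.empty
    assert np.ptp(traj.x) == 0.0 and np.ptp(traj.y) == 0.0


def test_play_bouts_last_at_least_3s_and_never_overlap():
    cfg = cp.SimulationConfig(
        n_calves=1, study_days=1, active_hours_per_day=2.0, play_time_fraction=0.02
    )
    calf = _one_calf(cfg)
    _, labels = cp.simulate_trajectory(cfg, calf, 1, seed=4)
    assert len(labels) > 3
    durations = labels["stop"] - labels["start"]
    assert (durations >= 3.0).all()
    starts = labels["start"].to_numpy()
    stops = labels["stop"].to_numpy()
    assert (starts[1:] >= stops[:-1]).all()


def test_median_radial_error_matches_cep():
    """Noisy minus true positions: median radial error -> CEP within 2%."""
    cfg = cp.SimulationConfig(
        n_calves=1,
        study_days=1,
        active_hours_per_day=8.0,
        missing_fraction=0.0,
        outlier_fraction=0.0,
    )
    calf = _one_calf(cfg)
    noisy, _, truth = cp.simulate_trajectory(cfg, calf, 1, seed=6, return_truth=True)
    radial = np.hypot(noisy.x - truth.x, noisy.y - truth.y)
    assert np.median(radial) == pytest.approx(cfg.cep_m, rel=0.02)


def test_realized_play_fraction_matches_configured():
    """Daily play-time fractions scatter around the configured target."""
    target = 0.002
    cfg = cp.SimulationConfig(
        n_calves=1,
        study_days=40,
        active_hours_per_day=4.0,
        play_time_fraction=target,
    )
    calf = _one_calf(cfg)
    horizon = cfg.active_hours_per_day * 3600.0
    fractions = []
    for day in range(1, 41):
        _, labels = cp.simulate_trajectory(cfg, calf, day)
        fractions.append(float((labels["stop"] - labels["start"]).sum()) / horizon)
    fractions = np.array(fractions)
    sem = fractions.std(ddof=1) / np.sqrt(len(fractions))
    assert abs(fractions.mean() - target) < 3 * sem


def test_clock_offset_shifts_labels_only():
    cfg = cp.SimulationConfig(
        n_calves=1, study_days=1, active_hours_per_day=0.5, play_time_fraction=0.05
    )
    calf = _one_calf(cfg)
    _, l0 = cp.simulate_trajectory(cfg, calf, 1, seed=2)
    cfg_off = cp.SimulationConfig(
        n_calves=1,
        study_days=1,
        active_hours_per_day=0.5,
        play_time_fraction=0.05,
        clock_offset_s=5.0,
    )
    _, l5 = cp.simulate_trajectory(cfg_off, calf, 1, seed=2)
    assert np.allclose(l5["start"], l0["start"] + 5.0)
    aligned = cp.align_labels(l5, -5.0)
    assert np.allclose(aligned["start"], l0["start"])


# ---------------------------------------------------------------------------
# temperature
# ---------------------------------------------------------------------------

def test_temperature_daily_mean_is_exact_subdaily_average():
    ts = cp.simulate_temperature(5, seed=1)
    manual = ts.subdaily.groupby("day")["temp_c"].mean()
    assert np.allclose(ts.daily.set_index("day")["mean_temp_c"], manual)
    assert (ts.subdaily.groupby("day").size() == 144).all()


def test_temperature_zero_noise_lies_on_seasonal_sinusoid():
    ts = cp.simulate_temperature(
        4, seed=0, mean_c=10.0, amplitude_c=5.0, noise_sd_c=0.0, start_day_of_year=100
    )
    doy = np.arange(100, 104)
    expected = 10.0 + 5.0 * np.sin(2 * np.pi * (doy - 110) / 365.25)
    assert np.allclose(ts.daily["mean_temp_c"], expected, atol=1e-9)


def test_temperature_seed_repeatability():
    a = cp.simulate_temperature(3, seed=11)
    b = cp.simulate_temperature(3, seed=11)
    pd.testing.assert_frame_equal(a.subdaily, b.subdaily)


# ---------------------------------------------------------------------------
# outcome generator
# ---------------------------------------------------------------------------

def _null_outcome_config(**kw):
    base = dict(
        beta_intercept=3.0,
        beta_age=0.0,
        beta_cohort2=0.0,
        beta_cohort3=0.0,
        beta_stepdown=0.0,
        beta_weaned=0.0,
        beta_moderate=0.0,
        beta_sick=0.0,
        beta_male=0.0,
        beta_temp=0.0,
        calf_sd=0.0,
    )
    base.update(kw)
    return cp.SimulationConfig(**base)


def test_outcomes_seed_deterministic():
    cfg = cp.SimulationConfig(n_calves=5, study_days=10)
    a = cp.simulate_cohort_outcomes(cfg, seed=3)
    b = cp.simulate_cohort_outcomes(cfg, seed=3)
    pd.testing.assert_frame_equal(a, b)


def test_outcomes_metadata_invariants():
    cfg = cp.SimulationConfig(n_calves=8, study_days=70)
    out = cp.simulate_cohort_outcomes(cfg, seed=1)
    assert (out.loc[out["day"] <= 35, "weaning_stage"] == "pre_weaned").all()
    assert (
        out.loc[(out["day"] > 35) & (out["day"] <= 60), "weaning_stage"] == "step_down"
    ).all()
    assert (out.loc[out["day"] > 60, "weaning_stage"] == "weaned").all()
    by_score = out.groupby("health_status")["wisconsin_score"]
    assert by_score.max().get("healthy", 0) <= 2
    assert (out["total_play_s"] % 3 == 0).all()
    assert (out["total_play_s"] >= 3 * out["n_instances"]).all()


def test_outcomes_null_model_has_no_age_trend():
    cfg = _null_outcome_config(n_calves=60, study_days=30, entry_age_sd_days=0.0)
    out = cp.simulate_cohort_outcomes(cfg, seed=9)
    means = out.groupby("age_days")["n_instances"].mean()
    slope = np.polyfit(means.index.to_numpy(float), np.log(means.to_numpy()), 1)[0]
    assert abs(slope) < 0.01


def test_outcomes_age_effect_matches_closed_form():
    """With only an age effect, log mean counts fall at beta_age per day."""
    cfg = _null_outcome_config(
        n_calves=200, study_days=30, beta_age=-0.02, beta_intercept=4.0,
        entry_age_sd_days=0.0,
    )
    out = cp.simulate_cohort_outcomes(cfg, seed=12)
    means = out.groupby("age_days")["n_instances"].mean()
    slope = np.polyfit(means.index.to_numpy(float), np.log(means.to_numpy()), 1)[0]
    assert slope == pytest.approx(-0.02, abs=0.005)
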