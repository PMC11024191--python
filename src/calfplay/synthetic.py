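"""Synthetic cohort generator.

Emulates the data a UWB location system produces for group-housed calves:
1 Hz (x, y) fixes inside a 6 m x 10 m pen with a 0.15 m circular error
probability, ethogram label intervals for locomotor play (rapid forward
movement lasting at least 3 s), calf metadata (cohort, sex-breed, entry
age, weaning stage by study day, Wisconsin-score health category), ambient
temperature, and daily play-outcome tables driven by a log-link
negative-binomial model with a calf random intercept.

Behaviour is a semi-Markov state machine (rest / walk / feeder visit) with
exponential dwell times, onto which play bouts and short sub-3-s sprints
("dashes", rapid movement that fails the play definition) are superimposed
as independent renewal processes.  Localization noise is isotropic
Gaussian with sigma = CEP / 1.1774 so the median radial error equals the
configured CEP.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .errors import ConfigError, InputError
from .preprocessing import Trajectory

# state codes for the per-sample schedule
_REST, _WALK, _FEEDER, _PLAY, _DASH = 0, 1, 2, 3, 4

#: start day-of-year per cohort (June, May, September entries)
COHORT_START_DOY = {1: 152, 2: 121, 3: 244}

SECONDS_PER_DAY = 86_400.0

WEANING_STAGES = ("pre_weaned", "step_down", "weaned")
HEALTH_STATUSES = ("healthy", "moderate", "sick")
SEX_BREEDS = ("female_HO", "male_HOxAA")


# ---------------------------------------------------------------------------
# husbandry schedule
# ---------------------------------------------------------------------------

def milk_allowance(day_of_study: int) -> float:
    """Daily milk-replacer allowance in litres.

    10 L/day through study day 35, then reduced by 400 ml/day until it
    reaches zero on day 60; never negative.
    """
    if day_of_study < 1 or int(day_of_study) != day_of_study:
        raise InputError(f"day_of_study must be a positive integer, got {day_of_study}")
    if day_of_study <= 35:
        return 10.0
    return max(0.0, 10.0 - 0.4 * (day_of_study - 35))


def weaning_stage(day_of_study: int) -> str:
    """Weaning stage by study day: pre-weaned (1-35), step-down (36-60),
    weaned (after 60)."""
    if day_of_study < 1:
        raise InputError(f"day_of_study must be >= 1, got {day_of_study}")
    if day_of_study <= 35:
        return "pre_weaned"
    if day_of_study <= 60:
        return "step_down"
    return "weaned"


def health_category(wisconsin_score: int) -> str:
    """Wisconsin total score to category: 0-2 healthy, 3-4 moderate,
    >= 5 sick."""
    if wisconsin_score < 0:
        raise InputError(f"score must be >= 0, got {wisconsin_score}")
    if wisconsin_score <= 2:
        return "healthy"
    if wisconsin_score <= 4:
        return "moderate"
    return "sick"


# ---------------------------------------------------------------------------
# calf metadata
# ---------------------------------------------------------------------------

@dataclass
class CalfMetadata:
    calf_id: str
    calf_index: int
    cohort_id: int
    sex_breed: str
    age_at_start_days: int

    def age_on_day(self, day: int) -> int:
        return self.age_at_start_days + day

    @staticmethod
    def weaning_stage(day: int) -> str:
        return weaning_stage(day)


def simulate_calves(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[list[CalfMetadata], pd.DataFrame]:
    """Draw calf metadata and a per calf-day health table.

    Health follows a three-state illness process: a healthy calf starts an
    episode with a small daily probability, stays sick for a geometric
    number of days, recovers through a moderate phase, then returns to
    healthy.  The Wisconsin total score is drawn within the category's
    defining range.
    """
    calves: list[CalfMetadata] = []
    rows = []
    score_range = {"healthy": (0, 2), "moderate": (3, 4), "sick": (5, 8)}
    for i in range(config.n_calves):
        cohort = (i % 3) + 1
        sex = "male_HOxAA" if rng.random() < config.male_fraction else "female_HO"
        age0 = int(np.clip(round(rng.normal(config.entry_age_mean_days,
                                            config.entry_age_sd_days)), 14, None))
        calf = CalfMetadata(f"C{i + 1:03d}", i, cohort, sex, age0)
        calves.append(calf)

        state = "healthy"
        for day in range(1, config.study_days + 1):
            if state == "healthy":
                if rng.random() < config.health_episode_rate:
                    state = "sick"
            elif state == "sick":
                if rng.random() < 1.0 / max(config.sick_mean_days, 1.0):
                    state = "moderate"
            else:  # moderate
                if rng.random() < 1.0 / max(config.moderate_mean_days, 1.0):
                    state = "healthy"
            lo, hi = score_range[state]
            score = int(rng.integers(lo, hi + 1))
            rows.append(
                {
                    "calf_id": calf.calf_id,
                    "cohort": cohort,
                    "day": day,
                    "age_days": calf.age_on_day(day),
                    "weaning_stage": weaning_stage(day),
                    "wisconsin_score": score,
                    "health_status": health_category(score),
                    "sex_breed": sex,
                }
            )
    return calves, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# temperature
# ---------------------------------------------------------------------------

@dataclass
class TemperatureSeries:
    """Ambient temperature: a 10-min series plus exact within-day means."""

    subdaily: pd.DataFrame  # columns: day, t_s, temp_c
    daily: pd.DataFrame  # columns: day, mean_temp_c


def simulate_temperature(
    study_days: int,
    seed: int | np.random.Generator = 0,
    *,
    mean_c: float = 12.0,
    amplitude_c: float = 8.0,
    diurnal_amplitude_c: float = 3.0,
    noise_sd_c: float = 2.0,
    start_day_of_year: int = 152,
    samples_per_day: int = 144,
) -> TemperatureSeries:
    """Seasonal sinusoid + within-day diurnal cycle + Gaussian noise,
    sampled every 10 minutes (144 values/day by default).

    The daily mean is computed as the arithmetic mean of that day's
    sub-daily values, so the two outputs are exactly consistent.  With
    ``noise_sd_c = 0`` the daily means lie on the seasonal sinusoid because
    the diurnal cycle spans exactly one period per day and averages out.
    """
    if study_days < 1:
        raise InputError("study_days must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    days = np.arange(1, study_days + 1)
    doy = start_day_of_year + days - 1
    seasonal = mean_c + amplitude_c * np.sin(2 * np.pi * (doy - 110) / 365.25)

    frac = (np.arange(samples_per_day) + 0.5) / samples_per_day
    diurnal = diurnal_amplitude_c * np.sin(2 * np.pi * frac)
    temp = (
        seasonal[:, None]
        + diurnal[None, :]
        + rng.normal(0.0, noise_sd_c, size=(study_days, samples_per_day))
    )
    subdaily = pd.DataFrame(
        {
            "day": np.repeat(days, samples_per_day),
            "t_s": np.tile(np.arange(samples_per_day) * 600.0, study_days)
            + (np.repeat(days, samples_per_day) - 1) * SECONDS_PER_DAY,
            "temp_c": temp.ravel(),
        }
    )
    daily = (
        subdaily.groupby("day", as_index=False)["temp_c"]
        .mean()
        .rename(columns={"temp_c": "mean_temp_c"})
    )
    return TemperatureSeries(subdaily=subdaily, daily=daily)


# ---------------------------------------------------------------------------
# trajectory simulation
# ---------------------------------------------------------------------------

def _renewal_bouts(
    rng: np.random.Generator,
    horizon_s: float,
    time_fraction: float,
    draw_duration,
) -> list[tuple[float, float]]:
    """Alternating gap/bout renewal process hitting a target time fraction."""
    if time_fraction <= 0:
        return []
    # mean gap chosen so E[bout] / (E[gap] + E[bout]) = time_fraction
    probe = [draw_duration() for _ in range(200)]
    mean_bout = float(np.mean(probe))
    mean_gap = mean_bout * (1.0 - time_fraction) / time_fraction
    bouts = []
    pos = rng.exponential(mean_gap)
    while True:
        dur = draw_duration()
        if pos + dur > horizon_s:
            break
        bouts.append((pos, pos + dur))
        pos += dur + rng.exponential(mean_gap)
    return bouts


def _fold(a: np.ndarray, hi: float) -> np.ndarray:
    """Reflect unbounded coordinates into [0, hi] (triangle-wave fold)."""
    period = 2.0 * hi
    b = np.mod(a, period)
    return np.where(b > hi, period - b, b)


def _background_states(
    config: SimulationConfig, rng: np.random.Generator, horizon_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """Semi-Markov rest/walk/feeder schedule covering [0, horizon_s].

    A state is disabled by setting its mean dwell time to zero; rest must
    stay enabled.
    """
    means = {
        _REST: config.rest_mean_s,
        _WALK: config.walk_mean_s,
        _FEEDER: config.feeder_visit_mean_s,
    }
    if means[_REST] <= 0:
        raise ConfigError("rest_mean_s must be positive")
    enabled = [s for s, m in means.items() if m > 0]
    states, durations = [], []
    total = 0.0
    state = _REST
    while total < horizon_s:
        states.append(state)
        dur = rng.exponential(means[state])
        durations.append(dur)
        total += dur
        if len(enabled) == 1:
            continue
        if state == _FEEDER:
            state = _REST
        else:
            others = [s for s in enabled if s != state]
            # feeder visits are rarer than rest/walk alternation
            weights = np.array([0.25 if s == _FEEDER else 1.0 for s in others])
            state = int(rng.choice(others, p=weights / weights.sum()))
    return np.array(states), np.array(durations)


def simulate_trajectory(
    config: SimulationConfig,
    calf: CalfMetadata,
    day: int,
    seed: int | None = None,
    return_truth: bool = False,
):
    """Simulate one calf-day of 1 Hz positions and its play-label intervals.

    Returns ``(trajectory, labels)`` where labels is a DataFrame with
    columns calf_id, start, stop, behaviour listing every play bout with
    exact start/stop times (shifted by ``clock_offset_s`` to emulate video
    clock desynchronisation).  With ``return_truth=True`` a third element
    carries the noise-free positions aligned to the retained samples.
    """
    config.validate()
    if day < 1:
        raise InputError(f"day must be >= 1, got {day}")
    base_seed = config.seed if seed is None else seed
    rng = np.random.default_rng([base_seed, calf.calf_index, day])

    hz = config.sample_hz
    dt = 1.0 / hz
    horizon = config.active_hours_per_day * 3600.0
    n = int(round(horizon * hz))
    day_start = (day - 1) * SECONDS_PER_DAY
    t_rel = np.arange(n) * dt

    # --- play bouts and sub-3-s dashes (renewal processes) -----------------
    play_bouts = _renewal_bouts(
        rng,
        horizon,
        config.play_time_fraction,
        lambda: config.play_min_bout_s + rng.exponential(config.play_mean_extra_s),
    )
    dashes = _renewal_bouts(
        rng,
        horizon,
        config.dash_time_fraction,
        lambda: rng.uniform(config.dash_min_s, config.dash_max_s),
    )
    dashes = [
        (a, b)
        for a, b in dashes
        if not any(a < pb and b > pa for pa, pb in play_bouts)
    ]

    # --- per-sample state schedule ----------------------------------------
    bg_states, bg_durs = _background_states(config, rng, horizon)
    edges = np.concatenate([[0.0], np.cumsum(bg_durs)])
    state = bg_states[np.clip(np.searchsorted(edges, t_rel, side="right") - 1,
                              0, len(bg_states) - 1)].copy()
    for a, b in play_bouts:
        state[(t_rel >= a) & (t_rel < b)] = _PLAY
    for a, b in dashes:
        state[(t_rel >= a) & (t_rel < b)] = _DASH

    # --- positions, one contiguous state run at a time ---------------------
    W, L = config.pen_width_m, config.pen_length_m
    feeder_xy = np.array([W - 0.5, L - 0.5])
    X = np.empty(n)
    Y = np.empty(n)
    pos = rng.uniform([0.3, 0.3], [W - 0.3, L - 0.3])
    heading = rng.uniform(0.0, 2.0 * np.pi)

    run_breaks = np.flatnonzero(np.diff(state) != 0) + 1
    bounds = np.concatenate([[0], run_breaks, [n]])
    for i0, i1 in zip(bounds[:-1], bounds[1:]):
        s = state[i0]
        m = i1 - i0
        if s == _REST:
            jitter = rng.normal(0.0, config.rest_jitter_m, size=(m, 2))
            X[i0:i1] = np.clip(pos[0] + jitter[:, 0], 0.0, W)
            Y[i0:i1] = np.clip(pos[1] + jitter[:, 1], 0.0, L)
        elif s == _FEEDER:
            vec = feeder_xy - pos
            dist = float(np.hypot(*vec))
            speed = rng.uniform(config.walk_speed_min, config.walk_speed_max)
            n_travel = min(m, int(math.ceil(dist / max(speed * dt, 1e-9))))
            if n_travel > 0 and dist > 0:
                unit = vec / dist
                steps = np.minimum(np.arange(1, n_travel + 1) * speed * dt, dist)
                X[i0:i0 + n_travel] = pos[0] + unit[0] * steps
                Y[i0:i0 + n_travel] = pos[1] + unit[1] * steps
                heading = math.atan2(unit[1], unit[0])
            n_dwell = m - n_travel
            if n_dwell > 0:
                jitter = rng.normal(0.0, config.rest_jitter_m, size=(n_dwell, 2))
                X[i0 + n_travel:i1] = np.clip(feeder_xy[0] + jitter[:, 0], 0.0, W)
                Y[i0 + n_travel:i1] = np.clip(feeder_xy[1] + jitter[:, 1], 0.0, L)
            pos = np.array([X[i1 - 1], Y[i1 - 1]])
        else:  # walk, play or dash: correlated-heading locomotion
            if s == _WALK:
                speeds = np.full(m, rng.uniform(config.walk_speed_min,
                                                config.walk_speed_max))
                turn_sd = config.walk_turn_sd_rad
            else:
                speeds = rng.uniform(config.play_speed_min, config.play_speed_max, m)
                turn_sd = config.play_turn_sd_rad
            increments = rng.normal(0.0, turn_sd, m)
            if s in (_PLAY, _DASH) and config.play_buck_prob_per_s > 0:
                bucks = rng.random(m) < config.play_buck_prob_per_s
                increments[bucks] += rng.choice([-1.0, 1.0], bucks.sum()) * rng.uniform(
                    0.5 * np.pi, np.pi, bucks.sum()
                )
            headings = heading + np.cumsum(increments)
            dx = speeds * dt * np.cos(headings)
            dy = speeds * dt * np.sin(headings)
            X[i0:i1] = _fold(pos[0] + np.cumsum(dx), W)
            Y[i0:i1] = _fold(pos[1] + np.cumsum(dy), L)
            pos = np.array([X[i1 - 1], Y[i1 - 1]])
            heading = headings[-1]

    truth_x, truth_y = X.copy(), Y.copy()

    # --- sensor degradation -------------------------------------------------
    sigma = config.noise_sigma_m
    if sigma > 0:
        X = X + rng.normal(0.0, sigma, n)
        Y = Y + rng.normal(0.0, sigma, n)
    if config.outlier_fraction > 0:
        n_out = rng.binomial(n, config.outlier_fraction)
        idx = rng.choice(n, size=n_out, replace=False)
        side = rng.integers(0, 4, n_out)
        off = rng.uniform(0.05, 1.0, n_out)
        X[idx[side == 0]] = -off[side == 0]
        X[idx[side == 1]] = W + off[side == 1]
        Y[idx[side == 2]] = -off[side == 2]
        Y[idx[side == 3]] = L + off[side == 3]
    keep = np.ones(n, dtype=bool)
    if config.missing_fraction > 0:
        target = config.missing_fraction * n
        dropped = 0
        while dropped < target:
            start = int(rng.integers(0, n))
            length = int(rng.exponential(60.0)) + 1
            block = slice(start, min(start + length, n))
            dropped += np.count_nonzero(keep[block])
            keep[block] = False

    t_abs = day_start + t_rel
    traj = Trajectory(calf.calf_id, t_abs[keep], X[keep], Y[keep], (W, L))
    labels = pd.DataFrame(
        {
            "calf_id": calf.calf_id,
            "start": [day_start + a + config.clock_offset_s for a, _ in play_bouts],
            "stop": [day_start + b + config.clock_offset_s for _, b in play_bouts],
            "behaviour": "play",
        }
    )
    if return_truth:
        truth = Trajectory(calf.calf_id, t_abs[keep], truth_x[keep], truth_y[keep], (W, L))
        return traj, labels, truth
    return traj, labels


# ---------------------------------------------------------------------------
# daily outcome generator (association-stage ground truth)
# ---------------------------------------------------------------------------

def simulate_cohort_outcomes(
    config: SimulationConfig, seed: int | None = None
) -> pd.DataFrame:
    """Simulate per calf-day play outcomes from the log-link model.

    Instance counts are negative-binomial with
    ``log mu = intercept + beta . covariates + calf random intercept``;
    daily play duration is 3 s times a per-instance window-count draw
    (shifted geometric, so every instance lasts at least one 3-s window).
    Returns one row per calf-day with covariates and both responses.
    """
    config.validate()
    rng = np.random.default_rng([config.seed if seed is None else seed, 7])
    calves, meta = simulate_calves(config, rng)

    cohorts = sorted(meta["cohort"].unique())
    temp_by_cohort = {}
    for c in cohorts:
        doy = COHORT_START_DOY.get(c, config.start_day_of_year)
        ts = simulate_temperature(
            config.study_days,
            rng,
            mean_c=config.temp_mean_c,
            amplitude_c=config.temp_amplitude_c,
            noise_sd_c=config.temp_noise_sd_c,
            start_day_of_year=doy,
        )
        temp_by_cohort[c] = ts.daily.set_index("day")["mean_temp_c"]

    df = meta.copy()
    df["mean_temp_c"] = [
        temp_by_cohort[c].loc[d] for c, d in zip(df["cohort"], df["day"])
    ]

    intercepts = {
        calf.calf_id: rng.normal(0.0, config.calf_sd) if config.calf_sd > 0 else 0.0
        for calf in calves
    }
    log_mu = (
        config.beta_intercept
        + config.beta_age * df["age_days"].to_numpy(float)
        + config.beta_cohort2 * (df["cohort"] == 2).to_numpy(float)
        + config.beta_cohort3 * (df["cohort"] == 3).to_numpy(float)
        + config.beta_stepdown * (df["weaning_stage"] == "step_down").to_numpy(float)
        + config.beta_weaned * (df["weaning_stage"] == "weaned").to_numpy(float)
        + config.beta_moderate * (df["health_status"] == "moderate").to_numpy(float)
        + config.beta_sick * (df["health_status"] == "sick").to_numpy(float)
        + config.beta_male * (df["sex_breed"] == "male_HOxAA").to_numpy(float)
        + config.beta_temp * df["mean_temp_c"].to_numpy(float)
        + df["calf_id"].map(intercepts).to_numpy(float)
    )
    mu = np.exp(log_mu)
    r = 1.0 / config.nb_alpha
    counts = rng.negative_binomial(r, r / (r + mu))

    # windows per instance: 1 + Geometric number of extra windows
    p_extra = 1.0 / max(config.mean_windows_per_instance, 1.0)
    windows = counts.astype(np.int64).copy()
    pos = counts > 0
    if p_extra < 1.0 and pos.any():
        windows[pos] += rng.negative_binomial(counts[pos], p_extra)

    df["n_instances"] = counts
    df["total_play_s"] = 3.0 * windows
    return df
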