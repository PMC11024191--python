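"""Configuration objects for the simulation and the pipeline.

All tunable science parameters live here so that a single YAML file (plus a
master seed) fully determines a pipeline run.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError

#: Rayleigh median factor sqrt(2 ln 2): for isotropic Gaussian noise with
#: per-axis standard deviation sigma, the median radial error is
#: sigma * RAYLEIGH_MEDIAN_FACTOR.  Dividing the circular error probability
#: (CEP, the median radial error) by this factor recovers sigma.
RAYLEIGH_MEDIAN_FACTOR = 1.1774

#: Seconds per analysis window.
WINDOW_S = 3.0


@dataclass
class Hyperparameters:
    """AdaBoost ensemble hyperparameters.

    Defaults are the optimum found for the play/non-play problem: shallow
    trees with at most 10 splits, 494 boosting cycles and a learning rate of
    0.001016.
    """

    max_splits: int = 10
    n_learning_cycles: int = 494
    learning_rate: float = 0.001016

    def validate(self) -> None:
        if self.max_splits < 1:
            raise ConfigError(f"max_splits must be >= 1, got {self.max_splits}")
        if self.n_learning_cycles < 1:
            raise ConfigError(
                f"n_learning_cycles must be >= 1, got {self.n_learning_cycles}"
            )
        if self.learning_rate <= 0:
            raise ConfigError(
                f"learning_rate must be > 0, got {self.learning_rate}"
            )


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Geometry, sampling and localization-noise defaults match the study
    conditions being emulated (6 m x 10 m straw pens, 1 Hz UWB fixes with a
    0.15 m circular error probability).  Behaviour-state kinematics are
    documented assumptions: the ethogram defines locomotor play only as
    rapid forward movement lasting at least 3 s, so the speed ranges below
    are generator choices, not measurements.
    """

    # -- geometry & sampling ------------------------------------------------
    pen_width_m: float = 6.0
    pen_length_m: float = 10.0
    n_calves: int = 15
    study_days: int = 14
    sample_hz: float = 1.0
    active_hours_per_day: float = 24.0

    # -- behaviour state machine (semi-Markov, exponential dwells) ----------
    rest_mean_s: float = 120.0
    walk_mean_s: float = 30.0
    feeder_visit_mean_s: float = 60.0
    rest_jitter_m: float = 0.02
    walk_speed_min: float = 0.15
    walk_speed_max: float = 0.5
    walk_turn_sd_rad: float = 0.6
    # locomotor play: rapid forward movement, minimum 3 s; discrete
    # "bucking" events flip the heading sharply (positions are 2-D, so
    # jumps/bucks appear as heading discontinuities, not vertical motion)
    play_speed_min: float = 2.0
    play_speed_max: float = 4.0
    play_turn_sd_rad: float = 0.15
    play_buck_prob_per_s: float = 0.10
    play_min_bout_s: float = 3.0
    play_mean_extra_s: float = 4.0
    play_time_fraction: float = 0.0016
    # short (< 3 s) sprints: rapid movement that fails the 3-s play
    # definition and is therefore labelled non-play
    dash_time_fraction: float = 0.0005
    dash_min_s: float = 1.0
    dash_max_s: float = 2.0

    # -- daily play-rate model (log scale, count response) -------------------
    beta_intercept: float = 4.04
    beta_age: float = -0.02
    beta_cohort2: float = -0.09
    beta_cohort3: float = 0.49
    beta_stepdown: float = 0.10
    beta_weaned: float = 0.42
    beta_moderate: float = 0.0
    beta_sick: float = -0.12
    beta_male: float = -0.18
    beta_temp: float = -0.008
    calf_sd: float = 0.3
    nb_alpha: float = 0.5
    #: mean number of 3-s windows in one play instance (shifted-geometric)
    mean_windows_per_instance: float = 2.0

    # -- calf metadata ------------------------------------------------------
    entry_age_mean_days: float = 33.0
    entry_age_sd_days: float = 6.0
    male_fraction: float = 3.0 / 46.0
    health_episode_rate: float = 0.02
    sick_mean_days: float = 4.0
    moderate_mean_days: float = 3.0

    # -- temperature --------------------------------------------------------
    temp_mean_c: float = 12.0
    temp_amplitude_c: float = 8.0
    temp_noise_sd_c: float = 2.0
    start_day_of_year: int = 152

    # -- sensor degradation -------------------------------------------------
    cep_m: float = 0.15
    missing_fraction: float = 0.01
    outlier_fraction: float = 0.003
    clock_offset_s: float = 0.0

    seed: int = 0

    def validate(self) -> None:
        if self.pen_width_m <= 0 or self.pen_length_m <= 0:
            raise ConfigError("pen dimensions must be positive")
        if self.n_calves < 1 or self.study_days < 1:
            raise ConfigError("n_calves and study_days must be >= 1")
        if self.sample_hz <= 0:
            raise ConfigError("sample_hz must be positive")
        if self.cep_m < 0:
            raise ConfigError("cep_m must be >= 0")
        if self.play_min_bout_s < 3.0:
            raise ConfigError("play bouts must last at least 3 s")
        for lo, hi, name in [
            (self.walk_speed_min, self.walk_speed_max, "walk"),
            (self.play_speed_min, self.play_speed_max, "play"),
        ]:
            if lo < 0 or hi < lo:
                raise ConfigError(f"{name} speed range inverted or negative")
        for frac, name in [
            (self.play_time_fraction, "play_time_fraction"),
            (self.dash_time_fraction, "dash_time_fraction"),
            (self.missing_fraction, "missing_fraction"),
            (self.outlier_fraction, "outlier_fraction"),
        ]:
            if not 0 <= frac < 1:
                raise ConfigError(f"{name} must be in [0, 1)")
        if self.calf_sd < 0 or self.nb_alpha <= 0:
            raise ConfigError("calf_sd must be >= 0 and nb_alpha > 0")

    @property
    def noise_sigma_m(self) -> float:
        """Per-axis Gaussian sigma whose median radial error equals cep_m."""
        return self.cep_m / RAYLEIGH_MEDIAN_FACTOR


@dataclass
class PipelineConfig:
    """Full pipeline configuration: file paths, stage toggles, parameters."""

    out_dir: str = "calfplay_run"
    # input paths; empty string means "produced by an earlier stage"
    trajectories_csv: str = ""
    labels_csv: str = ""
    metadata_csv: str = ""
    temperature_csv: str = ""
    exclusions_csv: str = ""

    # stage toggles
    run_simulate: bool = True
    run_preprocess: bool = True
    run_features: bool = True
    run_train: bool = True
    run_quantify: bool = True
    run_summarise: bool = True
    run_model: bool = True

    # stage parameters
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    hyperparameters: Hyperparameters = field(default_factory=Hyperparameters)
    smoothing_window_s: float = 10.0
    window_s: float = WINDOW_S
    test_fraction: float = 0.3
    condition_grid_start: int = 10
    condition_grid_stop: int = 2180
    condition_grid_step: int = 70
    condition_n_nonplay: int = 250_000
    seed: int = 0

    def validate(self) -> None:
        self.simulation.validate()
        self.hyperparameters.validate()
        if not 0 < self.test_fraction < 1:
            raise ConfigError("test_fraction must be in (0, 1)")
        if self.window_s <= 0 or self.smoothing_window_s <= 0:
            raise ConfigError("window lengths must be positive")
        if self.condition_grid_step <= 0:
            raise ConfigError("condition_grid_step must be positive")

    # -- YAML round trip ----------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ConfigError(f"unknown config keys: {unknown}")
        kwargs = dict(raw)
        if "simulation" in kwargs and isinstance(kwargs["simulation"], dict):
            sim_known = {f.name for f in dataclasses.fields(SimulationConfig)}
            bad = sorted(set(kwargs["simulation"]) - sim_known)
            if bad:
                raise ConfigError(f"unknown simulation keys: {bad}")
            kwargs["simulation"] = SimulationConfig(**kwargs["simulation"])
        if "hyperparameters" in kwargs and isinstance(kwargs["hyperparameters"], dict):
            kwargs["hyperparameters"] = Hyperparameters(**kwargs["hyperparameters"])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg
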