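"""End-to-end orchestration of the two-step classification +
quantification pipeline and the association stage.

Stages: simulate (optional) -> preprocess -> features -> train ->
quantify -> summarise -> model.  Every stage reads/writes documented CSV
artifacts under ``config.out_dir`` and the run ends with a manifest
recording versions, seeds, input digests and per-stage row counts.  The
master seed deterministically derives every stage seed.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import pickle
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import fit_count_model, fit_duration_model, rate_ratios, variance_explained_calf
from .classification import (
    evaluate,
    per_calf_summary,
    split_by_calf,
    train_boosted_classifier,
    undersample_majority,
)
from .config import PipelineConfig
from .errors import CalfPlayError, StageError
from .features import LABEL_PLAY, feature_table
from .io import (
    read_labels,
    read_table,
    read_trajectories,
    write_labels,
    write_table,
    write_trajectories,
)
from .preprocessing import (
    Trajectory,
    align_labels,
    exclusions_from_frame,
    filter_pen_bounds,
    remove_excluded_periods,
    smooth_moving_average,
)
from .quantification import (
    condition_grid,
    overestimation_pct,
    predicted_observed_correlation,
    quantify_play,
    select_training_condition,
    daily_play_summary,
)
from .synthetic import (
    COHORT_START_DOY,
    simulate_calves,
    simulate_temperature,
    simulate_trajectory,
)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def _stage_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


class PipelineRunner:
    """Executes the enabled stages of a :class:`PipelineConfig`."""

    def __init__(self, config: PipelineConfig):
        config.validate()
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "package_version": __version__,
            "seed": config.seed,
            "stages": {},
        }

    # -- helpers ------------------------------------------------------------
    def _path(self, name: str) -> Path:
        return self.out / name

    def _record(self, stage: str, **info) -> None:
        self.manifest["stages"][stage] = info

    def _input(self, configured: str, produced: str) -> Path:
        if configured:
            return Path(configured)
        return self._path(produced)

    # -- stages -------------------------------------------------------------
    def simulate(self) -> None:
        cfg = self.config.simulation
        seed = _stage_seed(self.config.seed, "simulate")
        rng = np.random.default_rng([seed, 7])
        calves, meta = simulate_calves(cfg, rng)
        temp_frames = []
        for cohort in sorted(meta["cohort"].unique()):
            ts = simulate_temperature(
                cfg.study_days,
                rng,
                mean_c=cfg.temp_mean_c,
                amplitude_c=cfg.temp_amplitude_c,
                noise_sd_c=cfg.temp_noise_sd_c,
                start_day_of_year=COHORT_START_DOY.get(cohort, cfg.start_day_of_year),
            )
            daily = ts.daily.copy()
            daily.insert(0, "cohort", cohort)
            temp_frames.append(daily)
        temperature = pd.concat(temp_frames, ignore_index=True)
        meta = meta.merge(temperature, on=["cohort", "day"], how="left")

        traj_frames, label_frames = [], []
        for calf in calves:
            for day in range(1, cfg.study_days + 1):
                traj, labels = simulate_trajectory(cfg, calf, day, seed=seed)
                traj_frames.append(traj.to_frame())
                label_frames.append(labels)
        write_trajectories(traj_frames, self._path("trajectories.csv"))
        write_labels(pd.concat(label_frames, ignore_index=True), self._path("labels.csv"))
        write_table(meta, self._path("metadata.csv"))
        write_table(temperature, self._path("temperature.csv"))
        self._record(
            "simulate",
            n_calves=len(calves),
            n_samples=int(sum(len(f) for f in traj_frames)),
            n_play_bouts=int(sum(len(f) for f in label_frames)),
        )

    def preprocess(self) -> None:
        cfg = self.config
        raw = read_trajectories(self._input(cfg.trajectories_csv, "trajectories.csv"))
        labels = read_labels(self._input(cfg.labels_csv, "labels.csv"))
        exclusions = []
        if cfg.exclusions_csv:
            exclusions = exclusions_from_frame(read_table(Path(cfg.exclusions_csv)))
        pen = (cfg.simulation.pen_width_m, cfg.simulation.pen_length_m)
        cleaned, removed_samples, total_samples = [], 0, 0
        for calf_id, grp in raw.groupby("calf_id"):
            traj = Trajectory.from_frame(grp, pen=pen)
            n0 = len(traj)
            total_samples += n0
            traj = remove_excluded_periods(traj, exclusions)
            traj, _ = filter_pen_bounds(traj)
            removed_samples += n0 - len(traj)
            traj = smooth_moving_average(traj, cfg.smoothing_window_s)
            cleaned.append(traj.to_frame())
        labels = align_labels(labels, -cfg.simulation.clock_offset_s)
        write_trajectories(cleaned, self._path("trajectories_clean.csv"))
        write_labels(labels, self._path("labels_aligned.csv"))
        report = {
            "total_samples": int(total_samples),
            "removed_samples": int(removed_samples),
            "percent_removed": (
                100.0 * removed_samples / total_samples if total_samples else 0.0
            ),
        }
        self._path("retention.json").write_text(json.dumps(report, indent=1))
        self._record("preprocess", **report)

    def features(self) -> None:
        cfg = self.config
        clean = read_trajectories(self._path("trajectories_clean.csv"))
        labels = read_labels(self._path("labels_aligned.csv"))
        pen = (cfg.simulation.pen_width_m, cfg.simulation.pen_length_m)
        frames = []
        for calf_id, grp in clean.groupby("calf_id"):
            traj = Trajectory.from_frame(grp, pen=pen)
            frames.append(feature_table(traj, labels, cfg.window_s))
        table = pd.concat(frames, ignore_index=True)
        if table.empty:
            raise StageError("features", "no_windows", "no complete windows produced")
        write_table(table, self._path("features.csv"))
        self._record(
            "features",
            n_windows=len(table),
            n_play=int((table["label"] == LABEL_PLAY).sum()),
        )

    def train(self) -> None:
        cfg = self.config
        table = read_table(self._path("features.csv"), required=["calf_id", "label"])
        seed = _stage_seed(cfg.seed, "train")
        split = split_by_calf(table, cfg.test_fraction, seed=seed)
        train_tab = table[table["calf_id"].isin(split.train_calves)]
        test_tab = table[table["calf_id"].isin(split.test_calves)]
        balanced = undersample_majority(train_tab, seed=seed)
        model = train_boosted_classifier(balanced, cfg.hyperparameters, seed=seed)
        from .classification import predict_play

        pred = predict_play(model, test_tab)
        truth = (test_tab["label"] == LABEL_PLAY).to_numpy()
        metrics = evaluate(truth, pred)
        by_calf = evaluate(truth, pred, groups=test_tab, group_cols=["calf_id"])
        write_table(metrics, self._path("metrics_overall.csv"))
        write_table(by_calf, self._path("metrics_by_calf.csv"))
        write_table(per_calf_summary(by_calf), self._path("metrics_by_calf_summary.csv"))
        with open(self._path("model.pkl"), "wb") as fh:
            pickle.dump({"version": __version__, "model": model, "split": split}, fh)
        train_tab.to_csv(self._path("train_windows.csv"), index=False)
        test_tab.to_csv(self._path("test_windows.csv"), index=False)
        self._record(
            "train",
            train_calves=split.train_calves,
            test_calves=split.test_calves,
            test_window_fraction=split.test_window_fraction,
        )

    def quantify(self) -> None:
        cfg = self.config
        model_path = self._path("model.pkl")
        if not model_path.exists():
            raise StageError(
                "quantify", "missing_dependency", f"missing model artifact {model_path}"
            )
        seed = _stage_seed(cfg.seed, "quantify")
        train_tab = pd.read_csv(self._path("train_windows.csv"))
        test_tab = pd.read_csv(self._path("test_windows.csv"))
        all_tab = read_table(self._path("features.csv"))
        grid = condition_grid(
            cfg.condition_grid_start, cfg.condition_grid_stop, cfg.condition_grid_step
        )
        chosen, rates = select_training_condition(
            train_tab,
            grid=grid,
            n_nonplay=cfg.condition_n_nonplay,
            hp=cfg.hyperparameters,
            seed=seed,
        )
        # final classifier trained at the winning condition
        rng = np.random.default_rng(seed)
        play_pool = train_tab[train_tab["label"] == LABEL_PLAY]
        nonplay_pool = train_tab[train_tab["label"] != LABEL_PLAY]
        cond = pd.concat(
            [
                play_pool.sample(chosen, random_state=int(rng.integers(2**31))),
                nonplay_pool.sample(
                    cfg.condition_n_nonplay, random_state=int(rng.integers(2**31))
                ),
            ]
        )
        model = train_boosted_classifier(cond, cfg.hyperparameters, seed=seed)
        with open(self._path("model_quantify.pkl"), "wb") as fh:
            pickle.dump({"version": __version__, "model": model, "rates": rates}, fh)

        # test-set diagnostics: overestimation and per-calf correlation
        test_res, _ = quantify_play(model, rates, test_tab, group_cols=("calf_id",))
        predicted = int(test_res["predicted_count"].sum())
        observed = int(test_res["observed_count"].sum())
        report = {
            "chosen_play_count": int(chosen),
            "tpr": rates.tpr,
            "fpr": rates.fpr,
            "test_predicted": predicted,
            "test_observed": observed,
        }
        if observed > 0:
            report["test_overestimation_pct"] = overestimation_pct(predicted, observed)
        if len(test_res) >= 3:
            try:
                rho, p = predicted_observed_correlation(
                    test_res["predicted_count"], test_res["observed_count"]
                )
                report.update(correlation_rho=rho, correlation_p=p)
            except CalfPlayError:
                pass
        # corrected positive sets over the whole dataset, per calf-day
        day_res, retained = quantify_play(model, rates, all_tab)
        write_table(day_res, self._path("quantification_by_day.csv"))
        write_table(retained, self._path("retained_windows.csv"))
        self._path("quantification.json").write_text(json.dumps(report, indent=1))
        self._record("quantify", **report)

    def summarise(self) -> None:
        retained = read_table(self._path("retained_windows.csv"))
        metadata = read_table(
            self._input(self.config.metadata_csv, "metadata.csv"),
            required=["calf_id", "day"],
        )
        summary = daily_play_summary(retained, metadata, self.config.window_s)
        write_table(summary, self._path("daily_summary.csv"))
        self._record(
            "summarise",
            n_calf_days=len(summary),
            total_play_s=float(summary["total_play_s"].sum()),
        )

    def model(self) -> None:
        summary = read_table(self._path("daily_summary.csv"))
        report = {}
        for response, fit_fn, name in (
            ("total_play_s", fit_duration_model, "duration"),
            ("n_instances", fit_count_model, "count"),
        ):
            res = fit_fn(summary)
            tab = res.table.copy()
            tab["rate_ratio"] = rate_ratios(res)["rate_ratio"]
            write_table(tab, self._path(f"association_{name}.csv"))
            report[name] = {
                "family": res.fit.family,
                "loglik": res.fit.loglik,
                "sigma_u": res.fit.sigma_u,
                "alpha": res.fit.alpha,
                "variance_explained_calf_pct": variance_explained_calf(res),
                "dropped_terms": res.dropped_terms,
            }
        self._path("association.json").write_text(json.dumps(report, indent=1))
        self._record("model", **{k: v["family"] for k, v in report.items()})

    # -- driver -------------------------------------------------------------
    def run(self) -> dict:
        stages = [
            ("simulate", self.config.run_simulate, self.simulate),
            ("preprocess", self.config.run_preprocess, self.preprocess),
            ("features", self.config.run_features, self.features),
            ("train", self.config.run_train, self.train),
            ("quantify", self.config.run_quantify, self.quantify),
            ("summarise", self.config.run_summarise, self.summarise),
            ("model", self.config.run_model, self.model),
        ]
        t0 = time.time()
        for name, enabled, fn in stages:
            if not enabled:
                continue
            try:
                fn()
            except StageError:
                raise
            except CalfPlayError as exc:
                raise StageError(name, type(exc).__name__, str(exc)) from exc
        self.manifest["config"] = dataclasses.asdict(self.config)
        self.manifest["elapsed_s"] = round(time.time() - t0, 2)
        inputs = {}
        for key in ("trajectories_csv", "labels_csv", "metadata_csv", "temperature_csv"):
            val = getattr(self.config, key)
            if val and Path(val).exists():
                inputs[key] = _digest(Path(val))
        self.manifest["input_digests"] = inputs
        (self.out / "manifest.json").write_text(json.dumps(self.manifest, indent=1))
        return self.manifest


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every enabled stage; returns the run manifest."""
    return PipelineRunner(config).run()
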