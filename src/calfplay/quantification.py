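"""Adjusted-count (AC) quantification of play behaviour.

A classifier applied to a low-prevalence behaviour overestimates it
whenever fpr > 0: the expected raw positive fraction is
p0 = q * tpr + (1 - q) * fpr, not q.  The adjusted count inverts that map,

    p' = (p0' - fpr) / (tpr - fpr),

clipped to [0, 1] (the Rogan-Gladen-style correction).  The confusion
rates come from fivefold cross-validation at a training condition chosen
to maximise tpr - fpr over a grid of play-instance counts paired with a
fixed non-play count.  Corrected per calf-day counts are turned back into
a concrete positive set by keeping the highest-scoring windows, from which
daily totals (seconds) and instance counts (maximal runs of consecutive
play windows) are summarised.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .config import WINDOW_S, Hyperparameters
from .errors import DegenerateClassifierError, InputError, InsufficientDataError
from .features import LABEL_PLAY
from .classification import play_scores, predict_play, train_boosted_classifier

#: minimum tpr - fpr for the correction to be invertible
MIN_RATE_GAP = 1e-6


@dataclass
class ConfusionRates:
    tpr: float
    fpr: float
    tp: int = 0
    fn: int = 0
    fp: int = 0
    tn: int = 0

    def __post_init__(self):
        if not (0.0 <= self.tpr <= 1.0 and 0.0 <= self.fpr <= 1.0):
            raise InputError("rates must lie in [0, 1]")


@dataclass
class QuantificationResult:
    """Raw and adjusted prevalence for one evaluation unit."""

    raw_prevalence: float
    adjusted_prevalence: float
    n_windows: int
    predicted_count: int
    observed_count: int | None = None

    @property
    def raw_count(self) -> int:
        return _round_half_away(self.raw_prevalence * self.n_windows)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def confusion_rates(predictions, labels) -> ConfusionRates:
    """tpr = tp/(tp+fn) and fpr = fp/(tn+fp) from aligned binary vectors."""
    pred = np.asarray(predictions, dtype=bool)
    lab = np.asarray(labels, dtype=bool)
    if pred.shape != lab.shape:
        raise InputError("predictions and labels must align")
    tp = int(np.sum(pred & lab))
    fn = int(np.sum(~pred & lab))
    fp = int(np.sum(pred & ~lab))
    tn = int(np.sum(~pred & ~lab))
    if tp + fn == 0:
        raise InputError("labels contain no positives; tpr undefined")
    if tn + fp == 0:
        raise InputError("labels contain no negatives; fpr undefined")
    return ConfusionRates(tpr=tp / (tp + fn), fpr=fp / (tn + fp), tp=tp, fn=fn, fp=fp, tn=tn)


def adjusted_count(p0_prime: float, rates: ConfusionRates) -> float:
    """AC-corrected prevalence, clipped to [0, 1].

    Exact inverse of the forward misclassification map
    p0 = q*tpr + (1-q)*fpr whenever the raw estimate lies in [fpr, tpr].
    """
    if rates.tpr - rates.fpr <= MIN_RATE_GAP:
        raise DegenerateClassifierError(
            f"tpr ({rates.tpr:.4f}) must exceed fpr ({rates.fpr:.4f}); "
            "the correction is not invertible"
        )
    return float(np.clip((p0_prime - rates.fpr) / (rates.tpr - rates.fpr), 0.0, 1.0))


def condition_grid(start: int = 10, stop: int = 2180, step: int = 70) -> list[int]:
    """The training-condition grid of play-instance counts."""
    return list(range(start, stop + 1, step))


def _cv_rates(
    table: pd.DataFrame,
    hp: Hyperparameters,
    seed: int,
    n_folds: int = 5,
) -> ConfusionRates:
    """Pooled out-of-fold confusion rates from stratified fivefold CV."""
    y = (table["label"] == LABEL_PLAY).to_numpy()
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    pred = np.zeros(len(table), dtype=bool)
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        model = train_boosted_classifier(table.iloc[tr], hp, seed=seed + fold)
        pred[te] = predict_play(model, table.iloc[te])
    return confusion_rates(pred, y)


def select_training_condition(
    train: pd.DataFrame,
    grid: list[int] | None = None,
    n_nonplay: int = 250_000,
    hp: Hyperparameters | None = None,
    seed: int = 0,
) -> tuple[int, ConfusionRates]:
    """Choose the play-instance training count maximising tpr - fpr.

    For each grid value p, a condition set of p play and ``n_nonplay``
    non-play windows is sampled from the training pool and its confusion
    rates estimated by fivefold CV; ties break toward the larger play
    count.  Returns the winning count and its rates.
    """
    grid = grid if grid is not None else condition_grid()
    hp = hp or Hyperparameters()
    play_pool = train[train["label"] == LABEL_PLAY]
    nonplay_pool = train[train["label"] != LABEL_PLAY]
    if len(play_pool) < max(grid):
        raise InsufficientDataError(
            f"training pool has {len(play_pool)} play windows; the grid "
            f"needs {max(grid)}"
        )
    if len(nonplay_pool) < n_nonplay:
        raise InsufficientDataError(
            f"training pool has {len(nonplay_pool)} non-play windows; the "
            f"condition needs {n_nonplay}"
        )
    rng = np.random.default_rng(seed)
    nonplay_idx = rng.choice(nonplay_pool.index.to_numpy(), n_nonplay, replace=False)
    play_order = rng.permutation(play_pool.index.to_numpy())
    best: tuple[float, int, ConfusionRates] | None = None
    for p in grid:
        cond = train.loc[np.concatenate([play_order[:p], nonplay_idx])]
        rates = _cv_rates(cond, hp, seed=seed)
        gap = rates.tpr - rates.fpr
        if best is None or gap > best[0] or (gap == best[0] and p > best[1]):
            best = (gap, p, rates)
    assert best is not None
    return best[1], best[2]


def quantify_play(
    model,
    rates: ConfusionRates,
    table: pd.DataFrame,
    group_cols: tuple[str, ...] = ("calf_id", "day"),
    window_s: float = WINDOW_S,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the classifier and the AC correction per calf-day.

    Returns ``(results, retained)``: one result row per group with the raw
    positive fraction p0', the adjusted prevalence p', window counts and —
    when labels are present — the observed play-window count; and the
    corrected positive set, built by keeping the ``round(p' * n)``
    highest-scoring windows of each group.
    """
    table = table.copy()
    if "day" in group_cols and "day" not in table.columns:
        table["day"] = (table["window_start"] // 86_400).astype(int) + 1
    scores = play_scores(model, table)
    table["_score"] = scores
    table["_pred"] = scores >= 0.5
    results = []
    retained_frames = []
    for key, grp in table.groupby(list(group_cols), sort=True):
        n = len(grp)
        if n == 0:
            continue
        p0 = float(grp["_pred"].mean())
        p_adj = adjusted_count(p0, rates)
        k = min(_round_half_away(p_adj * n), n)
        observed = (
            int((grp["label"] == LABEL_PLAY).sum()) if "label" in grp.columns else None
        )
        row = dict(zip(group_cols, key if isinstance(key, tuple) else (key,)))
        row.update(
            raw_prevalence=p0,
            adjusted_prevalence=p_adj,
            n_windows=n,
            raw_count=int(grp["_pred"].sum()),
            predicted_count=k,
            observed_count=observed,
        )
        results.append(row)
        if k > 0:
            top = grp.nlargest(k, "_score", keep="first")
            retained_frames.append(top)
    retained = (
        pd.concat(retained_frames).drop(columns=["_score", "_pred"])
        if retained_frames
        else table.iloc[0:0].drop(columns=["_score", "_pred"])
    )
    return pd.DataFrame(results), retained


def overestimation_pct(n_predicted: float, n_observed: float) -> float:
    """Signed percentage overestimation of predicted vs observed counts."""
    if n_observed <= 0:
        raise InputError("overestimation is undefined for zero observed samples")
    return 100.0 * (n_predicted - n_observed) / n_observed


def predicted_observed_correlation(predicted, observed) -> tuple[float, float]:
    """Spearman rank correlation between per-unit predicted and observed
    counts, with its p-value (t approximation)."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if len(predicted) != len(observed):
        raise InputError("paired vectors must align")
    if len(predicted) < 3:
        raise InputError("need at least 3 paired units")
    if np.ptp(predicted) == 0 or np.ptp(observed) == 0:
        raise InputError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(predicted, observed)
    return float(rho), float(p)


def daily_play_summary(
    retained: pd.DataFrame,
    metadata: pd.DataFrame,
    window_s: float = WINDOW_S,
) -> pd.DataFrame:
    """Per calf-day totals from the corrected positive window sets.

    Total play seconds = window length times the number of retained play
    windows; an instance is a maximal run of consecutive retained windows
    (start times ``window_s`` apart).  Covariates are joined from the
    metadata table; calf-days present in the metadata but with no retained
    windows get zero-filled rows, and retained calf-days missing from the
    metadata are flagged and excluded from modelling output.
    """
    per_day = []
    if not retained.empty:
        tab = retained.copy()
        if "day" not in tab.columns:
            tab["day"] = (tab["window_start"] // 86_400).astype(int) + 1
        for (calf, day), grp in tab.groupby(["calf_id", "day"]):
            starts = np.sort(grp["window_start"].to_numpy(float))
            n_inst = (
                1 + int(np.sum(np.diff(starts) > window_s + 1e-9)) if len(starts) else 0
            )
            per_day.append(
                {
                    "calf_id": calf,
                    "day": int(day),
                    "total_play_s": window_s * len(starts),
                    "n_instances": n_inst,
                }
            )
    play = pd.DataFrame(per_day, columns=["calf_id", "day", "total_play_s", "n_instances"])
    out = metadata.merge(play, on=["calf_id", "day"], how="outer", indicator=True)
    out["missing_metadata"] = out["_merge"] == "right_only"
    out = out.drop(columns="_merge")
    out["total_play_s"] = out["total_play_s"].astype(float).fillna(0.0)
    out["n_instances"] = out["n_instances"].astype(float).fillna(0).astype(int)
    return out
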