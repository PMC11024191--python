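"""Play/non-play classification.

Calf-wise 70/30 partitioning (whole calves on one side only, so no calf
leaks windows into both sets), random undersampling of the non-play
majority, an AdaBoost ensemble of shallow decision trees, seeded
random-search hyperparameter tuning with fivefold cross-validation, and
the usual epidemiological performance metrics (accuracy, sensitivity,
specificity, precision, F-score) reported per class and per grouping.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .config import Hyperparameters
from .errors import InputError, SplitError
from .features import FEATURE_COLUMNS, LABEL_PLAY

__all__ = [
    "DatasetSplit",
    "PerformanceMetrics",
    "split_by_calf",
    "undersample_majority",
    "train_boosted_classifier",
    "tune_hyperparameters",
    "evaluate",
    "metrics_from_counts",
]


@dataclass
class DatasetSplit:
    train_calves: list[str]
    test_calves: list[str]
    train_windows: int
    test_windows: int

    @property
    def test_window_fraction(self) -> float:
        return self.test_windows / (self.train_windows + self.test_windows)


def split_by_calf(
    table: pd.DataFrame, test_fraction: float = 0.3, seed: int = 0
) -> DatasetSplit:
    """Assign whole calves to train or test, targeting a window fraction.

    Calves are visited in a seeded random order; each is added to the test
    side only if doing so brings the test-side share of windows closer to
    ``test_fraction``.  Guarantees disjoint calf sets covering all calves.
    """
    counts = table.groupby("calf_id").size()
    if len(counts) < 2:
        raise SplitError("calf-wise split needs at least 2 calves")
    rng = np.random.default_rng(seed)
    order = rng.permutation(counts.index.to_numpy())
    total = counts.sum()
    test: list[str] = []
    test_n = 0
    for calf in order:
        cand = test_n + counts[calf]
        if abs(cand / total - test_fraction) <= abs(test_n / total - test_fraction):
            test.append(calf)
            test_n = cand
    # force at least one calf on each side
    if not test:
        test = [order[0]]
        test_n = int(counts[order[0]])
    if len(test) == len(counts):
        dropped = test.pop()
        test_n -= int(counts[dropped])
    train = [c for c in counts.index if c not in set(test)]
    return DatasetSplit(
        train_calves=sorted(train),
        test_calves=sorted(test),
        train_windows=int(total - test_n),
        test_windows=int(test_n),
    )


def undersample_majority(train: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Randomly undersample the majority class down to the minority count.

    The minority class is kept untouched; the majority is sampled without
    replacement.  Row order follows the original table.
    """
    by_class = train.groupby("label").size()
    if len(by_class) < 2 or (by_class == 0).any():
        raise InputError("undersampling needs both classes present")
    n_min = int(by_class.min())
    minority = by_class.idxmin()
    rng = np.random.default_rng(seed)
    keep_idx = []
    for label, group in train.groupby("label"):
        if label == minority:
            keep_idx.append(group.index.to_numpy())
        else:
            keep_idx.append(
                rng.choice(group.index.to_numpy(), size=n_min, replace=False)
            )
    idx = np.concatenate(keep_idx)
    return train.loc[np.sort(idx)]


def _design(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    X = table[FEATURE_COLUMNS].to_numpy(float)
    y = (table["label"] == LABEL_PLAY).to_numpy()
    return X, y


def train_boosted_classifier(
    train: pd.DataFrame,
    hp: Hyperparameters | None = None,
    seed: int = 0,
) -> AdaBoostClassifier:
    """Fit the AdaBoost ensemble of depth-limited trees.

    ``max_splits`` bounds the number of branch nodes per tree
    (``max_leaf_nodes = max_splits + 1``).  The fitted model exposes a
    play-probability score in [0, 1] via ``predict_proba``; predictions
    threshold that score at 0.5.
    """
    hp = hp or Hyperparameters()
    hp.validate()
    X, y = _design(train)
    if len(np.unique(y)) < 2:
        raise InputError("training data must contain both classes")
    model = AdaBoostClassifier(
        estimator=DecisionTreeClassifier(
            max_leaf_nodes=hp.max_splits + 1, random_state=seed
        ),
        n_estimators=hp.n_learning_cycles,
        learning_rate=hp.learning_rate,
        random_state=seed,
    )
    model.fit(X, y)
    return model


def play_scores(model: AdaBoostClassifier, table: pd.DataFrame) -> np.ndarray:
    """Classifier score for the play class, in [0, 1]."""
    X = table[FEATURE_COLUMNS].to_numpy(float)
    pos = list(model.classes_).index(True)
    return model.predict_proba(X)[:, pos]


def predict_play(
    model: AdaBoostClassifier, table: pd.DataFrame, threshold: float = 0.5
) -> np.ndarray:
    return play_scores(model, table) >= threshold


def _cv_misclassification(
    table: pd.DataFrame, hp: Hyperparameters, seed: int, n_folds: int = 5
) -> float:
    X, y = _design(table)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    errors = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        model = train_boosted_classifier(table.iloc[tr], hp, seed=seed + fold)
        pred = predict_play(model, table.iloc[te])
        errors.append(np.mean(pred != y[te]))
    return float(np.mean(errors))


def tune_hyperparameters(
    train: pd.DataFrame,
    search_space: dict | None = None,
    budget: int = 10,
    seed: int = 0,
    candidates: list[Hyperparameters] | None = None,
) -> Hyperparameters:
    """Seeded random search minimising fivefold-CV misclassification.

    ``search_space`` maps the three hyperparameter names to candidate lists
    (learning_rate may instead give a (low, high) log-uniform range);
    alternatively an explicit ``candidates`` list is evaluated exhaustively.
    Ties are broken toward fewer learning cycles, then smaller max_splits.
    """
    if candidates is not None:
        if not candidates:
            raise InputError("candidate list must be non-empty")
        scored = [
            (
                _cv_misclassification(train, hp, seed),
                hp.n_learning_cycles,
                hp.max_splits,
                i,
            )
            for i, hp in enumerate(candidates)
        ]
        scored.sort()
        return candidates[scored[0][3]]
    if budget < 1:
        raise InputError("budget must be >= 1")
    space = search_space or {
        "max_splits": [2, 5, 10, 20],
        "n_learning_cycles": [50, 100, 250, 494],
        "learning_rate": (1e-3, 1.0),
    }
    if any(len(v) == 0 for v in space.values()):
        raise InputError("search space must be non-empty")
    rng = np.random.default_rng(seed)
    candidates = []
    for _ in range(budget):
        lr = space["learning_rate"]
        if isinstance(lr, tuple):
            lr = float(np.exp(rng.uniform(np.log(lr[0]), np.log(lr[1]))))
        else:
            lr = float(rng.choice(lr))
        candidates.append(
            Hyperparameters(
                max_splits=int(rng.choice(space["max_splits"])),
                n_learning_cycles=int(rng.choice(space["n_learning_cycles"])),
                learning_rate=lr,
            )
        )
    scored = [
        (_cv_misclassification(train, hp, seed), hp.n_learning_cycles, hp.max_splits, i)
        for i, hp in enumerate(candidates)
    ]
    scored.sort()
    return candidates[scored[0][3]]


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class PerformanceMetrics:
    """Confusion counts and percentage metrics for one class as positive."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float = field(init=False)
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)
    precision: float = field(init=False)
    f_score: float = field(init=False)

    def __post_init__(self):
        n = self.tp + self.fp + self.tn + self.fn
        if n == 0:
            raise InputError("empty confusion table")
        self.accuracy = 100.0 * (self.tp + self.tn) / n
        self.sensitivity = (
            100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")
        )
        self.specificity = (
            100.0 * self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")
        )
        self.precision = (
            100.0 * self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")
        )
        ps = self.precision + self.sensitivity
        self.f_score = 2.0 * self.precision * self.sensitivity / ps if ps else float("nan")


def metrics_from_counts(tp: int, fp: int, tn: int, fn: int) -> PerformanceMetrics:
    return PerformanceMetrics(tp=tp, fp=fp, tn=tn, fn=fn)


def evaluate(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    groups: pd.DataFrame | None = None,
    group_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Per-class performance table, optionally broken down by grouping.

    Returns one row per (group x class) with accuracy, specificity,
    sensitivity, precision and F-score as percentages rounded to 2
    decimals; for the non-play row the class roles are swapped.  Empty
    groups are omitted.
    """
    y_true = np.asarray(y_true, dtype=bool)
    y_pred = np.asarray(y_pred, dtype=bool)
    if len(y_true) != len(y_pred):
        raise InputError("prediction/label length mismatch")

    def one(mask: np.ndarray, group_vals: dict) -> list[dict]:
        yt, yp = y_true[mask], y_pred[mask]
        rows = []
        for cls, pos_t, pos_p in (
            ("non_play", ~yt, ~yp),
            ("play", yt, yp),
        ):
            m = PerformanceMetrics(
                tp=int(np.sum(pos_t & pos_p)),
                fp=int(np.sum(~pos_t & pos_p)),
                tn=int(np.sum(~pos_t & ~pos_p)),
                fn=int(np.sum(pos_t & ~pos_p)),
            )
            rows.append(
                {
                    **group_vals,
                    "class": cls,
                    "n": int(mask.sum()),
                    "accuracy": round(m.accuracy, 2),
                    "specificity": round(m.specificity, 2),
                    "sensitivity": round(m.sensitivity, 2),
                    "precision": round(m.precision, 2),
                    "f_score": round(m.f_score, 2),
                }
            )
        return rows

    if groups is None or not group_cols:
        return pd.DataFrame(one(np.ones(len(y_true), dtype=bool), {"group": "overall"}))
    rows = []
    key = groups[group_cols].astype(str).agg("|".join, axis=1).to_numpy()
    for g in pd.unique(key):
        mask = key == g
        if mask.sum() == 0:
            continue
        rows.extend(one(mask, {"group": g}))
    return pd.DataFrame(rows)


def per_calf_summary(metrics: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD of per-calf metrics, one row per class."""
    out = []
    for cls, grp in metrics.groupby("class"):
        row = {"class": cls}
        for col in ("accuracy", "specificity", "sensitivity", "precision", "f_score"):
            row[f"{col}_mean"] = round(float(grp[col].mean()), 2)
            row[f"{col}_sd"] = round(float(grp[col].std(ddof=1)), 2)
        out.append(row)
    return pd.DataFrame(out)
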