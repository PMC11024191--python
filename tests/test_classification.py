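"""Calf-wise splitting, undersampling, boosting and performance metrics."""

import itertools

import numpy as np
import pandas as pd
import pytest

import calfplay as cp
from calfplay.classification import metrics_from_counts, play_scores, predict_play
from calfplay.errors import InputError, SplitError
from calfplay.features import FEATURE_COLUMNS


def toy_table(n_per_class=60, sep=4.0, seed=0, n_calves=4):
    """Linearly separable two-class table in the 15-feature layout."""
    rng = np.random.default_rng(seed)
    rows = []
    for label, centre in (("non_play", 0.0), ("play", sep)):
        X = rng.normal(centre, 0.5, size=(n_per_class, len(FEATURE_COLUMNS)))
        for i in range(n_per_class):
            rows.append(
                {
                    "calf_id": f"C{i % n_calves}",
                    "window_start": 3.0 * i,
                    "label": label,
                    **dict(zip(FEATURE_COLUMNS, X[i])),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def test_split_equal_calves_gives_three_of_ten():
    table = pd.DataFrame(
        {"calf_id": np.repeat([f"C{i}" for i in range(10)], 20), "label": "non_play"}
    )
    split = cp.split_by_calf(table, 0.3, seed=1)
    assert len(split.test_calves) == 3
    assert split.test_window_fraction == pytest.approx(0.3)


def test_split_calf_sets_are_disjoint_and_cover():
    table = toy_table(n_calves=6)
    split = cp.split_by_calf(table, 0.3, seed=2)
    assert not set(split.train_calves) & set(split.test_calves)
    assert set(split.train_calves) | set(split.test_calves) == set(table["calf_id"])


def test_split_single_calf_raises():
    table = pd.DataFrame({"calf_id": ["C1"] * 5, "label": "non_play"})
    with pytest.raises(SplitError):
        cp.split_by_calf(table)


def test_split_close_to_target_vs_exhaustive():
    """Greedy assignment lands within 5 points of the best achievable."""
    rng = np.random.default_rng(4)
    sizes = rng.integers(5, 120, size=10)
    table = pd.DataFrame(
        {
            "calf_id": np.repeat([f"C{i:02d}" for i in range(10)], sizes),
            "label": "non_play",
        }
    )
    total = sizes.sum()
    split = cp.split_by_calf(table, 0.3, seed=0)
    # exhaustive search over all non-trivial subsets
    best = min(
        abs(sum(combo) / total - 0.3)
        for r in range(1, 10)
        for combo in itertools.combinations(sizes, r)
    )
    achieved = abs(split.test_window_fraction - 0.3)
    assert achieved <= best + 0.05


# ---------------------------------------------------------------------------
# undersampling
# ---------------------------------------------------------------------------

def test_undersample_balances_and_keeps_minority():
    table = toy_table(n_per_class=50)
    majority_extra = table[table["label"] == "non_play"].sample(
        30, replace=True, random_state=0
    )
    skewed = pd.concat([table, majority_extra], ignore_index=True)
    balanced = cp.undersample_majority(skewed, seed=3)
    counts = balanced["label"].value_counts()
    assert counts["play"] == counts["non_play"] == 50
    # minority rows all retained
    assert set(skewed.index[skewed["label"] == "play"]) <= set(balanced.index)


def test_undersample_identity_when_balanced_and_seeded():
    table = toy_table(n_per_class=40)
    a = cp.undersample_majority(table, seed=1)
    b = cp.undersample_majority(table, seed=1)
    pd.testing.assert_frame_equal(a, b)
    assert len(a) == len(table)


def test_undersample_needs_both_classes():
    table = toy_table().query("label == 'play'")
    with pytest.raises(InputError):
        cp.undersample_majority(table)


# ---------------------------------------------------------------------------
# boosting
# ---------------------------------------------------------------------------

def test_boosted_classifier_fits_separable_data_perfectly():
    table = toy_table(sep=5.0)
    model = cp.train_boosted_classifier(table, cp.Hyperparameters(n_learning_cycles=25), seed=0)
    pred = predict_play(model, table)
    assert (pred == (table["label"] == "play").to_numpy()).all()


def test_boosted_classifier_label_inversion_symmetry():
    table = toy_table(sep=5.0)
    inverted = table.copy()
    inverted["label"] = np.where(inverted["label"] == "play", "non_play", "play")
    hp = cp.Hyperparameters(n_learning_cycles=25)
    m1 = cp.train_boosted_classifier(table, hp, seed=0)
    m2 = cp.train_boosted_classifier(inverted, hp, seed=0)
    assert np.array_equal(predict_play(m1, table), ~predict_play(m2, table))


def test_boosted_classifier_is_seed_deterministic():
    table = toy_table(sep=1.0)
    hp = cp.Hyperparameters(n_learning_cycles=40)
    s1 = play_scores(cp.train_boosted_classifier(table, hp, seed=7), table)
    s2 = play_scores(cp.train_boosted_classifier(table, hp, seed=7), table)
    assert np.array_equal(s1, s2)


def test_boosted_classifier_rejects_single_class():
    table = toy_table().query("label == 'non_play'")
    with pytest.raises(InputError):
        cp.train_boosted_classifier(table)


# ---------------------------------------------------------------------------
# tuning
# ---------------------------------------------------------------------------

def test_tune_budget_one_returns_single_candidate():
    table = toy_table(sep=3.0)
    only = cp.Hyperparameters(max_splits=3, n_learning_cycles=10, learning_rate=0.5)
    assert cp.tune_hyperparameters(table, candidates=[only]) == only


def test_tune_prefers_sound_over_crippled_candidates():
    # weak per-feature separation: a single crippled stump cannot compete
    table = toy_table(sep=0.5, n_per_class=80, seed=5)
    sound = cp.Hyperparameters(max_splits=10, n_learning_cycles=60, learning_rate=0.5)
    crippled = cp.Hyperparameters(max_splits=1, n_learning_cycles=1, learning_rate=1e-4)
    chosen = cp.tune_hyperparameters(table, candidates=[crippled, sound], seed=0)
    assert chosen == sound


def test_tune_random_search_is_seed_repeatable():
    table = toy_table(sep=2.0)
    a = cp.tune_hyperparameters(table, budget=3, seed=11)
    b = cp.tune_hyperparameters(table, budget=3, seed=11)
    assert a == b


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def test_perfect_predictions_score_100():
    y = np.array([True] * 5 + [False] * 15)
    out = cp.evaluate(y, y)
    play = out[out["class"] == "play"].iloc[0]
    assert play["accuracy"] == play["sensitivity"] == play["precision"] == 100.0


def test_all_negative_predictor_on_imbalanced_data():
    y = np.array([True] * 2 + [False] * 98)
    pred = np.zeros(100, dtype=bool)
    out = cp.evaluate(y, pred)
    play = out[out["class"] == "play"].iloc[0]
    assert play["sensitivity"] == 0.0
    assert play["accuracy"] == 98.0  # equals the non-play prevalence


def test_metrics_formula_arithmetic():
    m = metrics_from_counts(tp=9, fn=1, fp=99, tn=891)
    assert m.sensitivity == pytest.approx(90.0)
    assert m.specificity == pytest.approx(90.0)
    assert m.precision == pytest.approx(8.3333, abs=1e-3)
    assert m.accuracy == pytest.approx(90.0)


def test_evaluate_by_group_swaps_class_roles():
    y = np.array([True, True, False, False, False, False])
    pred = np.array([True, False, True, False, False, False])
    out = cp.evaluate(y, pred)
    play = out[out["class"] == "play"].iloc[0]
    non = out[out["class"] == "non_play"].iloc[0]
    assert play["sensitivity"] == non["specificity"]
    assert play["specificity"] == non["sensitivity"]
    assert play["accuracy"] == non["accuracy"]
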