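"""Adjusted-count correction, condition selection and daily summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import calfplay as cp
from calfplay.errors import DegenerateClassifierError, InputError, InsufficientDataError
from calfplay.features import FEATURE_COLUMNS
from calfplay.quantification import condition_grid, quantify_play

from _oracles import spearman_rho


class ScoreStub:
    """Duck-typed classifier exposing pre-computed play scores."""

    classes_ = [False, True]

    def __init__(self, scores):
        self._scores = np.asarray(scores, dtype=float)

    def predict_proba(self, X):
        s = self._scores[: len(X)]
        return np.column_stack([1 - s, s])


def window_frame(scores, labels, calf="C1", day=1):
    n = len(scores)
    df = pd.DataFrame(
        {
            "calf_id": calf,
            "day": day,
            "window_start": 3.0 * np.arange(n),
            "label": np.where(labels, "play", "non_play"),
        }
    )
    for c in FEATURE_COLUMNS:
        df[c] = 0.0
    return df, ScoreStub(scores)


# ---------------------------------------------------------------------------
# rates and the AC formula
# ---------------------------------------------------------------------------

def test_confusion_rates_examples():
    lab = np.array([True] * 10 + [False] * 990)
    perfect = cp.confusion_rates(lab, lab)
    assert perfect.tpr == 1.0 and perfect.fpr == 0.0
    allpos = cp.confusion_rates(np.ones_like(lab), lab)
    assert allpos.tpr == 1.0 and allpos.fpr == 1.0
    pred = np.array([True] * 9 + [False] * 1 + [True] * 99 + [False] * 891)
    r = cp.confusion_rates(pred, lab)
    assert r.tpr == pytest.approx(0.9) and r.fpr == pytest.approx(0.1)


def test_confusion_rates_requires_both_classes_in_labels():
    with pytest.raises(InputError):
        cp.confusion_rates(np.array([True, False]), np.array([False, False]))


def test_adjusted_count_fixed_points():
    r = cp.ConfusionRates(tpr=0.9, fpr=0.1)
    assert cp.adjusted_count(0.1, r) == 0.0
    assert cp.adjusted_count(0.9, r) == 1.0
    assert cp.adjusted_count(0.5, r) == pytest.approx(0.5)
    assert cp.adjusted_count(0.05, r) == 0.0  # clipped below
    with pytest.raises(DegenerateClassifierError):
        cp.adjusted_count(0.5, cp.ConfusionRates(tpr=0.3, fpr=0.3))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    st.floats(0.0, 1.0),
    st.floats(0.05, 1.0),
    st.floats(0.0, 0.95),
)
def test_adjusted_count_inverts_forward_map(q, tpr, fpr):
    """AC is the exact inverse of p0 = q*tpr + (1-q)*fpr when tpr > fpr."""
    if tpr - fpr <= 1e-3:
        return
    p0 = q * tpr + (1 - q) * fpr
    rates = cp.ConfusionRates(tpr=tpr, fpr=fpr)
    assert cp.adjusted_count(p0, rates) == pytest.approx(q, abs=1e-9)


def test_condition_grid_has_32_values():
    grid = condition_grid()
    assert grid[0] == 10 and grid[-1] == 2180 and len(grid) == 32
    assert grid[1] - grid[0] == 70


# ---------------------------------------------------------------------------
# condition selection
# ---------------------------------------------------------------------------

def informative_pool(n_play=60, n_nonplay=600, seed=0, sep=1.2):
    rng = np.random.default_rng(seed)
    rows = []
    for label, n, centre in (("play", n_play, sep), ("non_play", n_nonplay, 0.0)):
        X = rng.normal(centre, 1.0, size=(n, len(FEATURE_COLUMNS)))
        for i in range(n):
            rows.append(
                {
                    "calf_id": f"C{i % 5}",
                    "window_start": 3.0 * len(rows),
                    "label": label,
                    **dict(zip(FEATURE_COLUMNS, X[i])),
                }
            )
    return pd.DataFrame(rows)


def test_select_training_condition_prefers_more_play_examples():
    """With scarce play data the CV curve rises with the play count."""
    pool = informative_pool(n_play=60, n_nonplay=600, sep=0.35)
    hp = cp.Hyperparameters(n_learning_cycles=30)
    chosen, rates = cp.select_training_condition(
        pool, grid=[5, 20, 60], n_nonplay=300, hp=hp, seed=1
    )
    assert chosen == 60
    assert rates.tpr > rates.fpr


def test_select_training_condition_is_seed_repeatable():
    pool = informative_pool(n_play=30, n_nonplay=300)
    hp = cp.Hyperparameters(n_learning_cycles=20)
    a = cp.select_training_condition(pool, grid=[10, 30], n_nonplay=200, hp=hp, seed=5)
    b = cp.select_training_condition(pool, grid=[10, 30], n_nonplay=200, hp=hp, seed=5)
    assert a[0] == b[0]
    assert a[1].tpr == b[1].tpr and a[1].fpr == b[1].fpr


def test_select_training_condition_reports_shortfall():
    pool = informative_pool(n_play=10, n_nonplay=50)
    with pytest.raises(InsufficientDataError, match="play"):
        cp.select_training_condition(pool, grid=[100], n_nonplay=10)
    with pytest.raises(InsufficientDataError, match="non-play"):
        cp.select_training_condition(pool, grid=[5], n_nonplay=10_000)


# ---------------------------------------------------------------------------
# quantify_play
# ---------------------------------------------------------------------------

def test_quantify_play_perfect_classifier_keeps_raw_count():
    labels = np.array([True] * 5 + [False] * 95)
    scores = np.where(labels, 0.9, 0.1)
    table, model = window_frame(scores, labels)
    res, retained = quantify_play(model, cp.ConfusionRates(tpr=1.0, fpr=0.0), table)
    assert res.loc[0, "predicted_count"] == 5
    assert len(retained) == 5
    assert (retained["label"] == "play").all()


def test_quantify_play_clips_when_raw_below_fpr():
    labels = np.zeros(100, dtype=bool)
    labels[0] = True  # keep one positive so rates stay defined downstream
    scores = np.full(100, 0.1)
    scores[:2] = 0.9  # raw prevalence 2% < fpr 5%
    table, model = window_frame(scores, labels)
    res, retained = quantify_play(model, cp.ConfusionRates(tpr=0.9, fpr=0.05), table)
    assert res.loc[0, "adjusted_prevalence"] == 0.0
    assert res.loc[0, "predicted_count"] == 0
    assert retained.empty


def test_quantify_play_recovers_known_prevalence():
    """20 true play windows, rates (0.9, 0.01): the adjusted count sits
    near 20 while the raw count is biased high."""
    rng = np.random.default_rng(42)
    tpr, fpr = 0.9, 0.01
    n, k = 2000, 20
    adj_counts, raw_counts = [], []
    for _ in range(40):
        labels = np.zeros(n, dtype=bool)
        labels[:k] = True
        pred = np.where(labels, rng.random(n) < tpr, rng.random(n) < fpr)
        scores = np.where(pred, 0.9, 0.1)
        table, model = window_frame(scores, labels)
        res, _ = quantify_play(model, cp.ConfusionRates(tpr=tpr, fpr=fpr), table)
        adj_counts.append(res.loc[0, "predicted_count"])
        raw_counts.append(res.loc[0, "raw_count"])
    assert abs(np.mean(adj_counts) - k) < 3 * np.sqrt(k)  # Poisson-scale error
    assert np.mean(raw_counts) > k + 3 * np.sqrt(k)  # raw biased high


# ---------------------------------------------------------------------------
# overestimation and correlation
# ---------------------------------------------------------------------------

def test_overestimation_examples():
    assert cp.overestimation_pct(1223, 1050) == pytest.approx(16.48, abs=0.005)
    assert cp.overestimation_pct(100, 100) == 0.0
    assert cp.overestimation_pct(150, 100) == pytest.approx(50.0)
    with pytest.raises(InputError):
        cp.overestimation_pct(10, 0)


def test_spearman_correlation_examples():
    rho, _ = cp.predicted_observed_correlation([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
    assert rho == pytest.approx(1.0)
    rho, _ = cp.predicted_observed_correlation([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
    assert rho == pytest.approx(-1.0)
    a, b = [1, 2, 3, 4, 5], [2, 1, 4, 3, 5]
    rho, p = cp.predicted_observed_correlation(a, b)
    assert rho == pytest.approx(spearman_rho(a, b))  # rank-formula oracle: 0.8
    assert rho == pytest.approx(0.8)
    assert 0 < p <= 1


def test_spearman_correlation_input_errors():
    with pytest.raises(InputError):
        cp.predicted_observed_correlation([1, 2], [1, 2])
    with pytest.raises(InputError):
        cp.predicted_observed_correlation([1, 1, 1], [1, 2, 3])


# ---------------------------------------------------------------------------
# daily summaries
# ---------------------------------------------------------------------------

def _metadata(calf="C1", day=1):
    return pd.DataFrame(
        {
            "calf_id": [calf],
            "day": [day],
            "age_days": [40],
            "cohort": [1],
            "weaning_stage": ["step_down"],
            "health_status": ["healthy"],
            "sex_breed": ["female_HO"],
            "mean_temp_c": [12.0],
        }
    )


def _retained(starts, calf="C1", day=1):
    return pd.DataFrame(
        {"calf_id": calf, "day": day, "window_start": np.asarray(starts, float), "label": "play"}
    )


@pytest.mark.parametrize(
    "starts, seconds, instances",
    [
        ([0.0, 3.0, 6.0], 9.0, 1),
        ([0.0, 9.0], 6.0, 2),
        ([], 0.0, 0),
    ],
)
def test_daily_summary_run_length_rule(starts, seconds, instances):
    out = cp.daily_play_summary(_retained(starts), _metadata())
    row = out.iloc[0]
    assert row["total_play_s"] == seconds
    assert row["n_instances"] == instances


def test_daily_summary_flags_missing_metadata():
    out = cp.daily_play_summary(_retained([0.0], calf="C9"), _metadata(calf="C1"))
    flagged = out[out["calf_id"] == "C9"]
    assert flagged["missing_metadata"].all()
    ok = out[out["calf_id"] == "C1"]
    assert not ok["missing_metadata"].any()
    assert ok.iloc[0]["total_play_s"] == 0.0
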