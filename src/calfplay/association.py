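"""Mixed-model analysis of daily play against age, weaning, health,
cohort, sex-breed and temperature.

Both responses are modelled on the log link with a calf random intercept:
daily play duration (integer seconds, zeros allowed — Poisson with an
automatic negative-binomial upgrade when overdispersed) and daily instance
counts (negative binomial, NB2).  Reference levels are cohort 1,
pre-weaned, healthy and female Holstein.  Exponentiated coefficients are
rate ratios: the multiplicative change in expected daily play per unit
covariate change.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .glmm import GLMMResult, RandomInterceptGLMM, latent_residual_variance

FIXED_TERMS = [
    "intercept",
    "age_days",
    "cohort_2",
    "cohort_3",
    "weaning_step_down",
    "weaning_weaned",
    "health_moderate",
    "health_sick",
    "sex_male_HOxAA",
    "mean_temp_c",
]

#: Pearson dispersion above which the duration model upgrades to NB
OVERDISPERSION_THRESHOLD = 1.5


@dataclass
class AssociationResult:
    """Fixed effects, rate ratios and variance decomposition of one fit."""

    response: str
    fit: GLMMResult
    table: pd.DataFrame  # term, n, estimate, std_error, p_value, exp_estimate
    dropped_terms: list[str]

    @property
    def variance_explained_pct(self) -> float:
        return variance_explained_calf(self)


def _design(summaries: pd.DataFrame) -> tuple[np.ndarray, list[str], pd.Series]:
    """Design matrix with explicit treatment coding and reference levels."""
    df = summaries
    cols = {
        "intercept": np.ones(len(df)),
        "age_days": df["age_days"].to_numpy(float),
        "cohort_2": (df["cohort"].astype(int) == 2).astype(float),
        "cohort_3": (df["cohort"].astype(int) == 3).astype(float),
        "weaning_step_down": (df["weaning_stage"] == "step_down").astype(float),
        "weaning_weaned": (df["weaning_stage"] == "weaned").astype(float),
        "health_moderate": (df["health_status"] == "moderate").astype(float),
        "health_sick": (df["health_status"] == "sick").astype(float),
        "sex_male_HOxAA": (df["sex_breed"] == "male_HOxAA").astype(float),
        "mean_temp_c": df["mean_temp_c"].to_numpy(float),
    }
    X = pd.DataFrame(cols, index=df.index)
    # drop non-identifiable terms (a level absent from the data)
    dropped = [
        c
        for c in X.columns
        if c != "intercept" and float(X[c].std()) == 0.0
    ]
    kept = [c for c in X.columns if c not in dropped]
    return X[kept].to_numpy(float), kept, pd.Series(dropped)


def _level_n(summaries: pd.DataFrame, term: str) -> int:
    df = summaries
    mapping = {
        "cohort_2": (df["cohort"].astype(int) == 2),
        "cohort_3": (df["cohort"].astype(int) == 3),
        "weaning_step_down": df["weaning_stage"] == "step_down",
        "weaning_weaned": df["weaning_stage"] == "weaned",
        "health_moderate": df["health_status"] == "moderate",
        "health_sick": df["health_status"] == "sick",
        "sex_male_HOxAA": df["sex_breed"] == "male_HOxAA",
    }
    if term in mapping:
        return int(mapping[term].sum())
    return len(df)


def _check_input(summaries: pd.DataFrame, response: str) -> pd.DataFrame:
    needed = {
        "calf_id",
        "age_days",
        "cohort",
        "weaning_stage",
        "health_status",
        "sex_breed",
        "mean_temp_c",
        response,
    }
    missing = needed - set(summaries.columns)
    if missing:
        raise InputError(f"summaries missing columns: {sorted(missing)}")
    df = summaries
    if "missing_metadata" in df.columns:
        df = df[~df["missing_metadata"]]
    if df["calf_id"].nunique() < 2:
        raise InputError("association models need at least 2 calves")
    if len(df) < 10:
        raise InputError("association models need at least 10 calf-days")
    return df


def _fit(
    summaries: pd.DataFrame, response: str, family: str, n_quad: int = 1
) -> AssociationResult:
    df = _check_input(summaries, response)
    y = np.round(df[response].to_numpy(float)).astype(int)
    X, names, dropped = _design(df)
    model = RandomInterceptGLMM(
        y, X, df["calf_id"].to_numpy(), family=family, n_quad=n_quad
    )
    fit = model.fit(names=names)
    table = fit.summary_frame()
    table.insert(1, "n", [_level_n(df, t) for t in table["term"]])
    return AssociationResult(
        response=response, fit=fit, table=table, dropped_terms=list(dropped)
    )


def _pearson_dispersion(y: np.ndarray, X: np.ndarray) -> float:
    import statsmodels.api as sm

    glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    mu = np.clip(glm.fittedvalues, 1e-8, None)
    return float(np.sum((y - mu) ** 2 / mu) / (len(y) - X.shape[1]))


def fit_duration_model(summaries: pd.DataFrame, n_quad: int = 1) -> AssociationResult:
    """Log-link mixed model for total daily play seconds.

    Starts from a Poisson family (durations are integer seconds and
    zero-play days occur); if the marginal Pearson dispersion exceeds
    OVERDISPERSION_THRESHOLD the family is upgraded to NB2.
    """
    df = _check_input(summaries, "total_play_s")
    y = np.round(df["total_play_s"].to_numpy(float)).astype(int)
    X, _, _ = _design(df)
    family = (
        "negbin"
        if _pearson_dispersion(y, X) > OVERDISPERSION_THRESHOLD
        else "poisson"
    )
    return _fit(summaries, "total_play_s", family, n_quad=n_quad)


def fit_count_model(summaries: pd.DataFrame, n_quad: int = 1) -> AssociationResult:
    """Negative-binomial mixed model for daily play-instance counts."""
    return _fit(summaries, "n_instances", "negbin", n_quad=n_quad)


def rate_ratios(result: AssociationResult) -> pd.DataFrame:
    """Exponentiated estimates with percent-change phrasing."""
    tab = result.table.copy()
    tab["rate_ratio"] = np.exp(tab["estimate"])
    tab["pct_change"] = 100.0 * (tab["rate_ratio"] - 1.0)
    return tab[["term", "estimate", "rate_ratio", "pct_change", "p_value"]]


def variance_explained_calf(result: AssociationResult) -> float:
    """Percent of latent-scale variance attributable to the calf intercept.

    Latent intraclass proportion sigma_u^2 / (sigma_u^2 + sigma_eps^2)
    where the observation-level latent variance uses the trigamma method
    evaluated at the mean fitted value.
    """
    fit = result.fit
    resid = latent_residual_variance(fit.family, fit.fitted_mean, fit.alpha)
    total = fit.sigma_u**2 + resid
    if total <= 0:
        raise InputError("total latent variance is zero")
    return 100.0 * fit.sigma_u**2 / total


def sensitivity_refit_excluding(
    summaries: pd.DataFrame,
    response: str = "n_instances",
    exclude_sex_breed: str = "male_HOxAA",
    n_quad: int = 1,
) -> tuple[AssociationResult, pd.DataFrame]:
    """Refit after removing one sex-breed group; report sign agreement.

    Returns the refit and a per-term frame comparing the base and refit
    estimate signs for the terms shared by both fits.  If the exclusion
    removes a whole level its term is dropped from the refit design (with
    the drop recorded on the result).
    """
    if response == "n_instances":
        base = fit_count_model(summaries, n_quad=n_quad)
    else:
        base = fit_duration_model(summaries, n_quad=n_quad)
    subset = summaries[summaries["sex_breed"] != exclude_sex_breed]
    if len(subset) == len(summaries):
        refit = base
    elif response == "n_instances":
        refit = fit_count_model(subset, n_quad=n_quad)
    else:
        refit = fit_duration_model(subset, n_quad=n_quad)
    shared = [t for t in base.table["term"] if t in set(refit.table["term"])]
    b = base.table.set_index("term").loc[shared, "estimate"]
    r = refit.table.set_index("term").loc[shared, "estimate"]
    agreement = pd.DataFrame(
        {
            "term": shared,
            "base_estimate": b.to_numpy(),
            "refit_estimate": r.to_numpy(),
            "sign_agrees": np.sign(b.to_numpy()) == np.sign(r.to_numpy()),
        }
    )
    return refit, agreement
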