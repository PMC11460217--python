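"""Multinomial logistic regression of subgroup membership on covariates.

Fits a maximum-likelihood softmax regression (reference-coded) of patient
subgroup on demographic/clinical covariates, reports odds ratios with
Bonferroni-corrected Wald p-values, the AIC, Cragg-Uhler (Nagelkerke)
pseudo-R-squared and the likelihood-ratio test against the intercept-only
model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = ["SubgroupModel", "fit_multinomial", "bonferroni", "select_reference_group"]


@dataclass
class SubgroupModel:
    reference_group: int
    coefficients: pd.DataFrame   # long: subgroup, term, coef, se, odds_ratio, p_raw, p_bonferroni
    aic: float
    pseudo_r2_cragg_uhler: float
    lr_chi2: float
    lr_p: float
    n: int
    log_likelihood: float
    null_log_likelihood: float
    fitted_probabilities: np.ndarray  # n x G, columns ordered reference first


def bonferroni(p_raw: float | np.ndarray, m: int) -> float | np.ndarray:
    """Family-wise corrected p-value min(1, m * p)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, m * np.asarray(p_raw, dtype=float)) if np.ndim(p_raw) else min(
        1.0, m * float(p_raw)
    )


def build_design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Expand categorical covariates to indicators (first sorted level is the
    reference), keep numeric covariates linear, prepend an intercept."""
    parts = [pd.Series(1.0, index=covariates.index, name="intercept")]
    for col in covariates.columns:
        series = covariates[col]
        if pd.api.types.is_numeric_dtype(series):
            parts.append(series.astype(float))
        else:
            levels = sorted(series.astype(str).unique())
            for level in levels[1:]:
                parts.append(
                    (series.astype(str) == level).astype(float).rename(f"{col}[{level}]")
                )
    return pd.concat(parts, axis=1)


def fit_multinomial(
    covariates: pd.DataFrame,
    labels: pd.Series,
    reference: int,
    bonferroni_m: int | None = None,
) -> SubgroupModel:
    """ML multinomial logit of subgroup membership with corrected inference.

    Complete-case rows only. ``bonferroni_m`` defaults to the number of
    non-intercept coefficient tests across all non-reference equations.
    """
    data = covariates.join(labels.rename("_subgroup"), how="inner").dropna()
    y = data["_subgroup"].astype(int)
    groups = sorted(y.unique())
    if reference not in groups:
        raise ValueError(f"reference group {reference} not among subgroups {groups}")
    if len(groups) < 2:
        raise ValueError("need at least 2 subgroups")
    # statsmodels MNLogit takes the first category as the baseline
    order = [reference] + [g for g in groups if g != reference]
    codes = y.map({g: k for k, g in enumerate(order)}).to_numpy()

    X = build_design(data.drop(columns="_subgroup"))
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("singular design matrix (collinear covariates)")
    n = X.shape[0]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.MNLogit(codes, X.to_numpy()).fit(method="newton", maxiter=200, disp=0)
        null = sm.MNLogit(codes, np.ones((n, 1))).fit(method="newton", maxiter=200, disp=0)

    params = fit.params        # (k, G-1)
    pvals = fit.pvalues
    bses = fit.bse
    terms = list(X.columns)
    if np.any(np.abs(params[1:, :]) > 15):
        idx = np.argwhere(np.abs(params[1:, :]) > 15)[0]
        warnings.warn(
            f"possible quasi-separation: coefficient for {terms[idx[0] + 1]!r} exceeds 15",
            stacklevel=2,
        )

    m = bonferroni_m if bonferroni_m is not None else (len(terms) - 1) * (len(order) - 1)
    rows = []
    for g_idx, g in enumerate(order[1:]):
        for t_idx, term in enumerate(terms):
            p_raw = float(pvals[t_idx, g_idx])
            rows.append(
                {
                    "subgroup": g,
                    "term": term,
                    "coef": float(params[t_idx, g_idx]),
                    "se": float(bses[t_idx, g_idx]),
                    "odds_ratio": float(np.exp(params[t_idx, g_idx])),
                    "p_raw": p_raw,
                    "p_bonferroni": float(bonferroni(p_raw, m)) if term != "intercept" else np.nan,
                }
            )
    coef_table = pd.DataFrame(rows)

    ll1, ll0 = float(fit.llf), float(null.llf)
    lr_chi2 = 2.0 * (ll1 - ll0)
    df = (len(terms) - 1) * (len(order) - 1)
    lr_p = float(stats.chi2.sf(lr_chi2, df)) if df > 0 else 1.0
    # Cragg-Uhler / Nagelkerke: (1 - (L0/L1)^(2/n)) / (1 - L0^(2/n))
    cu = float((1.0 - np.exp(2.0 / n * (ll0 - ll1))) / (1.0 - np.exp(2.0 / n * ll0)))

    return SubgroupModel(
        reference_group=reference,
        coefficients=coef_table,
        aic=float(fit.aic),
        pseudo_r2_cragg_uhler=cu,
        lr_chi2=float(lr_chi2),
        lr_p=lr_p,
        n=n,
        log_likelihood=ll1,
        null_log_likelihood=ll0,
        fitted_probabilities=np.asarray(fit.predict()),
    )


def select_reference_group(covariates: pd.DataFrame, labels: pd.Series) -> int:
    """Subgroup most demographically similar to the whole cohort.

    Similarity is the sum over covariates of |subgroup mean - cohort mean| /
    cohort sd for numeric covariates and the total variation distance of the
    level distributions for categorical ones; the minimizing subgroup wins
    (ties -> smallest id).
    """
    labels = labels.loc[covariates.index]
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 subgroups")
    scores: dict[int, float] = {}
    for g in groups:
        sub = covariates.loc[labels == g]
        score = 0.0
        for col in covariates.columns:
            if pd.api.types.is_numeric_dtype(covariates[col]):
                sd = covariates[col].std(ddof=1)
                if sd > 0:
                    score += abs(sub[col].mean() - covariates[col].mean()) / sd
            else:
                all_freq = covariates[col].astype(str).value_counts(normalize=True)
                sub_freq = sub[col].astype(str).value_counts(normalize=True)
                levels = all_freq.index.union(sub_freq.index)
                score += 0.5 * sum(
                    abs(sub_freq.get(lv, 0.0) - all_freq.get(lv, 0.0)) for lv in levels
                )
        scores[int(g)] = score
    return min(scores, key=lambda g: (scores[g], g))
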