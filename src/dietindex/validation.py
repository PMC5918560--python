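"""Index validation: concurrent criterion contrasts and health regressions.

Concurrent criterion validity checks that an index separates groups known
to eat differently: non-smokers vs smokers, women vs men, older vs
younger.  Normally-distributed indices (HEI, MDS) use two-sample t tests;
the skewed HFD uses the Wilcoxon rank-sum.  Construct validity is probed
by nested linear regressions of health measures (BMI, frailty index) on
each index with age, sex, and zygosity as covariates; all model variables
are z-scored so coefficients are standardized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm


@dataclass
class CriterionResult:
    """One group contrast for one index."""

    index: str
    contrast: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    statistic: float
    p: float
    test: str  # 'two-sample t' | 'rank-sum'


@dataclass
class HealthRegressionResult:
    """Standardized association of one index with one health outcome."""

    index: str
    outcome: str
    beta: float
    se: float
    t: float
    p: float
    nested_p: float  # F test of the model with vs without the index
    covariates: tuple[str, ...]
    n: int


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant variable")
    return (x - x.mean()) / sd


def _contrast_groups(metadata: pd.DataFrame, age_split: float):
    """(contrast name, boolean mask for group A, labels) per contrast."""
    out = []
    if "sex" in metadata:
        out.append(("men_vs_women", metadata["sex"] == "M", ("men", "women")))
    if "age" in metadata:
        out.append(
            (f"over{age_split:g}_vs_under{age_split:g}",
             metadata["age"] >= age_split,
             (f"over {age_split:g}", f"under {age_split:g}"))
        )
    if "smoker" in metadata:
        out.append(("smokers_vs_nonsmokers", metadata["smoker"].astype(bool), ("smokers", "non-smokers")))
    return out


def criterion_tests(
    scores: pd.DataFrame,
    metadata: pd.DataFrame,
    age_split: float = 60.0,
    rank_sum_indices: tuple[str, ...] = ("hfd",),
) -> pd.DataFrame:
    """All index x contrast group comparisons.

    ``scores`` has one column per index.  Indices named in
    ``rank_sum_indices`` use the Wilcoxon rank-sum test; the rest use the
    two-sample t test.  The age split threshold is a parameter.
    """
    meta = metadata.loc[scores.index]
    rows = []
    for index_name in scores.columns:
        x = scores[index_name].to_numpy(dtype=float)
        if x.std(ddof=1) == 0:
            raise ValueError(f"{index_name}: scores are constant, contrast undefined")
        for contrast, mask_a, (label_a, label_b) in _contrast_groups(meta, age_split):
            a = x[mask_a.to_numpy()]
            b = x[~mask_a.to_numpy()]
            if len(a) < 2 or len(b) < 2:
                raise ValueError(f"{contrast}: each group needs n >= 2")
            if index_name in rank_sum_indices:
                stat, p = stats.ranksums(a, b)
                test = "rank-sum"
            else:
                stat, p = stats.ttest_ind(a, b)
                test = "two-sample t"
            rows.append(
                CriterionResult(
                    index_name, contrast, label_a, label_b, len(a), len(b),
                    float(a.mean()), float(b.mean()), float(stat), float(p), test,
                )
            )
    return pd.DataFrame([vars(r) for r in rows])


def health_regression(
    score: pd.Series,
    outcome: pd.Series,
    metadata: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "sex", "zygosity"),
) -> HealthRegressionResult:
    """Nested OLS of one health outcome on one index plus covariates.

    Continuous variables are z-scored; two-level categoricals are coded
    0/1 then z-scored, so the index coefficient is a standardized beta.
    The nested p compares the full model against covariates-only.
    """
    meta = metadata.loc[score.index]
    frame = pd.DataFrame({"outcome": outcome.loc[score.index], "index": score})
    for cov in covariates:
        col = meta[cov]
        if col.dtype == object or col.dtype == bool or isinstance(col.dtype, pd.CategoricalDtype):
            col = pd.factorize(col)[0]
        frame[cov] = np.asarray(col, dtype=float)
    frame = frame.dropna()
    z = frame.apply(lambda c: _zscore(c.to_numpy()), raw=False)
    X_full = sm.add_constant(z[["index", *covariates]])
    if np.linalg.matrix_rank(X_full.to_numpy()) < X_full.shape[1]:
        raise ValueError("rank-deficient design (collinear covariates)")
    full = sm.OLS(z["outcome"], X_full).fit()
    reduced = sm.OLS(z["outcome"], sm.add_constant(z[list(covariates)])).fit()
    _, nested_p, _ = full.compare_f_test(reduced)
    return HealthRegressionResult(
        index=str(score.name),
        outcome=str(outcome.name),
        beta=float(full.params["index"]),
        se=float(full.bse["index"]),
        t=float(full.tvalues["index"]),
        p=float(full.pvalues["index"]),
        nested_p=float(nested_p),
        covariates=covariates,
        n=int(full.nobs),
    )


def health_regressions(
    scores: pd.DataFrame,
    metadata: pd.DataFrame,
    outcomes: tuple[str, ...] = ("bmi", "frailty"),
    covariates: tuple[str, ...] = ("age", "sex", "zygosity"),
) -> pd.DataFrame:
    """Every index x outcome nested regression, as a tidy frame."""
    rows = []
    for outcome in outcomes:
        y = metadata.loc[scores.index, outcome]
        y.name = outcome
        for index_name in scores.columns:
            rows.append(
                vars(health_regression(scores[index_name], y, metadata, covariates))
            )
    return pd.DataFrame(rows)
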