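"""Dietary index vs microbiota association battery.

This module wires the downstream analyses that quantify how much gut
microbiota variation a dietary index captures:

* OTU preprocessing — prevalence filter (> 25% of samples by default),
  log10 relative abundance with a pseudo-fraction for zeros, and
  residualization against technical covariates (sequencing depth, run,
  DNA extractor, DNA loader, collection method);
* linear mixed-effects models of alpha diversity, OTU residuals, taxon
  abundances, and PCoA axes on each index, with z-scored variables so
  coefficients are standardized, random intercepts for technical
  covariates and FFQ batch, and nested (with/without index) likelihood
  ratio comparisons;
* Storey q-value FDR control across OTUs/taxa;
* the twin-discordance design — co-twins whose index scores differ by
  more than one SD *and* fall in different quartiles — with paired
  Wilcoxon signed-rank tests per OTU;
* regression of weighted-UniFrac distance between co-twins on their
  index dissimilarity and covariate differences.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

logger = logging.getLogger(__name__)

TECHNICAL_COVARIATES = ("depth", "run", "extractor", "loader", "collection")
TAXONOMY_LEVELS = {
    "kingdom": "k",
    "phylum": "p",
    "class": "c",
    "order": "o",
    "family": "f",
    "genus": "g",
}


# ------------------------------------------------------------ preprocessing

def prevalence_filter(rel_abund: pd.DataFrame, threshold: float = 0.25) -> pd.DataFrame:
    """Keep OTUs present (nonzero) in strictly more than ``threshold`` of samples."""
    prevalence = rel_abund.gt(0).mean(axis=0)
    return rel_abund.loc[:, prevalence > threshold]


def log10_abundance(rel_abund: pd.DataFrame) -> pd.DataFrame:
    """log10 relative abundance; zeros replaced by half the smallest
    nonzero relative abundance in the whole table (pseudo-fraction)."""
    arr = rel_abund.to_numpy(dtype=float)
    nonzero = arr[arr > 0]
    if nonzero.size == 0:
        raise ValueError("relative abundance table is all zero")
    pseudo = nonzero.min() / 2.0
    return pd.DataFrame(
        np.log10(np.where(arr > 0, arr, pseudo)),
        index=rel_abund.index,
        columns=rel_abund.columns,
    )


def residualize_abundance(
    log_abund: pd.DataFrame, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Per-OTU OLS residuals against the technical covariates.

    Numeric covariates enter directly; categoricals as dummy indicators.
    Constant covariates are dropped with a warning.  Residuals of all
    OTUs are computed in one least-squares solve.
    """
    if len(log_abund) < 2:
        raise ValueError("need at least 2 samples to residualize")
    cov = covariates.loc[log_abund.index]
    cols = []
    for name in cov.columns:
        col = cov[name]
        if col.nunique() < 2:
            warnings.warn(f"dropping constant technical covariate {name!r}")
            continue
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == bool:
            cols.append(pd.get_dummies(col, prefix=name, drop_first=True, dtype=float))
        else:
            cols.append(col.astype(float).to_frame(name))
    X = np.column_stack(
        [np.ones(len(log_abund))] + [c.to_numpy() for c in cols]
    )
    Y = log_abund.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return pd.DataFrame(Y - X @ beta, index=log_abund.index, columns=log_abund.columns)


def collapse_taxonomy(
    counts: pd.DataFrame, taxonomy: pd.Series, level: str = "genus"
) -> pd.DataFrame:
    """Sum OTU counts into taxa at the requested level.

    Taxonomy strings use the 'k__..; p__..; ...; g__..' convention.
    OTUs lacking an assignment at ``level`` pool under ``'unassigned'``.
    Per-sample totals are conserved.
    """
    if level not in TAXONOMY_LEVELS:
        raise KeyError(f"unknown taxonomy level {level!r}")
    prefix = TAXONOMY_LEVELS[level] + "__"
    labels = {}
    for otu in counts.columns:
        label = "unassigned"
        tax = taxonomy.get(otu)
        if isinstance(tax, str):
            for part in tax.split(";"):
                part = part.strip()
                if part.startswith(prefix) and len(part) > len(prefix):
                    label = part[len(prefix):]
                    break
        labels[otu] = label
    return counts.T.groupby(pd.Series(labels)).sum().T


# ------------------------------------------------------------- mixed models

@dataclass
class AssociationResult:
    """One standardized index-outcome association."""

    index: str
    outcome: str
    beta: float
    se: float
    t: float
    p: float
    aic: float
    lrt_p: float
    n: int
    model: str  # 'mixed' | 'ols_fallback'
    q: float | None = None


def _design_frame(
    outcome: pd.Series,
    exposure: pd.Series,
    metadata: pd.DataFrame,
    fixed: tuple[str, ...],
    random: tuple[str, ...],
) -> pd.DataFrame:
    """Aligned, z-scored modelling frame (random-effect columns unscaled)."""
    meta = metadata.loc[outcome.index]
    frame = pd.DataFrame({"outcome": outcome.astype(float), "exposure": exposure.loc[outcome.index].astype(float)})
    for name in fixed:
        col = meta[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == bool:
            col = pd.Series(pd.factorize(col)[0], index=meta.index)
        frame[name] = col.astype(float)
    frame = frame.dropna()
    for name in frame.columns:
        sd = frame[name].std(ddof=1)
        if sd == 0:
            raise ValueError(f"variable {name!r} is constant; model undefined")
        frame[name] = (frame[name] - frame[name].mean()) / sd
    for name in random:
        frame[name] = meta.loc[frame.index, name].astype(str).to_numpy()
    return frame


def mixed_assoc(
    outcome: pd.Series,
    exposure: pd.Series,
    metadata: pd.DataFrame,
    fixed: tuple[str, ...] = ("age", "bmi", "sex", "zygosity"),
    random: tuple[str, ...] = ("batch",),
    index_name: str | None = None,
    outcome_name: str | None = None,
) -> AssociationResult:
    """Standardized mixed-model association of one outcome with one index.

    Fits ``outcome ~ exposure + fixed`` with crossed random intercepts
    for every column in ``random`` (ML, so the nested likelihood-ratio
    comparison against the exposure-free model is valid).  A singular or
    non-converged random-effect fit falls back to a fixed-intercept OLS
    model, flagged in ``model``.
    """
    frame = _design_frame(outcome, exposure, metadata, fixed, random)
    rhs = " + ".join(["exposure", *fixed])
    reduced_rhs = " + ".join(fixed) if fixed else "1"
    vc = {name: f"0 + C({name})" for name in random}
    frame["_group"] = 1

    result = reduced = None
    if random:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                full = sm.MixedLM.from_formula(
                    f"outcome ~ {rhs}", groups="_group", vc_formula=vc, data=frame
                ).fit(reml=False, method="lbfgs")
                red = sm.MixedLM.from_formula(
                    f"outcome ~ {reduced_rhs}",
                    groups="_group", vc_formula=vc, data=frame,
                ).fit(reml=False, method="lbfgs")
                ok = (
                    np.isfinite(full.params["exposure"])
                    and np.isfinite(full.bse["exposure"])
                    and full.bse["exposure"] > 0
                )
                if ok:
                    result, reduced = full, red
            except (np.linalg.LinAlgError, ValueError):
                pass
    if result is not None:
        lrt = 2.0 * (result.llf - reduced.llf)
        lrt_p = float(stats.chi2.sf(max(lrt, 0.0), df=1))
        return AssociationResult(
            index=index_name or str(exposure.name),
            outcome=outcome_name or str(outcome.name),
            beta=float(result.params["exposure"]),
            se=float(result.bse["exposure"]),
            t=float(result.tvalues["exposure"]),
            p=float(result.pvalues["exposure"]),
            aic=float(result.aic),
            lrt_p=lrt_p,
            n=int(result.nobs),
            model="mixed",
        )
    # fixed-intercept fallback
    X = sm.add_constant(frame[["exposure", *fixed]].astype(float))
    ols = sm.OLS(frame["outcome"], X).fit()
    X0 = sm.add_constant(frame[list(fixed)].astype(float)) if fixed else np.ones((len(frame), 1))
    ols0 = sm.OLS(frame["outcome"], X0).fit()
    lrt = 2.0 * (ols.llf - ols0.llf)
    return AssociationResult(
        index=index_name or str(exposure.name),
        outcome=outcome_name or str(outcome.name),
        beta=float(ols.params["exposure"]),
        se=float(ols.bse["exposure"]),
        t=float(ols.tvalues["exposure"]),
        p=float(ols.pvalues["exposure"]),
        aic=float(ols.aic),
        lrt_p=float(stats.chi2.sf(max(lrt, 0.0), df=1)),
        n=int(ols.nobs),
        model="ols_fallback",
    )


def alpha_associations(
    alpha: pd.DataFrame,
    scores: pd.DataFrame,
    metadata: pd.DataFrame,
    fixed: tuple[str, ...] = ("age", "bmi", "sex", "zygosity", "depth"),
    random: tuple[str, ...] = ("run", "extractor", "loader", "collection", "batch"),
) -> pd.DataFrame:
    """Every index x alpha-metric mixed model, as a tidy frame."""
    common = alpha.index.intersection(scores.index)
    rows = [
        vars(
            mixed_assoc(
                alpha.loc[common, metric], scores.loc[common, index_name],
                metadata, fixed, random,
                index_name=index_name, outcome_name=metric,
            )
        )
        for index_name in scores.columns
        for metric in alpha.columns
    ]
    return pd.DataFrame(rows)


def otu_associations(
    residuals: pd.DataFrame,
    scores: pd.DataFrame,
    metadata: pd.DataFrame,
    fixed: tuple[str, ...] = ("age", "zygosity", "bmi", "sex"),
    random: tuple[str, ...] = ("batch",),
) -> pd.DataFrame:
    """Every index x OTU (or taxon) mixed model with per-index FDR."""
    common = residuals.index.intersection(scores.index)
    frames = []
    for index_name in scores.columns:
        rows = [
            vars(
                mixed_assoc(
                    residuals.loc[common, otu], scores.loc[common, index_name],
                    metadata, fixed, random,
                    index_name=index_name, outcome_name=str(otu),
                )
            )
            for otu in residuals.columns
        ]
        block = pd.DataFrame(rows)
        block["q"] = fdr(block["p"].to_numpy()).q
        frames.append(block)
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------- FDR

@dataclass
class QValueResult:
    q: np.ndarray
    pi0: float
    method: str  # 'storey' | 'bh_fallback'


def fdr(p, min_storey_m: int = 30) -> QValueResult:
    """Storey q-values with the smoother pi0 estimate.

    pi0 is estimated from #{p > lambda} / (m (1 - lambda)) on a lambda
    grid, smoothed with a cubic polynomial and read off at the largest
    lambda.  When the estimate is unusable (or m is too small for the
    smoother to be stable) the Benjamini-Hochberg procedure (pi0 = 1) is
    used instead and flagged.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value input")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    pi0, method = 1.0, "bh_fallback"
    if m >= min_storey_m:
        lambdas = np.arange(0.05, 0.96, 0.05)
        pi0_l = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
        coeffs = np.polyfit(lambdas, pi0_l, deg=3)
        est = float(np.polyval(coeffs, lambdas.max()))
        if np.isfinite(est) and est > 0:
            pi0, method = min(est, 1.0), "storey"
        else:
            warnings.warn("pi0 estimation failed; falling back to Benjamini-Hochberg")
    order = np.argsort(p)[::-1]  # largest p first
    q_sorted = np.empty(m)
    running = np.inf
    for rank_from_top, idx in enumerate(order):
        rank = m - rank_from_top  # rank of this p among ascending p's
        running = min(running, pi0 * m * p[idx] / rank)
        q_sorted[idx] = running
    return QValueResult(q=np.minimum(q_sorted, 1.0), pi0=pi0, method=method)


# ----------------------------------------------------------- twin analyses

@dataclass
class DiscordantPair:
    pair_id: object
    healthy_id: object
    less_healthy_id: object
    difference: float


def find_discordant_pairs(
    scores: pd.Series,
    pair_ids: pd.Series,
    sd_rule: float = 1.0,
    n_quantiles: int = 4,
) -> pd.DataFrame:
    """Twin pairs discordant for a dietary index.

    A pair qualifies only if BOTH hold: the score difference exceeds
    ``sd_rule`` population SDs (SD over the scored subset) and the twins
    fall in different quantiles (nearest-rank quartiles by default).
    The higher-scoring twin is labelled healthy.  Unpaired subjects are
    skipped silently with a logged count.
    """
    pair_ids = pair_ids.reindex(scores.index)
    unpaired = int(pair_ids.isna().sum())
    if unpaired:
        logger.info("skipping %d subjects without a twin pair id", unpaired)
    sd = scores.std(ddof=1)
    n = len(scores)
    ranks = scores.rank(method="first")
    quantile = np.ceil(n_quantiles * ranks / n).astype(int)

    rows = []
    n_incomplete = 0
    for pid, members in scores.groupby(pair_ids):
        if len(members) != 2:
            n_incomplete += 1
            continue
        (id_a, score_a), (id_b, score_b) = members.items()
        diff = abs(score_a - score_b)
        if diff > sd_rule * sd and quantile[id_a] != quantile[id_b]:
            healthy, less = (id_a, id_b) if score_a > score_b else (id_b, id_a)
            rows.append(DiscordantPair(pid, healthy, less, float(diff)))
    if n_incomplete:
        logger.info("skipping %d pairs without both members scored", n_incomplete)
    out = pd.DataFrame(
        [vars(r) for r in rows],
        columns=["pair_id", "healthy_id", "less_healthy_id", "difference"],
    )
    out.attrs["n_unpaired"] = unpaired
    out.attrs["sd"] = float(sd)
    return out


def paired_tests(residuals: pd.DataFrame, pairs: pd.DataFrame) -> pd.DataFrame:
    """Per-OTU paired Wilcoxon signed-rank tests across discordant pairs.

    Differences are healthy-twin minus less-healthy-twin residuals.
    With fewer than 6 usable pairs the p values are undefined (NaN,
    flagged in ``attrs['underpowered']``).  q values via :func:`fdr`.
    """
    usable = pairs[
        pairs["healthy_id"].isin(residuals.index)
        & pairs["less_healthy_id"].isin(residuals.index)
    ]
    n_pairs = len(usable)
    diffs = (
        residuals.loc[usable["healthy_id"]].to_numpy()
        - residuals.loc[usable["less_healthy_id"]].to_numpy()
    )
    rows = []
    for j, otu in enumerate(residuals.columns):
        d = diffs[:, j] if n_pairs else np.array([])
        if n_pairs < 6:
            rows.append({"outcome": otu, "statistic": np.nan, "p": np.nan,
                         "median_difference": np.nan})
            continue
        if np.all(d == 0):
            rows.append({"outcome": otu, "statistic": 0.0, "p": 1.0,
                         "median_difference": 0.0})
            continue
        res = stats.wilcoxon(d, zero_method="wilcox")
        rows.append({"outcome": otu, "statistic": float(res.statistic),
                     "p": float(res.pvalue), "median_difference": float(np.median(d))})
    out = pd.DataFrame(rows)
    out["n_pairs"] = n_pairs
    if n_pairs >= 6:
        out["q"] = fdr(out["p"].to_numpy()).q
    else:
        out["q"] = np.nan
    out.attrs["underpowered"] = n_pairs < 6
    return out


def build_pair_distance_frame(
    distances,
    scores: pd.Series,
    metadata: pd.DataFrame,
    pair_ids: pd.Series,
    covariates: tuple[str, ...] = ("bmi",),
    technical: tuple[str, ...] = ("extractor", "loader", "collection"),
) -> pd.DataFrame:
    """One row per complete twin pair: weighted-UniFrac distance between
    co-twins, absolute index and covariate differences, and 0/1
    same/different indicators for factorial technical variables."""
    dist = distances.to_data_frame() if hasattr(distances, "to_data_frame") else distances
    dist.index = dist.index.astype(str)
    dist.columns = dist.columns.astype(str)
    rows = {}
    for pid, members in scores.groupby(pair_ids.reindex(scores.index)):
        if len(members) != 2:
            continue
        id_a, id_b = members.index
        if str(id_a) not in dist.index or str(id_b) not in dist.columns:
            continue
        row = {"distance": float(dist.loc[str(id_a), str(id_b)]),
               "d_index": float(abs(members.iloc[0] - members.iloc[1]))}
        for cov in covariates:
            row[f"d_{cov}"] = float(abs(metadata.loc[id_a, cov] - metadata.loc[id_b, cov]))
        for tech in technical:
            row[f"diff_{tech}"] = float(metadata.loc[id_a, tech] != metadata.loc[id_b, tech])
        rows[pid] = row
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("pair_id")


def pair_distance_regression(pair_frame: pd.DataFrame) -> pd.DataFrame:
    """Standardized OLS of co-twin distance on index dissimilarity.

    ``pair_frame`` is one row per pair (see
    :func:`build_pair_distance_frame`) with the response in ``distance``.
    Duplicate pair rows are an integrity error.
    """
    if pair_frame.index.duplicated().any():
        raise ValueError("duplicate pair rows in distance regression input")
    predictors = [c for c in pair_frame.columns if c != "distance"]
    if len(pair_frame) <= len(predictors) + 1:
        raise ValueError("fewer pairs than model parameters")
    z = pd.DataFrame(index=pair_frame.index)
    for col in pair_frame.columns:
        v = pair_frame[col].to_numpy(dtype=float)
        sd = v.std(ddof=1)
        z[col] = (v - v.mean()) / sd if sd > 0 else 0.0
    res = sm.OLS(z["distance"], sm.add_constant(z[predictors])).fit()
    return pd.DataFrame(
        {
            "beta": res.params[predictors],
            "se": res.bse[predictors],
            "t": res.tvalues[predictors],
            "p": res.pvalues[predictors],
        }
    ).rename_axis("term")
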