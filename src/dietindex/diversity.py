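"""Rarefied alpha diversity, UniFrac beta diversity, and PCoA.

Alpha diversity follows the multiple-rarefaction protocol: each sample is
subsampled without replacement to a fixed depth (default 10,000 reads) a
fixed number of times (default 50), the four metrics — observed OTUs,
bias-corrected Chao1, Shannon (natural log), Simpson (1 - sum p^2) — are
computed on every rarefied table, and per-sample means across replicates
are reported.  Samples below the rarefaction depth are dropped, not
resampled with replacement.

The metric kernels are vectorised over replicate x OTU count matrices so
that cohort-scale rarefaction stays cheap; scikit-bio provides the same
metrics and is used as an independent cross-check in the test suite.
UniFrac distances and principal-coordinates analysis are delegated to
scikit-bio.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio
from skbio.diversity import beta_diversity
from skbio.stats.distance import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

logger = logging.getLogger(__name__)

ALPHA_METRICS = ("chao1", "observed", "shannon", "simpson")


@dataclass
class OTUTable:
    """Sample x OTU counts with taxonomy, phylogeny and technical covariates."""

    counts: pd.DataFrame  # samples x OTUs, nonnegative integers
    taxonomy: pd.Series | None = None  # per-OTU 'k__..; p__..; ..' strings
    tree: skbio.TreeNode | None = None
    sample_data: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("OTU counts must be nonnegative")

    @property
    def depths(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        totals = self.depths.replace(0, np.nan)
        return self.counts.div(totals, axis=0).fillna(0.0)


# ---------------------------------------------------------------- metrics

def observed_otus(counts: np.ndarray) -> np.ndarray:
    """Number of OTUs with nonzero count (rows = communities)."""
    counts = np.atleast_2d(counts)
    return (counts > 0).sum(axis=1).astype(float)


def chao1(counts: np.ndarray) -> np.ndarray | float:
    """Bias-corrected Chao1: S_obs + F1(F1-1) / (2(F2+1)).

    Reduces to S_obs when there are no singletons; 0 for an empty sample.
    """
    arr = np.atleast_2d(np.asarray(counts))
    s_obs = (arr > 0).sum(axis=1)
    f1 = (arr == 1).sum(axis=1)
    f2 = (arr == 2).sum(axis=1)
    est = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    return float(est[0]) if np.asarray(counts).ndim == 1 else est


def shannon(counts: np.ndarray, base: float | None = None) -> np.ndarray | float:
    """Shannon entropy of the count composition (natural log by default)."""
    arr = np.atleast_2d(np.asarray(counts, dtype=float))
    totals = arr.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(totals > 0, arr / np.where(totals > 0, totals, 1.0), 0.0)
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    h = -plogp.sum(axis=1)
    if base is not None:
        h = h / np.log(base)
    return float(h[0]) if np.asarray(counts).ndim == 1 else h


def simpson(counts: np.ndarray) -> np.ndarray | float:
    """Simpson diversity 1 - sum p^2 (0 for a one-OTU or empty sample)."""
    arr = np.atleast_2d(np.asarray(counts, dtype=float))
    totals = arr.sum(axis=1, keepdims=True)
    p = np.where(totals > 0, arr / np.where(totals > 0, totals, 1.0), 0.0)
    d = 1.0 - (p**2).sum(axis=1)
    return float(d[0]) if np.asarray(counts).ndim == 1 else d


# ------------------------------------------------------------- rarefaction

def rarefy_alpha(
    table: OTUTable | pd.DataFrame,
    depth: int = 10_000,
    reps: int = 50,
    seed: int | np.random.Generator = 0,
    shannon_base: float | None = None,
) -> pd.DataFrame:
    """Mean alpha-diversity metrics over rarefaction replicates.

    Samples with fewer than ``depth`` reads are dropped (logged).  Returns
    a frame with columns ``chao1, observed, shannon, simpson`` and an
    ``attrs['dropped']`` list of excluded samples.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    counts = table.counts if isinstance(table, OTUTable) else table
    rng = np.random.default_rng(seed)
    totals = counts.sum(axis=1)
    keep = totals >= depth
    dropped = list(counts.index[~keep])
    if dropped:
        logger.info("dropping %d samples below rarefaction depth %d", len(dropped), depth)
    kept = counts.loc[keep]
    arr = kept.to_numpy(dtype=np.int64)
    out = np.empty((arr.shape[0], 4))
    for i, row in enumerate(arr):
        if row.sum() == depth:
            sub = np.tile(row, (reps, 1))  # subsample is the sample itself
        else:
            sub = np.stack(
                [rng.multivariate_hypergeometric(row, depth) for _ in range(reps)]
            )
        out[i] = [
            chao1(sub).mean(),
            observed_otus(sub).mean(),
            shannon(sub, base=shannon_base).mean(),
            simpson(sub).mean(),
        ]
    profile = pd.DataFrame(out, index=kept.index, columns=list(ALPHA_METRICS))
    profile.attrs["dropped"] = dropped
    profile.attrs["depth"] = depth
    profile.attrs["reps"] = reps
    return profile


# ----------------------------------------------------------------- UniFrac

def unifrac(
    table: OTUTable | pd.DataFrame,
    tree: skbio.TreeNode | None = None,
    weighted: bool = False,
) -> DistanceMatrix:
    """UniFrac distance matrix (weighted variant is normalized).

    All OTUs must be tips of ``tree`` and the tree must carry branch
    lengths.  Unweighted UniFrac is the fraction of branch length leading
    to OTUs present in exactly one of the two samples; weighted UniFrac
    moves abundance mass along branches and normalizes to [0, 1].
    """
    if isinstance(table, OTUTable):
        counts, tree = table.counts, tree or table.tree
    else:
        counts = table
    if tree is None:
        raise ValueError("a phylogenetic tree is required for UniFrac")
    tip_names = {t.name for t in tree.tips()}
    missing = [o for o in counts.columns if o not in tip_names]
    if missing:
        raise ValueError(f"OTUs missing from tree: {missing[:5]}")
    metric = "weighted_unifrac" if weighted else "unweighted_unifrac"
    kwargs = {"normalized": True} if weighted else {}
    return beta_diversity(
        metric,
        counts.to_numpy(dtype=int),
        ids=list(counts.index.astype(str)),
        taxa=list(counts.columns),
        tree=tree,
        **kwargs,
    )


# -------------------------------------------------------------------- PCoA

def pcoa(distances, k: int = 10, eig_tol: float = 1e-10):
    """Classical scaling of a distance matrix.

    Returns ``(coordinates, eigenvalues)``: the first ``k`` axes with
    positive eigenvalue (axes from negative eigenvalues are excluded but
    all eigenvalues are reported), each axis sign-fixed so its
    largest-magnitude coordinate is positive.
    """
    if isinstance(distances, pd.DataFrame):
        if not np.allclose(distances.to_numpy(), distances.to_numpy().T):
            raise ValueError("distance matrix must be symmetric")
        dm = DistanceMatrix(distances.to_numpy(), ids=list(distances.index.astype(str)))
    elif isinstance(distances, DistanceMatrix):
        dm = distances
    else:
        arr = np.asarray(distances, dtype=float)
        if not np.allclose(arr, arr.T):
            raise ValueError("distance matrix must be symmetric")
        dm = DistanceMatrix(arr)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = _skbio_pcoa(dm, method="eigh")
    eigvals = res.eigvals.to_numpy()
    scale = max(eigvals.max(), 1.0)
    positive = np.flatnonzero(eigvals > eig_tol * scale)
    axes = positive[:k]
    coords = res.samples.iloc[:, axes].copy()
    for col in coords.columns:
        v = coords[col].to_numpy()
        if len(v) and v[np.argmax(np.abs(v))] < 0:
            coords[col] = -v
    coords.columns = [f"PC{i + 1}" for i in range(coords.shape[1])]
    coords.index = pd.Index(dm.ids, name="sample")
    eig = pd.Series(eigvals, index=[f"eig{i + 1}" for i in range(len(eigvals))])
    return coords, eig
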