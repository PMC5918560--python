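"""FFQ data model and energy bookkeeping.

A food-frequency questionnaire (FFQ) records, for each subject, how many
times per week each item on a fixed food list is consumed.  Downstream
index scoring works on *daily gram intakes*, obtained by multiplying the
weekly frequency by a standard portion size and dividing by seven, and on
*energy-adjusted* intakes obtained by the residual method (the residual of
an intake regressed on total energy, re-centred at the sample mean).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: columns a composition table must provide (amounts are per 100 g of item)
COMPOSITION_COLUMNS = [
    "category",
    "mds_group",
    "portion_g",
    "energy_kcal_100g",
    "mufa_g_100g",
    "pufa_g_100g",
    "sfa_g_100g",
    "sodium_g_100g",
    "alcohol_g_100g",
    "solid_fat_kcal_100g",
    "added_sugar_kcal_100g",
    "total_fruit_cup_100g",
    "whole_fruit_cup_100g",
    "total_veg_cup_100g",
    "greens_beans_cup_100g",
    "whole_grains_oz_100g",
    "dairy_cup_100g",
    "total_protein_oz_100g",
    "seafood_plant_oz_100g",
    "refined_grains_oz_100g",
    "health_value",
]


@dataclass
class FFQDataset:
    """Complete FFQ responses for a cohort.

    Parameters
    ----------
    frequencies
        Subjects x items table of weekly consumption frequencies
        (times/week).  Subjects with any missing item response are dropped
        on construction via :meth:`from_frames` (incomplete questionnaires
        are not scoreable).
    portions
        Grams consumed per eating occasion, indexed by item.
    metadata
        Per-subject covariates (age, sex, zygosity, pair id, BMI, smoking,
        frailty, FFQ batch), indexed like ``frequencies``.
    """

    frequencies: pd.DataFrame
    portions: pd.Series
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if (self.frequencies.to_numpy() < 0).any():
            raise ValueError("weekly frequencies must be nonnegative")

    @classmethod
    def from_frames(
        cls,
        frequencies: pd.DataFrame,
        portions: pd.Series,
        metadata: pd.DataFrame | None = None,
    ) -> "FFQDataset":
        """Build a dataset, dropping subjects with incomplete responses."""
        complete = frequencies.notna().all(axis=1)
        n_dropped = int((~complete).sum())
        if n_dropped:
            logger.info("dropped %d subjects with incomplete FFQ responses", n_dropped)
        frequencies = frequencies.loc[complete]
        if metadata is None:
            metadata = pd.DataFrame(index=frequencies.index)
        else:
            metadata = metadata.loc[frequencies.index]
        return cls(frequencies, portions, metadata, n_dropped)

    @property
    def subjects(self) -> pd.Index:
        return self.frequencies.index

    @property
    def items(self) -> pd.Index:
        return self.frequencies.columns


def to_daily_grams(ffq: FFQDataset) -> pd.DataFrame:
    """Convert weekly frequencies to daily gram intakes.

    grams/day = (times/week) x (portion grams) / 7.
    Raises if a consumed item has no portion size.
    """
    missing = ffq.items.difference(ffq.portions.index)
    if len(missing):
        consumed = ffq.frequencies[list(missing)].gt(0).any()
        if consumed.any():
            raise KeyError(
                f"no portion size for consumed item(s): {list(consumed[consumed].index)}"
            )
    portions = ffq.portions.reindex(ffq.items).fillna(0.0)
    return ffq.frequencies.mul(portions, axis=1) / 7.0


def total_energy(intakes: pd.DataFrame, composition: pd.DataFrame) -> pd.Series:
    """Total daily energy (kcal/day) per subject.

    ``sum_i grams_i * energy_i / 100`` over items.  Subjects with zero
    total intake get 0 kcal and are logged; callers computing energy
    densities must exclude them (see :func:`zero_energy_subjects`).
    """
    missing = intakes.columns.difference(composition.index)
    if len(missing):
        raise KeyError(f"composition table missing items: {list(missing)}")
    kcal_per_g = composition.loc[intakes.columns, "energy_kcal_100g"] / 100.0
    energy = intakes.mul(kcal_per_g, axis=1).sum(axis=1)
    energy.name = "energy_kcal"
    n_zero = int((energy <= 0).sum())
    if n_zero:
        logger.info("%d subjects have zero daily energy intake", n_zero)
    return energy


def zero_energy_subjects(energy: pd.Series) -> pd.Index:
    """Subjects flagged for zero (or negative) total energy."""
    return energy.index[energy <= 0]


def energy_adjust_residual(amount: pd.Series, energy: pd.Series) -> pd.Series:
    """Residual-method energy adjustment of one intake variable.

    OLS of ``amount`` on ``energy``; the adjusted value is the residual
    plus the sample mean of ``amount``, so the sample mean is preserved
    and the adjusted amounts are uncorrelated with energy on the fitting
    sample.
    """
    amount, energy = amount.align(energy, join="inner")
    n = len(amount)
    if n < 3:
        raise ValueError(f"need at least 3 subjects for energy adjustment, got {n}")
    x = energy.to_numpy(dtype=float)
    y = amount.to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.var(x) == 0:
        raise ValueError("total energy is constant; residual adjustment undefined")
    xc = x - x.mean()
    beta = (xc @ (y - y.mean())) / (xc @ xc)
    adjusted = y - beta * xc  # residual + mean(y)
    return pd.Series(adjusted, index=amount.index, name=amount.name)


def energy_adjust_table(
    amounts: pd.DataFrame,
    energy: pd.Series,
    batch: pd.Series | None = None,
    adjust_scope: str = "batch",
) -> pd.DataFrame:
    """Energy-adjust every column of ``amounts`` by the residual method.

    ``adjust_scope='batch'`` fits the adjustment regression separately
    within each FFQ batch (keeps batches comparable when medians are also
    computed batch-wise); ``'pooled'`` fits once on the whole sample.
    """
    if adjust_scope not in ("batch", "pooled"):
        raise ValueError(f"adjust_scope must be 'batch' or 'pooled', got {adjust_scope!r}")
    if adjust_scope == "pooled" or batch is None:
        return amounts.apply(lambda col: energy_adjust_residual(col, energy))
    batch = batch.loc[amounts.index]
    parts = []
    for _, idx in amounts.groupby(batch).groups.items():
        block = amounts.loc[idx]
        parts.append(block.apply(lambda col: energy_adjust_residual(col, energy.loc[idx])))
    return pd.concat(parts).loc[amounts.index]


def read_composition(path) -> pd.DataFrame:
    """Read a composition table TSV (items in the first column)."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in COMPOSITION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"composition table missing columns: {missing}")
    return table


def read_ffq(freq_path, composition: pd.DataFrame, metadata_path=None) -> FFQDataset:
    """Read an FFQ frequency TSV; portion sizes come from the composition table."""
    freq = pd.read_csv(freq_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0) if metadata_path else None
    return FFQDataset.from_frames(freq, composition["portion_g"], meta)
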