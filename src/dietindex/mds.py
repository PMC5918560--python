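"""Modified Mediterranean Diet Score.

The modified MDS awards one point per component for being on the healthy
side of the study-population median: above the median for the beneficial
groups (vegetables, legumes, fruit+nuts, cereal, fish) and the
unsaturated:saturated lipid ratio, below the median for the detrimental
groups (meat, dairy), and one point for alcohol intake inside a moderate,
sex-specific window.  Group intakes are energy-adjusted by the residual
method before the median split, and medians are computed within FFQ batch
so that batches collected years apart stay comparable.

Conventions (documented, config-free): ties at the median score 0 (the
split is strictly above / strictly below), and the default roster has
9 components (7 median-split groups + lipid ratio + alcohol window).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ffq import energy_adjust_table, total_energy

BENEFICIAL_GROUPS = ["vegetables", "legumes", "fruit_nuts", "cereal", "fish"]
DETRIMENTAL_GROUPS = ["meat", "dairy"]
MEDIAN_SPLIT_COMPONENTS = BENEFICIAL_GROUPS + DETRIMENTAL_GROUPS + ["lipid_ratio"]


@dataclass(frozen=True)
class AlcoholWindow:
    """Moderate-consumption window (g ethanol/day), sex-specific."""

    female: tuple[float, float] = (5.0, 25.0)
    male: tuple[float, float] = (10.0, 50.0)

    def contains(self, grams: pd.Series, sex: pd.Series) -> pd.Series:
        lo = sex.map({"F": self.female[0], "M": self.male[0]})
        hi = sex.map({"F": self.female[1], "M": self.male[1]})
        return (grams >= lo) & (grams <= hi)


@dataclass
class MDSConfig:
    alcohol_window: AlcoholWindow = field(default_factory=AlcoholWindow)
    adjust_scope: str = "batch"  # 'batch' | 'pooled'
    #: optional extra median-split columns (extension point toward a 0-10 roster)
    extra_beneficial: tuple[str, ...] = ()


def mds_components(
    intakes: pd.DataFrame,
    composition: pd.DataFrame,
    metadata: pd.DataFrame,
    config: MDSConfig | None = None,
) -> pd.DataFrame:
    """Per-subject energy-adjusted group intakes plus ratio and ethanol.

    Food items are pooled into MDS groups by the composition table's
    ``mds_group`` label; the seven food groups are residual
    energy-adjusted (g/day), the lipid ratio (MUFA+PUFA)/SFA is scale-free
    and left unadjusted, and ethanol g/day stays raw for the window rule.
    """
    config = config or MDSConfig()
    comp = composition.loc[intakes.columns]
    grams = {}
    for group in BENEFICIAL_GROUPS + DETRIMENTAL_GROUPS:
        members = comp.index[comp["mds_group"] == group]
        grams[group] = intakes[members].sum(axis=1)
    groups = pd.DataFrame(grams, index=intakes.index)

    energy = total_energy(intakes, composition)
    batch = metadata["batch"].loc[intakes.index] if "batch" in metadata else None
    adjusted = energy_adjust_table(groups, energy, batch, config.adjust_scope)
    # residual adjustment can produce small negatives; intakes are amounts
    adjusted = adjusted.clip(lower=0.0)

    x = intakes.to_numpy(dtype=float) / 100.0
    mufa = x @ comp["mufa_g_100g"].to_numpy(dtype=float)
    pufa = x @ comp["pufa_g_100g"].to_numpy(dtype=float)
    sfa = x @ comp["sfa_g_100g"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(sfa > 0, (mufa + pufa) / np.where(sfa > 0, sfa, 1.0), np.inf)
    ratio = np.where((mufa + pufa) == 0, np.where(sfa > 0, 0.0, 0.0), ratio)
    adjusted["lipid_ratio"] = ratio
    adjusted["ethanol_g"] = x @ comp["alcohol_g_100g"].to_numpy(dtype=float)
    return adjusted


def population_medians(components: pd.DataFrame, batch: pd.Series) -> pd.DataFrame:
    """Median of each median-split component within each FFQ batch."""
    batch = batch.loc[components.index]
    sizes = batch.value_counts()
    small = sizes[sizes < 2]
    if len(small):
        raise ValueError(f"batches need >= 2 subjects for medians: {dict(small)}")
    cols = [c for c in components.columns if c != "ethanol_g"]
    return components[cols].groupby(batch, observed=True).median()


def mds_score(
    components: pd.DataFrame,
    medians: pd.DataFrame,
    metadata: pd.DataFrame,
    config: MDSConfig | None = None,
) -> pd.DataFrame:
    """0/1 component scores and the integer total, one row per subject.

    Beneficial groups and the lipid ratio score 1 strictly above the
    subject's own batch median; detrimental groups score 1 strictly
    below it; alcohol scores 1 inside the sex-specific window.
    """
    config = config or MDSConfig()
    meta = metadata.loc[components.index]
    batch = meta["batch"]
    unknown = set(batch.unique()) - set(medians.index)
    if unknown:
        raise KeyError(f"no medians for batch(es): {sorted(unknown)}")
    med = medians.loc[batch].set_axis(components.index)

    out = {}
    for group in BENEFICIAL_GROUPS + list(config.extra_beneficial) + ["lipid_ratio"]:
        out[group] = (components[group] > med[group]).astype(int)
    for group in DETRIMENTAL_GROUPS:
        out[group] = (components[group] < med[group]).astype(int)
    out["alcohol"] = config.alcohol_window.contains(
        components["ethanol_g"], meta["sex"]
    ).astype(int)
    scores = pd.DataFrame(out, index=components.index)
    scores["total"] = scores.sum(axis=1)
    return scores


def mds_total(
    intakes: pd.DataFrame,
    composition: pd.DataFrame,
    metadata: pd.DataFrame,
    config: MDSConfig | None = None,
) -> pd.DataFrame:
    """Convenience pipeline: components -> batch medians -> scores."""
    config = config or MDSConfig()
    comps = mds_components(intakes, composition, metadata, config)
    medians = population_medians(comps, metadata["batch"])
    return mds_score(comps, medians, metadata, config)
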