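"""Healthy Eating Index 2010 scoring.

The HEI-2010 summarises diet quality on a 0-100 scale from twelve
energy-density-based components.  *Adequacy* components (fruit,
vegetables, whole grains, dairy, protein foods, the unsaturated:saturated
fatty-acid ratio) award more points the more is eaten per 1000 kcal, up to
a full-score standard; *moderation* components (refined grains, sodium,
empty calories) award the maximum below a lower threshold, zero above an
upper threshold, and interpolate linearly in between.  Because every
component is an energy density, the score is invariant to proportional
scaling of the whole diet.

Item-to-component amounts come from the composition table: each food item
carries cup- or ounce-equivalents per 100 g for the component numerators,
plus grams of MUFA/PUFA/SFA and sodium and the solid-fat / added-sugar /
alcohol energy making up empty calories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .ffq import total_energy, zero_energy_subjects

logger = logging.getLogger(__name__)

KCAL_PER_G_ALCOHOL = 7.0

#: composition columns (per 100 g) feeding each component numerator (per day)
_AMOUNT_SOURCES = {
    "total_fruit_cup": "total_fruit_cup_100g",
    "whole_fruit_cup": "whole_fruit_cup_100g",
    "total_veg_cup": "total_veg_cup_100g",
    "greens_beans_cup": "greens_beans_cup_100g",
    "whole_grains_oz": "whole_grains_oz_100g",
    "dairy_cup": "dairy_cup_100g",
    "total_protein_oz": "total_protein_oz_100g",
    "seafood_plant_oz": "seafood_plant_oz_100g",
    "refined_grains_oz": "refined_grains_oz_100g",
    "sodium_g": "sodium_g_100g",
    "mufa_g": "mufa_g_100g",
    "pufa_g": "pufa_g_100g",
    "sfa_g": "sfa_g_100g",
    "alcohol_g": "alcohol_g_100g",
    "solid_fat_kcal": "solid_fat_kcal_100g",
    "added_sugar_kcal": "added_sugar_kcal_100g",
}


@dataclass(frozen=True)
class HEIComponentStandard:
    """One HEI component's scoring standard."""

    name: str
    kind: str  # 'adequacy' | 'moderation' | 'ratio'
    max_points: float
    unit: str
    numerator: str
    full_threshold: float
    zero_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("adequacy", "moderation", "ratio"):
            raise ValueError(f"unknown component kind {self.kind!r}")
        if self.max_points <= 0:
            raise ValueError("max_points must be positive")
        if self.kind == "moderation" and (
            self.zero_threshold is None or self.zero_threshold <= self.full_threshold
        ):
            raise ValueError(f"{self.name}: moderation needs zero_threshold > full_threshold")
        if self.kind == "ratio" and (
            self.zero_threshold is None or self.zero_threshold >= self.full_threshold
        ):
            raise ValueError(f"{self.name}: ratio needs zero_threshold < full_threshold")


class HEIStandards:
    """The full set of twelve component standards (points sum to 100)."""

    def __init__(self, components: list[HEIComponentStandard]):
        if len(components) != 12:
            raise ValueError(f"expected 12 components, got {len(components)}")
        total = sum(c.max_points for c in components)
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"component max points must sum to 100, got {total}")
        self.components = components

    def __iter__(self):
        return iter(self.components)

    def __getitem__(self, name: str) -> HEIComponentStandard:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(name)

    @classmethod
    def from_yaml(cls, source) -> "HEIStandards":
        if hasattr(source, "read"):
            raw = yaml.safe_load(source)
        else:
            with open(source) as fh:
                raw = yaml.safe_load(fh)
        return cls([HEIComponentStandard(**c) for c in raw["components"]])

    @classmethod
    def default(cls) -> "HEIStandards":
        with resources.files("dietindex.data").joinpath("hei2010.yaml").open() as fh:
            raw = yaml.safe_load(fh)
        return cls([HEIComponentStandard(**c) for c in raw["components"]])


def map_items_to_components(
    intakes: pd.DataFrame, composition: pd.DataFrame
) -> pd.DataFrame:
    """Per-subject daily amounts of every HEI component numerator.

    Each item contributes according to its per-100 g annotations (items
    are split into e.g. lean and solid-fat fractions by those
    annotations, so one item can feed several components).
    """
    missing = intakes.columns.difference(composition.index)
    if len(missing):
        raise KeyError(f"items lacking component annotations: {list(missing)}")
    comp = composition.loc[intakes.columns]
    lacking = [c for c in _AMOUNT_SOURCES.values() if c not in comp.columns]
    if lacking:
        raise KeyError(f"composition table lacks annotation columns: {lacking}")
    x = intakes.to_numpy(dtype=float) / 100.0  # units of 100 g/day
    out = {
        amount: x @ comp[source].to_numpy(dtype=float)
        for amount, source in _AMOUNT_SOURCES.items()
    }
    out["energy_kcal"] = total_energy(intakes, composition).to_numpy()
    return pd.DataFrame(out, index=intakes.index)


def component_densities(amounts: pd.DataFrame) -> pd.DataFrame:
    """Scoring inputs: per-1000 kcal densities, the fatty-acid ratio, and
    empty calories as % of energy.  Requires positive energy."""
    energy = amounts["energy_kcal"]
    if (energy <= 0).any():
        raise ValueError("component densities undefined for zero-energy subjects")
    dens = {}
    for col in (
        "total_fruit_cup",
        "whole_fruit_cup",
        "total_veg_cup",
        "greens_beans_cup",
        "whole_grains_oz",
        "dairy_cup",
        "total_protein_oz",
        "seafood_plant_oz",
        "refined_grains_oz",
        "sodium_g",
    ):
        dens[col] = amounts[col] / energy * 1000.0
    sfa = amounts["sfa_g"]
    unsat = amounts["mufa_g"] + amounts["pufa_g"]
    # degenerate denominator: no saturated fat scores like a maximally
    # favourable ratio when any unsaturated fat is present
    ratio = np.where(sfa > 0, unsat / sfa.replace(0, np.nan), np.where(unsat > 0, np.inf, 0.0))
    dens["fatty_acid_ratio"] = pd.Series(ratio, index=amounts.index)
    empty_kcal = (
        amounts["solid_fat_kcal"]
        + amounts["added_sugar_kcal"]
        + amounts["alcohol_g"] * KCAL_PER_G_ALCOHOL
    )
    dens["empty_calories_pct"] = empty_kcal / energy * 100.0
    return pd.DataFrame(dens, index=amounts.index)


def score_adequacy(density, standard: HEIComponentStandard):
    """Linear up to the full-score standard, capped at max_points."""
    density = np.asarray(density, dtype=float)
    if (density < 0).any():
        raise ValueError("densities must be nonnegative")
    return np.minimum(standard.max_points, standard.max_points * density / standard.full_threshold)


def score_moderation(density, standard: HEIComponentStandard):
    """max_points at/below the lower threshold, 0 at/above the upper,
    linear in between."""
    density = np.asarray(density, dtype=float)
    lo, hi = standard.full_threshold, standard.zero_threshold
    frac = np.clip((hi - density) / (hi - lo), 0.0, 1.0)
    return standard.max_points * frac


def score_ratio(value, standard: HEIComponentStandard):
    """Fatty-acid ratio: max at/above full_threshold, 0 at/below
    zero_threshold, linear in between (infinite ratio scores max)."""
    value = np.asarray(value, dtype=float)
    lo, hi = standard.zero_threshold, standard.full_threshold
    with np.errstate(invalid="ignore"):
        frac = np.clip((value - lo) / (hi - lo), 0.0, 1.0)
    frac = np.where(np.isposinf(value), 1.0, frac)
    return standard.max_points * frac


def score_components(densities: pd.DataFrame, standards: HEIStandards) -> pd.DataFrame:
    scorers = {"adequacy": score_adequacy, "moderation": score_moderation, "ratio": score_ratio}
    cols = {}
    for std in standards:
        cols[std.name] = scorers[std.kind](densities[std.numerator].to_numpy(), std)
    scores = pd.DataFrame(cols, index=densities.index)
    scores["total"] = scores.sum(axis=1)
    return scores


def hei_total(
    intakes: pd.DataFrame,
    composition: pd.DataFrame,
    standards: HEIStandards | None = None,
) -> pd.DataFrame:
    """HEI-2010 component and total scores, one row per subject.

    Zero-energy subjects are excluded (score undefined) with a log entry.
    """
    if standards is None:
        standards = HEIStandards.default()
    amounts = map_items_to_components(intakes, composition)
    excluded = zero_energy_subjects(amounts["energy_kcal"])
    if len(excluded):
        logger.info("excluding %d zero-energy subjects from HEI scoring", len(excluded))
        amounts = amounts.drop(index=excluded)
    return score_components(component_densities(amounts), standards)
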