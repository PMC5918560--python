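"""Synthetic twin-cohort generator.

Everything the pipeline consumes can be simulated here: a food
composition lookup table, FFQ responses driven by a latent diet-quality
trait with twin-pair correlation, health measures with known (planted)
standardized slopes on the realized HEI, and an OTU table with a random
phylogeny, technical covariates, and planted diet-microbe effects.
Planted effects make parameter-recovery and calibration tests possible
without any real data.

Design notes
------------
* One seeded generator per dataset; the same spec and seed reproduce the
  dataset bit for bit.
* Twin-pair correlation is a shared additive latent component; MZ pairs
  load on it with twice the DZ weight (a minimal ACE-like structure).
* Microbiota counts are multinomial draws at a log-uniform depth in
  [15k, 60k] from log-normal relative abundances, so the standard
  10,000-read rarefaction is always feasible.
* A planted effect on an OTU rewrites that OTU's per-sample latent noise
  as ``effect_size * z(exposure) + noise`` so the slope is standardized
  by construction; a planted effect on Shannon diversity sets a
  per-sample target entropy and solves for the softmax temperature that
  achieves it, so realized diversity tracks the exposure with the stated
  standardized slope.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import skbio
from scipy.optimize import brentq

from .ffq import COMPOSITION_COLUMNS, FFQDataset
from .diversity import OTUTable
from . import hei as _hei

#: per-category generation parameters; ranges are uniform draws per item.
#: 'loading' is the item's healthiness: how strongly the latent diet-quality
#: trait raises (positive) or lowers (negative) its consumption.
CATEGORY_PARAMS: dict[str, dict] = {
    "vegetables": dict(mds_group="vegetables", loading=0.8, energy=(25, 60),
                       portion=(60, 120), base_freq=(1.5, 5.0), hv=(0.75, 0.95),
                       equiv={"total_veg_cup_100g": (0.35, 0.5)},
                       fats=((0.0, 0.2), (0.0, 0.2), (0.0, 0.1)), sodium=(0.01, 0.05)),
    "leafy_greens": dict(mds_group="vegetables", loading=0.9, energy=(20, 40),
                         portion=(40, 90), base_freq=(0.8, 3.0), hv=(0.8, 1.0),
                         equiv={"total_veg_cup_100g": (0.3, 0.45),
                                "greens_beans_cup_100g": (0.3, 0.45)},
                         fats=((0.0, 0.2), (0.0, 0.2), (0.0, 0.1)), sodium=(0.01, 0.05)),
    "legumes": dict(mds_group="legumes", loading=0.7, energy=(80, 130),
                    portion=(60, 120), base_freq=(0.5, 2.5), hv=(0.75, 0.95),
                    equiv={"greens_beans_cup_100g": (0.2, 0.35),
                           "total_veg_cup_100g": (0.1, 0.2),
                           "total_protein_oz_100g": (0.6, 1.0),
                           "seafood_plant_oz_100g": (0.6, 1.0)},
                    fats=((0.1, 0.5), (0.1, 0.5), (0.0, 0.2)), sodium=(0.01, 0.3)),
    "fruit": dict(mds_group="fruit_nuts", loading=0.8, energy=(40, 80),
                  portion=(80, 150), base_freq=(1.5, 6.0), hv=(0.8, 1.0),
                  equiv={"total_fruit_cup_100g": (0.35, 0.55),
                         "whole_fruit_cup_100g": (0.3, 0.5)},
                  fats=((0.0, 0.1), (0.0, 0.1), (0.0, 0.05)), sodium=(0.0, 0.01)),
    "nuts": dict(mds_group="fruit_nuts", loading=0.5, energy=(550, 650),
                 portion=(20, 40), base_freq=(0.3, 2.0), hv=(0.6, 0.9),
                 equiv={"total_protein_oz_100g": (1.5, 2.2),
                        "seafood_plant_oz_100g": (1.5, 2.2)},
                 fats=((20, 35), (10, 20), (4, 8)), sodium=(0.0, 0.3)),
    "whole_grains": dict(mds_group="cereal", loading=0.7, energy=(300, 380),
                         portion=(30, 80), base_freq=(2.0, 7.0), hv=(0.7, 0.9),
                         equiv={"whole_grains_oz_100g": (2.5, 3.5)},
                         fats=((0.3, 1.5), (0.3, 1.5), (0.2, 0.8)), sodium=(0.0, 0.2)),
    "refined_grains": dict(mds_group="cereal", loading=-0.5, energy=(320, 400),
                           portion=(30, 90), base_freq=(2.0, 8.0), hv=(0.2, 0.45),
                           equiv={"refined_grains_oz_100g": (2.5, 3.5)},
                           fats=((0.5, 2.0), (0.3, 1.5), (0.5, 2.5)),
                           sodium=(0.3, 0.6), added_sugar=(20, 80)),
    "fish": dict(mds_group="fish", loading=0.6, energy=(100, 200),
                 portion=(80, 150), base_freq=(0.3, 2.5), hv=(0.7, 0.95),
                 equiv={"total_protein_oz_100g": (2.5, 3.5),
                        "seafood_plant_oz_100g": (2.5, 3.5)},
                 fats=((2, 6), (2, 6), (1, 3)), sodium=(0.1, 0.4)),
    "meat": dict(mds_group="meat", loading=-0.6, energy=(200, 320),
                 portion=(80, 160), base_freq=(1.0, 5.0), hv=(0.15, 0.4),
                 equiv={"total_protein_oz_100g": (2.0, 3.0)},
                 fats=((3, 7), (0.5, 2), (4, 9)), sodium=(0.3, 0.8),
                 solid_fat=(60, 140)),
    "dairy": dict(mds_group="dairy", loading=-0.2, energy=(60, 350),
                  portion=(100, 250), base_freq=(2.0, 10.0), hv=(0.35, 0.6),
                  equiv={"dairy_cup_100g": (0.3, 0.45)},
                  fats=((1, 4), (0.1, 0.5), (2, 8)), sodium=(0.1, 0.5),
                  solid_fat=(20, 100)),
    "oils": dict(mds_group="fats", loading=0.2, energy=(800, 900),
                 portion=(5, 15), base_freq=(3.0, 12.0), hv=(0.4, 0.7),
                 equiv={}, fats=((30, 60), (15, 45), (8, 15)), sodium=(0.0, 0.1)),
    "sweets": dict(mds_group="fats", loading=-0.9, energy=(400, 550),
                   portion=(30, 80), base_freq=(1.0, 8.0), hv=(0.05, 0.25),
                   equiv={}, fats=((3, 8), (1, 3), (5, 15)), sodium=(0.2, 0.5),
                   solid_fat=(80, 180), added_sugar=(150, 250)),
    "alcohol": dict(mds_group="alcohol", loading=-0.1, energy=(40, 250),
                    portion=(150, 330), base_freq=(0.5, 8.0), hv=(0.1, 0.3),
                    equiv={}, fats=((0.0, 0.0), (0.0, 0.0), (0.0, 0.0)),
                    sodium=(0.0, 0.02), alcohol=(3, 12)),
}

CATEGORIES = list(CATEGORY_PARAMS)
MIN_ITEMS = 20


@dataclass(frozen=True)
class CohortSpec:
    """Conditions under which a synthetic cohort is generated."""

    n_subjects: int
    n_items: int = 152
    twin_pair_fraction: float = 0.8
    mz_fraction: float = 0.57
    n_batches: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_items < MIN_ITEMS:
            raise ValueError(
                f"need at least {MIN_ITEMS} items to populate all food groups, "
                f"got {self.n_items}"
            )
        for name in ("twin_pair_fraction", "mz_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_subjects < 1 or self.n_batches < 1:
            raise ValueError("n_subjects and n_batches must be positive")


@dataclass(frozen=True)
class PlantedEffect:
    """A known diet-microbiota effect injected into the generator.

    ``target`` is an OTU id or the alpha metric name ``'shannon'``;
    ``exposure`` names a metadata column (typically an index score);
    ``effect_size`` is the standardized slope.  When ``noise_sd`` is
    None it defaults to ``sqrt(1 - effect_size**2)`` so the planted
    standardized slope equals ``effect_size`` exactly.
    """

    target: str
    exposure: str
    effect_size: float
    noise_sd: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.effect_size):
            raise ValueError("effect_size must be finite")
        if self.noise_sd is not None and self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    def latent(self, z_exposure: np.ndarray, eps: np.ndarray) -> np.ndarray:
        nsd = self.noise_sd
        if nsd is None:
            nsd = float(np.sqrt(max(0.0, 1.0 - self.effect_size**2)))
        return self.effect_size * z_exposure + nsd * eps


def _uniform(rng, lo_hi, size):
    lo, hi = lo_hi
    return rng.uniform(lo, hi, size)


def generate_composition_table(spec: CohortSpec) -> pd.DataFrame:
    """A CoFids-style per-100 g composition and annotation table.

    Items cycle through the food categories so every MDS group is
    populated; per-item numbers are drawn from category-typical ranges.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    items = [f"item_{i:03d}" for i in range(spec.n_items)]
    cats = [CATEGORIES[i % len(CATEGORIES)] for i in range(spec.n_items)]
    table = pd.DataFrame(0.0, index=pd.Index(items, name="item"),
                         columns=[c for c in COMPOSITION_COLUMNS if c not in ("category", "mds_group")])
    table.insert(0, "category", cats)
    table.insert(1, "mds_group", [CATEGORY_PARAMS[c]["mds_group"] for c in cats])
    for cat in CATEGORIES:
        mask = table["category"] == cat
        n = int(mask.sum())
        if n == 0:
            continue
        p = CATEGORY_PARAMS[cat]
        table.loc[mask, "energy_kcal_100g"] = _uniform(rng, p["energy"], n)
        table.loc[mask, "portion_g"] = _uniform(rng, p["portion"], n)
        mufa, pufa, sfa = p["fats"]
        table.loc[mask, "mufa_g_100g"] = _uniform(rng, mufa, n)
        table.loc[mask, "pufa_g_100g"] = _uniform(rng, pufa, n)
        table.loc[mask, "sfa_g_100g"] = _uniform(rng, sfa, n)
        table.loc[mask, "sodium_g_100g"] = _uniform(rng, p["sodium"], n)
        table.loc[mask, "health_value"] = _uniform(rng, p["hv"], n)
        for col, rng_pair in p["equiv"].items():
            table.loc[mask, col] = _uniform(rng, rng_pair, n)
        if "alcohol" in p:
            table.loc[mask, "alcohol_g_100g"] = _uniform(rng, p["alcohol"], n)
        if "solid_fat" in p:
            table.loc[mask, "solid_fat_kcal_100g"] = _uniform(rng, p["solid_fat"], n)
        if "added_sugar" in p:
            table.loc[mask, "added_sugar_kcal_100g"] = _uniform(rng, p["added_sugar"], n)
    return table


def generate_ffq_cohort(
    spec: CohortSpec,
    composition: pd.DataFrame,
    bmi_slope: float = -0.08,
    frailty_slope: float = -0.12,
    female_fraction: float = 0.9,
) -> FFQDataset:
    """FFQ frequencies plus metadata for a synthetic twin cohort.

    A latent diet-quality trait (twin-correlated, slightly higher in
    women and non-smokers) drives item frequencies through the category
    healthiness loadings, so healthy eaters score higher on the HEI by
    construction.  BMI and the frailty index are then generated with the
    stated *standardized* slopes on the realized HEI score, giving the
    validation stage known truths to recover.
    """
    if not composition.index.size >= spec.n_items:
        raise ValueError("composition table does not cover spec.n_items")
    composition = composition.iloc[: spec.n_items]
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    n = spec.n_subjects
    subjects = pd.Index([f"S{i:05d}" for i in range(n)], name="subject")

    # --- twin structure -------------------------------------------------
    n_paired = int(round(n * spec.twin_pair_fraction / 2)) * 2
    pair_of = np.full(n, -1)
    pair_of[:n_paired] = np.repeat(np.arange(n_paired // 2), 2)
    n_pairs = n_paired // 2
    pair_is_mz = rng.random(n_pairs) < spec.mz_fraction
    zygosity = np.where(rng.random(n) < spec.mz_fraction, "MZ", "DZ")
    for p in range(n_pairs):
        zygosity[pair_of == p] = "MZ" if pair_is_mz[p] else "DZ"

    # --- latent diet quality -------------------------------------------
    shared = rng.standard_normal(max(n_pairs, 1))
    unique = rng.standard_normal(n)
    w = np.where(zygosity == "MZ", 0.8, 0.4)  # MZ share 2x the DZ weight
    quality = np.where(
        pair_of >= 0,
        w * shared[np.clip(pair_of, 0, None)] + np.sqrt(1 - w**2) * unique,
        unique,
    )

    # --- demographics (twins share age and sex) -------------------------
    age = np.clip(rng.normal(58.4, 13.2, n), 18, 95)
    is_female = rng.random(n) < female_fraction
    for p in range(n_pairs):
        members = np.flatnonzero(pair_of == p)
        age[members] = age[members[0]]
        is_female[members] = is_female[members[0]]
    sex = np.where(is_female, "F", "M")

    quality = quality + 0.25 * (is_female - is_female.mean())
    quality = quality + 0.08 * (age - age.mean()) / age.std()
    smoker = rng.random(n) < 1 / (1 + np.exp(2.1 + 0.7 * quality))
    quality = quality - 0.3 * smoker

    batch = np.array([f"batch{1 + b}" for b in rng.integers(0, spec.n_batches, n)])

    # --- item frequencies ----------------------------------------------
    cats = composition["category"].to_numpy()
    loading = np.array([CATEGORY_PARAMS[c]["loading"] for c in cats])
    base_mid = np.array(
        [np.log(np.mean(CATEGORY_PARAMS[c]["base_freq"])) for c in cats]
    )
    # only a minority of the 152 items is habitually consumed, and item
    # frequencies are modest, so daily energy lands near 2000 kcal
    base = base_mid - np.log(2.5) + rng.normal(0, 0.3, spec.n_items)
    logf = (
        base[None, :]
        + 0.5 * loading[None, :] * quality[:, None]
        + 0.6 * rng.standard_normal((n, spec.n_items))
    )
    consume_p = 1 / (1 + np.exp(-(-0.4 + 0.5 * loading[None, :] * quality[:, None])))
    consumed = rng.random((n, spec.n_items)) < consume_p
    freq = np.where(consumed, np.minimum(np.exp(logf), 21.0), 0.0)
    frequencies = pd.DataFrame(freq, index=subjects, columns=composition.index)

    # --- health measures planted on the realized HEI --------------------
    intakes = frequencies.mul(composition["portion_g"], axis=1) / 7.0
    hei_scores = _hei.hei_total(intakes, composition)["total"]
    z_hei = (hei_scores - hei_scores.mean()) / hei_scores.std(ddof=1)
    z_hei = z_hei.reindex(subjects).fillna(0.0).to_numpy()
    bmi = 26.2 + 5.0 * (
        bmi_slope * z_hei
        + np.sqrt(max(0.0, 1 - bmi_slope**2)) * rng.standard_normal(n)
    )
    bmi = np.clip(bmi, 15, 55)
    frailty = np.clip(
        0.2 + 0.1 * (
            frailty_slope * z_hei
            + np.sqrt(max(0.0, 1 - frailty_slope**2)) * rng.standard_normal(n)
        ),
        0.0, 1.0,
    )

    metadata = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "smoker": smoker,
            "bmi": bmi,
            "frailty": frailty,
            "zygosity": zygosity,
            "pair_id": [f"P{p:04d}" if p >= 0 else np.nan for p in pair_of],
            "batch": batch,
            "quality": quality,
            "seed": spec.seed,
        },
        index=subjects,
    )
    return FFQDataset(frequencies, composition["portion_g"], metadata)


# ---------------------------------------------------------------- microbiota

def _softmax_rows(logp: np.ndarray) -> np.ndarray:
    x = logp - logp.max(axis=-1, keepdims=True)
    e = np.exp(x)
    return e / e.sum(axis=-1, keepdims=True)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _solve_temperature(logp: np.ndarray, target_h: float) -> float:
    """Softmax temperature achieving the target Shannon entropy."""
    def f(tau):
        return _entropy(_softmax_rows(logp / tau)) - target_h

    lo, hi = 0.05, 50.0
    if f(lo) > 0:
        return lo
    if f(hi) < 0:
        return hi
    return brentq(f, lo, hi, xtol=1e-4)


def _random_tree_newick(labels: list[str], rng: np.random.Generator) -> str:
    """Random rooted bifurcating tree with exponential branch lengths."""
    nodes = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        la, lb = rng.exponential(0.2, 2) + 0.01
        nodes.append(f"({a}:{la:.6f},{b}:{lb:.6f})")
    return nodes[0] + ";"


def _taxonomy(otu_ids: list[str], rng: np.random.Generator) -> pd.Series:
    k = len(otu_ids)
    n_gen = max(5, k // 5)
    n_fam = max(3, k // 12)
    n_phy = 4
    fam_of_gen = rng.integers(0, n_fam, n_gen)
    phy_of_fam = rng.integers(0, n_phy, n_fam)
    gen = rng.integers(0, n_gen, k)
    labels = []
    for g in gen:
        f = fam_of_gen[g]
        p = phy_of_fam[f]
        genus = f"Genus{g:03d}" if rng.random() > 0.05 else ""  # some unassigned
        labels.append(
            f"k__Bacteria; p__Phylum{p}; c__Class{p}; o__Order{f % 6}; "
            f"f__Family{f:02d}; g__{genus}"
        )
    return pd.Series(labels, index=otu_ids, name="taxonomy")


def generate_microbiota(
    metadata: pd.DataFrame,
    effects: tuple[PlantedEffect, ...] | list[PlantedEffect] = (),
    n_otus: int = 150,
    seed: int = 0,
    depth_range: tuple[int, int] = (15_000, 60_000),
    base_entropy: float | None = None,
    entropy_sd: float = 0.35,
) -> OTUTable:
    """OTU counts, taxonomy, and a random phylogeny for the cohort.

    Counts come from an overdispersed log-normal -> multinomial model.
    Technical covariates (sequencing run, DNA extractor, DNA loader,
    collection method) and the FFQ batch get small planted offsets so the
    residualization and random-effect machinery has real structure to
    remove.  See :class:`PlantedEffect` for how diet effects are planted.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    n = len(metadata)
    samples = metadata.index
    otu_ids = [f"otu_{k:04d}" for k in range(n_otus)]

    for eff in effects:
        if eff.target != "shannon" and eff.target not in otu_ids:
            raise KeyError(f"planted effect targets unknown OTU/metric {eff.target!r}")
        if eff.exposure not in metadata.columns:
            raise KeyError(f"planted effect exposure {eff.exposure!r} not in metadata")

    def z(col: str) -> np.ndarray:
        v = metadata[col].to_numpy(dtype=float)
        return (v - v.mean()) / v.std(ddof=1)

    # OTU ids follow the rank-abundance curve: otu_0000 is the most
    # abundant on average.  This keeps planted-effect targets at a
    # predictable community share.
    mu = np.sort(rng.normal(0.0, 2.0, n_otus))[::-1]
    sigma = rng.uniform(0.4, 1.2, n_otus)
    eps = rng.standard_normal((n, n_otus))
    for eff in effects:
        if eff.target == "shannon":
            continue
        k = otu_ids.index(eff.target)
        eps[:, k] = eff.latent(z(eff.exposure), rng.standard_normal(n))

    # technical covariates with small per-OTU offsets
    tech = pd.DataFrame(
        {
            "run": rng.choice([f"R{i}" for i in range(1, 5)], n),
            "extractor": rng.choice(["E1", "E2", "E3"], n),
            "loader": rng.choice(["L1", "L2", "L3"], n),
            "collection": rng.choice(["clinic", "post"], n),
        },
        index=samples,
    )
    logab = mu[None, :] + sigma[None, :] * eps
    covs = tech.copy()
    if "batch" in metadata.columns:
        covs["batch"] = metadata["batch"]
    for name in covs.columns:
        levels, codes = np.unique(covs[name].to_numpy(), return_inverse=True)
        offsets = rng.normal(0.0, 0.08, (len(levels), n_otus))
        logab = logab + offsets[codes]

    shannon_effects = [e for e in effects if e.target == "shannon"]
    if shannon_effects:
        eff = shannon_effects[0]
        h0 = base_entropy if base_entropy is not None else 0.65 * np.log(n_otus)
        target = h0 + entropy_sd * eff.latent(z(eff.exposure), rng.standard_normal(n))
        target = np.clip(target, 0.15, 0.97 * np.log(n_otus))
        probs = np.empty_like(logab)
        for i in range(n):
            tau = _solve_temperature(logab[i], target[i])
            probs[i] = _softmax_rows(logab[i] / tau)
    else:
        probs = _softmax_rows(logab)

    lo, hi = depth_range
    depths = np.exp(rng.uniform(np.log(lo), np.log(hi), n)).astype(int)
    counts = np.empty((n, n_otus), dtype=np.int64)
    for i in range(n):
        counts[i] = rng.multinomial(depths[i], probs[i])

    tree = skbio.TreeNode.read(
        io.StringIO(_random_tree_newick(otu_ids, rng)), convert_underscores=False
    )
    sample_data = tech
    sample_data["depth"] = counts.sum(axis=1)
    return OTUTable(
        counts=pd.DataFrame(counts, index=samples, columns=otu_ids),
        taxonomy=_taxonomy(otu_ids, rng),
        tree=tree,
        sample_data=sample_data,
    )


# -------------------------------------------------------------------- I/O

def write_dataset(
    out_dir,
    ffq: FFQDataset,
    composition: pd.DataFrame,
    otu_table: OTUTable | None = None,
) -> None:
    """Write the synthetic dataset as plain-text TSV / Newick files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ffq.frequencies.to_csv(out / "ffq.tsv", sep="\t")
    composition.to_csv(out / "composition.tsv", sep="\t")
    ffq.metadata.to_csv(out / "metadata.tsv", sep="\t")
    if otu_table is not None:
        otu_table.counts.to_csv(out / "otu_counts.tsv", sep="\t")
        otu_table.sample_data.to_csv(out / "otu_sample_data.tsv", sep="\t")
        otu_table.taxonomy.to_csv(out / "taxonomy.tsv", sep="\t")
        otu_table.tree.write(str(out / "tree.nwk"))
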