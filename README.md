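# dietindex

Dietary-index scoring and gut-microbiota association analysis for
food-frequency-questionnaire (FFQ) cohorts.

Habitual diet is one of the strongest environmental drivers of gut
microbiota composition, but dietary data are high-dimensional and
internally correlated. Dietary indices compress an FFQ into a single
diet-quality covariate. This package implements three such indices and
the full downstream pipeline needed to ask *which index captures the
most microbiota variation* — validation against health measures,
rarefied alpha diversity, UniFrac/PCoA beta diversity, OTU-level
mixed-effects associations with FDR control, and twin-discordance
paired tests — plus a synthetic twin-cohort generator so every stage is
testable without access to any private cohort data.

## The three indices

**Healthy Eating Index 2010 (HEI).** Twelve energy-density components,
`total = Σ_c points_c ∈ [0, 100]`. Adequacy components score
`min(max_c, max_c · d / t_c)` where `d` is the intake density per
1000 kcal and `t_c` the full-score standard; moderation components score
`max_c` below a lower threshold, 0 above an upper threshold, linear in
between. Component standards ship as an editable YAML file
(`dietindex/data/hei2010.yaml`).

**Modified Mediterranean Diet Score (MDS).** One point per component for
being on the healthy side of the study-population median of residual
energy-adjusted group intake (strictly above for vegetables, legumes,
fruit+nuts, cereal, fish, and the (MUFA+PUFA)/SFA ratio; strictly below
for meat and dairy), plus one point for ethanol inside a moderate,
sex-specific window — 9 components, integer total. Medians are computed
within FFQ batch.

**Healthy Food Diversity index (HFD).** With food shares
`s_i = g_i / Σ g`, health values `hv_i ∈ (0, 1]`, the score is
`HFD = (Σ hv_i s_i) · (1 − Σ s_i²)` — a health-value-weighted
Berry/Simpson diversity in `[0, 1 − 1/n_items)`.

Energy adjustment uses the residual method: the residual of an intake
regressed on total energy, re-centred at the sample mean.

## Worked example

```python
from dietindex import (CohortSpec, generate_composition_table,
                       generate_ffq_cohort, to_daily_grams,
                       hei_total, mds_total, hfd_total)

spec = CohortSpec(n_subjects=300, seed=1)
composition = generate_composition_table(spec)
cohort = generate_ffq_cohort(spec, composition)
intakes = to_daily_grams(cohort)

hei = hei_total(intakes, composition)
mds = mds_total(intakes, composition, cohort.metadata)
hfd = hfd_total(intakes, composition)
print(f"HEI  {hei['total'].mean():.1f} ± {hei['total'].std():.1f}")
print(f"MDS  {mds['total'].mean():.2f} ± {mds['total'].std():.2f}")
print(f"HFD  {hfd['hfd'].mean():.3f} ± {hfd['hfd'].std():.3f}")
```

prints

```
HEI  61.3 ± 14.8
MDS  4.64 ± 2.35
HFD  0.495 ± 0.095
```

i.e. a mean HEI of about 61 of 100 points with a ~15-point spread, a
mean MDS near the midpoint of its 0–9 range, and HFD values around 0.5 —
the synthetic cohort's healthy eaters score higher on all three by
construction. The same objects feed the microbiota stage:

```python
from dietindex import PlantedEffect, generate_microbiota, rarefy_alpha
from dietindex.association import mixed_assoc

meta = cohort.metadata.assign(hei=hei["total"])
table = generate_microbiota(meta, effects=[PlantedEffect("shannon", "hei", 0.3)],
                            n_otus=150, seed=1)
alpha = rarefy_alpha(table, depth=10_000, reps=50, seed=1)
result = mixed_assoc(alpha["shannon"], meta["hei"], meta.join(table.sample_data),
                     fixed=("age", "bmi", "sex", "zygosity", "depth"),
                     random=("run", "extractor", "loader", "collection", "batch"))
print(f"standardized beta = {result.beta:.3f} (p = {result.p:.3g})")
```

prints `standardized beta = 0.285 (p = 3.09e-07)`, recovering the
planted standardized index→Shannon slope of 0.3.

A `dietindex` console script exposes the same pipeline from the shell:
`dietindex simulate`, `dietindex score hei|mds|hfd`,
`dietindex validate`, `dietindex associate`.

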