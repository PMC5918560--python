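# Methods

## Scope and data model

The package operates on four tabular inputs: an FFQ response table
(subjects × items, weekly consumption frequencies), a food-composition
lookup table (per-100 g energy, fatty acids, sodium, alcohol,
solid-fat/added-sugar energy, HEI component equivalences, an MDS group
label, and an HFD health value per item), per-subject metadata (age,
sex, zygosity, twin-pair id, BMI, smoking, frailty index, FFQ batch),
and an OTU table with taxonomy, a Newick phylogeny and technical
covariates. Subjects with incomplete FFQ responses are dropped (with a
logged count) — partial questionnaires cannot be scored consistently.

Weekly frequencies convert to daily grams as `freq × portion / 7`.
The divisor 7 and the sourcing of portion sizes from the composition
table are package conventions; real deployments must supply their own
portion and item→component mapping tables in the same schema.
Energy is tracked in kcal throughout (the HEI standards are defined per
1000 kcal); alcohol contributes 7 kcal/g where energy from ethanol is
needed.

## Index construction

**HEI-2010.** Items map to component numerators through their per-100 g
annotations, so one item can contribute to several components (e.g. a
meat item contributes lean protein oz-equivalents *and* solid-fat
energy). Densities are per 1000 kcal, except the fatty-acid ratio
(MUFA+PUFA)/SFA and empty calories (% of energy from solid fats, added
sugars, and alcohol). Scoring is piecewise linear; the twelve default
standards (shipped in `data/hei2010.yaml`, points summing to 100) can
be replaced wholesale by a user YAML. Numerical conventions: with
SFA = 0 the ratio component scores its maximum when any unsaturated fat
is present and 0 otherwise; zero-energy subjects are excluded from
scoring with a log entry, since densities are undefined.

**Modified MDS.** The seven food groups are summed from items by their
`mds_group` label and residual energy-adjusted; adjusted intakes are
clipped at zero (a residual can otherwise be negative, which has no
meaning as an amount). The adjustment is fitted *within FFQ batch* by
default (`MDSConfig.adjust_scope = "batch"`, with `"pooled"`
available), mirroring the batch-wise medians: batches collected years
apart with different instruments should not be compared against a
pooled centre. Ties at the median score 0 — the split is strictly
above/strictly below — and the component roster is 9 (7 median-split
groups + lipid ratio + alcohol window). The lipid ratio is scale-free
and therefore not energy-adjusted. The alcohol window defaults to
5–25 g/day for women and 10–50 g/day for men, editable via
`MDSConfig`. `MDSConfig.extra_beneficial` is the extension point for a
10-component roster.

**HFD.** Shares are computed on grams/day with no energy adjustment
(deliberate: the index is defined on consumed amounts), zero-intake
items contribute nothing, and the score is bounded by
`1 − 1/n_items`, approached by equal shares of maximally healthy foods.

## Validation stage

Concurrent criterion contrasts (men vs women, over/under an age
threshold, smokers vs non-smokers) use two-sample t tests for the
approximately normal HEI and MDS and the Wilcoxon rank-sum for the
skewed HFD. The age threshold defaults to 60 and is a parameter —
conventions differ between 50 and 60 in the validation literature.
Health regressions fit `outcome ~ index + age + sex + zygosity` by OLS
with every variable z-scored (binary variables are coded 0/1 then
z-scored), so the index coefficient is a standardized beta; the nested
p-value is the F test of the full model against covariates-only. Twin
pairs are treated as independent observations here, as is conventional
for these validation models; a pair-clustered-variance option would be
the natural extension.

## Microbiota stage

**Alpha diversity.** Samples are rarefied to 10,000 reads 50 times
(both parameters exposed); samples below depth are dropped, not
resampled. Four metrics are computed per rarefaction replicate and
averaged: observed OTUs, bias-corrected Chao1
`S_obs + F1(F1−1)/(2(F2+1))` (the bias-corrected form avoids division
by zero at F2 = 0), Shannon entropy in natural log (a `base` switch is
provided; log-base conventions vary between toolchains), and Simpson
diversity `1 − Σ p²`. The metric kernels are vectorised over
replicate-by-OTU matrices for cohort-scale speed; the test suite
cross-checks them against scikit-bio's implementations.

**Beta diversity.** Unweighted UniFrac feeds PCoA (first 10 axes
extracted; axes with negative eigenvalues are reported but excluded;
each axis's sign is fixed so its largest-magnitude coordinate is
positive, making downstream regressions deterministic). Weighted,
normalized UniFrac distances between co-twins feed the pair-distance
regressions. Both come from scikit-bio.

**Associations.** Every model z-scores the outcome, the index, and the
continuous covariates, so reported coefficients are standardized.
Alpha-diversity and PCoA-axis models are linear mixed models with fixed
effects age, BMI, sex, zygosity and sequencing depth, and crossed
random intercepts for run, extractor, loader, collection method and
FFQ batch. OTU and taxon models act on residuals: relative abundances
present in strictly more than 25% of samples are log10-transformed
(zeros replaced by half the smallest nonzero relative abundance in the
table) and residualized against the technical covariates by per-OTU
OLS; the mixed model then uses fixed effects age, zygosity, BMI, sex
with FFQ batch as the random intercept. All mixed models are fitted by
maximum likelihood so the nested likelihood-ratio comparison
(with/without the index) is valid; a singular or non-converged
random-effect fit falls back to a fixed-intercept OLS model, flagged in
the result. FDR control uses Storey q-values with the smoother pi0
estimate (cubic polynomial over a lambda grid of 0.05–0.95, read off at
0.95); when pi0 estimation fails, or with fewer than 30 p-values where
the smoother is unstable, the Benjamini–Hochberg procedure (pi0 = 1) is
used and flagged.

**Twin discordance.** A pair is discordant for an index when the score
difference exceeds one SD *and* the twins fall in different quartiles —
a strict conjunction. The SD is taken over the scored (microbiota)
subset and quartiles are nearest-rank. Per-OTU paired Wilcoxon
signed-rank tests compare healthy-twin minus less-healthy-twin
residuals, with FDR across OTUs; fewer than six usable pairs leaves the
p-values undefined (flagged) rather than fabricating an asymptotic
approximation.

## The synthetic generator

The generator emulates a UK adult twin-registry cohort: 152 EPIC-style food items
cycling through 13 food categories (so every MDS group is populated), a
latent diet-quality trait with a shared twin component (MZ pairs load
on it with twice the DZ weight — a minimal ACE-like structure;
heritability estimation is out of scope), item frequencies that rise or
fall with the trait according to category healthiness loadings, and
demographics matched to that cohort's profile (90% female, age
58 ± 13, ~10% current smokers with lower diet quality). BMI and the
frailty index are generated with known *standardized* slopes on the
realized HEI score (defaults −0.08 and −0.12), which is what makes
parameter-recovery tests of the validation stage possible.

Microbiota counts are multinomial draws at a log-uniform depth in
[15k, 60k] (so 10,000-read rarefaction is always feasible) from
log-normal relative abundances; OTU ids follow the rank-abundance curve
(otu_0000 is most abundant on average), which lets tests plant effects
at a predictable community share. A planted OTU effect rewrites that
OTU's latent noise as `effect × z(exposure) + sqrt(1−effect²) × ε`, so
the slope is standardized by construction. A planted Shannon effect
sets a per-sample target entropy `H0 + sd_H (effect·z + noise)` and
solves for the softmax temperature achieving it (Brent's method on the
monotone entropy-temperature map), so realized diversity tracks the
exposure at the stated standardized slope with only the small
attenuation of multinomial sampling. Technical covariates and batch
receive small per-level offsets (sd 0.08 on the log scale) so the
residualization and random-effect machinery has real structure to
remove. One seeded generator drives each dataset; identical spec and
seed reproduce it bit for bit.

What the generator does **not** emulate: food co-consumption
covariance, longitudinal diet, categorical FFQ response scales,
strain-level realism, phylogenetic signal in abundances (the tree is
random), and zero-inflation beyond what multinomial sampling induces.
Passing recovery tests therefore demonstrate that the pipeline's
estimators are unbiased and calibrated under the stated generative
model — not that real-data effect sizes will match.

## Test problem sizes

Recovery and calibration tests run at the conditions they probe:
n = 2000 subjects and 20 seeds for the planted Shannon slope of 0.1 and
the five planted OTU effects of 0.3; 200 permutations for the null
calibration of the mixed models; 200 repetitions of 500 null + 20
signal tests for FDR calibration. Two knobs are scaled for desk-scale
runtimes and documented here: the recovery tests rarefy with 5
replicates (the default pipeline uses 50; replicate count only shrinks
rarefaction noise, which is already far below the planted signal), and
the OTU battery in the pipeline test uses 200 OTUs. The
diversity-effect and OTU-effect recoveries use separate planted tables
because an evenness effect necessarily moves *every* relative abundance
with the exposure, which would make OTU-level false-discovery
accounting meaningless.

## Known limitations

* The item→component mapping, portion sizes, and HFD health values are
  synthetic stand-ins; scoring real cohorts requires the corresponding
  real lookup tables in the same schema.
* Storey's pi0 smoother is anti-conservative for small test families;
  the automatic BH fallback below 30 tests is a blunt guard, and
  realized false-discovery proportions in few-signal regimes are lumpy.
* Mixed models treat crossed random intercepts via variance components
  with a single trivial group; with many levels per factor this is
  slower than specialised sparse solvers.
* The twin-pair distance regression conditions on complete pairs and
  drops singletons silently (with a logged count).
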