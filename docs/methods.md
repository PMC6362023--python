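# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the limits of what the test suite demonstrates.

## Covariate adjustment

Per gene, expression is regressed by OLS on RIN, ethnicity (treatment-coded
dummies, most frequent level as reference) and sex; the adjusted value is
residual + fitted intercept. All covariate columns are mean-centred before
fitting, so the fitted intercept equals the gene's mean and the adjusted
values are invariant both to adding a constant to a covariate and to the
dummy reference choice. Collinear design columns are dropped greedily
left-to-right with a logged warning (scale-invariant rank test on
column-normalised designs). Adjustment is fitted jointly over all retained
samples, not per region: the downstream scoring model carries its own
region term. Re-adjusting an adjusted matrix changes values by < 1e−8
(idempotence), which the suite checks.

## Relative expression score

For gene g, stage s and a region group, OLS of adjusted expression on
`intercept + region dummies + 1{stage = s}` defines
`score = R² × sgn(β̂_s)` with plain (unadjusted) R². Conventions:

- zero within-group variance (< 1e−12 sum of squares) → score 0, including
  sgn(0) → 0 for a vanishing stage coefficient;
- a stage absent from the group's samples, or comprising all of them
  (indicator confounded with the intercept), yields a missing value, which
  propagates as a dropped row into downstream regressions — never imputed
  as zero;
- region dummies are included even for single-region groups, where they
  reduce to the intercept;
- genes unexpressed within a group are retained under the zero-variance →
  0 rule rather than dropped.

The vectorised scoring path (one `lstsq` per stage against all genes) is
tested to 1e−10 against an independent normal-equations oracle on ≤ 12
samples. Scores are invariant under positive affine transforms of a gene's
expression and flip sign under negation.

**The score is zero-sum across stages.** A gene relatively high at one
stage is mechanically relatively low at the others: a mean shift δ at stage
s induces a coefficient ≈ −δ·n_s/(n−n_t) at every other stage t. Any
association signal tied to stage-s expression therefore *mirrors*, with
opposite sign and roughly 1/12 the magnitude (13 stages), into all other
stages. This is a property of the statistic, not an artefact — the real
analysis shows exactly this prenatal-positive/childhood-negative mirror —
and it bounds how hard effects can be planted before non-planted stages
start flagging (see generator calibration below).

### Tiers

Tier 1 pools every region ("whole brain"), Bonferroni m = number of stages
(13 by default). Tier 2 runs the three region groups separately,
m = stages × groups (39). Adjusted p = min(1, p·m).

## Gene-level association

SNP filters: MAF ≥ 0.01, INFO ≥ 0.6 (each skippable when the column is
absent), exclusion of configured intervals (default xMHC,
chr6:25,000,000–34,000,000 — the region is conventional, the coordinates
are an editable default) and chromosomes (default X). Mapping: protein-
coding genes only; a + strand gene [s, e] captures SNP positions in
[s − 35000, e + 10000], mirrored for − strand; a SNP may map to several
genes.

The SNP-wise mean statistic is `T = Σ_i F⁻¹_{χ²₁}(1 − p_i)` (p-values
floored at a configurable 1e−300 with a warning). Its null for SNP
z-scores with correlation **R** is `Σ_j λ_j χ²₁` over the eigenvalues λ of
**R** (eigenvalues ≤ 1e−12 are discarded, so perfect LD collapses exactly
to a single SNP). Three evaluations are provided:

- **exact** (default): Ruben's representation of a positive-weight
  quadratic form as a mixture of central chi-squares,
  `Q ~ β·χ²_{k+2J}` with β = λ_min and mixing weights from Ruben's
  recursion, truncated when the geometric bound on the remaining mass falls
  below 1e−16 (cap 50,000 terms). Every term is positive, so the survival
  function has no cancellation at any tail depth and vectorises over T.
  Batch evaluation groups genes by eigenvalue multiset (rounded to 8
  decimals) and caches the coefficients.
- **brown**: the Satterthwaite/Brown two-moment scaled chi-square,
  c = Var/2E, f = 2E²/Var with E = k, Var = 2·ΣᵢⱼRᵢⱼ². Kept as a fast
  approximation; its mid-range error reaches a few hundredths and its deep
  tail is only order-of-magnitude correct, which the suite documents.
- **mc**: Monte-Carlo draws of the quadratic form with the (count+1)/(N+1)
  estimator — the independent oracle used in tests.

An Imhof characteristic-function inversion (`assoc._imhof_sf`, adaptive
quadrature) is kept as a second independent route and cross-checked against
the Ruben series; it is not used in the pipeline because adaptive
quadrature is slow and its absolute-tolerance floor makes deep-tail values
meaningless.

Gene Z = Φ⁻¹(1 − p): larger association ⇒ larger Z, so downstream
regression coefficients are signed the intuitive way. Covariates per gene:
window-extended size in bp (end − start + 1 + 45 kb), SNP density = k/size,
and natural-log copies of both; the property regression uses all four by
default. When a mapped SNP lacks LD information it is treated as
uncorrelated with the rest (identity fill), and user-supplied per-gene LD
matrices are validated (symmetric, unit diagonal, PSD).

## Gene-property regression

OLS of Z on [intercept, score, size, density, log size, log density,
conditioned scores…] over the intersection of scored and associated genes
(incomplete rows dropped and logged; ≥ 10 genes required; constant score →
"degenerate property" error). Two-tailed p from the t distribution with
residual degrees of freedom. Conditioning a stage on itself duplicates the
score column; the duplicate is dropped and the result flagged. Conditional
analyses report uncorrected p. The signed −log₁₀(p) column mirrors the
bar/point figure convention.

## Decile and pathway analysis

Deciles: rank ascending by score, ties broken by gene id, sizes by
largest-remainder allocation (first n mod 10 bins get the extra gene) —
a pure function of the sorted (score, id) sequence. Competitive test per
decile: OLS of Z on [intercept, membership, covariates], two-tailed,
adjusted ×10. Significant deciles merge only when they share the direction
of the most significant one (the mixed-direction case never arises in the
motivating data, where only top deciles fire).

Fisher term scan: per term, the 2×2 in-set/in-term table on the expressed-
gene background, one-sided "greater" by default (configurable
`fisher_alternative`), Bonferroni over the testable terms of each source
(GO and MP separately); terms without background overlap are skipped with
a notice. Evidence codes IEA, NAS, RCA are excluded before any scan.

Step-wise refinement processes significant terms smallest-first (ties by
term id). At each step, every surviving term with *weaker* original
enrichment (larger original p, ties by id) is re-tested on a universe from
which the genes of all already-processed *other* terms are removed; a
re-test p above the uncorrected 0.05 threshold (configurable) drops the
term. Removal is cumulative-except-self: shared genes are removed (two
identical terms reduce the later one to an empty table, which drops it),
but a term is never blanked by its own earlier removal — pure cumulative
removal would drop fully disjoint significant terms, which is clearly not
the intent of the procedure. An audit log records every re-test.

Conditional term association: OLS of Z on [intercept, 1{term ∩ deciles},
1{deciles}, covariates], one-tailed in the configured direction ("greater"
for enrichment-type stages, "less" to probe depletion-type stages for
genes of lower association).

## Synthetic-data generator

The generator emulates the statistical shape of a developmental brain
transcriptome crossed with GWAS summary statistics at the scale of the
motivating study:

- **Design**: 13 ordered stages (labels are config data; no ages are
  hard-coded), 3 donors per stage (39 ≈ the real atlas's 38 donors; the
  per-stage counts are free parameters, not reconstructions), 15 regions
  in three groups (4 prefrontal, 7 non-prefrontal cortical, 4 subcortical),
  one sample per (donor, region).
- **Expression** = gene baseline U(3, 10) + region effect N(0, 0.3²) +
  stage effect N(0, 0.6²) + RIN/ethnicity/sex effects + N(0, 1) noise,
  floored at 0; RIN ~ U(6, 9.5) straddles the quality cutoff so the filter
  removes ~28% of samples; 2% of genes are all-zero to exercise gene
  filtering.
- **GWAS**: 5–12 SNPs per gene placed uniformly in the strand-aware
  mapping window (plus, for 20% of genes, one SNP 5 kb outside it), MAF
  and INFO mostly above the filters with 5% deliberate failures each,
  an X-like chromosome and an xMHC-like zone populated with genes/SNPs so
  the exclusions bite, and 5% non-coding genes. SNP z-scores are drawn
  from a block compound-symmetry MVN (blocks of 5, r = 0.5) with mean
  planted_z/√k on each in-window SNP; p-values are two-sided normal.
- **Planting**: each planted effect (stage, group, ρ) draws — or shares —
  a latent v ~ N(0, 1) over genes. Expression at the planted (stage,
  group) shifts by 1.5·sgn(ρ)·v (adjusted-expression units). Because the
  gene statistic is a quadratic form, association carries no sign, so the
  planted gene-level strength must be a nonnegative monotone function of
  the latent: strength = 10·Φ(raw), raw = Σ|ρ|·v + orthogonal noise at
  unit variance. Positive ρ ties high relative expression to strong
  association; negative ρ plants the depletion pattern; shared latents
  make the same genes carry two stages' signals (the conditional-analysis
  scenario).

**Calibration of the planting defaults.** Amplitude 1.5, stage-effect sd
0.6 and strength ceiling 10 were set together, by pilot simulation of the
generator before the statistical tests were frozen, to satisfy two
competing constraints at ρ = 0.15 and 2000 genes: the planted stage's
expected t-statistic ≈ 4.7 (detection ≈ 95% at the tier-1 threshold
|t| > 2.9), while the zero-sum mirror leakage into each non-planted stage
stays at systematic |t| ≈ 1.1–1.3, i.e. a ~3–5% chance per stage of a
spurious tier-1 flag. A strength ceiling of 10 probit units corresponds to
the strongest gene-level signals in a modern well-powered GWAS.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: realistic human LD maps and allele-frequency
spectra, genome builds, donor-level random effects or repeated measures
(samples are independent given the design), region-specific developmental
trajectories beyond additive region/stage effects, count-level noise
(expression is Gaussian around its mean), ontology DAG structure
(term membership is taken as given), and between-stage autocorrelation of
expression.

## Problem sizes used in the checks

The Monte-Carlo acceptance checks run the full chain at the study's
default conditions (2000 genes, 13 stages, 15 regions): 100 replicates for
the type-I and positive-recovery rates, 30 for the depletion signature,
100/50 for the conditional scenarios, 50 for the refinement scenario; the
null-calibration oracle uses 10⁶ MVN draws per (k, r) setting, and the
Fisher oracle enumerates every 2×2 table with total count ≤ 30
(> 30,000 tables). `scripts/acceptance.py` reruns the same quantities at
40/20 replicates per block, which keeps a full pass to a few minutes on a
single CPU.

## Known limitations

- The exact null's Ruben series needs λ_min > 0 after the 1e−12 eigenvalue
  cut; degenerate LD matrices are handled by that cut, but a matrix with
  pathological near-zero-but-kept eigenvalues would slow convergence
  (the 50,000-term cap then applies).
- Gene size in the covariates is the window-extended span, one of two
  defensible readings (the other being gene-body length).
- The decile merge rule and the Fisher sidedness are documented defaults
  behind config options; the motivating analysis does not pin them down.
- Very small samples can confound a stage with a demographic covariate,
  making every score for that stage exactly zero; such stages are reported
  as degenerate rather than analysed.
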