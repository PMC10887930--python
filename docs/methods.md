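# Methods

This note documents the statistical models, the synthetic-data generator,
and the numerical choices behind each pipeline stage, in the spirit of the
model documentation shipped by statistical packages.  It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Study design assumed throughout

Two genotypes with contrasting heat tolerance (`tolerant`, `susceptible`),
two conditions (`CK` control, `HS` heat stress), `n` biological replicates
per genotype × condition group (default 3, i.e. 12 libraries).  The same
sample layout is assumed for the metabolome, with samples matched
one-to-one across omics by (genotype, condition, replicate); the replicate
count for metabolomics is taken equal to transcriptomics and is
configurable.

## Differential expression (`heatomics.de`)

**Normalization.** Median-of-ratios size factors: for every gene with
nonzero counts in all samples, form the ratio of its count to its
geometric mean across samples; a sample's factor is the median of these
ratios.  The estimator is equivariant under per-sample scaling and returns
all ones on identical columns.  If no gene covers all samples the function
fails loudly rather than silently switching to a pseudo-reference.

**FPKM.** `count / ((length/10³) × (column_sum/10⁶))` with the per-sample
mapped total taken as the column sum.  Expressed genes are those with
ΣFPKM across samples strictly greater than 1.

**The NB Wald test.** Within one genotype, per gene:

* group means μ̂_HS, μ̂_CK of size-factor-normalized counts;
* log₂FC = log₂((μ̂_HS + pc)/(μ̂_CK + pc)) with pseudocount pc = 0.5
  normalized counts (avoids division by zero; the paper-scale thresholds
  |log₂FC| > 1 are far from the pseudocount's region of influence for
  expressed genes);
* dispersion α from method of moments, (s² − μ̄)/μ̄² with the pooled
  within-group variance s² (d_resid = n_HS + n_CK − 2 degrees of freedom),
  **moderated** toward the experiment-wide median of the positive per-gene
  estimates with prior_df = 4 prior degrees of freedom, then floored at
  1e−8.  At 2–3 replicates the raw per-gene estimate is so noisy that
  unmoderated tests are either badly anticonservative or powerless;
  empirical-Bayes squeezing is the standard remedy;
* standard error from the expected NB information,
  SE² = [(1/μ̂_HS + α)/n_HS + (1/μ̂_CK + α)/n_CK] / ln²2;
* the Wald statistic log₂FC/SE is referred to a **t distribution with a
  per-gene Satterthwaite effective df**: the Poisson part of the variance
  is known given the mean, the dispersion part carries
  d_resid + prior_df df, and the effective df is clipped to
  [d_total, 2·d_total].  A plain normal reference is anticonservative at
  n = 3 (empirical type-I ≈ 0.09 at nominal 0.05) and a fixed t(d_resid)
  erratically conservative; the clipped Satterthwaite reference keeps the
  null rejection rate near nominal across dispersion and mean regimes, as
  the calibration test and the acceptance script verify;
* Benjamini–Hochberg adjustment across genes; calls `up`/`down` at
  |log₂FC| > 1 (strict) and p-adj < 0.05.

This is a deliberately transparent substitute for shrinkage-based DE
packages: no fold-change shrinkage, no outlier filtering, no multi-factor
designs.  Its calls will not numerically match a DESeq2 run on the original
archive and do not attempt to; the downstream screens only need calibrated
calls.

**Sample QC.** Pairwise Spearman correlation of FPKM columns (replicates of
the same genotype are expected to exceed 0.95; constant samples yield NaN
with a warning) and PCA on log₂(FPKM + 1), genes as variables, centered
and not scaled, reporting percent variance explained in decreasing order.

## Response classification and the frontloading screen (`heatomics.responses`)

Categories are a pure function of the two calls: `common_up` (both up),
`common_down` (both down), `unique_tolerant` / `unique_susceptible`
(response in exactly one genotype), `discordant` (opposite directions),
`none`.

The screen runs on the `unique_susceptible` genes over group means of
FPKM + 1 (pseudocount 1 FPKM; results are invariant to joint rescaling of
FPKM and pseudocount).  With fc_g = mean_HS/mean_CK per genotype, the
fold-change ratio is oriented so that > 1 always means "stronger response
in the susceptible genotype": fc_s/fc_t for up-regulated candidates,
fc_t/fc_s for down-regulated ones.  Classification:

* `frontloaded` — up-regulated candidate, fc_ratio > 2 **and**
  control_ratio = mean_s,CK/mean_t,CK < 1.  The control-ratio condition
  formalizes "higher baseline in the tolerant genotype"; the published
  screen states it as prose, not as a numeric threshold, so the strict < 1
  cut is this package's choice.
* `stress_indicator` — down-regulated candidate with fc_ratio > 2.
* `neither` otherwise.

Consequences worth knowing: when a unique-down gene has an unchanged
tolerant side, its fc_ratio equals the susceptible repression and any
repression beyond 2-fold makes it a stress indicator — the screen defines
the class, so planted "unique_susceptible_down" genes are absorbed by it;
and for unique-up genes with equal baselines the control ratio sits at 1,
so sampling noise sends roughly half of them below the strict cut.  The
heat-side ratio (mean_s,HS/mean_t,HS) is reported for plotting but not used
in classification.

## Clustering and enrichment (`heatomics.cluster`)

Profiles are per-gene z-scores of the four group-mean FPKM values
(constant profiles dropped with a warning).  k-means is Lloyd's algorithm,
Euclidean, best of 10 random initializations, deterministic given the
seed; the pipeline default k = 4 for genes and k = 9 for differential
metabolites.

**Elbow.** WSS is computed over a k range and the suggestion is the k
maximizing the second difference of **log** WSS.  On the log scale a
steadily shrinking cluster criterion has roughly constant curvature, so
the maximum marks the transition from steep decay to plateau — the visual
elbow.  (The second difference of raw WSS peaks at the smallest k on any
geometrically decaying curve and never finds the planted structure.)  The
suggestion is advisory, flagged low-confidence when the maximal curvature
is less than twice the median; with fewer than three k values the default
is returned with a warning.

**Enrichment.** Upper-tail hypergeometric p = P(X ≥ k) for k selected
genes in a term of K universe genes, drawing n from N, using only
universe-intersected annotations, BH across tested terms, significance at
p-adj < 0.05.  The universe defaults to all expressed genes.  Annotations
come from a user-supplied GMT file; no live database access.

## Metabolomics (`heatomics.metabolome`)

**Preprocessing.** log₂(intensity + pc) with pc = half the smallest
nonzero intensity when zeros are present (0 otherwise), then per-metabolite
mean centering.  All-zero metabolites are dropped with a warning.

**OPLS-DA.** Two classes encoded ±1.  NIPALS-style extraction: for each of
`n_ortho` orthogonal components (default 1, the standard choice for
two-class problems), compute the PLS weight w ∝ Xᵀy, the loading p of the
corresponding score, and split off the y-orthogonal part of p as the
orthogonal weight; deflate X by the orthogonal component.  One predictive
component is then extracted from the filtered X.  Reported:

* R²X — fraction of (centered) X variance captured by the model, split
  into predictive and orthogonal parts;
* R²Y — fraction of class variance explained by the predictive component;
* Q² = 1 − PRESS/SSY via stratified k-fold cross-validation (default 7
  folds, capped at the minority class size; each fold refits the full
  orthogonal-plus-predictive sequence on the training rows only).  Q²
  cannot exceed R²Y beyond numerical noise;
* VIP over the predictive component,
  VIP_j = sqrt(p · Σ_a SSY_a (w_aj/‖w_a‖)²/Σ_a SSY_a), which with one
  predictive component reduces to sqrt(p)·|w_j|/‖w‖ so that
  Σ VIP² = p exactly.  VIP is computed on the predictive component only
  because it ranks class-discriminating metabolites.

**Permutation test.** The class labels are shuffled `n_perm` times
(default 200), the model refit, and (R²Y, Q²) recorded;
p = (1 + #{null Q² ≥ observed Q²})/(n_perm + 1).  Permutations identical
to the observed assignment or its mirror are rejected and redrawn: they
carry no information about the null, and at 3 + 3 samples they would
otherwise occur with probability 1/10 and floor the attainable p at ~0.1
regardless of effect size.

**DEM calls.** log₂FC from group geometric means of raw intensities
(equivalently arithmetic means on the log scale, consistent with the
log-normal model); `up` iff log₂FC ≥ 1 and VIP ≥ 1, `down` iff
log₂FC ≤ −1 and VIP ≥ 1 — inclusive thresholds.  Differential metabolites
are clustered on z-scored group means of log₂ intensity with the shared
k-means routine.

## Integration (`heatomics.network`)

Pearson correlation (Spearman available) between log₂(FPKM + 1) of the DEG
set and log₂ metabolite intensities across matched samples; two-sided p
from the t distribution with n − 2 df; edges require r² > 0.9 and
p < 0.05, per-pair and unadjusted (a BH option exists but is off by
default to match the published screen).  Correlations use per-sample
values, not group means: at four group means no pair can reach p < 0.05 at
r² > 0.9 in general.  Rows that are constant to within a relative
tolerance of 1e−9 are skipped with a warning — after mean centering an
exactly constant profile leaves machine-epsilon residue that would
otherwise correlate as pure noise.  Edge sets are invariant under
monotone-linear rescaling of either profile and shrink monotonically as
the r² threshold tightens.

## Agronomics (`heatomics.agronomics`)

Heat-tolerant coefficient = 100 × HS yield / CK yield, yield loss its
complement computed pre-rounding, both reported to 2 decimals with
half-away-from-zero rounding.  The bundled four-hybrid field-trial table
reproduces the published coefficients to within one unit in the last
printed digit (one printed cell is off by exactly one ulp from its own
yields, an artifact of the source table's rounding).  2^−ΔΔCT uses target
and reference-gene cycle thresholds in treated vs control samples and is
multiplicative under composition of ΔΔCt shifts.

## The synthetic generator (`heatomics.simulate`)

Counts are NB with var = μ + αμ² (default α = 0.05, a typical biological
replicate dispersion).  Per-gene baselines are log-normal (natural-log
mean 4.0, sd 1.5) rescaled so an average library holds ~10⁶ reads;
per-sample depths vary log-normally (sd 0.2) to exercise size-factor
estimation; gene lengths are uniform on 500–5000 bp for FPKM.  Planted
classes (default 50 genes each, effect |log₂FC| = 2, which must exceed the
call threshold of 1 to be recoverable):

* `common_up`/`common_down` — ±effect in both genotypes under HS;
* `unique_susceptible_up`/`unique_susceptible_down` — effect in the
  susceptible genotype only, tolerant side truly unchanged;
* `frontloaded` — tolerant baseline = 4 × susceptible baseline
  (`frontload_baseline_ratio`), tolerant heat response 1.0 (the tolerant
  side is planted as genuinely non-responsive), susceptible induced by the
  effect;
* `stress_indicator` — susceptible repressed by the effect, equal
  baselines.

Metabolites are log-normal on the log₂ scale (baseline mean 17, sd 2,
replicate noise sd 0.3) with planted DEM classes shifted by ±2 log₂ units
under HS in the relevant genotype(s) (defaults: 15 metabolites per class).

The generator emulates depth variation, biological dispersion and planted
effect classes; it does **not** emulate composition bias beyond what the
planted classes induce, batch effects, isoform structure, count outliers,
or correlated gene modules.  Passing tests therefore demonstrate correct
recovery of the planted signal classes under idealized NB/log-normal
noise, not robustness to every artifact of real sequencing or LC-MS data.
One knowable small-scale artifact: in toy simulations where planted genes
are a large fraction of the transcriptome, the HS library total inflates
and compresses FPKM ratios; at the default 15% planted share the effect is
minor.

Everything is reproducible from `rng_seed`; counts, metabolites and
annotations use independent child streams so changing one layer's size
does not perturb the others.

## Problem sizes

The test suite and the acceptance script run the generator at its default
study scale (2000 genes, 500 metabolites, 3 replicates), with 100–200
refits for permutation/null distributions and 10⁵ pairs for the network
null — sizes at which every stage completes in seconds while leaving the
Monte-Carlo bands quoted in the tests comfortably wide.

## Known limitations

* The NB test is two-group only; no covariates, interactions, or shrinkage
  of fold changes.
* The frontloading screen's control-ratio cut is strict and unsmoothed; a
  gene with a genuinely higher tolerant baseline but noisy control means
  can fall on either side at small n.
* OPLS-DA assumes exactly two classes; multi-class designs require
  one-vs-one contrasts.
* Network p-values are per-pair; with ~10⁶ pairs the unadjusted screen is
  only meaningful together with the stringent r² threshold, which is the
  point of the published rule.
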