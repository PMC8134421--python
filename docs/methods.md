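# Methods

## Beta-binomial model of allelic read counts

At a heterozygous locus the alternative-allele read count for individual
*i* is modelled as `k_i ~ BetaBinomial(n_i, α, β)` with the
mean/overdispersion parameterisation `α = π(1−ρ)/ρ`,
`β = (1−π)(1−ρ)/ρ`. π is the mean alternative-allele fraction (0.5 under
balanced expression) and ρ ∈ (0,1) absorbs the extra-binomial variance
that biological replicates of allelic expression always show
(`Var k = nπ(1−π)(1 + (n−1)ρ)`). This parameterisation was chosen so
that the balanced null is the single constraint π = 0.5, leaving ρ free
in both hypotheses: overdispersion must not be conflated with imbalance.

The log PMF is computed with `scipy.special.gammaln`
(`ln C(n,k) + ln B(k+α, n−k+β) − ln B(α, β)`), which is stable over the
full parameter box. Optimisation is bounded L-BFGS-B on
`[10⁻⁶, 1−10⁻⁶]²` from a moment start (pooled `Σk/Σn` for π; the
dispersion of per-individual fractions for ρ), with two random restarts.
When the line search aborts exactly at the optimum — which happens when
successive function differences fall below float precision, typically
with ρ̂ on the lower bound — a projected-gradient check and a
derivative-free Nelder–Mead polish decide whether the point is accepted
as converged; only genuine failures propagate a `converged=False` flag,
and such loci are excluded from FDR with a logged count. The null fit
(π fixed) is a one-dimensional bounded Brent minimisation.

## ASE calling

Per locus, the likelihood-ratio statistic `max(0, 2(LL_alt − LL_null))`
is referred to χ² with one degree of freedom (the clip guards against
optimiser jitter leaving the alternative marginally below the null). The
one-degree-of-freedom reference is asymptotic in the number of
individuals; simulated null cohorts at 30 individuals show type-I error
within [0.03, 0.07] at nominal 0.05, which the test suite checks. Loci
observed in fewer than 5 individuals are excluded before testing, and
Benjamini–Hochberg (via `statsmodels.multipletests`) is applied once
across all tested loci of a cohort; a locus is an ASE-SNV when
q < 0.05. ρ is fitted per locus; whether sharing ρ across loci would be
preferable is data-dependent and left as a constructor option
(`AseCohortModel(..., null_pi=...)` plus per-locus fits) rather than a
global assumption. Records with zero total reads are dropped with a
logged count; the test is symmetric in π, so ref/alt orientation does
not affect p-values.

## Feature curation

The canonical annotation header has 109 columns: the 107 CADD v1.4
GRCh37 annotation columns plus `pLI_score` and `gnomAD_AF`. Three
exclusion lists ship as package data — 12 non-functional columns
(identifiers, coordinates), 16 columns with high missingness
(motif/miRNA/splice-predictor scores), and 11 columns correlated with
ASE detectability (expression level and local allele-frequency counts,
including `gnomAD_AF`, which would let the model learn where ASE is
*detectable* rather than where it occurs) — leaving 70 modelling
features. `gnomAD_AF` is therefore treated as excluded even though it is
also part of the considered set.

Imputation uses per-column defaults. The CADD release-notes empirical
values are not redistributable here, so the shipped defaults are
data-driven placeholders in the same spirit: column median for numeric,
modal category for categorical/binary, all configurable through
`FeatureSpec.imputation_default`. Categorical columns are encoded as
alphabetically ordered integer codes (tree ensembles split on
thresholds, so ordinal codes suffice and keep the matrix narrow); the
code book is fitted on the training matrix only, persisted in a JSON
sidecar, and unseen categories at apply time map to a reserved unknown
code with a warning.

## Classifier

`GradientBoostingClassifier` (scikit-learn) with 100 boosting stages per
model. "Iterations" are read as boosting stages — the natural meaning
for a boosting configuration — and exposed as
`TrainConfig.n_boost_iterations`. A stratified 10% holdout is removed
first; the rest enters nested cross-validation: 10 stratified outer
folds each train one model, and a 6-fold inner loop selects
hyperparameters from a small grid by mean AUROC. The default grid is the
single library-default point (learning rate 0.1, depth 3), making inner
selection a no-op unless a real grid is supplied; this mirrors training
with default parameters while keeping the selection machinery testable
(a two-point grid is exercised in the tests). Per-class row counts must
support the fold structure or construction fails with advice to reduce
folds.

Predictions on new data are the arithmetic mean of the outer-fold
models' probabilities (per-fold outputs are also exposed for fold-wise
ROC curves); classification uses `p ≥ threshold`, default 0.5. Gini
(impurity) importances are taken per fold model, normalised to sum to
one, and summarised as mean and quartiles across folds. Everything is
reproducible from (data, config, seed): fold seeds derive
deterministically from the config seed.

## Evaluation

AUROC is the Mann–Whitney rank statistic (ties counted half), exactly
the area under the ROC curve and checked against an all-pairs
concordance oracle to 10⁻¹⁰. Ensemble evaluation reports mean ± SD of
per-fold AUROCs plus PPV/NPV/sensitivity/specificity at the threshold,
computed on the mean probability; rates with empty denominators are
flagged undefined rather than reported as zero. Display rounding is
half-up to two decimals. The same code path evaluates a model trained on
one cohort against another cohort's matrix (cross-cohort application).

## Bias test

The gene-function bias diagnostic replaces a web enrichment service with
a local hypergeometric over-representation test on user-supplied GMT
gene sets: an offline, deterministic ranking function is all the
diagnostic requires. Terms are ranked by upper-tail hypergeometric
p-value within a configurable background universe (default: all genes
covered by the full ASE-SNV set), ties broken by larger overlap then
term id. The observed profile of the correctly predicted ASE-SNVs' genes
is compared, for its top 10 terms, with profiles of 10 equally sized
SNV subsets drawn without replacement from the full ASE-SNV set; a term
absent from a resample profile is assigned rank T+1 and flagged so the
distributions stay comparable. Both the resample count and top-k are
configurable upward for tighter nulls.

## Synthetic data

The generators emulate the study conditions a cohort ASE analysis faces:
beta-binomial counts with shared overdispersion (default ρ = 0.05),
null loci at π = 0.5 and ASE loci drawing π from a mirrored uniform on
(0.6, 0.95) ∪ (0.05, 0.4) so imbalance direction is symmetric; read
depths from a shifted negative binomial (1 + NB, mean 40, dispersion 5
— resembling exome-coverage RNA counts while guaranteeing depth ≥ 1);
and annotation matrices whose numeric columns are unit-variance
Gaussians shifted by `effect × label`, with label-tilted categorical
columns and independent missingness. A single global seed fans out to
per-locus substreams keyed by locus index, so any subset of loci is
reproducible regardless of iteration order.

What the generators do **not** emulate: mapping bias toward the
reference allele, genotyping error, correlated features, linkage between
nearby loci, or realistic annotation distributions. Passing tests
therefore demonstrate correctness of the statistical machinery and
recoverability of planted signal, not expected performance on real
cohorts.

## Problem sizes and numerical choices

The test and acceptance workloads use 2000 null loci at 30
individuals/depth ~40 for type-I calibration, 100 replicates at 50
individuals/depth 50 for π recovery, and a 5000-variant, 20-feature
matrix over 10 seeds for importance recovery — sizes at which the
binomial/rank statistics under test have standard errors comfortably
inside the asserted bands while a laptop run stays in minutes. Grid
oracles use 300×300 parameter grids (loglik agreement within 10⁻³).
Degenerate inputs are errors, not silent defaults: empty tables,
single-class labels, k > n, boundary parameters and mismatched columns
all raise with the offending item named.

## Known limitations

- Per-locus ρ estimates are noisy below ~10 individuals; the LRT is
  still calibrated in simulation but π̂ confidence degrades.
- The χ²₁ reference is asymptotic; very low depths (< ~10 reads) at few
  individuals make the test conservative.
- Ordinal encoding of categoricals is tailored to tree models; linear
  baselines would need one-hot encoding.
- Haplotype- or gene-level aggregation, allosomal loci, and per-individual
  ASE calls are out of scope.
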