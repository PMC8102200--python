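# Methods

This note documents the models behind `stepcourse`, the defaults and why
they are set where they are, the numerical conventions, and what the
synthetic benchmarks do and do not demonstrate.

## Setting

The input is a genes × samples matrix of raw RNA-seq read counts over S
ordered differentiation stages (default order MBC < prePB < PB < PC, the
staged in-vitro plasma-cell differentiation system) with R replicates per
stage (default design 4 × 3; any S ≥ 2, R ≥ 2 works). Stage order is always
declared explicitly, never inferred from sample names. Replicates are
treated as exchangeable within a stage; donor identity is not modeled as a
blocking factor anywhere.

## Normalization

Median-of-ratios size factors: the reference set is the genes with strictly
positive counts in every sample; for each sample the factor is the median
over reference genes of count / (gene's geometric mean across samples).
Factors are returned exactly as those medians, not rescaled. If the
reference set is empty the estimator fails loudly — a pseudo-reference
fallback is deliberately not provided, since matrices that sparse need a
different normalization strategy, and silently switching estimators would
change results. Medians of even-length sets use the midpoint convention
(determinism). The estimator is implemented natively rather than delegated
to a DE library so the normalization stage carries no heavyweight
dependency; one test cross-checks the factors against an independent
implementation (pydeseq2) to 1e-10.

Log expression is always log2(normalized + 1). The pseudocount guards
zeros and is negligible at the scales the thresholds act on: a normalized
count of 63 maps to exactly 6.0.

## Active-expression threshold

Pooled per-stage log2(stage-mean + 1) values across all genes and stages
form a bimodal distribution: transcriptional background vs. active
transcription. A two-component Gaussian mixture (10 random restarts under
the pipeline seed, best likelihood wins) is fitted to the pooled values —
one threshold for all stages, since a single cutoff is applied to every
subpopulation — and the cutoff is the equal-posterior-responsibility
crossing between the components, mapped back to the count scale as
2^crossing − 1. The crossing is found by root-finding on the log-density
difference inside the bracket between the component means, with a dense
grid as fallback.

Two guards reject fits with no usable bimodality: component means closer
than 1 log2 unit, and Ashman's D = √2·|μ₂−μ₁|/√(σ₁²+σ₂²) below 2. The
second is needed because a 2-component mixture fitted to a *single*
Gaussian splits it into two components roughly 1.2 σ apart — separated in
absolute terms yet not bimodal; D catches this (a split Gaussian lands near
1.5, truly bimodal expression data well above 2). On failure the estimator
instructs the user to supply a fixed threshold (e.g. 64).

Activity is inclusive: a gene is active in a stage when its stage-mean
normalized count is ≥ the threshold. Categories partition the genes:
`all-stages`, `specific:<stage>` (exactly one active stage), `multi-stage`
(≥ 2 but not all), `inactive` (excluded downstream).

## Differential expression

For each consecutive-stage pair, counts follow
NB(mean = s_j·q_g·2^(x_j·β_g), var = μ + α_g μ²) with x the group
indicator. Size factors come from the full matrix, so scaling is shared
across contrasts.

Dispersion: gene-wise method-of-moments on normalized counts
(α̂ = (pooled within-group variance − ξ·mean)/mean², ξ = mean(1/s_j)),
a parametric trend α(μ) = a₀ + a₁/μ fitted by iterative weighted least
squares with outlier exclusion, then empirical-Bayes shrinkage in log
space: the posterior mean of log α under a normal prior centred on the
trend, with sampling variance trigamma((m−2)/2) and prior variance
estimated from the spread of residuals (floored at 0.25). Two corrections
matter at R = 3:

- the log of a variance-type estimate at df = m − 2 is biased down by
  digamma(df/2) − log(df/2) (≈ −0.27 at df = 4); the gene-wise log estimate
  is re-centred before shrinkage, otherwise dispersions are systematically
  understated and the type-I error inflates visibly;
- genes more than 2 posterior standard deviations *above* the trend keep
  their own estimate (dispersion outliers are not shrunk), protecting the
  test on genuinely noisy genes.

The group coefficient is fitted by vectorized IRLS (all genes at once) and
tested with a Wald statistic against the standard normal. The shrinkage is
what stabilizes the statistic at small R; stacking a heavier-tailed
reference on top of shrunk dispersions is markedly conservative (measured
type-I ≈ 0.01 at nominal 0.05). Under the package's null simulation
(NB μ = 100, α = 0.1, 3 vs 3) the raw p < 0.05 fraction sits near 0.055.
Genes with all-zero counts in both groups get an undefined p and call `ns`.

Compared with full DESeq2 machinery there is no Cook's-distance outlier
handling, no independent filtering and no LFC shrinkage; fold-change
filtering acts on the unshrunk estimate. An adapter seam (`size_factors`
and per-contrast tables) allows substituting an external implementation
when exact parity with that toolchain matters.

Multiple testing: BH, by default pooled once over the raw p-values of all
consecutive contrasts (`fdr_scope="global"`), controlling the FDR across
all comparisons jointly; per-contrast adjustment is available. Calls
require adjusted p < 0.05, fold change ≥ 2 in either direction (linear
scale), and mean normalized count ≥ 64 (= 2⁶) in at least one of the two
groups of the contrast. All three cutoffs are configuration parameters;
some analyses of this design relax the fold-change floor to 1.5, which is
why it is exposed rather than hard-coded.

## Step-pattern classification

The core method fits piecewise-constant models to each gene's
replicate-level log2 trajectory — per-replicate values, not stage means, so
within-stage variance informs selection. A breakpoint b ∈ {1..S−1} places a
level change between stages b and b+1. Enumeration is exhaustive over
k ∈ {0, 1, 2} transitions (1 + (S−1) + C(S−1,2) candidates; 7 at S = 4),
each fitted by least squares (segment level = mean of its points), capped
at k ≤ min(2, S−1).

Selection, BIC mode (default): score = n·ln(SSE/n) + p·ln(n) with
n = total points and p = (k+1)+1 (segment means + noise variance); minimal
score wins, ties toward smaller k then earlier breakpoints. F-test mode:
nested F-tests on the per-k best fits at level 0.01, accepting an added
transition only when significant. In both modes any selected transition
with |Δ| < `step_min_delta` (default 1 log2 unit, i.e. 2-fold — mirroring
the DE fold-change floor) demotes the gene to the best smaller-k model,
recursively; with SSE = 0 at several k the smallest k wins. The selection
rule is this package's own contract: it was chosen for determinism and
testability (oracle equivalence against brute-force enumeration is part of
the acceptance checks), not as a claim about any other implementation of
step fitting.

Labels: k=0 → flat; k=1 → one-step-up/-down with transition stage = first
stage of the new regime (a one-step-up at breakpoint 1 of the default
course is "up-at-prePB"); k=2 with opposite-sign deltas → two-step-up-down
or two-step-down-up at the first breakpoint's stage. Same-sign two-step
fits are not impulses: they collapse to the one-step label at the major
transition (largest |Δ|, ties toward the earlier breakpoint), keeping the
taxonomy at exactly four non-flat patterns. Negating all values swaps up ↔
down labels with identical breakpoints; adding a constant changes nothing
but the levels — both properties are tested.

The profiled gene set is explicit. The pipeline's `run-all` default is the
intersection of actively expressed genes and genes DE in at least one
consecutive contrast; any other subset can be passed, since reasonable
universes (all genes, active genes, DE genes) differ and the choice changes
headline counts.

## Regulator annotation and ORA

Step-profiled genes are flagged against user-supplied TF and EE catalogs
(case-normalized to upper case; a gene in both catalogs counts once in
group totals). Catalogs are inputs, not vendored, to avoid freezing
third-party lists with their own licensing and versioning.

ORA is the exact upper-tail hypergeometric: population = universe,
successes = set ∩ universe, draws = query; p = P(X ≥ overlap). Zero-overlap
sets are reported with their tail probability at 0, never dropped. BH runs
across all tested sets. The default universe is the actively expressed gene
set, not the whole annotation — enrichment of a pattern group is judged
against the expressed transcriptome; this is a design decision, exposed as
an argument. Topology-aware pathway statistics are out of scope; plain ORA
is the declared method.

## Synthetic-data generator

Each gene draws a pattern from a configurable mix (reference configuration:
12,000 genes, 0.5 flat / 0.15 one-step-up / 0.15 one-step-down / 0.1
up-down / 0.1 down-up), a base log2 level from Normal(7, 2²), and — for
step patterns — uniformly random admissible breakpoints with a ±3 log2-unit
(8-fold) step returning to base for impulses. A fraction of genes
(default 15%) sit flat at log2 level 2 (background). Stage means 2^level
are multiplied by per-sample size factors drawn uniform on [0.5, 2] —
library-size confounding is planted so normalization is genuinely
exercised — and counts drawn NB with dispersion α = 0.1 (variance μ + αμ²;
α = 0 degrades to Poisson). Truth tables record label, breakpoints, segment
levels and per-stage activity (level ≥ 6, i.e. count ≥ 64). delta = 0
degenerates every program to flat and is recorded as such.

Defaults were chosen once to represent a realistic bulk RNA-seq
differentiation design of this shape: 3 replicates matches the three-donor
layout such experiments use; α = 0.1 is a typical bulk biological
coefficient of variation (~0.3); 8-fold steps are the magnitude of the
developmental on/off switches the four-pattern taxonomy targets.

What the generator does **not** emulate: donor batch effects, correlated
gene modules, composition effects from a dominant transcript class (e.g.
immunoglobulin genes in late stages), biotype structure, or read-level
artifacts. Recovery rates on it (≈97% label accuracy at the reference
settings) therefore demonstrate correctness of the estimators under the
stated noise model, not expected accuracy on real data, where step
magnitudes are heterogeneous and replicate variance is donor-structured.

## Numerical conventions and degenerate inputs

- TSV everywhere; floats printed with 6 significant digits; fixed column
  orders; identical config + seed ⇒ byte-identical outputs.
- Gene identifiers are opaque strings (no symbol/ID mapping); duplicate ids
  are rejected at parse time, as are negative or non-integer counts (the
  error names the offending row and column).
- Threshold comparison for activity is inclusive (≥); SSE ties and BIC
  ties break toward simpler models and earlier breakpoints; even-length
  medians use midpoints.
- The mixture fit requires ≥ 200 pooled values; below that, fixed-threshold
  mode is the supported path.
- Designs must declare ≥ 2 stages with ≥ 2 samples each (variance
  estimation); the step fitter itself accepts any ≥ 1 replicate per stage.

## Known limitations

- The NB Wald test is mildly anticonservative at R = 3 (≈0.055 at nominal
  0.05 under the null simulation); analyses needing strict type-I control
  at tiny n should prefer the F-test selection mode's conservatism for
  steps and treat borderline DE calls with care.
- Two transitions maximum: genuinely multi-phase trajectories (S > 4 with
  three or more regime changes) are folded into the nearest two-step
  approximation.
- No donor blocking; paired designs lose power relative to a
  mixed-model analysis.
- Pattern counts depend on the profiled gene universe; comparisons across
  analyses must fix the subset rule first.

## Benchmark problem sizes

The test suite and the acceptance script run on simulations sized so the
whole suite completes in well under a minute on one CPU: 12,000 genes for
pattern recovery, 2,000 for null calibrations, 1,000 random genes for the
selection-oracle equivalence, 500 for DE power. These sizes put binomial
sampling error well inside the asserted margins.
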