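# Methods

## The classification framework

`phenoplast` operationalizes a framework for asking how often plant
populations respond to environmental heterogeneity by phenotypic
plasticity versus canalization (with or without genetic differentiation),
using reciprocal-transplant trait records. The atomic unit is a *block*:
the four cell means of one trait in one study, `AinA`, `AinB`, `BinB`,
`BinA`, each carried with a dispersion (SE, SD or variance) and a sample
size of at least 10 individuals. Each block splits into two *paired
records*, one per population (its resident and nonresident cells), so a
dataset of `k` blocks always yields exactly `2k` pairs.

Five patterns are distinguished:

1. **canalized – no differentiation**: neither population plastic, resident
   phenotypes indistinguishable;
2. **canalized – population differentiation**: neither plastic, resident
   phenotypes differ (local adaptation of trait means);
3. **perfect adaptive plasticity**: both plastic, each transplant converges
   onto the resident population's phenotype;
4. **adaptive plasticity**: both plastic, transplants move toward but do
   not reach the resident phenotype (parallel, non-congruent reaction
   norms);
5. **nonadaptive plasticity**: both plastic, transplants diverge from the
   resident phenotype; subtyped *steep* (overshoot in the right
   direction) or *wrong sign* (movement away from the optimum).

## Standardized metrics

The published description of the four metrics is verbal; the closed
forms used here are reconstructed from that description plus three
constraints, and each lives behind a single function so an alternative
standardizer could be swapped in one place:

- every metric must range over `[0, ∞)`;
- the plasticity cutoff at the dataset-mean CV must correspond to a
  one-standard-deviation shift, which holds exactly when plasticity is
  standardized by the resident mean (`|Δ|/mean = CV ⇔ |Δ| = SD`), hence
  `P = |x_res − x_non|/|x_res|`;
- adaptiveness must read 0 = perfect convergence, `(0, 1)` = partial
  convergence, `≥ 1` = divergence, hence
  `S_A = |AinB − BinB|/|AinA − BinB|` and its mirror for B.

For differentiation the text privileges neither population, so the
standardizer is the mean of the two resident means,
`D = |AinA − BinB|/|(AinA+BinB)/2|`; standardizing by one resident mean
alone would break relabeling symmetry, which is kept as a tested
invariant. Absolute values are applied to numerator and standardizer so
negative trait means (log-transformed traits) cannot produce negative
metrics.

A consequence of these choices worth stating plainly: the block-level
adaptiveness metric `max(|AinB−BinB|, |BinA−AinA|)/|AinA−BinB|` is
*identically* the maximum of the two per-pair scores, because both pairs
share the standardizer `|AinA − BinB|`. The classifier still exposes
both score modes (`pair_max` and `block`) so either reporting convention
can be requested explicitly; a property test asserts their equivalence.

**Degenerate standardizers** (resident mean 0 for plasticity; equal
resident means for adaptiveness; opposite-signed resident means for
differentiation) yield `+∞` when the numerator is positive and `0` when
it is also zero, flagged `degenerate` either way. Degenerate records are
labeled `unclassified`, excluded from CDFs and from every frequency
denominator, and counted separately. Rationale: `0/0` carries no signal
in either direction, and silently assigning such records to a category
would bias frequencies.

## Threshold and decision tree

The cutoff `θ` is the mean coefficient of variation `SD/|mean|` over all
cells (`derive_threshold`), 0.53 by convention; zero-mean cells are
excluded from the average with a warning. Boundary conventions are
deterministic and assigned to the adjacent outer categories: a pair with
`P = θ` is *not* plastic, a block with score `S = θ` is perfect
adaptive, `S = 1` is nonadaptive. These are measure-zero events on real
data but matter for reproducible tests.

A block is plastic only when **both** pairs are plastic; blocks with
exactly one plastic pair fall into the nonplastic branch and are
subclassified by differentiation like any other nonplastic block (the
only reading consistent with a two-way plastic/nonplastic block split).
For nonadaptive blocks the steep/wrong-sign conditions are evaluated per
population (only where that population's score is `≥ 1`); the
block-level subtype records *wrong sign* if either population is wrong
sign, since wrong-sign plasticity is the stronger claim of
maladaptation. Within the divergent region the two sign conditions are
mutually exclusive and exhaustive — an exhaustive-enumeration test
checks the partition, and the classifier raises if a configuration ever
falls through.

## Bootstrap uncertainty

Empirical CDFs of each metric ("fraction of records within a given
effect size") let a reader apply their own threshold. Confidence bands
are pointwise percentile intervals (95% by default; the band type and
level are configurable since the published account names neither) on a
fixed grid: the sorted observed values plus `θ`. Three resampling
schemes, 5000 replicates by convention:

1. `blocks` — resample blocks with replacement, the four cells moving as
   one unit;
2. `corr0` — additionally perturb each resampled cell mean with an
   independent Gaussian deviate, SD equal to that cell's SEM;
3. `corr1` — one standard-normal draw per block scales all four SEMs
   (perfectly correlated deviates).

The 0 and 1 correlation extremes bracket plausible nonnegative
within-block error dependence. Deviates are Gaussian (the natural
reading of SEM-based perturbation) and may push a mean across zero;
metrics are recomputed as-is, since truncation would bias the CDFs.
Stream discipline: one root `SeedSequence` spawns a substream per
replicate, so replicate *r* is reproducible independently of the total
replicate count, and identical seeds give bit-identical bands. A
calibration test checks the `corr0` bootstrap SD of the plasticity
metric against first-order error propagation,
`σ(P) ≈ sqrt(SEM_non² + (x_non/x_res)²·SEM_res²)/|x_res|`
(the delta method applied to `P = |x_res − x_non|/|x_res|`), agreeing
within 15% at 5000 replicates.

## Reporting

Frequency tables use the denominators the five-pattern framework
implies: canalized subcategories as percentages of all classified
blocks, plastic subcategories as percentages of plastic blocks,
steep/wrong-sign as percentages of nonadaptive blocks; empty
denominators report "undefined", never 0. Percentages are stored at full
precision and rendered to one decimal. The sensitivity sweep re-runs the
classifier at `θ/2, θ, 2θ` (0.265/0.53/1.06) by default; nonplastic
fractions are provably nondecreasing in `θ`.

The within-study clustering check uses a statistic of our own design
(no published procedure exists to follow): the mean, over studies
contributing at least two classified blocks, of the proportion of a
study's blocks sharing the study's modal pattern. The null shuffles
pattern labels across those blocks preserving per-study counts; the
p-value is the fraction of permuted statistics at or above the observed
one. Single-block studies are excluded because their modal proportion is
1 by construction and would only dilute the statistic.

## Synthetic data

The generator solves true cell means analytically from target effect
sizes (never rejection-sampling, which would bias scenario difficulty).
With `a = AinA = base_mean`, target plasticity `p`, adaptiveness `s`,
differentiation `d`:

- canalized: `a = m(1+d/2)`, `b = m(1−d/2)`; nonresident means shifted
  by the sub-threshold fraction `p`;
- plastic (perfect/adaptive/steep): resident gap `D = p·a/(1+s)`,
  `b = a − D`, transplants overshoot the other resident mean by `s·D`;
- wrong sign: `D = p·a/(s−1)`, transplants move away from the other
  resident mean.

This geometry makes pair A's plasticity and both adaptiveness scores hit
their targets exactly; pair B's plasticity is the implied `p·a/b`. Exact
equality for both pairs is impossible once the resident means differ,
and `p·a/b > p`, so plastic blocks stay plastic whenever `p > θ`.
Infeasible targets (a nonpositive cell mean, or a score inconsistent
with the requested scenario) raise before any sampling.

Observed means add Gaussian noise with SD = `noise_cv·|true|/√n`; each
cell honestly records that same value as its SE, so the derived
threshold of a noise-free constant-CV dataset equals `noise_cv` exactly.
The generator simulates reported summary statistics, not individual
plants — the pipeline consumes only means/SE/n, so individual-level
features of real data (non-normal trait distributions, within-study
trait correlations, unbalanced designs) are not emulated. Passing tests
therefore demonstrate correctness of the metrics, decision tree,
bootstrap and reporting given summary records; they do not validate the
framework's biological assumptions (e.g. that resident populations sit
at their local optima).

### Defaults as study conditions

`noise_cv = 0.05` and `n_per_cell = 50` are the stated recovery
conditions; `base_mean = 10` is arbitrary and immaterial by scale
invariance (asserted by tests). Per-scenario effect-size defaults were
chosen once for geometric admissibility (all true means positive) with
margins of at least 0.2 from the `θ = 0.53` and `1` boundaries:
no-diff (p=0.1, d=0), differentiated (p=0.1, d=1.2), perfect (p=0.9,
s=0.2), adaptive (p=0.8, s=0.75), steep (p=0.9, s=1.8), wrong sign
(p=0.6, s=3.0). Dataset synthesis draws scenarios from user weights,
trait categories with probabilities 0.508/0.436/0.055 (the three-way
life-history/morphological/physiological composition), and groups blocks
into synthetic studies of size 1 + Poisson(2) (median ≈ 3 traits per
study, range comparable to published syntheses).

## Problem sizes

Test and acceptance runs use 300–2000 synthetic blocks, 200–5000
bootstrap replicates and 2000–10000 permutations — sizes at which
binomial/Monte-Carlo error is far smaller than the asserted margins
while the full suite completes in seconds.

## Known limitations

- The reconstructed standardizers are one consistent reading of a verbal
  description; under them the two block-score conventions coincide, so
  analyses that genuinely need them to differ require a different
  standardizer (swappable in one place in `metrics.py`).
- The reader handles exactly 2×2 blocks; multi-site studies must be
  pre-flattened into site pairs by the user.
- No variance-weighted effect sizes (dispersion enters only through the
  threshold derivation and the bootstrap deviates) and no per-record
  hypothesis testing — categorization is a pure threshold rule.
- The clustering statistic is interpretable but not comparable across
  packages; only its direction (clustered vs not) is meaningful.
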