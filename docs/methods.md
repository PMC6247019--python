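# Methods

This note documents the models, estimators and simulation design behind
`cofit`, the defaults and why they were chosen, and what the synthetic-data
tests do and do not demonstrate about real data.

## Serial-passage fitness estimator

A saturated mariner (Himar1) insertion library is grown for `G` generations
under selection. Insert *i* enters the outgrowth at relative frequency
`N_0` and leaves at `N_f`; the whole population expands by the factor `d`.
The per-insert fitness is

    W = ln(N_f · d / N_0) / ln((1 − N_f) · d / (1 − N_0))

on a scale where neutral = 1. The numerator is the log fold-expansion of
the insert's own lineage; the denominator is the log fold-expansion of
everything else. Under discrete geometric growth (a clone of fitness `W`
multiplies by `2^W` per generation) with an otherwise neutral population
this estimator is exactly consistent, which is what the noise-free recovery
test verifies to 1e-9. The exact algebraic form of the fitness statistic
used with wet-lab data varies between protocols; this expansion-corrected
form is the standard serial-passage choice and is adopted here as a
documented assumption — it is the unique common variant consistent with a
neutral value of 1 and with classification thresholds placed at 0.95/1.05.

Numerical and policy choices:

* **d defaults to `2^G`** but any simulation reports its realized `d`
  (total final abundance over total initial), and that value is preferred:
  it makes the estimator measure fitness relative to the population's
  actual average growth, which matters when beneficial clones expand the
  population beyond `2^G`.
* **Extinct inserts are floored, not dropped.** An insert present at t0 but
  unobserved at t_final is scored at the pseudofrequency
  `N_f = 0.5 / total_tf` and flagged `floored`. Dropping such inserts would
  bias strongly detrimental genes toward neutral. The floor compresses very
  strong defects (a true W of 0.6 may read as ≈0.7 at desk-scale depth);
  this compression is visible in the RMSE oracle and never crosses the 0.95
  classification boundary at default settings. Flooring deliberately breaks
  exact scale invariance of W for the floored inserts only, since the
  pseudofrequency depends on the library total.
* **An insert that swept the library** (`N_f = 1`) is symmetrically floored
  at `1 − 0.5/total_tf`; `N_0 = 1` (a single-insert library) is an error.
* **Replicate handling:** W is computed per insert within each replicate
  library, then the values are pooled (unweighted) into the gene's sample
  before averaging. Pooling per-insert values preserves the sample size for
  the downstream t-tests; which pooling rule real protocols use is rarely
  stated, so this one is fixed and documented.
* **Gene assignment:** an insert belongs to a gene when its TA position
  lies in the gene body, optionally trimmed by `edge_trim · length` at each
  end (default 0 — no trimming, the literal annotated body). Inserts in
  overlapping genes count for all of them (with a warning); intergenic
  inserts are carried through as neutral.

## Gene classification

Genes with at least four observed insertion sites are classified by mean W:
detrimental < 0.95, beneficial > 1.05, neutral otherwise (boundaries
inclusive to neutral, because the outer classes are defined by strict
inequalities). Genes with fewer than four insertions are "apparently
lethal" when longer than 400 bp and "insufficient" otherwise: long genes
without inserts are almost certainly essential, while short genes may
simply lack TA sites. Note that a non-essential gene with very few TA
sites can therefore be misclassified as lethal; at the default simulated
TA density (one site per ~50 bp of gene) this is vanishingly rare for
genes above 400 bp.

## Conditional and strain comparisons

`compare_arms` runs a Welch two-sample t-test on the pooled per-insert W
samples of the two arms and calls a gene significant only when
|ΔW| > 0.05 **and** p < 0.05/m, with m the number of genes actually
testable (≥2 eligible inserts in both arms) in that run. The effect-size
gate reflects the resolution limit of the assay; the Bonferroni denominator
is recomputed per run rather than hard-coded to any particular genome size.
Degenerate cases: two identical constant samples give p = 1 (no evidence of
difference); genes failing the two-insert precondition are reported with
their ΔW, flagged `untestable`, and are never significant. Inserts are the
test unit because they are the only sample that yields the very small
p-values a dense library can support; Welch (unequal variance) is the
conservative default.

`compare_strains` removes the baseline cost of gene disruption by working
with background-corrected deltas (mean W with stressor minus mean W
without, per strain), reports a between-strain Welch t-test on the
stress-arm samples, and flags a gene *degradation-dependent detrimental*
when disruption is significantly detrimental in the degrading wild type
but not in the non-degrading mutant. Genes with no testable stress-arm
sample in one strain are flagged `missing-in-strain` and excluded.

Null behaviour was checked rather than assumed: on all-neutral two-arm
simulations (200 genes × 20 seeds) the per-test size of the Welch test sits
inside the exact binomial 95% interval of the nominal 0.05, and the
combined rule calls zero genes in ≥95% of runs.

## Differential-expression stand-in

The transcriptomics arm needs calibrated (p, log2FC, q) triples, not a
reproduction of any specific published tool, so the test is fully
specified here:

1. library-size normalization by median-of-ratios against the geometric-
   mean reference (genes with a zero anywhere are excluded from the
   reference; if none remain, total-count normalization is the fallback);
2. log2 fold change from normalized group means with a 0.5 pseudocount;
3. per-gene NB dispersion by method of moments from the pooled
   within-group variance, **moderated** toward the across-gene mean with a
   prior weight of 20 residual degrees of freedom and floored at 1e-8;
4. a two-sided Wald test on the difference of log means, with the variance
   of a group mean taken as `(μ + αμ²)/n` and propagated by the delta
   method; the reference distribution is standard normal.

The moderation in step 3 is what keeps the Wald p-values uniform under the
null at triplicate sample sizes: raw per-gene moment estimates carry only
~4 degrees of freedom, which fattens the statistic's tails far beyond
normal. Sharing information across genes (the same reasoning behind
empirical-Bayes dispersion shrinkage in the established DE packages)
restores calibration — measured Kolmogorov–Smirnov distance from uniform
is ≈0.02 at 2000 genes, dispersion 0.05, n = 3 — while preserving power
(a 4-fold spike at mean 200 is recovered at q < 0.01 essentially always).

Significance gating is strict on both sides: |log2FC| > log2(2) and
q < 0.01, with q from Benjamini–Hochberg step-up. Low-expression filtering
keeps genes reaching 1 CPM in at least as many samples as the smallest
condition group.

## Overlap and concordance statistics

The cross-stressor overlap of two contrasts reports (a) the Spearman rank
correlation (average ranks on ties) of log2 fold changes over the **union**
of genes FDR-significant in either contrast — union rather than
intersection retains genes that respond in only one condition, which is
exactly the signal the comparison is about — and (b) the shared-response
fraction: the percentage of genes passing the full fold+FDR gate in
contrast A that pass it in B with the same sign. "Shared" has no unique
definition in the literature; this operationalization is fixed and
documented, and a label-permutation test confirms it falls to the
chance level implied by the set sizes when the contrasts are unrelated.

Concordance labels combine the two arms: a gene whose disruption is
significantly detrimental under the stressor and which is significantly
upregulated is responding *appropriately*; significant downregulation of
such a gene is *counterproductive*; beneficial-disruption genes are
mirrored; everything else is *unclassified*.

## Synthetic-data generator

The generator emulates the statistical structure of a dense mariner
Tn-seq experiment and of triplicate bulk RNA-seq, scaled to desk size.

**Genome and truth.** Random sequence with configurable GC content (GC
controls TA density), tiled with non-overlapping genes separated by
spacers. Default 1000 genes of mean length 550 bp (sd 150, min 150), 15%
intergenic sequence, GC 0.72. These defaults were chosen jointly so the
realized library reproduces the field's benchmark numbers for a dense
mariner library in a high-GC organism — ≈87% site saturation, ≈1 insert
per 56–60 bp, ≈9 inserts per average gene. Fitness effects are a mixture:
8% essential, 10% detrimental (W uniform on 0.6–0.9), 2% beneficial
(W uniform on 1.1–1.3), remainder exactly neutral (W = 1); category counts
are deterministic by default so truth fractions are exact.

**Library.** A fraction `saturation` (default 0.87) of all TA sites
receives an insert, never inside an essential gene. Insert abundances are
symmetric-Dirichlet (concentration 1, i.e. roughly exponential abundance
spread, as observed in real libraries); t0 counts are one multinomial draw
of `depth` reads (default 5×10⁵ — real libraries run into the millions;
the scale-down keeps per-insert counts in the tens so noise remains
realistic while runtimes stay in seconds).

**Outgrowth.** Generations default to a uniform draw on [20, 25]. The t0
counts are treated as a census of the population entering the outgrowth;
lineage *i* multiplies by `2^(W_i·G)`, the realized expansion factor is
reported, and the end point is sequenced as one multinomial draw (or
returned as exact expected frequencies in noiseless mode; the RMSE oracle
quantizes these to integer reads so that extinct inserts floor exactly as
in a noisy run). Optional Dirichlet jitter on the final frequencies adds
extra-multinomial dispersion. Passaging bottlenecks are not modelled
explicitly — no bottleneck schedule is specified for the experiments this
emulates — so their stochastic effect is subsumed in the sequencing draw
plus the optional overdispersion. Multi-arm experiments share one master
library (sites and abundance weights) across arms and replicates, with
independent sequencing draws per (arm, replicate), as when one library is
split across outgrowth flasks.

**Expression.** Baseline means are log-normal (median ≈150 counts), counts
negative binomial with common dispersion 0.05, three replicates per
condition, mild log-normal library-size variation (sd 0.15). A common
responsive gene set (default 25% of genes) carries true log2 responses
`√ρ·shared + √(1−ρ)·private` with effect sd 1.5, so two stressors have
expected response correlation ρ by construction; ρ defaults to 0.6, a
mid-range overlap. Estimated Spearman rho on the union of significant
genes tracks the oracle correlation of the true responses to within ≈0.01
at this setting (mild attenuation from estimation noise is expected and
measured, not assumed).

All randomness flows from one top-level seed through `SeedSequence`
spawning, one substream per stage, so every pipeline run is bit-for-bit
reproducible.

**What the synthetic tests do not show.** The generator has no PCR or
mapping bias, no positional insertion preference beyond TA, no
between-replicate batch structure, no bottleneck drift, and gene-free
random sequence statistics; real libraries violate all of these to some
degree. Passing tests demonstrate that the estimators and decision rules
are correct and calibrated under their stated model, not that any
particular biological dataset satisfies that model.

## Problem sizes used in the validation suite

The automated checks run at the following scales, chosen to keep the whole
suite in the low minutes on one CPU while leaving per-insert counts and
per-gene insert numbers in the realistic range: noise-free recovery on a
201-insert calibration library over the full W × G grid; stochastic
recovery on 20 seeds × 1000 genes at depth 5×10⁵ with two replicates;
null calibration on 20 seeds × 200 genes; the two-strain design on
100 seeds × 80 genes at depth 10⁵; DE calibration on 10 seeds × 2000 genes
and overlap recovery on 20 seeds. `scripts/acceptance.py` re-runs the same
computations at slightly reduced seed counts and prints each quantity with
the problem size it used.
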