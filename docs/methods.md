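# Methods

## Model

A miRNA's activity in a cell or spot is defined operationally: its
catalogued targets are enriched at the low end of that sample's
standardized expression ranking.  The package makes no mechanistic claim
beyond this rank signal — transcription-factor changes or co-regulation
that happen to depress a target set will look like activity.

Counts `c(g, s)` are library-size normalized to a common total per sample
(default 10,000) and standardized per gene with **population** moments
(denominator 1/S, not 1/(S−1)):

    z(g, s) = (c(g, s) − a(g)) / σ(g)

Standardization is relative across samples: a gene repressed equally in
*every* sample contributes nothing (see "universal activity" below).
Genes with σ = 0 are dropped — the transform is undefined for them and a
constant gene carries no ranking information.  Cleaning precedes
normalization: duplicate gene symbols are collapsed keeping the
higher-total row (a deterministic, conservative choice; summing duplicates
is a defensible alternative), all-zero genes are removed, and cells with
bit-identical profiles are deduplicated keeping the first.  Removing cells
with < 1000 reads is available but opt-in, as very shallow cells distort
per-gene moments.  Matrices larger than 10,000 cells are subsampled
(uniformly, or stratified per population for comparative runs) with a
fixed, overridable seed.

## The exact mHG test

For the binary target-membership list λ (length N, K ones) ranked by
ascending z, the statistic is the minimum over all prefix cutoffs n of the
hypergeometric upper tail P(X ≥ b_n), X ~ HG(N, K, n).  Because the
cutoff is optimized, the statistic is not a p-value; the exact p-value is
the fraction of the C(N, K) distinct arrangements of the ones whose
statistic is at least as extreme.

Numerics, chosen for stability at N ~ 20,000 and p ~ 1e-300:

- The p-value DP propagates **path probabilities** rather than path
  counts: `D[b]` is the probability that a uniformly random arrangement
  reaches lattice cell (n, b) without having entered the rejection region.
  All quantities stay in [0, 1] (no overflow), and the p-value accumulates
  as the mass first *entering* the region — a sum of small positives, so
  tiny p-values keep relative accuracy (never computed as 1 − x).
- Rejection-region membership compares tails against the observed
  statistic with relative slack 1e-9, absorbing float round-off when the
  statistic arrives from a different computation route.  The slack is far
  below the spacing of distinct tail values at practical N; exhaustive
  enumeration over all binary lists with N ≤ 10 confirms DP = oracle to
  1e-10 relative.
- The public scalar `hypergeometric_tail` uses exact integer arithmetic
  (math.comb / Fraction), correct to full double precision for any
  desk-scale N; the vectorized internals use a gammaln tail matrix
  (relative error ~1e-11), consistent within themselves.  A per-(N, K)
  `MHGTester` caches the tail matrix so one miRNA tested across thousands
  of cells pays O(NK) once.
- Optional X/L bounds restrict the minimization (prefixes with ≥ X ones,
  cutoffs ≤ L); the plain test over 1..N is the default and the only mode
  used by the pipeline.
- K = 0 (no targets present) returns statistic and p-value exactly 1.
- Ties in z are broken by ascending gene identifier, making results
  deterministic but convention-dependent; determinism under gene- and
  cell-order permutations is covered by tests.

## Scoring modes

- **spatial**: score = fraction of spots with p strictly < 1e-5
  (threshold exposed); descending.
- **total**: score = Benjamini–Hochberg-corrected mean activity p across
  cells; ascending.  The mean of per-cell p-values is a heuristic
  aggregate, not itself a calibrated p-value; a conservative p-value
  merging rule (e.g. 2×mean capped at 1) is a documented alternative for
  users needing exactness.
- **comparative**: two-sided Wilcoxon rank-sum between the two
  populations' activity p-values — normal approximation with midranks and
  tie correction, no continuity correction, degenerate all-tied case
  defined as p = 1 (the mode targets populations ≥ 100 cells, where the
  approximation is accurate) — then BH across miRNAs.  Tiering: a miRNA
  enters tier 1 (tier 2) if its score is < 1e-8 and its per-population
  mean activity level reaches the 0.97 (0.9) across-miRNA quantile in at
  least one population.  The activity level is measured as mean
  −log10 p: the tiering is meant to promote *consistently active* miRNAs,
  and on the raw-p scale the same words would select the least active
  ones; the raw-scale reading remains selectable (`scale="raw"`).
  Quantiles are empirical with linear interpolation.  FDR is
  Benjamini–Hochberg throughout.

## Synthetic data

The generator emulates the input structure the method assumes, not any
particular tissue.  Baseline: per-gene means from a log-normal
(median 5 counts, σ_log = 1) and counts from a negative binomial with
dispersion θ = 10 (variance μ + μ²/θ) — droplet-like overdispersion.
Activity is planted **on the count means**: in planted cells each target's
mean is multiplied by exp(−δ·σ_g/μ_g), so the post-normalization z-shift
is roughly −δ and the entire pipeline, normalization included, is
exercised.  The standard benchmark conditions are δ = 2, 20 targets per
miRNA, 200 planted + 200 background cells.

What passing these benchmarks shows: the pipeline recovers a planted
rank-signal of realistic size and calibrates correctly under a null.  What
it does not show: robustness to batch effects, cell-type structure,
ambient RNA, dropout beyond NB noise, or miRNA target catalogues' biases —
none of which the generator models.

Two constructions deserve notes:

- **Universal activity** (regression scenario): activity present in every
  cell with no globally down-regulated gene — a different small subset
  (5%) of a large (200-gene), well-expressed target set (log-normal mean
  log 50, σ_log 0.3, θ = 50) is strongly repressed (δ = 12, mean
  multiplier ≈ 0.09) in each cell.  The subset must be a minority and the
  targets well expressed: a gene repressed in a fraction q of cells has
  its z bounded by −√((1−q)/q) through mixture-variance inflation, and a
  lowly expressed count gene cannot reach deep negative z at all (the
  zero floor).  Under these conditions the planted miRNA is detected
  (p < 0.01) in ≥ 95% of cells while no single gene separates the cells.
- **Disjoint target sets** (concordance scenario): by default target sets
  are drawn independently and overlap; a miRNA sharing targets with a
  planted one then inherits *real* activity at those shared genes.  Tests
  that need non-planted miRNAs to be genuinely null request disjoint
  sets.

Downsampling is binomial thinning per count, fraction 1 being the
identity.

## Expression/activity agreement

Where miRNA expression is measured independently, agreement is tested by
ranking miRNAs by expression and applying the same mHG machinery to the
active (top end) or non-active (bottom end) calls.  Activity calls use
p < 0.05 (active) and p > 0.1 (non-active), with the in-between band
excluded.  Strand-level calls collapse onto strandless identifiers —
active if any strand is active; non-active only if no strand is active —
and precursor rows (`name-1`, `name-2`, …) are summed into the mature
name before ranking.  Expression ties break by identifier.

## Embedding and figures

Activity maps color samples by −log10 p at their spatial coordinates or
at 2-D embedding coordinates.  The embedding preprocessing contract:
exclude cells with < 200 detected genes and genes seen in < 3 cells, trim
cells below the 2nd / above the 98th percentile of total counts,
normalize to 10,000, log(1+x), select 2000 highly variable genes, 50
principal components, neighborhood graph, UMAP (delegated to scanpy; the
coordinates are treated as opaque).  Figures are artifacts, not
contracts: tests assert creation and coarse content, never pixels.

## Problem sizes used in tests

The suite runs entirely on synthetic data sized for a single CPU: unit
fixtures of tens of genes; benchmark datasets of 200–1000 genes and
40–400 cells; 20 seeds for recovery rates, 50 for null calibration; the
exhaustive DP-vs-enumeration check covers every binary list with N ≤ 10.
The printed-parameter validation configurations run at their true sizes
(N up to 1462, B up to 740).

## Known limitations

Symbol-level target matching only (no alias resolution, documented
failure mode for catalogues using synonyms); activity of miRNAs whose
targets are unexpressed or near-constant is undetectable by construction;
the total-mode score inherits the non-calibration of averaged p-values;
comparative mode supports exactly two populations; p-values below ~1e-308
underflow to the smallest positive double.
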