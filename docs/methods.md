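# Methods

This note documents the models, estimators and numerical choices behind
`mirdel`, what the synthetic-data generator does and does not emulate, and
the known limitations.

## Study design being modelled

A case/control small RNA-seq comparison in which every case carries the
same hemizygous deletion. Under simple dosage, miRNA genes inside the
deleted interval are expressed at ~50% in cases; miRNAs elsewhere may also
shift through trans effects (in the motivating 22q11.2 system, via
haploinsufficiency of the biogenesis factor *DGCR8*). The default study
conditions mirror the motivating dataset: 9 control and 7 case libraries,
single-end 50 nt reads, the NEBNext 3′ adapter `TGGAATTCTCGGGTGCCAAGG`,
~7% of reads without adapter, and a 15–35 nt usable-insert range.

## Synthetic data generator

`build_toy_reference` creates a two-contig genome (30 kb each by default)
and plants randomly generated hairpins (70–110 nt) at non-overlapping loci
on either strand; mature miRNAs are 21–23 nt sub-intervals with ≥4 nt
flanks. Mature length is kept ≥21 nt so that even the shortest −3/−3
isomiR insert (15 nt) survives the length filter — a deliberate choice
that makes exact count recovery achievable on error-free data; real
miRBase matures as short as 18 nt would shed their extreme isomiRs at the
filter. By default 20% of hairpins (5 of 25) fall inside the deletion
interval. The remaining space is tiled with gene features
(protein_coding / lincRNA / snoRNA / tRNA / rRNA / intergenic) from which
background reads are drawn.

`simulate_counts` draws per-miRNA means log-normally
(location ln 400, scale 1.2 — spanning the orders of magnitude typical of
miRNA-seq), per-library size factors log-normally (σ = 0.15), and counts
from NB(s_j·µ_i·fold_ij, α) with variance µ + αµ². The default dispersion
is α = 0.03: libraries here are replicate clonal iPSC-derived cultures,
whose extra-Poisson CV (~17%) sits well below that of heterogeneous tissue
cohorts. `α = 0` degenerates to Poisson.

`synthesize_reads` inverts the read-processing chain: mature sequence ±
independently sampled 5′/3′ offsets (70% at 0, 12% at ±1, 2.5% at ±2,
0.5% at ±3), substitution errors (0.2%/base), 3′ adapter appended (except
for the 7% adapterless fraction), padded with 'A' / truncated to 50 nt.
Qualities are constant 'I' (the pipeline never uses them). Background
fragments (15% of reads, 15–35 nt, either strand) come from gene features.
Every read carries a provenance record.

Not emulated: ligation/sequence-composition biases, position-dependent
error profiles, indels, UMIs, multi-mapping paralog families with shared
seeds, and isomiR composition differences between groups (the offset
distribution is global — the motivating study gives no group-specific
isomiR information). Passing tests therefore demonstrate correctness of
the *rules* (trimming, end-tolerance assignment, cross-mapping
resolution, NB inference), not robustness to those real-data artefacts.

## Quantification rules

* Trimming: leftmost position where a prefix of the adapter (truncated at
  the read's 3′ end, ≥6 nt) matches with ≤10% mismatches. The named
  parameters are not published for the original analysis; 6/0.1 makes the
  boundary examples deterministic.
* Length filter: 15–35 nt inclusive. Reads without adapter are retained
  through the filter; at 50 nt read length they necessarily fail it and
  are tallied as `adapterless`.
* Alignment: exhaustive ungapped scan at every offset, ≤1 substitution,
  ambiguous bases count as mismatches. Hairpins are scanned sense-only
  (matures are strand-specific); the genome on both strands. The
  production path runs the same scan vectorized over a concatenated target
  text (windows spanning target boundaries are rejected), with an exact
  substring fast path; a naive per-offset Hamming oracle pins the
  semantics in the tests.
* Assignment: a read maps to a mature iff |5′ offset| ≤ 3 **and**
  |3′ offset| ≤ 3, exact ends included (a rule excluding offset 0 would
  discard the canonical read). Among qualifying matures the smallest
  |off5|+|off3| wins, with mismatch count as the primary key across
  hairpins; exact ties are discarded (`ambiguous`) to keep counts
  integral.
* Cross-mapping: a hairpin-assigned read becomes non-miRNA only if its
  best genome hit outside every hairpin locus has *strictly fewer*
  mismatches; ties keep the miRNA. A perfect hairpin hit therefore never
  needs the genome pass (nothing can beat 0 mismatches) — an equivalence
  the pipeline exploits.
* Categorization: among minimum-mismatch genome hits, overlapping features
  (≥1 bp) contribute categories with precedence snoRNA > tRNA > rRNA >
  lincRNA > protein_coding > intergenic; unannotated hits are intergenic,
  no hit is unmapped. The fate classes (adapterless, length_filtered,
  miRNA, ambiguous, the categories, unmapped) partition every read.

## Differential expression

Size factors are the median across no-zero-count miRNAs of the ratio of a
sample's count to the row geometric mean. Dispersion:
α̂_i = max(0, (pooled within-group variance − µ_i)/µ_i²), a least-squares
trend α(µ) = a₁/µ + a₀ over positive α̂, and the final α is the average of
the two (simple moderation; zero-mean rows fall back to the trend).
The Wald statistic divides log2(m̄_ctrl/m̄_case) by a delta-method SE with
Var(m̄_g) = µΣ_j s_j⁻¹/n_g² + αµ²/n_g; p-values are two-sided normal
tails. A pseudo-mean of 0.5 enters only when a group mean is exactly zero.
All-zero miRNAs are dropped before testing, so BH uses m = number tested.

Numerical/calibration notes, measured in the test suite:

* Under the null (2000 miRNAs, 9 vs 7, α = 0.1) the empirical type-I rate
  at p < 0.01 is ≈0.016: normal rather than t(≈14) tails plus
  moment-estimated dispersion make the test mildly anticonservative at
  this sample size. This is inherent to the prescribed statistic, not a
  bug; genome-wide claims rest on the BH-adjusted values.
* Scaling one library by c rescales *all* normalized counts by the common
  factor c^(1/n), so log2FC is exactly scale-invariant; z and p are not
  exactly invariant because the Poisson part of the variance
  (the µ and (V−µ) terms) is not scale-free. The drift is O(c^(1/n)−1)
  and negligible for deep libraries.
* With 20% of the miRNAome deleted (the 25-miRNA default toy),
  median-of-ratios normalization absorbs ~10% of the deletion effect —
  a real property of ratio-based normalization under global shifts. Power
  analyses therefore use a sparse-DE configuration (5 affected among 100)
  matching the motivating study's regime (45 DE of ~1.8×10³ tested), where
  the attenuation is negligible.

The published per-miRNA table is internally BH-consistent: the top
(p, p_adj) pair implies m ≈ 1.8×10³ tests, and the step-up with that m
reproduces the six genome-wide-significant adjusted values to printed
precision. Ranks of the lower rows interleave with unprinted miRNAs and
are not recoverable, so only the consecutive top ranks are checked.

## Region enrichment

Expressed = mean RPM ≥ 1 (closed boundary), RPM per sample being
count·10⁶/assigned-miRNA-total. Membership in the deletion interval uses
the locus midpoint (avoids edge-straddling). Fisher's exact test is
computed by direct enumeration of the hypergeometric support with
log-gamma pmf evaluations; one-sided = P(X ≥ a), two-sided = total
probability of outcomes no more likely than observed. On the published
5/0/1/40 table the one-sided p is 6/C(46,5) ≈ 4.38×10⁻⁶; the ~2×10⁻⁶
reported for that comparison is not derivable from the stated cells (the
original table construction is ambiguous), and no agreement is forced.
The default interval chr22:18,500,000–21,900,000 approximates the ~3 Mb
deletion; it is configurable because the endpoints are not published.

## GO networks

The enrichment universe defaults to all annotated genes (the original
tools' backgrounds are unpublished; configurable). EASE is implemented as
the published DAVID variant — the overlap cell decremented by one with
margins unchanged — so p_EASE ≥ p_Fisher always. Brain-term selection is a
case-insensitive keyword list (neuro, neuron, brain, synap, axon, dendrit,
glia) — configuration, not a constant, since the original selection
criteria are unstated. Term-term edges require overlap coefficient
strictly > 0.5; term grouping is consumed as a two-column input map. SIF
output is canonically sorted, so identical inputs give identical bytes.

## qPCR and cohort statistics

ΔCt normalizes the target Ct (replicate mean) against the arithmetic mean
of the two normalizer Cts (equivalent to the geometric mean of their
linear quantities at efficiency 2); ΔΔCt contrasts group-mean ΔCt values
and fold = 2^−ΔΔCt, so swapping groups inverts the fold exactly.
Per-sample folds (referenced to the reference-group mean ΔCt) feed the
pooled t-test; both the per-sample-fold SD and the ΔCt SD are reported,
since error bars in such figures can be either. One-tailed p is reported
in the observed direction (half the two-tailed value). Cohort summaries
use the n−1 SD and round only at presentation.

## Problem sizes

The test suite simulates at desk scale by design: the round-trip check
uses 10 libraries × 50 miRNAs (~2×10⁵ reads), null calibration 2000
miRNAs, power analysis 20 seeds × 100 miRNAs. These sizes give the stated
statistical resolutions (binomial CI on a 0.01 rate needs ≥10³ tests; the
round-trip is exact regardless of scale) while keeping the full suite
under a minute of simulation time.

## Limitations

* The Wald test is a deliberately simple NB inference; it does not
  reproduce any specific tool's shrinkage, outlier handling or exact
  p-values, and full-scale re-analysis of the original libraries is out of
  scope.
* The aligner is ungapped with ≤1 substitution; indel-bearing reads are
  lost (consistent with the quantification rules being modelled).
* Multi-mapping across identical mature sequences on different hairpins is
  resolved by discarding exact ties rather than fractional counting.
* The generator's background model is uniform over feature intervals; real
  non-miRNA content (degradation products, abundant structural RNAs) is
  far more skewed.
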