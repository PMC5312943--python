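# Methods

## The model and its assumptions

The pipeline treats macronuclear development as a replicated time-course
contrast problem. Abundances x (FPKM or TPM) are analyzed on the
log2(x + 1) scale; the +1 pseudocount makes zero abundance map to zero and
stabilizes low-expression genes. Relative expression is defined against the
mean of the 0-hour (just-mixed) samples, so 0 h is a built-in control with
mean zero per gene and is never eligible as an expression peak.

A gene is *development-specific* when, for some developmental condition
c ∈ {6h, 12h, 24h, 48h, 72h},

    mean_rel(c) ≥ log2(fold) + max(0, mean_rel(veg)),     fold = 3 by default

i.e. the condition mean must exceed both controls (0 h and vegetative) by
the fold threshold on the log scale. Evaluating the 3-fold rule on the
log2(x+1) scale, after the transform, follows the order of operations of the
procedure being implemented; a raw-ratio variant
(`classify_preferential_raw`) is provided as a config alternative. Peak ties
break to the earliest time point, which makes calls reproducible under
column reordering. The FPKM quality filter is inclusive (max ≥ 3), the
micronuclear TPM variant strict (max > 3); the two rules are deliberately
different.

## Co-expression modules

The network is the signed weighted adjacency a_ij = ((1 + r_ij)/2)^β,
β = 22, with unsigned topological overlap as the clustering similarity:

    TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)

Module detection is a *static* cut of the average-linkage tree of 1 − TOM,
with the cut expressed as a fraction of the maximal merge height (default
0.995) and a minimum module size of 50; branches below the size floor are
left unassigned (label 0). The dynamic hybrid tree cut of the reference R
implementation is intentionally not reproduced: its depth-split behavior is
underdetermined here, and the quantity this module is accountable for is
recovery of planted temporal structure, not label-for-label equivalence
with another implementation. No post-hoc gene reassignment is performed
(equivalent to a reassignment threshold of 0).

Eigengenes are the first principal component of the per-gene standardized
module submatrix, sign-oriented to correlate positively with the module mean
profile. Merging is iterative: the most correlated qualifying pair
(eigengene r ≥ 1 − 0.25) merges first, eigengenes are recomputed, and the
process repeats to a fixed point; the canonical pair ordering makes merging
deterministic.

The vegetative-variability removal rule is a bespoke formalization of a
qualitative screening step: a module is removed when its member-median
relative expression differs between the two vegetative replicates by more
than δ = 1.5 log2 units *and* is positive in exactly one replicate — the
signature of an apparent induction driven by a single vegetative sample.
δ is a config parameter; 1.5 log2 units (≈ 3-fold) matches the scale of the
classifier's own fold threshold.

Modules are ranked by the peak developmental condition of their mean
profile (ties: larger module first); within modules, genes are ordered by
average-linkage clustering under the centered-Pearson distance (1 − r).

## Enrichment

Over-representation uses the upper tail P(X ≥ k) of the hypergeometric
distribution (the convention that reproduces the printed bounds; a density
alone cannot), summed from gammaln-based log-pmf terms with logsumexp so
that p-values below double-precision underflow remain exact on the log
scale. BH correction is applied within each term class (GO / domain /
curated) because the classes are tested as separate analyses; k = 0 terms
are retained at p = 1 so the BH denominator is well-defined. Comparisons
against published bounds use raw p-values with draw size n = 1162.

## Orthogroup logic

Orthogroups are consumed as tables (inference is out of scope). Oversize
means ≥ 20 focal-species members (the strict reading of "fewer than 20").
The class partition {all_specific, mixed, none, excluded_oversize} covers
every orthogroup, including those with a single focal member, so counts are
conservation-checkable; the *considered* summary count defaults to groups
with ≥ 2 focal members (`require_paralogs=True`), since paralog divergence
is only defined for paralogous sets and that choice matches the reported
scale of ~2.2k considered groups. Focal genes absent from the call set
(below the quality filter) count as non-specific and are tallied.

Comparator microarray pipelines: probes collapse to genes by geometric mean
(arithmetic mean in log space), then log2; genes below the platform floor
(log2 intensity 7 for the first comparator, 9 for the second) in **all**
experiments are removed; normalization subtracts the mean of that platform's
control conditions (starvation for the first, vegetative for the second);
the 3-fold rule then requires each control to be exceeded independently.

Cross-species intersection counts orthogroups with ≥ 1 focal-specific and
≥ 1 comparator-specific member; with two comparators the union is asserted
to satisfy inclusion–exclusion. Recently acquired genes are focal-specific
genes whose orthogroup has a sister-species member and no member in any
excluded species; singletons cannot qualify.

Duplication epochs: the duplication node is the gene-tree MRCA of the focal
paralogs (trees are treated as rooted; polytomies and single-paralog cases
return "unresolved"). The epoch is the species-tree branch above the LCA of
the union of species observed in the two child clades, reported as "after
divergence from ⟨nearest outgroup⟩, before divergence of ⟨clade⟩". No
duplication–loss reconciliation or molecular dating is attempted.

## Motifs

Flanks are ≤ 500 nt adjacent to the CDS on the coding strand, truncated at
record ends, at overlapping annotated CDSs (keeping the CDS-proximal
portion) and at terminal telomeric repeat runs (C4A4/G4T4 units); flanks
< 80 nt are dropped. Coordinates are 0-based half-open.

The external motif finder is not reimplemented. Instead, every k-mer
(k = 8–12), canonicalized over strands, is scored by per-sequence presence
(ZOOPS: one count per sequence regardless of occurrences, matching
"found in m of n promoters" phrasing) with an upper-tail hypergeometric test
of foreground hits against the pooled population, threshold 1e-11. K-mers
whose foreground count is too small to reach the threshold even with zero
background hits are pruned before scoring — a pure optimization with a
provably identical reported set. Reported motifs pass a greedy redundancy
collapse: of two k-mers sharing ≥ min(k) − 2 aligned identical positions at
any offset/orientation, only the lower-p one is kept, so the reported
representative of a planted motif may be a sub-k-mer or the opposite-strand
form.

Positional statistics use the distance from the motif start to the
CDS-proximal flank end (nt upstream of the translation start, for upstream
flanks), one most-proximal occurrence per sequence, compared between
foreground and background by a two-sided two-sample K-S test. Conservation
in ortholog flanks is tested against an upper-tail binomial at a supplied
background occurrence rate — the population of the corresponding published
hypergeometric test is unstated, and a binomial at the stated background
rate is the well-defined null available from the printed quantities.

## Tissue projection

log2(x + 1), per-gene mean-centering across samples, then per-site sample
means, in that order. The published shift detection is visual; here a site
is flagged when the projected set's median at that site exceeds the pooled
median of all other sites by 0.5 log2 units with a two-sided Mann–Whitney
p < 0.01 — a bespoke formalization with both knobs in config. Tissue
specificity requires a site's centered value to exceed every other site by
> 1 log2 unit (strict), which forces at most one site per gene.

## Synthetic data: what it emulates and what it does not

The time-course generator reproduces the 14-sample design (two replicates of
vegetative and 0/6/12/24/48/72 h). Genes carry a constant log2 baseline
(Normal(3, 1.5), clipped ≥ 0.5); planted module genes add log2(induction
fold) at their peak condition; samples add Normal(0, noise_sd = 0.3) noise
on the log2(x+1) scale before back-transforming and clipping at zero —
log-normal abundance noise on the pipeline's working scale. Defaults
(8-fold induction, noise 0.3, 60-gene modules) were chosen once as a
realistic strong-induction regime: developmental inductions in this system
routinely exceed an order of magnitude, and 0.3 log2 units is a typical
replicate-to-replicate spread for well-measured genes.

The generators do **not** emulate: count noise or mean–variance
relationships of sequencing data, library-size artifacts, temporal
autocorrelation between adjacent time points (planted modules peak at a
single condition), sequence composition beyond i.i.d. nucleotides at a set
GC (default 0.30, reflecting an AT-rich genome), or micronuclear genome
architecture. Passing the planted-recovery benchmarks therefore shows the
algorithms are correct and well-calibrated on data satisfying their own
assumptions — not that the biological module boundaries of any real dataset
would be reproduced.

Orthogroup class allocation is deterministic (largest-remainder counts; the
first k groups get class c), so planted truth counts are exact by
construction and recovery tests are sharp.

## Numerical choices and degenerate inputs

- Hypergeometric tails: log-space summation; k = 0 returns exactly 1.
- Correlations clip to [−1, 1] before powering; zero-variance genes are
  dropped from the network with a warning (they have no defined correlation).
- TOM is symmetrized and clipped to [0, 1]; isolated node pairs (zero
  connectivity) get TOM 0 rather than NaN.
- Tie-breaks: classifier peak → earliest time point; module renumbering →
  size then label; temporal rank → peak index, then size, then label;
  merging → highest eigengene correlation, then canonical label pair.
- All generators use `numpy.random.default_rng` seeded explicitly; the
  pipeline derives per-stage seeds from one root seed (kept below 2^31).
- Problem sizes in tests and the demo (hundreds of genes, hundreds-to-
  thousands of promoters, ≤ 10 seeds per Monte-Carlo check) were chosen as
  the smallest scales at which the planted effects are comfortably
  identifiable; the statistical conclusions do not depend on scaling up.

## Known limitations

- Module boundaries from the static tree cut need not match dynamic-cut
  implementations on borderline branches; only planted-structure recovery is
  claimed.
- The k-mer stage cannot represent gapped or strongly degenerate motifs;
  IUPAC degeneracy appears only in reporting and in the optional one-mismatch
  scan.
- The exact hypergeometric test is conservative for small term sizes
  (discreteness); null calibration approaches the nominal 5% only when
  counts are large enough for the tail distribution to be near-continuous.
- The vegetative-variability flag and the tissue ECDF shift rule are
  formalizations of qualitative published criteria; their thresholds
  (δ = 1.5, shift 0.5 / p < 0.01) are config, not ground truth.
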