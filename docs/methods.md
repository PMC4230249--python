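# Methods

## Scope and data model

The package re-implements the analysis stages of an SSR-based linkage-map
and BAC-library characterization project for yellowtail: genotype handling
and backcross conversion for one outbred F1 family, two-point linkage
analysis per parent, genome-length/coverage estimation from map summaries,
SSR mining from masked end-reads, and BLAST-tabular orthology filtering
into Oxford grids.  Raw study genotypes are not distributed, so the
pipeline runs on (a) synthetic data from generators that expose their
ground truth and (b) the published per-linkage-group summary rows embedded
in `seriomap.published`.

## Pseudo-testcross model

One dam × sire family with default 90 progeny.  Grandparents are unknown,
so linkage phase is unknown: each marker heterozygous in a parent is
converted to backcross format by deducing which of that parent's two
alleles each progeny inherited.  The code "A" is assigned to the
lexicographically first parental allele — an arbitrary per-marker choice —
and all downstream statistics are therefore phase-folded: the recombinant
count for a pair is min(r, n−r).  Calls whose parental origin is
undecidable (both parents share the relevant alleles, e.g. a/b × a/b
progeny a/b) and Mendelian-inconsistent calls become missing.

Segregation is tested per marker with the 1-d.f. goodness-of-fit
chi-square against 1:1, no continuity correction, flagged at p < 0.05.
Under null simulations the flag rate is calibrated (≈5%); the test suite
asserts this within the binomial 3σ band.

## Two-point analysis and map assembly

* **LOD**: standard backcross statistic at the folded MLE θ̂ = r/n, with the
  θ̂ = 0 limit n·log₁₀2 and LOD ≡ 0 at θ̂ = 0.5.  An all-pairs matrix engine
  (integer matrix products over presence/code indicators) makes the ~240k
  pairs of a 700-marker map instantaneous; scalar and matrix paths are
  cross-checked in tests.
* **Grouping**: connected components (single-linkage closure) of the
  LOD ≥ threshold graph, threshold 4.0.  Raising the threshold can only
  refine the partition (tested property).  At 90 meioses the per-pair
  false-linkage probability at LOD 4 is ~1×10⁻⁵ (exact binomial tail), so
  a ~240k-pair experiment occasionally produces one spurious chromosome
  merge; this is inherent to the threshold, not to the implementation.
* **Ordering objective**: the total count of recombination events summed
  over adjacent intervals.  Exhaustive search up to 8 markers; above that,
  nearest-neighbour chains from every start (the best three refined for
  large groups), 2-opt reversals plus or-opt relocations of 1–3-marker
  segments (including reversed insertion), and deterministic double-bridge
  restarts for groups of ≤ 16 markers.  Ties on the objective — ubiquitous
  among co-segregating or very tight markers — are broken lexicographically
  by the count over gap-2 pairs, which orients tied blocks using flanking
  information.  Orientation is normalized so the lexicographically smaller
  terminal marker comes first.  The heuristic attains the
  exhaustive-permutation minimum on 200 random ≤ 8-marker instances in the
  acceptance suite.  A caveat established during validation: at n = 90 the
  minimum-recombination order of a 29-marker group frequently has a
  *lower* objective than the true order — the objective overfits sampling
  noise — so local inversions of markers ~1–2 cM apart are statistically
  unavoidable regardless of the optimizer.
* **Double-recombinant checking**: a transmission code differing from both
  flanking informative codes in map order implies two crossovers in a short
  interval, at dense spacing almost always a genotyping error.  These
  events are counted per ordered group, and the map-building pipeline also
  *acts* on them: singleton flips are blanked, the group re-ordered and
  distances re-estimated.  Without this filter a 0.5% genotyping-error rate
  inflates every adjacent θ̂ by ~2 error probabilities and the summed map
  length by >50%; with it, simulated map length is recovered within ~5%.
  The cost is that genuine tight double crossovers (rare under the
  simulated no-interference model, rarer under interference) are also
  removed, giving a small downward bias.
* **Distances**: adjacent two-point θ̂ through the Kosambi function
  d = 25·ln[(1+2θ)/(1−2θ)]; θ̂ is capped at 0.49 before conversion, and
  markers with no informative pairing are placed at the cap with a warning.
  Co-segregating markers share a position; the first marker at each
  distinct position carries the framework flag (one representative per
  resolvable position).  No multipoint re-estimation is attempted — the
  pipeline is strictly pairwise.

## Genome length and coverage

From per-group rows (n markers, m framework markers, observed length):

* average framework interval d = Σ length / Σ(m − 1) (a group with m
  framework markers contributes m − 1 intervals);
* L1: per group length + 2d, summed;
* L2: per group length × (m+1)/(m−1) for m ≥ 2; groups with m ≤ 1
  contribute their observed length unchanged (the only reading consistent
  with a published single-framework group printing L2 = 0.00);
* coverage c = 1 − e^(−2dn/L) with n the total framework count.

Both d's denominator and coverage's n use **framework** markers: feeding
the published rows back through the formulas reproduces the printed
averages (4.96/4.32 cM), totals (1,274.64/1,284.34 and
1,282.35/1,285.45 cM) and coverages (83.56%/83.88%) to within ±0.02,
whereas all-marker counts do not (they would put coverage at ~99.6%).
Computation is at full precision with 2-decimal rounding on output only;
reproduction tolerance is ±0.02 because whether the published totals were
summed from rounded or unrounded per-group values is unknowable.

Library arithmetic: clones-with-insert = round(rate × clones); total insert
= clones-with-insert × mean insert; fold coverage relative to the genome
size from the flow-cytometry C-value at 978 Mbp/pg.  Fold coverage is
reported both raw (16.1×) and rounded (16×).

## SSR mining

Reads are pre-masked (N/lowercase); qualification keeps reads with more
than 100 unmasked bases.  The scanner reports all maximal perfect tandem
repeats of primitive 1–10 bp units with at least `min_copies` full copies
(default 7, reading "over six repeats" strictly; the threshold is an
argument so ≥ 6 is one call away).  Masked bases break arrays; compound
SSRs are reported as separate adjacent motifs; partial trailing copies are
not counted and spans cover full copies only.  Units are named canonically
as the smallest rotation over both strands, making the tally
strand-invariant.  Coordinates are 0-based half-open internally and
1-based inclusive in the TSV writer.  Marker selection takes the longest
motif per read (ties leftmost) and prefers the SP6 read of each clone,
falling back to T7.

## Orthology and Oxford grids

Tabular 12-column hits are parsed with coordinate normalization (reversed
query coordinates flagged).  Two distinct filters exist and are *not*
composed: overlap deduplication (keep the most significant hit of each
overlapping cluster — the general homology-survey rule) and the orthology
acceptance rule (sort by e-value, examine ranks 1–3; if rank 2 or 3
overlaps rank 1 on the query with ≥ 1 shared base and e₁/e_k > 10⁻³, the
pair is unclear and rejected; only rank 1 can ever be accepted).  Zero
e-values are floored at 10⁻¹⁸⁰ before ratios.  Accepted assignments are
counted per linkage group × chromosome with natural label ordering;
highlighting is strict (> 10 red, > 7 yellow, > 5 blue), and relationship
classification (one-to-one, one-to-two) uses the > 5 cutoff by default,
configurable.

## Synthetic-data generators

* **Cross**: 24 chromosomes with lengths drawn U(40, 60) cM (matching the
  published per-group averages of ~41 cM) or supplied explicitly; 29
  markers per chromosome placed uniformly (or at supplied positions); 90
  progeny.  Meioses follow a no-interference model: a Bernoulli(½) start
  haplotype and switches between adjacent markers with Haldane
  recombination probabilities — equivalent to a Poisson crossover process.
  Genotyping error flips each parental transmission independently at
  `error_rate`; calls are blanked at `missing_rate`; an informativeness mix
  can make markers dam-only/sire-only informative.  Truth retains marker
  positions, chromosome assignments and pre-error transmissions.  Because
  the simulator is interference-free while maps are reported in Kosambi cM,
  recovery comparisons convert true adjacent Haldane intervals through the
  Kosambi function — like-for-like on the estimator's scale.  Interference
  itself is not simulated; planted SSR/hit generators likewise idealize
  real data (perfect repeats, i.i.d. composition, exactly engineered decoy
  ratios), so passing tests demonstrate correctness of the *procedures*,
  not robustness to artefacts these idealizations exclude (indel-containing
  repeat arrays, compositional heterogeneity, paralogy structure).
* **Reads**: i.i.d. bases at the target GC (41.36% default, 620 bp reads);
  planted perfect arrays are placed interior with flanking bases forced to
  break the repeat period, so planted coordinates are exact; optional
  scrubbing removes chance background arrays at ≥ 6 copies, making the
  planted catalogue the complete motif truth; optional short reads exercise
  the qualification rule.
* **Hits**: each marker gets a rank-1 hit on its group's true chromosome
  (two-chromosome groups alternate, a synthetic fusion); engineered decoys
  either trigger rejection (overlapping, e₁/e₂ ∈ (10⁻³, 1]) or pass
  (ratio ≤ 10⁻⁴), with intended outcomes recorded.

All generators are deterministic under a single seed fanned out to
substreams; every recovery test consumes stored truth rather than
re-deriving it.

## Problem sizes and numerical choices

The study-scale simulation used throughout (24 × 29 markers, 90 progeny,
0.5% error, 2% missing) runs the full pipeline in seconds; null
calibration uses 2,000 independent markers; oracle comparisons use 200
random ordering instances and 1,000 random hit sets.  Seeds are fixed in
tests and exposed as `--seed` in the analysis drivers.  Degenerate inputs
error loudly (no informative progeny, zero framework intervals,
non-positive coverage inputs) or degrade with warnings (markers with no
informative pairing, unmapped markers in grids, malformed BLAST lines).

## Known limitations

* Framework-marker status has no operational definition beyond position
  uniqueness here; published framework counts are always taken as input for
  the summary statistics, never recomputed from genotypes.
* Grouping is single-linkage; a single borderline LOD-4 pair can merge two
  chromosomes (~once per few runs at study scale).  No automatic
  split/inspection step is provided.
* Strictly pairwise: no multipoint likelihood, no interference-aware
  distances, no sex-averaged map.
* The orthology stage consumes BLAST tabular output; it does not run
  BLAST, handle unplaced scaffolds specially, or require subject-side
  overlap in deduplication (query-side only).
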