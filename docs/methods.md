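# Methods

## Model and procedure

### Superset re-calling

Peak callers applied per library are deliberately conservative, so a genuine
but weak accessible region may be called in one library and missed in
another; naive per-library peak lists then overstate between-library
differences. `chromdyn` instead treats the union of *all* libraries' peak
calls as the candidate locus set ("superset") and re-quantifies each locus in
each library. Merging fuses overlapping **and book-ended** intervals: a
contiguous accessible region is one re-call unit, which makes locus counts
reproducible under arbitrary sub-splitting of the input peaks.

Coverage is normalized per library to reads-per-ten-million: the track is
multiplied by 10⁷ / total_unique_reads before quantification. "Tag density"
of a locus is defined as the **mean per-base scaled coverage** over the locus
(normalized units per bp). This definition is length-independent and agrees
with the per-base "read density" used in pileups; the original open/closed
threshold θ = 0.2734 was published without a unit definition, so θ is exposed
as a parameter and the density definition is recorded in output metadata.
A density exactly equal to θ is called **open** (θ is a minimum threshold);
the tie rule is fixed for determinism.

The same normalization is applied to any track handed to the pileup code
(ATAC or CUT&RUN); the choice is recorded in output metadata rather than
hard-coded per assay.

### Dynamics classification

Within one condition, replicate libraries of a (condition, timepoint) cell
are merged by averaging their scaled tracks — equivalently their density
columns, since density is linear in the signal. Each locus's open/closed
trajectory over the three ordered timepoints maps to a class:

| pattern (D0 D1 D3) | label | notes |
|---|---|---|
| 0 1 1 | CO1 | opens at the first post-initial timepoint, stays open |
| 0 0 1 | CO2 | opens only at the final timepoint |
| 1 0 0 | OC1 | closes early |
| 1 1 0 | OC2 | closes late |
| 1 1 1 | PO / PO_UP / PO_DOWN | split by Δ, below |
| 0 0 0 | PC | persistently closed |
| 0 1 0, 1 0 1 | COMPLEX | non-monotone |

The early/late subgroup rules (CO1 = opens early and stays open, CO2 = opens
only at the end, mirrored for OC) are the minimal monotone reading of
"subdivided by the day of opening/closing"; non-monotone patterns get an
explicit COMPLEX label rather than being forced into CO/OC, keeping those
classes semantically clean. PC loci are retained in outputs but are expected
to be excluded from CO/OC/PO-style figures. Classification is exhaustive and
mutually exclusive by construction, and is defined for exactly three
timepoints; generalizations would need new subgroup rules.

Persistently open loci are subdivided by
Δ = log₂((d_last + ε) / (d_first + ε)) with pseudocount ε = 0.01 normalized
units: Δ ≥ `fc_threshold` → PO_UP, Δ ≤ −`fc_threshold` → PO_DOWN, else PO.
The direction of the subdivision is given by the source analysis but no
magnitude was published; the default `fc_threshold` = 1.0 (two-fold) is a
package choice exposed as a flag. Equality at the threshold counts as
changed; the additional strict-sign clause (Δ must be nonzero) only matters
at `fc_threshold` = 0 and guarantees Δ = 0 is always plain PO.

Condition comparison is per class by locus identity on the one shared
superset (a shared superset is what makes locus-identity Venn counts
well-defined): `shared` counts loci carrying the class in both conditions,
`unique` by set difference.

### Co-binding and expression coupling

Two binding-site sets are each merged, then overlapped with a ≥1 bp criterion
(the minimum overlap is a flag). The result is A-centric — the fraction of
A loci touching any B locus — and the B-centric count is obtained by swapping
arguments. The A loci that touch B form the "shared" (co-bound) locus set
used downstream.

Locus-to-gene assignment links gene g to locus p iff the distance from g's
TSS to the nearest base of p is ≤ the window (10 kb default for gene
assignment, 5 kb for co-binding presence). Distance is to the nearest
*covered base*: 0 inside the locus, `start − tss` to the left,
`tss − (end − 1)` to the right of the half-open interval. Accessibility is
unstranded, so strand plays no role in windows; it is retained on genes for
reporting only. The TSS (not the gene body) anchors both windows, keeping the
5 kb presence rule consistent with the 10 kb assignment rule.

Genes are ranked by log₂ fold change descending, ties broken by gene id for
determinism, and the 0/1 co-binding indicator is smoothed with a centered
moving average of `window_genes` (odd; default 101) genes, **truncated** at
the edges — every reported value is a genuine mean of observed indicators,
never padded. Truncation preserves an exact reversal symmetry: smoothing a
reversed indicator equals reversing the smoothed profile.

Pileups center each locus window on the integer midpoint
⌊(start + end)/2⌋ with a fixed ±flank (default 2,000 bp) in `bin_size`
(default 50 bp) bins; each bin holds the mean per-base coverage, bases
beyond contig bounds contribute zero, and the profile is the unweighted mean
over loci. Replicate tracks are averaged (after scaling) before profiling,
consistent with replicate merging elsewhere.

## Synthetic data

The simulator emulates the statistical skeleton of a 3-timepoint
(D0/D1/D3), two-condition (WT/KO) accessibility study:

- **Loci.** Seven classes (CO1, CO2, OC1, OC2, PO, PO_UP, PO_DOWN) ×
  `n_per_class` (default 500) loci of 400 bp, placed by rejection sampling on
  the configured contigs with ≥1 kb gaps (so superset merging preserves locus
  identity exactly). PC loci are not planted: a never-open locus enters no
  peak list and cannot reach the superset.
- **Densities.** Each class fixes a per-timepoint mean density pattern built
  from `open_density_mean` = 1.0 and `closed_density_mean` = 0.05 (normalized
  units), chosen to straddle θ = 0.2734 the way confident peaks and
  background do in real libraries; PO_UP/PO_DOWN means move by
  ±`po_change_log2`/2 = ±1 log₂ unit on each side of the open mean (planted
  |Δ| = 2). Sampled density = mean × exp(N(0, `noise_sd`)), lognormal
  multiplicative noise (default sd 0.2 in natural log) — positive support
  and realistic coverage dispersion; no noise model was published.
- **Libraries.** Per (condition, timepoint, replicate), total unique reads
  are drawn uniformly in [0.8, 1.2] × 10⁷ and the emitted bedGraph is the
  planted density *divided by* that library's 10⁷/total factor, so the
  normalization step is exercised non-trivially. Background (non-locus)
  signal is a small constant 0.01 rather than zero so thresholding is
  non-degenerate. Per-library peak BEDs contain exactly the loci whose
  *sampled* density clears θ — weak-at-that-timepoint loci are genuinely
  missing from individual peak lists, which is the phenomenon re-calling
  corrects.
- **Conditions.** The second condition keeps each locus's class with
  probability `label_agreement` (default 0.3) and redraws it uniformly
  otherwise, reproducing the qualitative observation that shared
  class-membership between conditions is smaller than the unique parts.
- **Genes and binding.** 2,000 genes with log₂FC ~ N(0,1); the top/bottom
  expression terciles get a co-bound site within 5 kb of the TSS with
  probability `cobind_fraction_up` = 0.6 / `cobind_fraction_down` = 0.1 (the
  middle tercile uses their mean). Planted co-bound sites (200 bp, center
  offset uniform in ±4.5 kb) appear in both factors' BED files; each factor
  additionally gets 1,000 unshared decoy sites placed uniformly.

What the simulator does **not** model: read-level sampling (fragment
lengths, Tn5 insertion bias, duplicates), locus-length variation, spatially
correlated background, mappability, or condition-specific expression
programs. Passing recovery tests therefore demonstrates the correctness of
the interval algebra, normalization, thresholding and classification logic
under controlled dispersion — not robustness to alignment artifacts or
caller idiosyncrasies in real data. Cross-talk is real, though: a site
planted for one gene can legitimately sit within 5 kb of a neighboring
gene's TSS, so measured presence can exceed the planted indicator, as in
real genomes.

## Numerical choices and degenerate inputs

- Coordinates are BED-standard 0-based half-open everywhere; contig names
  match by exact string equality, and a locus on a contig absent from a
  track scores density 0 with a logged warning listing the contigs seen.
- Open/closed tie: density = θ ⇒ open. PO tie: |Δ| = `fc_threshold` ⇒
  PO_UP/PO_DOWN.
- Parsers reject rather than repair: inverted/negative coordinates,
  overlapping bedGraph segments, negative values, duplicate library or gene
  ids, NA fold changes, unknown timepoints all raise errors naming the file
  and (for line-oriented formats) the line.
- Empty inputs: an empty BED is a valid empty set; an empty A set in overlap
  (undefined fraction), an empty locus list in pileups, and an empty peak-set
  list in superset construction are usage errors.
- Moving-average and truth-table oracles are exact; density comparisons in
  tests use 1e-9 absolute tolerance against per-base brute force.

## Problem sizes

Default test and reproduction runs use the default study configuration
(3,500 loci × 6 libraries × 2 conditions, 2,000 genes, ~2,700 binding sites
per factor), which completes in seconds on one CPU; the interval-algebra
oracle checks run on 10 kb toy contigs where per-base arrays are exact and
cheap. These sizes were chosen so the full property suite can be run
routinely during development; the implementation itself is vectorized
bisection over sorted arrays and scales linearly in loci × libraries.

## Known limitations

- Classification is fixed to three timepoints; k-timepoint monotone rules
  would require defining CO/OC subgroup semantics beyond "early/late".
- θ = 0.2734 is taken as given (overridable), not re-derived from data, and
  its original unit convention is unknowable from the published description;
  results are therefore comparable across runs of this package but not
  bit-comparable to the original analysis.
- Overlap statistics are descriptive counts; no permutation/null enrichment
  testing is provided.
- bigWig ingestion is out of scope; tracks are plain-text bedGraph.
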