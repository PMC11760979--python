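"""TF co-binding, locus-to-gene assignment, pileups and ranked-density profiles.

Given binding-site sets for two factors (e.g. c-JUN and MBD3 CUT&RUN peaks),
this module measures their overlap, assigns loci to genes by TSS distance
windows, averages signal around locus centers (metaprofile pileups), and
relates co-binding to expression: genes are ranked by fold change, each gene
is marked for co-binding presence within a TSS window, and the 0/1 indicator
is smoothed with a moving average over the gene ranking so enrichment of
co-binding near up- or downregulated genes becomes visible as a sloped
profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io import GenomicInterval, GeneRecord, SignalTrack
from .recall import merge_intervals

__all__ = [
    "OverlapResult",
    "PileupProfile",
    "MovingAverageProfile",
    "overlap_binding",
    "tss_distance",
    "assign_loci_to_genes",
    "mark_cobinding_presence",
    "smooth_indicator",
    "moving_average_profile",
    "pileup_profile",
]

GENE_WINDOW_DEFAULT = 10_000   # bp, locus-to-gene assignment
COBIND_WINDOW_DEFAULT = 5_000  # bp, co-binding presence at a gene


@dataclass(slots=True)
class OverlapResult:
    """A-centric overlap between two merged binding-site sets."""

    n_a: int
    n_b: int
    n_a_overlapping_b: int
    shared: list[GenomicInterval]  # the A loci that overlap B

    @property
    def fraction(self) -> float:
        return self.n_a_overlapping_b / self.n_a


@dataclass(slots=True)
class PileupProfile:
    """Mean scaled coverage per bin across loci, aligned on locus centers."""

    flank: int
    bin_size: int
    values: np.ndarray
    n_loci: int

    @property
    def bin_offsets(self) -> np.ndarray:
        """Bin-center offsets relative to the locus center (bp)."""
        n = len(self.values)
        return -self.flank + self.bin_size * (np.arange(n) + 0.5)


@dataclass(slots=True)
class MovingAverageProfile:
    """Co-binding indicator smoothed along the expression ranking.

    Genes are ordered by log2fc descending (most upregulated first); the
    smoothing window is truncated, not padded, at both ends, so every value
    stays a genuine mean of observed indicators.
    """

    gene_ids: list[str]
    log2fc: np.ndarray
    indicator: np.ndarray
    window_genes: int
    smoothed: np.ndarray


def overlap_binding(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    min_overlap: int = 1,
) -> OverlapResult:
    """Overlap of binding-locus set A with set B (e.g. c-JUN vs MBD3).

    Both sets are merged internally first; an A locus counts as overlapping
    when it shares at least ``min_overlap`` bp with some B locus. Swap the
    arguments for the B-centric counts.
    """
    if not a:
        raise ValueError("empty A set: overlap fraction undefined")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    a_m = merge_intervals(a)
    b_m = merge_intervals(b)
    tmp: dict[str, list[list[int]]] = {}
    for iv in b_m:
        tmp.setdefault(iv.chrom, [[], []])
        tmp[iv.chrom][0].append(iv.start)
        tmp[iv.chrom][1].append(iv.end)
    arrs = {
        c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
        for c, (s, e) in tmp.items()
    }
    shared: list[GenomicInterval] = []
    for iv in a_m:
        if iv.chrom not in arrs:
            continue
        starts, ends = arrs[iv.chrom]
        i = int(np.searchsorted(ends, iv.start, side="right"))
        j = int(np.searchsorted(starts, iv.end, side="left"))
        if i >= j:
            continue
        overlap = np.minimum(ends[i:j], iv.end) - np.maximum(starts[i:j], iv.start)
        if int(overlap.max()) >= min_overlap:
            shared.append(iv)
    return OverlapResult(len(a_m), len(b_m), len(shared), shared)


def tss_distance(interval: GenomicInterval, tss: int) -> int:
    """Distance (bp) from a TSS to the nearest base covered by the interval;
    0 when the locus contains the TSS."""
    if tss < interval.start:
        return interval.start - tss
    if tss >= interval.end:
        return tss - (interval.end - 1)
    return 0


def assign_loci_to_genes(
    loci: Sequence[GenomicInterval],
    genes: Sequence[GeneRecord],
    window: int = GENE_WINDOW_DEFAULT,
) -> tuple[dict[str, list[int]], dict[int, list[str]]]:
    """Link gene g to locus p iff the TSS-to-locus distance is <= ``window``.

    Many-to-many by design. Returns ``(gene_to_loci, locus_to_genes)``; locus
    references are indices into the input ``loci`` sequence.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for idx, iv in enumerate(loci):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, idx))
    arrs = {}
    for chrom, items in by_chrom.items():
        items.sort()
        starts = np.array([s for s, _, _ in items], dtype=np.int64)
        ends = np.array([e for _, e, _ in items], dtype=np.int64)
        idxs = np.array([i for _, _, i in items], dtype=np.int64)
        # running max of ends makes the bisection valid even for overlapping input
        arrs[chrom] = (starts, ends, np.maximum.accumulate(ends), idxs)
    gene_to_loci: dict[str, list[int]] = {g.gene_id: [] for g in genes}
    locus_to_genes: dict[int, list[str]] = {}
    for g in genes:
        if g.chrom not in arrs:
            continue
        starts, ends, cummax_ends, idxs = arrs[g.chrom]
        lo = int(np.searchsorted(cummax_ends, g.tss - window, side="right"))
        hi = int(np.searchsorted(starts, g.tss + window, side="right"))
        for k in range(lo, hi):
            iv = loci[int(idxs[k])]
            if tss_distance(iv, g.tss) <= window:
                gene_to_loci[g.gene_id].append(int(idxs[k]))
                locus_to_genes.setdefault(int(idxs[k]), []).append(g.gene_id)
    return gene_to_loci, locus_to_genes


def mark_cobinding_presence(
    genes: Sequence[GeneRecord],
    shared_loci: Sequence[GenomicInterval],
    window: int = COBIND_WINDOW_DEFAULT,
) -> np.ndarray:
    """0/1 per gene (input order): 1 iff >=1 shared (co-bound) locus lies
    within ``window`` bp of the gene's TSS."""
    gene_to_loci, _ = assign_loci_to_genes(shared_loci, genes, window)
    return np.array(
        [1 if gene_to_loci[g.gene_id] else 0 for g in genes], dtype=np.int64
    )


def smooth_indicator(indicator: Sequence[float], window_genes: int) -> np.ndarray:
    """Centered moving average with truncated edge windows.

    ``smoothed[i]`` is the mean over positions ``max(0, i-h) .. min(n-1, i+h)``
    with ``h = (window_genes - 1) // 2``.
    """
    if window_genes < 1 or window_genes % 2 == 0:
        raise ValueError(f"window_genes must be odd and >= 1, got {window_genes}")
    x = np.asarray(indicator, dtype=np.float64)
    n = len(x)
    h = (window_genes - 1) // 2
    csum = np.concatenate([[0.0], np.cumsum(x)])
    i = np.arange(n)
    lo = np.maximum(0, i - h)
    hi = np.minimum(n, i + h + 1)
    return (csum[hi] - csum[lo]) / (hi - lo)


def moving_average_profile(
    genes: Sequence[GeneRecord],
    indicator: Sequence[float],
    window_genes: int = 101,
) -> MovingAverageProfile:
    """Smooth a per-gene co-binding indicator along the expression ranking.

    ``indicator`` is aligned to the input gene order; genes are sorted here by
    log2fc descending (ties broken by gene_id for determinism) and the
    indicator is carried along before smoothing.
    """
    if len(genes) != len(indicator):
        raise ValueError("indicator must align with genes")
    order = sorted(range(len(genes)), key=lambda i: (-genes[i].log2fc, genes[i].gene_id))
    ind = np.asarray(indicator, dtype=np.float64)[order]
    return MovingAverageProfile(
        gene_ids=[genes[i].gene_id for i in order],
        log2fc=np.array([genes[i].log2fc for i in order]),
        indicator=ind,
        window_genes=window_genes,
        smoothed=smooth_indicator(ind, window_genes),
    )


def pileup_profile(
    loci: Sequence[GenomicInterval],
    track: SignalTrack,
    flank: int = 2_000,
    bin_size: int = 50,
) -> PileupProfile:
    """Average signal profile centered on locus midpoints.

    For each locus the window ``[center - flank, center + flank)`` is split
    into ``2*flank/bin_size`` bins; each bin holds the mean per-base coverage,
    with bases beyond contig bounds contributing zero. The profile is the mean
    over loci.
    """
    if not loci:
        raise ValueError("pileup_profile requires at least one locus")
    if flank <= 0 or bin_size <= 0 or flank % bin_size != 0:
        raise ValueError(
            f"flank ({flank}) must be a positive multiple of bin_size ({bin_size})"
        )
    n_bins = 2 * flank // bin_size
    acc = np.zeros(n_bins, dtype=np.float64)
    for iv in loci:
        w0 = iv.center - flank
        for b in range(n_bins):
            s = w0 + b * bin_size
            acc[b] += track.sum_over(iv.chrom, s, s + bin_size) / bin_size
    return PileupProfile(flank, bin_size, acc / len(loci), len(loci))
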