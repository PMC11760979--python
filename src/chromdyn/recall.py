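"""Cross-library peak re-calling.

Peak callers run per library are conservative: a weak accessible region that
is confidently called in one library may be missed entirely in another, which
inflates apparent between-library differences. The re-call strategy removes
this artifact: merge every library's called peaks into one universal *superset*
of candidate loci, then quantify the normalized tag density of every locus in
every library and call each locus open or closed against a single fixed
threshold (default theta = 0.2734, in mean per-base normalized-coverage
units). All downstream dynamics analysis operates on the re-called matrix.

Normalization is reads-per-ten-million: each library's coverage track is
multiplied by ``1e7 / total_unique_reads`` before densities are measured.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import GenomicInterval, LibraryStats, SignalTrack

__all__ = [
    "THETA_DEFAULT",
    "ScaleFactor",
    "AccessibilityParams",
    "SupersetMatrix",
    "OpenMatrix",
    "compute_scale_factor",
    "scale_track",
    "average_tracks",
    "merge_intervals",
    "build_superset",
    "quantify_density",
    "call_open",
]

logger = logging.getLogger(__name__)

#: Fixed open/closed threshold on mean per-base normalized tag density.
THETA_DEFAULT = 0.2734


@dataclass(frozen=True, slots=True)
class ScaleFactor:
    """Reads-per-ten-million normalization multiplier for one library."""

    library_id: str
    factor: float


@dataclass(frozen=True, slots=True)
class AccessibilityParams:
    """Open/closed calling parameters. A density exactly equal to ``theta``
    is called open (``theta`` is a *minimum* threshold)."""

    theta: float = THETA_DEFAULT

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise ValueError(f"theta must be >= 0, got {self.theta}")


@dataclass(slots=True)
class SupersetMatrix:
    """Merged universal locus list plus a loci × libraries density matrix.

    ``density[i, j]`` is the mean per-base scaled coverage of library
    ``library_order[j]`` over locus ``loci[i]``.
    """

    loci: list[GenomicInterval]
    density: np.ndarray
    library_order: list[str]

    def __post_init__(self) -> None:
        if self.density.shape != (len(self.loci), len(self.library_order)):
            raise ValueError(
                f"density shape {self.density.shape} does not match "
                f"{len(self.loci)} loci x {len(self.library_order)} libraries"
            )


@dataclass(slots=True)
class OpenMatrix:
    """Boolean open/closed calls aligned to a :class:`SupersetMatrix`."""

    loci: list[GenomicInterval]
    calls: np.ndarray  # bool, loci x libraries; True = open
    library_order: list[str]
    theta: float


def compute_scale_factor(stats: LibraryStats) -> ScaleFactor:
    """``factor = 1e7 / total_unique_reads`` (reads-per-ten-million)."""
    if stats.total_unique_reads <= 0:
        raise ValueError(
            f"{stats.library_id}: total_unique_reads must be positive"
        )
    return ScaleFactor(stats.library_id, 1e7 / stats.total_unique_reads)


def scale_track(track: SignalTrack, factor: float | ScaleFactor) -> SignalTrack:
    """Multiply every track value by the normalization factor; geometry is
    unchanged."""
    f = factor.factor if isinstance(factor, ScaleFactor) else float(factor)
    if f <= 0:
        raise ValueError(f"scale factor must be positive, got {f}")
    return track.scale(f)


def average_tracks(tracks: Sequence[SignalTrack]) -> SignalTrack:
    """Mean of several (scaled) tracks — used to merge biological replicates.

    The result's segmentation is the union of all input breakpoints; bases
    covered by no input segment keep implicit value 0.
    """
    if not tracks:
        raise ValueError("average_tracks requires at least one track")
    if len(tracks) == 1:
        return tracks[0].scale(1.0)
    contigs = sorted(set().union(*(set(t.contigs()) for t in tracks)))
    data = {}
    for chrom in contigs:
        points = np.unique(
            np.concatenate(
                [np.concatenate(t.arrays(chrom)[:2]) for t in tracks if t.has_contig(chrom)]
            )
        )
        seg_s, seg_e = points[:-1], points[1:]
        total = np.zeros(len(seg_s), dtype=np.float64)
        for t in tracks:
            if not t.has_contig(chrom):
                continue
            starts, ends, values = t.arrays(chrom)
            idx = np.searchsorted(starts, seg_s, side="right") - 1
            safe = np.clip(idx, 0, None)
            covered = (idx >= 0) & (seg_s < ends[safe])
            total[covered] += values[safe[covered]]
        mean = total / len(tracks)
        keep = mean > 0
        if np.any(keep):
            data[chrom] = (seg_s[keep], seg_e[keep], mean[keep])
    return SignalTrack(data)


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: sorted, disjoint, with overlapping *and book-ended*
    (touching) intervals fused into one. Names/scores are dropped."""
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals, key=GenomicInterval.sort_key):
        if merged and iv.chrom == merged[-1].chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def build_superset(
    peak_sets: Sequence[tuple[str, Sequence[GenomicInterval]]]
) -> list[GenomicInterval]:
    """Universal candidate-locus list: the merged union of every library's
    peak calls, irrespective of which library each peak was called in."""
    if not peak_sets:
        raise ValueError("build_superset requires at least one peak set")
    return merge_intervals([iv for _, ivs in peak_sets for iv in ivs])


def _check_sorted_disjoint(loci: Sequence[GenomicInterval]) -> None:
    for prev, cur in zip(loci, loci[1:]):
        if cur.sort_key() < prev.sort_key():
            raise ValueError("loci must be sorted by (chrom, start)")
        if cur.chrom == prev.chrom and cur.start < prev.end:
            raise ValueError(
                f"loci must be disjoint; {prev.chrom}:{prev.start}-{prev.end} "
                f"overlaps {cur.chrom}:{cur.start}-{cur.end}"
            )


def quantify_density(
    loci: Sequence[GenomicInterval],
    tracks: Mapping[str, SignalTrack],
    library_order: Sequence[str] | None = None,
) -> SupersetMatrix:
    """Mean per-base scaled coverage of every locus in every library.

    A locus on a contig absent from a track scores density 0 (no signal), with
    a warning logged once per (library, contig) pair.
    """
    _check_sorted_disjoint(loci)
    order = list(library_order) if library_order is not None else sorted(tracks)
    density = np.zeros((len(loci), len(order)), dtype=np.float64)
    for j, lib in enumerate(order):
        track = tracks[lib]
        warned: set[str] = set()
        for i, locus in enumerate(loci):
            if not track.has_contig(locus.chrom):
                if locus.chrom not in warned:
                    logger.warning(
                        "library %s has no signal on contig %s (density 0; "
                        "track contigs: %s)", lib, locus.chrom, track.contigs(),
                    )
                    warned.add(locus.chrom)
                continue
            density[i, j] = track.mean_over(locus.chrom, locus.start, locus.end)
    return SupersetMatrix(list(loci), density, order)


def call_open(
    matrix: SupersetMatrix, params: AccessibilityParams | None = None
) -> OpenMatrix:
    """Elementwise open/closed call: density >= theta ⇒ open."""
    params = params or AccessibilityParams()
    return OpenMatrix(
        matrix.loci, matrix.density >= params.theta, list(matrix.library_order),
        params.theta,
    )
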