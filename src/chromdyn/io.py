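"""Plain-text genomic I/O: BED intervals, bedGraph signal tracks, tabular inputs.

Coordinates are BED-style throughout the package: 0-based starts, half-open
``[start, end)`` spans. Parsers validate and reject malformed records rather
than silently repairing them, and chromosome names are compared by exact
string equality (no ``chr`` aliasing) — a contig-name mismatch between inputs
surfaces as missing signal with a warning, never as silently shifted counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "GenomicInterval",
    "SignalTrack",
    "LibraryStats",
    "GeneRecord",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_library_stats",
    "write_library_stats",
    "read_gene_table",
    "write_gene_table",
]

VALID_STRANDS = ("+", "-")


class FormatError(ValueError):
    """An input file violated its format contract (bad coordinates, overlaps, ...)."""


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A half-open genomic span ``chrom:[start, end)`` — the atom of all
    peak / binding-site / locus sets handled by the pipeline."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be a non-empty string")
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval: [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Integer midpoint, ``floor((start + end) / 2)``."""
        return (self.start + self.end) // 2

    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass(frozen=True, slots=True)
class LibraryStats:
    """Per-library sequencing metadata: unique read count plus the design
    cell (timepoint, condition) the library belongs to."""

    library_id: str
    total_unique_reads: int
    timepoint: str
    condition: str

    def __post_init__(self) -> None:
        if self.total_unique_reads <= 0:
            raise ValueError(
                f"{self.library_id}: total_unique_reads must be positive, "
                f"got {self.total_unique_reads}"
            )


@dataclass(frozen=True, slots=True)
class GeneRecord:
    """A gene anchored at its TSS, carrying the expression log2 fold change
    (relative to the declared reference condition) used for ranking."""

    gene_id: str
    chrom: str
    tss: int
    strand: str
    log2fc: float

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"{self.gene_id}: negative TSS {self.tss}")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"{self.gene_id}: invalid strand {self.strand!r}")
        if not np.isfinite(self.log2fc):
            raise ValueError(f"{self.gene_id}: log2fc must be finite")


class SignalTrack:
    """Piecewise-constant, non-negative coverage signal.

    Stored per contig as parallel sorted arrays ``(starts, ends, values)`` of
    non-overlapping segments; any base not covered by a segment has implicit
    value 0. Values are in normalized tag-density units per bp once the track
    has been scaled (see :func:`chromdyn.recall.scale_track`).
    """

    def __init__(
        self, data: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None
    ) -> None:
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = dict(data or {})

    @classmethod
    def from_segments(
        cls, segments: Iterable[tuple[str, int, int, float]]
    ) -> "SignalTrack":
        """Build a track from ``(chrom, start, end, value)`` tuples, sorting per
        contig and rejecting overlaps and negative values."""
        per: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in segments:
            if value < 0:
                raise FormatError(
                    f"negative signal value {value} at {chrom}:{start}-{end}"
                )
            if start < 0 or end <= start:
                raise FormatError(
                    f"bad segment coordinates {chrom}:[{start}, {end})"
                )
            per.setdefault(chrom, []).append((start, end, value))
        data = {}
        for chrom, segs in per.items():
            segs.sort()
            starts = np.array([s for s, _, _ in segs], dtype=np.int64)
            ends = np.array([e for _, e, _ in segs], dtype=np.int64)
            values = np.array([v for _, _, v in segs], dtype=np.float64)
            if np.any(starts[1:] < ends[:-1]):
                raise FormatError(f"overlapping segments on contig {chrom}")
            data[chrom] = (starts, ends, values)
        return cls(data)

    def contigs(self) -> list[str]:
        return sorted(self._data)

    def has_contig(self, chrom: str) -> bool:
        return chrom in self._data

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Raw ``(starts, ends, values)`` arrays for one contig."""
        return self._data[chrom]

    def segments(self) -> Iterator[tuple[str, int, int, float]]:
        for chrom in self.contigs():
            starts, ends, values = self._data[chrom]
            for s, e, v in zip(starts, ends, values):
                yield chrom, int(s), int(e), float(v)

    def n_segments(self) -> int:
        return sum(len(v[0]) for v in self._data.values())

    def scale(self, factor: float) -> "SignalTrack":
        """Return a new track with every value multiplied by ``factor``."""
        return SignalTrack(
            {c: (s, e, v * factor) for c, (s, e, v) in self._data.items()}
        )

    def mass(self) -> float:
        """Total signal mass: sum of value × span over all segments."""
        return float(
            sum(np.sum(v * (e - s)) for s, e, v in self._data.values())
        )

    def sum_over(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-base signal over ``[start, end)``; 0 on absent contigs."""
        if chrom not in self._data or end <= start:
            return 0.0
        starts, ends, values = self._data[chrom]
        # sorted non-overlapping ⇒ ends are sorted too
        i = int(np.searchsorted(ends, start, side="right"))
        j = int(np.searchsorted(starts, end, side="left"))
        if i >= j:
            return 0.0
        overlap = np.minimum(ends[i:j], end) - np.maximum(starts[i:j], start)
        return float(np.sum(overlap * values[i:j]))

    def mean_over(self, chrom: str, start: int, end: int) -> float:
        """Mean per-base signal over ``[start, end)``."""
        if end <= start:
            raise ValueError("mean_over requires end > start")
        return self.sum_over(chrom, start, end) / (end - start)

    def to_dense(self, chrom: str, length: int) -> np.ndarray:
        """Per-base value array for the first ``length`` bases of a contig."""
        out = np.zeros(length, dtype=np.float64)
        if chrom in self._data:
            starts, ends, values = self._data[chrom]
            for s, e, v in zip(starts, ends, values):
                if s >= length:
                    break
                out[s : min(int(e), length)] = v
        return out


_BED_SKIP = ("track", "browser", "#")


def _data_lines(path: str | Path) -> Iterator[tuple[int, str]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith(_BED_SKIP):
                continue
            yield lineno, line


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED5 intervals, in file order.

    Column 4 maps to ``name`` (``.`` → absent) and column 5 to ``score``.
    Track/browser/comment lines are skipped; malformed coordinates raise
    :class:`FormatError` naming the offending line.
    """
    out: list[GenomicInterval] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{path}:{lineno}: expected >=3 tab-separated fields"
            )
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise FormatError(
                f"{path}:{lineno}: non-integer coordinates {fields[1]!r}, {fields[2]!r}"
            ) from exc
        name = None
        if len(fields) > 3 and fields[3] != ".":
            name = fields[3]
        score = None
        if len(fields) > 4 and fields[4] != ".":
            try:
                score = float(fields[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric score") from exc
        try:
            out.append(GenomicInterval(fields[0], start, end, name, score))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    """Write intervals as 3–5 column BED with deterministic formatting."""
    with open(path, "w", encoding="utf-8") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None:
                cols.append(iv.name if iv.name is not None else ".")
            if iv.score is not None:
                cols.append(repr(iv.score))
            fh.write("\t".join(cols) + "\n")


def read_bedgraph(path: str | Path) -> SignalTrack:
    """Read a 4-column bedGraph into a :class:`SignalTrack`.

    Input segments may be unsorted; overlapping segments or negative values
    raise :class:`FormatError`.
    """
    segments: list[tuple[str, int, int, float]] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 4:
            raise FormatError(f"{path}:{lineno}: expected 4 tab-separated fields")
        try:
            start, end = int(fields[1]), int(fields[2])
            value = float(fields[3])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: malformed bedGraph fields") from exc
        if start < 0 or end <= start:
            raise FormatError(
                f"{path}:{lineno}: bad coordinates [{start}, {end})"
            )
        if value < 0:
            raise FormatError(f"{path}:{lineno}: negative value {value}")
        segments.append((fields[0], start, end, value))
    return SignalTrack.from_segments(segments)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for chrom, start, end, value in track.segments():
            fh.write(f"{chrom}\t{start}\t{end}\t{value!r}\n")


_STATS_COLUMNS = ["library_id", "total_unique_reads", "timepoint", "condition"]


def read_library_stats(
    path: str | Path, timepoints: Sequence[str] | None = None
) -> list[LibraryStats]:
    """Read the per-library read-count/design TSV.

    When ``timepoints`` (the run configuration's ordered timepoint labels) is
    given, every row's timepoint must belong to it. Duplicate library ids are
    rejected.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"library_id": str})
    missing = [c for c in _STATS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if df["library_id"].duplicated().any():
        dupes = df["library_id"][df["library_id"].duplicated()].tolist()
        raise FormatError(f"{path}: duplicate library_id {dupes}")
    out = []
    for row in df.itertuples(index=False):
        if timepoints is not None and str(row.timepoint) not in timepoints:
            raise FormatError(
                f"{path}: unknown timepoint {row.timepoint!r} for "
                f"{row.library_id} (declared: {list(timepoints)})"
            )
        try:
            out.append(
                LibraryStats(
                    str(row.library_id),
                    int(row.total_unique_reads),
                    str(row.timepoint),
                    str(row.condition),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return out


def write_library_stats(stats: Sequence[LibraryStats], path: str | Path) -> None:
    pd.DataFrame(
        [(s.library_id, s.total_unique_reads, s.timepoint, s.condition) for s in stats],
        columns=_STATS_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


_GENE_COLUMNS = ["gene_id", "chrom", "tss", "strand", "log2fc"]


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Read the per-gene TSS + expression fold-change table.

    A missing/NA ``log2fc`` is an error: every gene must be rankable.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str, "chrom": str})
    missing = [c for c in _GENE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if df["gene_id"].duplicated().any():
        dupes = df["gene_id"][df["gene_id"].duplicated()].tolist()
        raise FormatError(f"{path}: duplicate gene_id {dupes}")
    if df["log2fc"].isna().any():
        bad = df.loc[df["log2fc"].isna(), "gene_id"].tolist()
        raise FormatError(f"{path}: missing log2fc for {bad}")
    out = []
    for row in df.itertuples(index=False):
        try:
            out.append(
                GeneRecord(
                    str(row.gene_id), str(row.chrom), int(row.tss),
                    str(row.strand), float(row.log2fc),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return out


def write_gene_table(genes: Sequence[GeneRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(g.gene_id, g.chrom, g.tss, g.strand, g.log2fc) for g in genes],
        columns=_GENE_COLUMNS,
    ).to_csv(path, sep="\t", index=False)
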