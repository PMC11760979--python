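"""Temporal chromatin dynamics classification.

Each superset locus, within one condition, traces an open/closed trajectory
over the ordered timepoints (D0 < D1 < D3 by default). Trajectories map to
dynamics classes:

========  =======================  =====================================
pattern   label                    meaning
========  =======================  =====================================
0 1 1     CO1                      closed-to-open, opens early (D1)
0 0 1     CO2                      closed-to-open, opens late (D3)
1 0 0     OC1                      open-to-closed, closes early (D1)
1 1 0     OC2                      open-to-closed, closes late (D3)
1 1 1     PO / PO_UP / PO_DOWN     persistently open, split by density change
0 0 0     PC                       persistently closed
0 1 0     COMPLEX                  non-monotone
1 0 1     COMPLEX                  non-monotone
========  =======================  =====================================

Persistently open loci are subdivided by the density log-ratio between the
last and first timepoints, Δ = log2((d_last + ε) / (d_first + ε)): Δ at or
above ``fc_threshold`` → PO_UP, at or below −``fc_threshold`` → PO_DOWN,
otherwise plain PO. Δ = 0 is always plain PO.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from .io import GenomicInterval

__all__ = [
    "DynamicsLabel",
    "DynamicsParams",
    "TimeCourse",
    "ClassComparison",
    "classify_pattern",
    "classify_dynamics",
    "compare_conditions",
    "summarize_dynamics",
]


class DynamicsLabel(str, Enum):
    """Per-locus temporal accessibility class."""

    CO1 = "CO1"
    CO2 = "CO2"
    OC1 = "OC1"
    OC2 = "OC2"
    PO = "PO"
    PO_UP = "PO_UP"
    PO_DOWN = "PO_DOWN"
    PC = "PC"
    COMPLEX = "COMPLEX"

    def __str__(self) -> str:  # plain value in TSV output
        return self.value


@dataclass(frozen=True, slots=True)
class DynamicsParams:
    """Persistently-open subdivision parameters.

    ``fc_threshold`` is the minimum |log2 density ratio| (last vs first
    timepoint) to call PO_UP / PO_DOWN; default 1.0 (two-fold).
    ``pseudocount`` is added to both densities before the ratio so closed-side
    densities near zero cannot explode the log (normalized units).
    """

    fc_threshold: float = 1.0
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        if self.fc_threshold < 0:
            raise ValueError("fc_threshold must be >= 0")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")


@dataclass(slots=True)
class TimeCourse:
    """Per-locus open/closed calls and densities along ordered timepoints,
    for one condition."""

    timepoints: tuple[str, ...]
    calls: np.ndarray    # bool, loci x timepoints
    density: np.ndarray  # float, loci x timepoints

    def __post_init__(self) -> None:
        if len(self.timepoints) < 2:
            raise ValueError("a time course needs at least 2 timepoints")
        shape = (self.calls.shape[0], len(self.timepoints))
        if self.calls.shape != shape or self.density.shape != shape:
            raise ValueError("calls/density not aligned to timepoints")


# Monotone and degenerate 3-timepoint patterns (True = open).
_PATTERN_LABELS: dict[tuple[bool, bool, bool], DynamicsLabel] = {
    (False, True, True): DynamicsLabel.CO1,
    (False, False, True): DynamicsLabel.CO2,
    (True, False, False): DynamicsLabel.OC1,
    (True, True, False): DynamicsLabel.OC2,
    (False, False, False): DynamicsLabel.PC,
    (False, True, False): DynamicsLabel.COMPLEX,
    (True, False, True): DynamicsLabel.COMPLEX,
}


def classify_pattern(
    calls: Sequence[bool], delta: float, params: DynamicsParams | None = None
) -> DynamicsLabel:
    """Label one locus from its 3-timepoint call pattern and density change Δ.

    Δ only matters for the all-open pattern; the strict-sign clause makes
    Δ = 0 plain PO even at ``fc_threshold = 0``.
    """
    params = params or DynamicsParams()
    key = tuple(bool(c) for c in calls)
    if len(key) != 3:
        raise ValueError(f"expected 3 timepoint calls, got {len(key)}")
    if key == (True, True, True):
        if delta >= params.fc_threshold and delta > 0:
            return DynamicsLabel.PO_UP
        if delta <= -params.fc_threshold and delta < 0:
            return DynamicsLabel.PO_DOWN
        return DynamicsLabel.PO
    return _PATTERN_LABELS[key]


def classify_dynamics(
    tc: TimeCourse, params: DynamicsParams | None = None
) -> list[DynamicsLabel]:
    """Label every locus of a 3-timepoint course; exhaustive and exclusive."""
    params = params or DynamicsParams()
    if len(tc.timepoints) != 3:
        raise ValueError(
            f"classification is defined for exactly 3 timepoints, "
            f"got {len(tc.timepoints)}"
        )
    eps = params.pseudocount
    delta = np.log2((tc.density[:, -1] + eps) / (tc.density[:, 0] + eps))
    return [
        classify_pattern(tc.calls[i], float(delta[i]), params)
        for i in range(tc.calls.shape[0])
    ]


def delta_log2(tc: TimeCourse, params: DynamicsParams | None = None) -> np.ndarray:
    """Δ = log2((d_last + ε) / (d_first + ε)) per locus."""
    eps = (params or DynamicsParams()).pseudocount
    return np.log2((tc.density[:, -1] + eps) / (tc.density[:, 0] + eps))


@dataclass(slots=True)
class ClassComparison:
    """Per-class locus-identity overlap between two conditions.

    ``per_class[label] = (unique_a, unique_b, shared)`` where shared counts
    loci carrying that label in *both* conditions.
    """

    per_class: dict[DynamicsLabel, tuple[int, int, int]]

    def as_rows(self) -> list[tuple[str, int, int, int]]:
        return [
            (label.value, *self.per_class[label]) for label in DynamicsLabel
        ]


def compare_conditions(
    labels_a: Sequence[DynamicsLabel],
    labels_b: Sequence[DynamicsLabel],
    loci: Sequence[GenomicInterval] | None = None,
) -> ClassComparison:
    """Venn counts per class between two conditions on one shared locus list.

    Both label vectors must be indexed by the same superset loci; ``loci`` is
    accepted for length validation only.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError(
            f"label vectors index different loci: {len(labels_a)} vs {len(labels_b)}"
        )
    if loci is not None and len(loci) != len(labels_a):
        raise ValueError("loci and label vectors have different lengths")
    per_class = {}
    for label in DynamicsLabel:
        in_a = {i for i, l in enumerate(labels_a) if l is label}
        in_b = {i for i, l in enumerate(labels_b) if l is label}
        shared = len(in_a & in_b)
        per_class[label] = (len(in_a) - shared, len(in_b) - shared, shared)
    return ClassComparison(per_class)


def summarize_dynamics(
    labels: Sequence[DynamicsLabel],
) -> Mapping[DynamicsLabel, int]:
    """Count loci per class; every class appears (zero-filled)."""
    counts = Counter(labels)
    return {label: counts.get(label, 0) for label in DynamicsLabel}
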