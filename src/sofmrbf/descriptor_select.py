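"""Correlation analysis and cluster-representative descriptor selection.

After the SOFM groups descriptors, each multi-member group contributes the
single member whose Pearson correlation with the experimental BDE has the
largest magnitude; singleton groups pass through unchanged.  The chosen
set therefore has exactly one descriptor per group, and (because |r| is
invariant under affine rescaling and sign flips) the selection does not
depend on descriptor units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .data_model import CANONICAL_DESCRIPTORS, DescriptorTable
from .sofm import Partition

__all__ = [
    "CorrelationReport",
    "SelectionResult",
    "pearson_r",
    "correlation_report",
    "select_representatives",
    "partitions_stable",
    "stability_onset",
]


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation; undefined (error) for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


@dataclass(frozen=True)
class CorrelationReport:
    """Per-descriptor Pearson r with the experimental BDE."""

    r: Mapping[str, float]

    def __post_init__(self) -> None:
        for name, value in self.r.items():
            if abs(value) > 1 + 1e-12:
                raise ValueError(f"|r| > 1 for {name!r}")

    def abs_r(self, name: str) -> float:
        return abs(self.r[name])

    def ranked(self) -> list[tuple[str, float]]:
        """Descriptors sorted by decreasing |r| (ties in canonical order)."""
        order = {n: i for i, n in enumerate(CANONICAL_DESCRIPTORS)}
        return sorted(self.r.items(), key=lambda kv: (-abs(kv[1]), order.get(kv[0], len(order))))


def correlation_report(table: DescriptorTable) -> CorrelationReport:
    """Correlation of each canonical descriptor with expt_bde on training rows."""
    mask = table.train_mask
    y = table.expt_bde[mask]
    x = table.descriptor_matrix()[mask]
    r = {
        name: pearson_r(x[:, j], y)
        for j, name in enumerate(CANONICAL_DESCRIPTORS)
    }
    return CorrelationReport(r)


@dataclass(frozen=True)
class SelectionResult:
    """Chosen representatives: one per group, reported in canonical order."""

    partition: Partition
    chosen: tuple[str, ...]
    provenance: Mapping[frozenset, str]

    def __post_init__(self) -> None:
        if len(self.chosen) != len(self.partition):
            raise ValueError("exactly one representative per group expected")


def select_representatives(partition: Partition, report: CorrelationReport) -> SelectionResult:
    """Pick the max-|r| member of every group (singletons pass through).

    Ties on |r| resolve to the earlier descriptor in canonical order.
    """
    missing = partition.names - set(report.r)
    if missing:
        raise ValueError(f"descriptors missing from correlation report: {sorted(missing)!r}")
    order = {n: i for i, n in enumerate(CANONICAL_DESCRIPTORS)}
    chosen: list[str] = []
    provenance: dict[frozenset, str] = {}
    for group in partition.groups:
        members = sorted(group, key=lambda n: order.get(n, len(order)))
        if len(members) == 1:
            pick = members[0]
            provenance[group] = "singleton"
        else:
            pick = max(members, key=lambda n: (abs(report.r[n]), -order.get(n, len(order))))
            provenance[group] = f"argmax |r| = {abs(report.r[pick]):.2f}"
        chosen.append(pick)
    chosen.sort(key=lambda n: order.get(n, len(order)))
    return SelectionResult(partition=partition, chosen=tuple(chosen), provenance=provenance)


def partitions_stable(partitions: Sequence[Partition]) -> bool:
    """True iff all partitions induce the same grouping (labels ignored)."""
    if len(partitions) < 1:
        raise ValueError("need at least one partition")
    first = partitions[0]
    return all(p == first for p in partitions[1:])


def stability_onset(partitions_by_step: Mapping[int, Partition]) -> int | None:
    """Smallest step count from which all later partitions agree, or None."""
    steps = sorted(partitions_by_step)
    for i, step in enumerate(steps):
        if partitions_stable([partitions_by_step[s] for s in steps[i:]]):
            return step
    return None
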