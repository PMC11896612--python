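"""Peak-based binding calls and peak-set co-occupancy statistics.

Binding status per (enhancer, TF family) follows the C/c encoding: ``C``
for a binding peak with a corresponding motif (any conserved tier, strong
or weak), ``c`` for a peak without one, ``unbound`` otherwise. Overlap is
>= 1 bp everywhere; no reciprocal-overlap requirement is imposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .genome_io import EnhancerRecord, GenomicInterval

BOUND_WITH_MOTIF = "C"
BOUND_NO_MOTIF = "c"
UNBOUND = "unbound"


@dataclass
class PeakSet:
    """One TF's called peaks (ChIP-seq or CUT&RUN) on one assembly."""

    tf_name: str
    source_id: str
    intervals: list[GenomicInterval]
    assembly: str = ""

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals)


@dataclass
class BindingCall:
    enhancer: str
    family: str
    status: str

    def __post_init__(self) -> None:
        if self.status not in (BOUND_WITH_MOTIF, BOUND_NO_MOTIF, UNBOUND):
            raise ValueError(f"invalid binding status {self.status!r}")


@dataclass
class CoOccupancyStats:
    """Fractions of reference peaks overlapped by query peak sets."""

    reference_id: str
    n_reference: int
    per_query: dict[str, float]
    union_fraction: float
    joint_fraction: float


def _any_overlap(region: GenomicInterval, intervals: Sequence[GenomicInterval]) -> bool:
    return any(region.overlaps(iv) for iv in intervals)


def call_binding(
    enhancer: EnhancerRecord,
    peaks: PeakSet,
    family_status: dict[str, Optional[str]],
    family: Optional[str] = None,
    assembly: str = "",
) -> BindingCall:
    """Combine peak overlap with motif presence into a C/c/unbound call.

    ``family_status`` is the per-family M/m/absent map from the motif scan;
    ``family`` defaults to the peak set's TF name. Bound means >= 1 bp
    overlap between the enhancer interval and any peak.
    """
    if assembly and peaks.assembly and assembly != peaks.assembly:
        raise ValueError(
            f"assembly mismatch: enhancer on {assembly!r}, peaks on {peaks.assembly!r}"
        )
    fam = family if family is not None else peaks.tf_name
    bound = _any_overlap(enhancer.interval, peaks.intervals)
    if not bound:
        status = UNBOUND
    elif family_status.get(fam) in ("M", "m"):
        status = BOUND_WITH_MOTIF
    else:
        status = BOUND_NO_MOTIF
    return BindingCall(enhancer.name, fam, status)


def peakset_overlap_fraction(
    reference: PeakSet, queries: Sequence[PeakSet]
) -> CoOccupancyStats:
    """Fraction of reference peaks overlapped by each query set, by their
    union, and by all of them jointly (>= 1 bp overlap throughout)."""
    if not reference.intervals:
        raise ValueError(f"reference peak set {reference.tf_name!r} is empty")
    n = len(reference.intervals)
    per_query: dict[str, float] = {}
    hit_by: list[set[str]] = [set() for _ in range(n)]
    for q in queries:
        count = 0
        for i, peak in enumerate(reference.intervals):
            if _any_overlap(peak, q.intervals):
                hit_by[i].add(q.tf_name)
                count += 1
        per_query[q.tf_name] = count / n
    all_ids = {q.tf_name for q in queries}
    union_fraction = sum(1 for s in hit_by if s) / n
    joint_fraction = sum(1 for s in hit_by if s == all_ids) / n if all_ids else 0.0
    return CoOccupancyStats(reference.tf_name, n, per_query, union_fraction, joint_fraction)


def annotation_overlap(
    reference: PeakSet, annotation: Sequence[GenomicInterval]
) -> float:
    """Fraction of reference peaks with >= 1 bp overlap with an annotation
    (e.g. EC enhancer/promoter mark regions)."""
    if not reference.intervals:
        raise ValueError(f"reference peak set {reference.tf_name!r} is empty")
    hits = sum(1 for p in reference.intervals if _any_overlap(p, annotation))
    return hits / len(reference.intervals)


def cooccupancy_report(stats: CoOccupancyStats) -> dict[str, float]:
    """Flat key-value report with fractions rounded to 0.1%."""
    out = {"n_reference_peaks": stats.n_reference}
    for tf, f in stats.per_query.items():
        out[f"fraction_overlapping_{tf}"] = round(f, 3)
    out["fraction_overlapping_union"] = round(stats.union_fraction, 3)
    out["fraction_overlapping_all"] = round(stats.joint_fraction, 3)
    return out
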