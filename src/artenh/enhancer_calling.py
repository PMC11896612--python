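"""Candidate-region construction and the cross-species putative-enhancer rule.

A region is called putative when it carries at least one enhancer-associated
chromatin mark (open chromatin, EP300, H3K27Ac/H3K4Me1) in both mouse and
human endothelial cells. For genes poorly transcribed in the human cell
lines, the rule is relaxed to two distinct mouse mark datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .genome_io import GenomicInterval, OrthologyMap, merge_intervals

MOUSE = "mouse"
HUMAN = "human"


@dataclass
class MarkTrack:
    """One enhancer-mark dataset: a set of intervals on one assembly.

    ``specific`` holds a per-interval flag; ``False`` marks intervals whose
    signal extends to many non-endothelial cell types (they still count as
    evidence but are propagated with a non-specific annotation).
    """

    dataset_id: str
    species: str
    intervals: list[GenomicInterval]
    assembly: str = ""
    specific: Optional[list[bool]] = None

    def __post_init__(self) -> None:
        if self.species not in (MOUSE, HUMAN):
            raise ValueError(f"species must be 'mouse' or 'human', got {self.species!r}")
        if self.specific is None:
            self.specific = [True] * len(self.intervals)
        if len(self.specific) != len(self.intervals):
            raise ValueError("specific flags must align with intervals")


@dataclass
class MarkEvidence:
    """Per-dataset overlap booleans for one region.

    ``nonspecific[d]`` is True when dataset ``d`` overlaps the region but
    only through intervals flagged as not EC-specific. ``notes`` carries
    per-dataset annotations such as 'unmapped' for human datasets when the
    region has no human orthologue.
    """

    region: GenomicInterval
    marks: dict[str, bool]
    species: dict[str, str]
    nonspecific: dict[str, bool] = field(default_factory=dict)
    notes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.marks) != set(self.species):
            raise ValueError("marks and species must cover the same datasets")

    def n_true(self, species: str) -> int:
        return sum(1 for d, v in self.marks.items() if v and self.species[d] == species)

    @property
    def has_both_species(self) -> bool:
        return self.n_true(MOUSE) >= 1 and self.n_true(HUMAN) >= 1


@dataclass(frozen=True)
class TranscriptionStatus:
    """Whether the anchor gene is robustly transcribed in each species' ECs
    (assessed upstream from promoter open chromatin / H3K4Me3; an input
    here, not a computation)."""

    gene_name: str
    transcribed_human: bool
    transcribed_mouse: bool = True


BOTH_SPECIES = "both_species"
MOUSE_ONLY_RELAXED = "mouse_only_relaxed"
PUTATIVE = "putative"
BELOW_THRESHOLD = "below_threshold"


@dataclass
class PutativeCall:
    region: GenomicInterval
    evidence: MarkEvidence
    decision: str
    rule_used: str


def build_candidate_regions(
    tracks: Sequence[MarkTrack], locus: GenomicInterval, merge_gap: int = 500
) -> list[GenomicInterval]:
    """Merge all mark intervals intersecting a locus into candidate regions.

    Intervals closer than ``merge_gap`` bp are fused. All tracks must be on
    one assembly (the study's by-eye region selection is replaced here by
    this deterministic surrogate).
    """
    assemblies = {t.assembly for t in tracks}
    if len(assemblies) > 1:
        raise ValueError(f"tracks span multiple assemblies: {sorted(assemblies)}")
    hits = [
        iv for t in tracks for iv in t.intervals if iv.overlaps(locus)
    ]
    return merge_intervals(hits, gap=merge_gap)


def collect_mark_evidence(
    region: GenomicInterval,
    tracks: Sequence[MarkTrack],
    orthology: Optional[OrthologyMap] = None,
    region_species: str = MOUSE,
) -> MarkEvidence:
    """Overlap one region against every configured mark dataset.

    Datasets from the other species are queried through the orthology block
    map; if the region cannot be mapped, those datasets record False with an
    'unmapped' note. A dataset records True on >= 1 bp overlap with any of
    its intervals.
    """
    marks: dict[str, bool] = {}
    species: dict[str, str] = {}
    nonspecific: dict[str, bool] = {}
    notes: dict[str, str] = {}
    mapped: Optional[list[GenomicInterval]] = None
    for track in tracks:
        species[track.dataset_id] = track.species
        if track.species == region_species:
            queries = [region]
        else:
            if mapped is None:
                mapped = orthology.map_interval(region) if orthology else []
            queries = mapped
            if not queries:
                marks[track.dataset_id] = False
                notes[track.dataset_id] = "unmapped"
                continue
        hit_specific = False
        hit_nonspecific = False
        for iv, spec_flag in zip(track.intervals, track.specific):
            if any(q.overlaps(iv) for q in queries):
                if spec_flag:
                    hit_specific = True
                else:
                    hit_nonspecific = True
        marks[track.dataset_id] = hit_specific or hit_nonspecific
        if hit_nonspecific and not hit_specific:
            nonspecific[track.dataset_id] = True
    return MarkEvidence(region, marks, species, nonspecific, notes)


def call_putative(evidence: MarkEvidence, status: TranscriptionStatus) -> PutativeCall:
    """Apply the cross-species evidence rule.

    For genes transcribed in human ECs: putative iff >= 1 mouse dataset and
    >= 1 human dataset carry a mark. Otherwise the relaxed rule applies:
    putative iff >= 2 distinct mouse datasets carry a mark.
    """
    if status.transcribed_human:
        rule = BOTH_SPECIES
        ok = evidence.n_true(MOUSE) >= 1 and evidence.n_true(HUMAN) >= 1
    else:
        rule = MOUSE_ONLY_RELAXED
        ok = evidence.n_true(MOUSE) >= 2
    return PutativeCall(evidence.region, evidence, PUTATIVE if ok else BELOW_THRESHOLD, rule)


@dataclass
class MarkedEnhancer:
    """A known enhancer carrying complete mark evidence (for retrospective
    aggregation over published in vivo-validated enhancers)."""

    name: str
    evidence: MarkEvidence
    class_label: Optional[str] = None


def retrospective_mark_summary(
    records: Sequence[MarkedEnhancer], class_label: Optional[str] = None
) -> dict:
    """Aggregate mark evidence over a set of known enhancers.

    Returns total count, the number marked in both species (>= 1 mouse and
    >= 1 human dataset), per-dataset positive counts, and — when
    ``class_label`` is given — the same counts restricted to records whose
    ``class_label`` matches.
    """
    for rec in records:
        if rec.evidence is None or not rec.evidence.marks:
            raise ValueError(f"record {rec.name!r} is missing mark evidence")
    datasets = sorted(records[0].evidence.marks) if records else []
    for rec in records:
        if sorted(rec.evidence.marks) != datasets:
            raise ValueError(f"record {rec.name!r} does not cover all datasets")

    def _counts(recs: Sequence[MarkedEnhancer]) -> dict:
        return {
            "n_total": len(recs),
            "n_with_mark_both_species": sum(1 for r in recs if r.evidence.has_both_species),
            "per_dataset": {
                d: sum(1 for r in recs if r.evidence.marks[d]) for d in datasets
            },
        }

    out = {"overall": _counts(records)}
    if class_label is not None:
        subset = [r for r in records if r.class_label == class_label]
        out["restricted"] = _counts(subset)
        out["restricted_to"] = class_label
    return out


def putative_calls_frame(calls: Iterable[PutativeCall]) -> pd.DataFrame:
    """Flatten putative calls into the output table schema."""
    rows = []
    for c in calls:
        row = {
            "seq_id": c.region.seq_id,
            "start": c.region.start,
            "end": c.region.end,
            "decision": c.decision,
            "rule_used": c.rule_used,
        }
        for d in sorted(c.evidence.marks):
            row[d] = c.evidence.marks[d]
        rows.append(row)
    return pd.DataFrame(rows)
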