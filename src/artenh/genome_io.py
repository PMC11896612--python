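"""Interval, sequence and table I/O plus the enhancer-naming convention.

All coordinates inside the package are 0-based half-open (BED convention).
Genome-browser style 1-based fully-closed coordinates, as printed in
publication tables, are converted at the boundary via
:meth:`GenomicInterval.from_one_based`.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO

VALID_STRANDS = ("+", "-", ".")

# IUPAC nucleotide codes plus the alignment gap character.
IUPAC_NT = set("ACGTURYSWKMBDHVN")
ALLOWED_SEQ_CHARS = IUPAC_NT | {"-"}

IN_VIVO_CLASSES = ("arterial", "pan_EC", "venous", "weak", "inactive")


class BedParseError(ValueError):
    """Raised for malformed or invalid BED lines; message names the line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A located span on a named sequence, 0-based half-open.

    Parameters
    ----------
    seq_id : str
        Chromosome / contig / assembly-sequence name.
    start, end : int
        0-based half-open span; ``start < end`` is enforced, so every
        interval has positive width.
    strand : str
        One of ``+``, ``-`` or ``.`` (unstranded).
    """

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.seq_id:
            raise ValueError("seq_id must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"interval must have positive width: start={self.start} end={self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    @classmethod
    def from_one_based(
        cls, seq_id: str, start: int, end: int, strand: str = "."
    ) -> "GenomicInterval":
        """Build from 1-based fully-closed coordinates (browser convention)."""
        return cls(seq_id, start - 1, end, strand)

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two spans share >= 1 bp on the same sequence."""
        return (
            self.seq_id == other.seq_id
            and max(self.start, other.start) < min(self.end, other.end)
        )

    def intersection_width(self, other: "GenomicInterval") -> int:
        if self.seq_id != other.seq_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class GeneAnchor:
    """A gene's transcriptional start site and orientation."""

    gene_name: str
    tss: GenomicInterval
    gene_strand: str

    def __post_init__(self) -> None:
        if self.tss.width != 1:
            raise ValueError(f"TSS interval must have width 1, got {self.tss.width}")
        if self.gene_strand not in ("+", "-"):
            raise ValueError("gene_strand must be '+' or '-'")

    @property
    def tss_pos(self) -> int:
        return self.tss.start


# Convention produced by name_enhancer: gene, sign, integer kb distance.
NAME_PATTERN = re.compile(r"^(?P<gene>.+?)(?P<sign>[+-])(?P<kb>\d+)$")


@dataclass
class EnhancerRecord:
    """A named candidate or validated enhancer with class annotations.

    Names produced by :func:`name_enhancer` follow ``<gene><sign><kb>``;
    historical names from the literature (e.g. intronic "in3" forms) are
    accepted as-is.
    """

    name: str
    gene: str
    interval: Optional[GenomicInterval] = None
    species: str = "mouse"
    orthologue_interval: Optional[GenomicInterval] = None
    in_vivo_class: Optional[str] = None
    in_silico_class: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("enhancer name must be non-empty")
        if self.in_vivo_class is not None and self.in_vivo_class not in IN_VIVO_CLASSES:
            raise ValueError(
                f"in_vivo_class must be one of {IN_VIVO_CLASSES}, got {self.in_vivo_class!r}"
            )


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 (extra columns, e.g. narrowPeak, are ignored).

    Comment (``#``), ``track`` and ``browser`` lines are skipped. Malformed
    or invalid lines raise :class:`BedParseError` naming the line number.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            strand = "."
            if len(fields) >= 6 and fields[5] in VALID_STRANDS:
                strand = fields[5]
            try:
                intervals.append(GenomicInterval(fields[0], start, end, strand))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED6 (name '.', score 0); round-trips read_bed."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into {id: uppercase sequence}; ids up to first whitespace.

    Duplicate ids and non-IUPAC characters (gap ``-`` allowed, for aligned
    FASTA) raise ``ValueError``.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        bad = set(seq) - ALLOWED_SEQ_CHARS
        if bad:
            raise ValueError(
                f"non-IUPAC characters {sorted(bad)} in FASTA record {rec.id!r}"
            )
        records[rec.id] = seq
    return records


def write_fasta(records: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def name_enhancer(anchor: GeneAnchor, enhancer: GenomicInterval) -> str:
    """Name an enhancer by its gene and signed kb distance from the TSS.

    Distance is from the enhancer midpoint to the TSS, rounded to the
    nearest kb with ties away from zero. The sign is "+" when the enhancer
    lies downstream of the TSS in the direction of transcription, "-" when
    upstream; a zero-kb distance renders as "+0".
    """
    if anchor.tss.seq_id != enhancer.seq_id:
        raise ValueError(
            f"anchor on {anchor.tss.seq_id} but enhancer on {enhancer.seq_id}"
        )
    offset = enhancer.midpoint - anchor.tss_pos
    if anchor.gene_strand == "-":
        offset = -offset
    kb = int(math.floor(abs(offset) / 1000.0 + 0.5))
    sign = "+" if (offset >= 0 or kb == 0) else "-"
    return f"{anchor.gene_name}{sign}{kb}"


class OrthologyMap:
    """Cross-species coordinate mapping through explicit alignment blocks.

    Each block pairs a source interval with an equally oriented target
    interval; positions map linearly within a block. This models browser
    alignment blocks without a chain-file engine.
    """

    def __init__(self, blocks: list[tuple[GenomicInterval, GenomicInterval]]):
        self.blocks = list(blocks)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "OrthologyMap":
        df = pd.read_csv(path, sep="\t", comment="#")
        required = {
            "source_seq", "source_start", "source_end",
            "target_seq", "target_start", "target_end",
        }
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"orthology map missing columns: {sorted(missing)}")
        blocks = []
        for row in df.itertuples(index=False):
            blocks.append(
                (
                    GenomicInterval(row.source_seq, int(row.source_start), int(row.source_end)),
                    GenomicInterval(row.target_seq, int(row.target_start), int(row.target_end)),
                )
            )
        return cls(blocks)

    def write_tsv(self, path: str | Path) -> None:
        rows = [
            {
                "source_seq": s.seq_id, "source_start": s.start, "source_end": s.end,
                "target_seq": t.seq_id, "target_start": t.start, "target_end": t.end,
            }
            for s, t in self.blocks
        ]
        pd.DataFrame(
            rows,
            columns=["source_seq", "source_start", "source_end",
                     "target_seq", "target_start", "target_end"],
        ).to_csv(path, sep="\t", index=False)

    def map_interval(self, region: GenomicInterval) -> list[GenomicInterval]:
        """Map a region into target coordinates; [] when unmappable."""
        mapped: list[GenomicInterval] = []
        for src, tgt in self.blocks:
            if not region.overlaps(src):
                continue
            scale = tgt.width / src.width
            lo = max(region.start, src.start)
            hi = min(region.end, src.end)
            t_lo = tgt.start + int(round((lo - src.start) * scale))
            t_hi = tgt.start + int(round((hi - src.start) * scale))
            if t_hi <= t_lo:
                t_hi = t_lo + 1
            mapped.append(GenomicInterval(tgt.seq_id, t_lo, min(t_hi, tgt.end) if t_hi > t_lo else t_hi))
        return mapped


ENHANCER_TABLE_COLUMNS = [
    "name", "species", "seq_id", "start", "end", "strand",
    "gene", "in_vivo_class", "in_silico_class",
]


def read_enhancer_table(path: str | Path) -> list[EnhancerRecord]:
    """Read the tab-separated enhancer table (header required)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"in_vivo_class": "string", "in_silico_class": "string"})
    missing = set(ENHANCER_TABLE_COLUMNS[:7]) - set(df.columns)
    if missing:
        raise ValueError(f"enhancer table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            EnhancerRecord(
                name=str(row.name),
                gene=str(row.gene),
                interval=GenomicInterval(str(row.seq_id), int(row.start), int(row.end), str(row.strand)),
                species=str(row.species),
                in_vivo_class=None if pd.isna(getattr(row, "in_vivo_class", None)) else str(row.in_vivo_class),
                in_silico_class=None if pd.isna(getattr(row, "in_silico_class", None)) else str(row.in_silico_class),
            )
        )
    return records


def write_enhancer_table(records: Iterable[EnhancerRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "name": r.name, "species": r.species,
                "seq_id": r.interval.seq_id, "start": r.interval.start,
                "end": r.interval.end, "strand": r.interval.strand,
                "gene": r.gene,
                "in_vivo_class": r.in_vivo_class or "",
                "in_silico_class": r.in_silico_class or "",
            }
        )
    pd.DataFrame(rows, columns=ENHANCER_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def merge_intervals(
    intervals: Iterable[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals whose spans are closer than ``gap`` bp, per seq_id.

    Output is sorted by (seq_id, start); strand information is dropped
    (merged spans are unstranded).
    """
    by_seq: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_seq.setdefault(iv.seq_id, []).append(iv)
    merged: list[GenomicInterval] = []
    for seq_id in sorted(by_seq):
        ivs = sorted(by_seq[seq_id], key=lambda i: (i.start, i.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end + gap:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(seq_id, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(seq_id, cur_start, cur_end))
    return merged
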