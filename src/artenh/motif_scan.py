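"""TF-family motif scanning, FOX:ETS composite detection, conservation tiers.

Motifs are IUPAC consensus strings (an optional position weight matrix with
a score threshold may replace consensus matching). Each hit inside an
enhancer core is assigned one of three conservation tiers against an
orthologous alignment:

* ``strong`` — the motif is conserved to the same phylogenetic depth as the
  surrounding enhancer sequence (every species in which the core aligns
  also matches the motif, human included);
* ``weak``   — conserved in the orthologous human sequence but not to the
  full depth of the core;
* ``none``   — not conserved in the orthologous human sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    # N matches anything, including an N in the scanned sequence; every
    # other code rejects sequence N.
    "N": frozenset("ACGTN"),
}

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A", "U": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N", "-": "-",
}

STRONG, WEAK, NONE = "strong", "weak", "none"
TIERS = (STRONG, WEAK, NONE)


def reverse_complement(seq: str) -> str:
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq))
    except KeyError as exc:
        raise ValueError(f"cannot complement character {exc.args[0]!r}") from exc


def matches_consensus(window: str, consensus: str) -> bool:
    """IUPAC match of a sequence window against a consensus of equal length."""
    if len(window) != len(consensus):
        return False
    return all(b in IUPAC[c] for b, c in zip(window, consensus))


@dataclass(frozen=True)
class MotifDefinition:
    """A TF-family binding motif.

    ``composite_of`` marks compound elements: a pair of member families and
    a maximum gap (bp) between them, e.g. the FOX:ETS vasculogenic element.
    """

    family: str
    consensus: str
    matrix: Optional[tuple[tuple[float, ...], ...]] = None  # rows A,C,G,T x width
    threshold: Optional[float] = None
    composite_of: Optional[tuple[str, str]] = None
    composite_window: int = 2

    def __post_init__(self) -> None:
        bad = set(self.consensus.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC code(s) {sorted(bad)} in consensus {self.consensus!r}")
        if self.matrix is not None:
            if len(self.matrix) != 4:
                raise ValueError("weight matrix must have 4 rows (A,C,G,T)")
            if any(len(row) != len(self.consensus) for row in self.matrix):
                raise ValueError("weight-matrix width must equal consensus length")
            if self.threshold is None:
                raise ValueError("a weight matrix requires a score threshold")

    @property
    def width(self) -> int:
        return len(self.consensus)


@dataclass
class MotifHit:
    """One motif match inside an enhancer core (0-based half-open coords).

    ``matched_sequence`` is reported in the orientation of the hit, so it
    matches the consensus directly on either strand.
    """

    enhancer: str
    family: str
    start: int
    end: int
    strand: str
    matched_sequence: str
    tier: Optional[str] = None
    composite_member: bool = False

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.matched_sequence):
            raise ValueError("hit span must equal matched sequence length")
        if self.strand not in ("+", "-"):
            raise ValueError("hit strand must be '+' or '-'")
        if self.tier is not None and self.tier not in TIERS:
            raise ValueError(f"tier must be one of {TIERS}")


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _pwm_score(window: str, matrix) -> float:
    score = 0.0
    for j, b in enumerate(window):
        i = _BASE_INDEX.get(b)
        if i is None:
            return -math.inf
        score += matrix[i][j]
    return score


def scan_consensus(
    sequence: str, motif: MotifDefinition, enhancer: str = ""
) -> list[MotifHit]:
    """Report every match of the motif on both strands of ``sequence``.

    Overlapping matches are all reported; hits are sorted by start, then
    strand ('+' before '-'). Tier is left unset.
    """
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
    consensus = motif.consensus.upper()
    rc_consensus = reverse_complement(consensus)
    w = motif.width
    hits: list[MotifHit] = []
    for i in range(len(seq) - w + 1):
        window = seq[i : i + w]
        if motif.matrix is not None:
            fwd = _pwm_score(window, motif.matrix) >= motif.threshold
            rev = _pwm_score(reverse_complement(window), motif.matrix) >= motif.threshold
        else:
            fwd = matches_consensus(window, consensus)
            rev = matches_consensus(window, rc_consensus)
        if fwd:
            hits.append(MotifHit(enhancer, motif.family, i, i + w, "+", window))
        if rev:
            hits.append(MotifHit(enhancer, motif.family, i, i + w, "-", reverse_complement(window)))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def detect_composite_fox_ets(
    fox_hits: Sequence[MotifHit],
    ets_hits: Sequence[MotifHit],
    window: int = 2,
) -> None:
    """Flag FOX hits forming a FOX:ETS composite element (in place).

    A FOX hit is a composite member when a same-strand ETS hit lies
    immediately 3' of it (in motif orientation) with at most ``window`` bp
    of gap; the paired ETS hit is flagged too. FOX hits left unflagged are
    "independent FOX" sites.
    """
    for fox in fox_hits:
        for ets in ets_hits:
            if fox.strand != ets.strand:
                continue
            if fox.strand == "+":
                gap = ets.start - fox.end
            else:
                gap = fox.start - ets.end
            if 0 <= gap <= window:
                fox.composite_member = True
                ets.composite_member = True


@dataclass
class AlignmentProfile:
    """Orthologous sequences aligned to one enhancer core.

    Rows are equal-length aligned strings over IUPAC codes plus ``-``;
    the reference species comes first in ``species`` and its row, gaps
    removed, is the scanned core sequence. Species are ordered by
    divergence from the reference.
    """

    enhancer: str
    species: list[str]
    rows: dict[str, str]
    reference: str = ""

    def __post_init__(self) -> None:
        if not self.reference:
            self.reference = self.species[0]
        if self.reference not in self.rows:
            raise ValueError(f"reference species {self.reference!r} missing from rows")
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("aligned rows must all have equal length")
        if set(self.species) != set(self.rows):
            raise ValueError("species list and rows must cover the same species")

    @property
    def reference_core(self) -> str:
        return self.rows[self.reference].replace("-", "")

    def core_columns(self) -> list[int]:
        """Alignment columns at which the reference row is non-gap."""
        return [i for i, b in enumerate(self.rows[self.reference]) if b != "-"]


def classify_conservation_tier(
    hit: MotifHit,
    profile: AlignmentProfile,
    motif: MotifDefinition,
    human_species: str = "human",
    coverage_threshold: float = 0.5,
) -> str:
    """Assign a conservation tier to one hit.

    The enhancer's conservation depth ``D_e`` is the set of species whose
    aligned row covers at least ``coverage_threshold`` of the core with
    non-gap bases. ``D_m`` is the set of species whose aligned bases at the
    hit's columns match the consensus (gaps fail). Tier is ``strong`` when
    human matches and ``D_e`` is a subset of ``D_m``, ``weak`` when human
    matches but some core-depth species does not, ``none`` when the human
    row does not match.
    """
    cols = profile.core_columns()
    if hit.end > len(cols):
        raise ValueError(
            f"hit [{hit.start},{hit.end}) outside reference core of length {len(cols)}"
        )
    hit_cols = cols[hit.start : hit.end]
    ref_window = "".join(profile.rows[profile.reference][c] for c in hit_cols)
    ref_oriented = ref_window if hit.strand == "+" else reverse_complement(ref_window)
    if motif.matrix is None and not matches_consensus(ref_oriented, motif.consensus.upper()):
        raise ValueError(
            f"reference row window {ref_window!r} does not match the hit for {hit.family}"
        )

    n_core = len(cols)
    depth_set: set[str] = set()
    match_set: set[str] = set()
    for sp in profile.species:
        row = profile.rows[sp]
        covered = sum(1 for c in cols if row[c] != "-")
        if covered / n_core >= coverage_threshold:
            depth_set.add(sp)
        window = "".join(row[c] for c in hit_cols)
        if "-" in window:
            continue
        oriented = window if hit.strand == "+" else reverse_complement(window)
        if motif.matrix is not None:
            if _pwm_score(oriented, motif.matrix) >= motif.threshold:
                match_set.add(sp)
        elif matches_consensus(oriented, motif.consensus.upper()):
            match_set.add(sp)

    if human_species not in match_set:
        return NONE
    if depth_set <= match_set:
        return STRONG
    return WEAK


def summarize_motifs_per_enhancer(
    hits: Sequence[MotifHit], composite_label: str = "FOX:ETS"
) -> dict[str, Optional[str]]:
    """Collapse tiered hits into the per-family M/m/absent encoding.

    Status is ``M`` when the family has at least one strongly conserved
    hit, ``m`` when it has only weakly conserved hits, absent (None)
    otherwise; tier-``none`` hits never confer status. Composite-member FOX
    hits are excluded from the independent FOX status and reported under
    ``composite_label`` instead.
    """
    enhancers = {h.enhancer for h in hits}
    if len(enhancers) > 1:
        raise ValueError(f"hits span multiple enhancers: {sorted(enhancers)}")
    status: dict[str, Optional[str]] = {}

    def _accumulate(key: str, tier: Optional[str]) -> None:
        if tier == STRONG:
            status[key] = "M"
        elif tier == WEAK and status.get(key) != "M":
            status[key] = "m"
        else:
            status.setdefault(key, None)

    for h in hits:
        if h.family == "FOX" and h.composite_member:
            _accumulate(composite_label, h.tier)
        else:
            _accumulate(h.family, h.tier)
    return status


# Default consensus set. RBPJ (TGGGAA) and the ETS core (HGGAAR) follow the
# published consensi; the remaining families use standard literature
# consensi and are meant to be overridden by a user-supplied motif file
# when reproducing any specific study's tallies.
DEFAULT_MOTIFS: tuple[MotifDefinition, ...] = (
    MotifDefinition("ETS", "HGGAAR"),
    MotifDefinition("RBPJ", "TGGGAA"),
    MotifDefinition("SOX", "WWCAAW"),
    MotifDefinition("FOX", "RYAAAYA"),
    MotifDefinition("MEF2", "CTAWWWWTAG"),
    MotifDefinition("NR2F2", "TGACCT"),
    MotifDefinition("KLF4", "GGGGNGGGG"),
    MotifDefinition("TCF_LEF", "CTTTGWW"),
    MotifDefinition("SMAD", "GGCGCC"),
)


def read_motif_tsv(path) -> list[MotifDefinition]:
    """Read motif definitions from TSV (family, consensus[, composite_of, window])."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"family", "consensus"} <= set(df.columns):
        raise ValueError("motif TSV requires 'family' and 'consensus' columns")
    defs = []
    for row in df.itertuples(index=False):
        composite = None
        if "composite_of" in df.columns and isinstance(row.composite_of, str) and row.composite_of:
            a, b = row.composite_of.split(",")
            composite = (a.strip(), b.strip())
        window = int(row.window) if "window" in df.columns and not _isna(row.window) else 2
        defs.append(
            MotifDefinition(str(row.family), str(row.consensus).upper(),
                            composite_of=composite, composite_window=window)
        )
    return defs


def _isna(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def scan_enhancer(
    profile: AlignmentProfile,
    motifs: Iterable[MotifDefinition] = DEFAULT_MOTIFS,
    human_species: str = "human",
    composite_window: int = 2,
    coverage_threshold: float = 0.5,
) -> list[MotifHit]:
    """Scan one enhancer core: consensus hits, composites, conservation tiers."""
    core = profile.reference_core
    all_hits: list[MotifHit] = []
    by_family: dict[str, list[MotifHit]] = {}
    for motif in motifs:
        if motif.composite_of is not None:
            continue
        hits = scan_consensus(core, motif, enhancer=profile.enhancer)
        for h in hits:
            h.tier = classify_conservation_tier(
                h, profile, motif,
                human_species=human_species,
                coverage_threshold=coverage_threshold,
            )
        by_family.setdefault(motif.family, []).extend(hits)
        all_hits.extend(hits)
    if "FOX" in by_family and "ETS" in by_family:
        detect_composite_fox_ets(by_family["FOX"], by_family["ETS"], window=composite_window)
    all_hits.sort(key=lambda h: (h.start, h.strand, h.family))
    return all_hits
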