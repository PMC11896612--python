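"""Class-wise cross-tabulation of motif/binding status and in vivo vs in
silico concordance.

Cells of the status table are (k, n): the number of enhancers in a class
whose per-family status falls in a chosen status set (e.g. {M}, {M, m},
{C}, {C, c}) over the class size. The enrichment contrast is an extension
over the raw fractions: a two-sided exact (hypergeometric) test on the
2x2 table, with a Haldane 0.5 correction on the odds ratio when a cell is
zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd
from scipy.stats import fisher_exact

from .genome_io import EnhancerRecord


@dataclass
class StatusProfile:
    """One enhancer's class label plus per-family status symbols.

    ``family_status`` maps family -> set of symbols from {M, m, C, c}
    (motif tier and binding status are independent dimensions, so a family
    can carry e.g. {"M", "C"}). An empty set means assessed-and-absent; a
    missing family means not assessed and is an error during tabulation.
    """

    name: str
    class_label: str
    family_status: dict[str, set] = field(default_factory=dict)


@dataclass
class SummaryTable:
    """Counts (k, n) per (family, class) for a chosen status set."""

    status_set: frozenset
    k: pd.DataFrame  # families x classes
    n: pd.Series  # class sizes

    def cell(self, family: str, class_label: str) -> tuple[int, int]:
        return int(self.k.loc[family, class_label]), int(self.n[class_label])

    def to_frame(self) -> pd.DataFrame:
        out = self.k.copy().astype(str)
        for cls in self.k.columns:
            out[cls] = [f"{int(v)}/{int(self.n[cls])}" for v in self.k[cls]]
        return out


def tabulate_status(
    profiles: Sequence[StatusProfile],
    status_set: Iterable[str],
    families: Optional[Sequence[str]] = None,
    classes: Optional[Sequence[str]] = None,
) -> SummaryTable:
    """Count, per family and class, enhancers whose status intersects
    ``status_set``."""
    status_set = frozenset(status_set)
    if families is None:
        families = sorted({f for p in profiles for f in p.family_status})
    if classes is None:
        classes = sorted({p.class_label for p in profiles})
    for p in profiles:
        if not p.class_label:
            raise ValueError(f"enhancer {p.name!r} has no class label")
        for fam in families:
            if fam not in p.family_status:
                raise ValueError(f"enhancer {p.name!r} missing status for family {fam!r}")
    n = pd.Series(
        {cls: sum(1 for p in profiles if p.class_label == cls) for cls in classes}
    )
    k = pd.DataFrame(0, index=list(families), columns=list(classes))
    for p in profiles:
        if p.class_label not in k.columns:
            continue
        for fam in families:
            if p.family_status[fam] & status_set:
                k.loc[fam, p.class_label] += 1
    return SummaryTable(status_set, k, n)


def enrichment_contrast(
    table: SummaryTable, family: str, class_a: str, class_b: str
) -> tuple[float, float]:
    """Odds ratio and two-sided exact p-value for one family between two
    classes.

    The p-value sums all 2x2 tables with the same margins whose
    hypergeometric probability does not exceed the observed table's. The
    odds ratio uses a Haldane 0.5 correction when any cell is zero. Note
    this test is an extension: the source analyses report raw fractions
    only.
    """
    k_a, n_a = table.cell(family, class_a)
    k_b, n_b = table.cell(family, class_b)
    if n_a == 0 or n_b == 0:
        raise ValueError("both classes must be nonempty")
    cells = [[k_a, n_a - k_a], [k_b, n_b - k_b]]
    _, pvalue = fisher_exact(cells, alternative="two-sided")
    a, b, c, d = k_a, n_a - k_a, k_b, n_b - k_b
    if 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds_ratio = (a * d) / (b * c)
    return odds_ratio, float(pvalue)


@dataclass
class ConcordanceTable:
    """Contingency of in vivo classes (rows) vs in silico labels (columns)."""

    counts: pd.DataFrame

    def cell(self, in_vivo: str, in_silico: str) -> int:
        try:
            return int(self.counts.loc[in_vivo, in_silico])
        except KeyError:
            return 0

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)


def concordance(enhancers: Sequence[EnhancerRecord]) -> ConcordanceTable:
    """Cross-tabulate in vivo activity classes against in silico labels.

    Every record must carry both labels; in silico labels are opaque
    strings matched exactly.
    """
    for e in enhancers:
        if e.in_vivo_class is None:
            raise ValueError(f"enhancer {e.name!r} missing in_vivo_class")
        if e.in_silico_class is None:
            raise ValueError(f"enhancer {e.name!r} missing in_silico_class")
    rows = [e.in_vivo_class for e in enhancers]
    cols = [e.in_silico_class for e in enhancers]
    counts = pd.crosstab(pd.Series(rows, name="in_vivo"), pd.Series(cols, name="in_silico"))
    return ConcordanceTable(counts)


def render_status_grid(profiles: Sequence[StatusProfile],
                       families: Sequence[str]) -> str:
    """Plain-text M/m/C/c grid, one row per enhancer."""
    width = max((len(p.name) for p in profiles), default=4)
    header = "enhancer".ljust(width) + "\tclass\t" + "\t".join(families)
    lines = [header]
    for p in profiles:
        cells = []
        for fam in families:
            syms = p.family_status.get(fam, set())
            order = [s for s in ("M", "m", "C", "c") if s in syms]
            cells.append("".join(order) if order else ".")
        lines.append(p.name.ljust(width) + f"\t{p.class_label}\t" + "\t".join(cells))
    return "\n".join(lines)
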