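"""Transgenic reporter-assay activity classification.

An enhancer is called active when vascular GFP appears in strictly more
than 5% of injected mosaic transgenic embryos. The weak/strong split is an
input annotation ("weak GFP and/or limited to a small number of ECs" is a
qualitative judgement made at the microscope, not recomputable from
counts).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

ACTIVE_STRONG = "active_strong"
ACTIVE_WEAK = "active_weak"
INACTIVE = "inactive"

DEFAULT_THRESHOLD = 0.05


@dataclass(frozen=True)
class AssayCount:
    enhancer: str
    n_injected: int
    n_gfp_positive: int
    weak_flag: bool = False
    pattern_label: Optional[str] = None  # arterial / venous / pan_EC

    def __post_init__(self) -> None:
        if self.n_injected <= 0:
            raise ValueError(f"{self.enhancer}: n_injected must be positive")
        if not 0 <= self.n_gfp_positive <= self.n_injected:
            raise ValueError(
                f"{self.enhancer}: n_gfp_positive must lie in [0, n_injected]"
            )


@dataclass(frozen=True)
class ActivityCall:
    enhancer: str
    fraction_positive: float
    decision: str


def classify_activity(
    count: AssayCount, threshold: float = DEFAULT_THRESHOLD
) -> ActivityCall:
    """Strictly-greater-than threshold rule on the GFP-positive fraction."""
    frac = count.n_gfp_positive / count.n_injected
    if frac > threshold:
        decision = ACTIVE_WEAK if count.weak_flag else ACTIVE_STRONG
    else:
        decision = INACTIVE
    return ActivityCall(count.enhancer, frac, decision)


@dataclass
class ActivitySummary:
    n_active: int
    n_active_strong: int
    n_active_weak: int
    n_inactive: int
    calls: list[ActivityCall]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "enhancer": c.enhancer,
                    "fraction_positive": c.fraction_positive,
                    "decision": c.decision,
                }
                for c in self.calls
            ]
        )


def cohort_activity_summary(
    counts: Sequence[AssayCount], threshold: float = DEFAULT_THRESHOLD
) -> ActivitySummary:
    """Classify every assay and tally active (strong + weak) vs inactive."""
    calls = [classify_activity(c, threshold) for c in counts]
    n_strong = sum(1 for c in calls if c.decision == ACTIVE_STRONG)
    n_weak = sum(1 for c in calls if c.decision == ACTIVE_WEAK)
    n_inactive = sum(1 for c in calls if c.decision == INACTIVE)
    return ActivitySummary(n_strong + n_weak, n_strong, n_weak, n_inactive, calls)


def read_assay_counts(path) -> list[AssayCount]:
    """Read assay counts from TSV (enhancer, n_injected, n_gfp_positive
    [, weak_flag, pattern_label])."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"enhancer", "n_injected", "n_gfp_positive"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"assay count table missing columns: {sorted(missing)}")
    counts = []
    for row in df.itertuples(index=False):
        weak = bool(getattr(row, "weak_flag", False)) if "weak_flag" in df.columns else False
        label = getattr(row, "pattern_label", None) if "pattern_label" in df.columns else None
        if isinstance(label, float) or label in ("", None):
            label = None
        counts.append(
            AssayCount(str(row.enhancer), int(row.n_injected), int(row.n_gfp_positive),
                       weak_flag=weak, pattern_label=label)
        )
    return counts
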