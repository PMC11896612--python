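"""Packaged reference tables and their loaders.

Two small TSVs ship with the package:

* ``known_ec_enhancer_marks.tsv`` — 32 published in vivo-validated
  endothelial enhancers (eight of them arterial) with per-dataset
  enhancer-mark evidence in two human and three mouse datasets.
* ``transgenic_screen.tsv`` — the mosaic transgenic zebrafish screen of
  putative arterial enhancers: injection/GFP counts, in vivo activity
  classes and the independent in silico (HUVEC vs HUAEC chromatin)
  designations, plus the eight previously published arterial enhancers.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .activity import AssayCount
from .enhancer_calling import HUMAN, MOUSE, MarkedEnhancer, MarkEvidence
from .genome_io import EnhancerRecord, GenomicInterval

MARK_DATASETS = {
    "h_dnase": HUMAN,
    "h_histone": HUMAN,
    "m_artery_atac": MOUSE,
    "m_retina_atac": MOUSE,
    "m_e11_p300": MOUSE,
}


def _data_path(filename: str):
    return resources.files("artenh.data").joinpath(filename)


def load_known_enhancer_marks() -> list[MarkedEnhancer]:
    """The 32 known EC enhancers as records with complete mark evidence.

    Mark values ``yes*`` (signal extending to many non-EC cell types)
    count as evidence but set the non-specific flag. The eight published
    arterial enhancers carry ``class_label='arterial'``.
    """
    with resources.as_file(_data_path("known_ec_enhancer_marks.tsv")) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    records = []
    for row in df.itertuples(index=False):
        region = GenomicInterval.from_one_based(
            str(row.mm9_seq), int(row.mm9_start), int(row.mm9_end)
        )
        marks, nonspecific = {}, {}
        for d in MARK_DATASETS:
            val = str(getattr(row, d)).strip().lower()
            marks[d] = val.startswith("yes")
            if val == "yes*":
                nonspecific[d] = True
        records.append(
            MarkedEnhancer(
                name=str(row.name),
                evidence=MarkEvidence(region, marks, dict(MARK_DATASETS), nonspecific),
                class_label="arterial" if int(row.arterial) == 1 else None,
            )
        )
    return records


def load_transgenic_screen() -> pd.DataFrame:
    """The transgenic screen table as a DataFrame (one row per region)."""
    with resources.as_file(_data_path("transgenic_screen.tsv")) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    df["published"] = df["published"].astype(bool)
    df["weak_flag"] = df["weak_flag"].astype(bool)
    return df


def screen_assay_counts(df: pd.DataFrame | None = None) -> list[AssayCount]:
    """Assay counts for every screen row with printed injection numbers."""
    if df is None:
        df = load_transgenic_screen()
    counts = []
    for row in df.itertuples(index=False):
        if pd.isna(row.n_injected) or pd.isna(row.n_gfp_positive):
            continue
        counts.append(
            AssayCount(
                enhancer=str(row.name),
                n_injected=int(row.n_injected),
                n_gfp_positive=int(row.n_gfp_positive),
                weak_flag=bool(row.weak_flag),
            )
        )
    return counts


def screen_enhancer_records(
    df: pd.DataFrame | None = None,
    published: bool | None = None,
    in_vivo_class: str | None = None,
) -> list[EnhancerRecord]:
    """Screen rows as label-carrying records (no coordinates in this table).

    ``published`` / ``in_vivo_class`` filter the rows; None keeps all.
    """
    if df is None:
        df = load_transgenic_screen()
    records = []
    for row in df.itertuples(index=False):
        if published is not None and bool(row.published) != published:
            continue
        if in_vivo_class is not None and str(row.in_vivo_class) != in_vivo_class:
            continue
        records.append(
            EnhancerRecord(
                name=str(row.name),
                gene=str(row.gene),
                in_vivo_class=str(row.in_vivo_class),
                in_silico_class=str(row.in_silico_label),
            )
        )
    return records
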