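"""Stage orchestration behind the command-line interface.

Stages run in a fixed order — call-enhancers, scan-motifs, call-binding,
classify-activity, summarize — each reading and writing only the
documented TSV/BED/FASTA formats, so they are independently runnable.
Every output table opens with a provenance comment block (tool version,
manifest hash, seed); reruns on unchanged inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .activity import cohort_activity_summary, read_assay_counts
from .binding_overlap import PeakSet, call_binding
from .class_summary import StatusProfile, concordance, tabulate_status
from .enhancer_calling import (
    MOUSE,
    MarkTrack,
    TranscriptionStatus,
    build_candidate_regions,
    call_putative,
    collect_mark_evidence,
    putative_calls_frame,
)
from .genome_io import (
    GenomicInterval,
    OrthologyMap,
    read_bed,
    read_enhancer_table,
    read_fasta,
)
from .motif_scan import (
    DEFAULT_MOTIFS,
    AlignmentProfile,
    read_motif_tsv,
    scan_enhancer,
    summarize_motifs_per_enhancer,
)

log = logging.getLogger("artenh")

STAGES = ("call-enhancers", "scan-motifs", "call-binding", "classify-activity", "summarize")


@dataclass
class RunManifest:
    """Paths and parameters for a full pipeline run.

    Paths are resolved relative to the manifest file's directory. The
    manifest file itself is a flat ``key=value`` text file.
    """

    base_dir: Path
    marks_manifest: str = "marks_manifest.tsv"
    orthology: str = "orthology.tsv"
    alignments_dir: str = "alignments"
    peaks_manifest: str = "peaks_manifest.tsv"
    assay_counts: str = "assay_counts.tsv"
    transcription_status: str = "transcription_status.tsv"
    enhancers: str = "enhancers.tsv"
    loci: str = "loci.tsv"
    motifs: str = ""  # empty -> built-in default motif set
    out_dir: str = "pipeline_out"
    merge_gap: int = 500
    activity_threshold: float = 0.05
    composite_window: int = 2
    coverage_threshold: float = 0.5
    seed: int = 0

    def path(self, key: str) -> Path:
        return self.base_dir / getattr(self, key)

    @property
    def out(self) -> Path:
        return self.base_dir / self.out_dir


_INT_KEYS = {"merge_gap", "composite_window", "seed"}
_FLOAT_KEYS = {"activity_threshold", "coverage_threshold"}


def parse_manifest(path: str | Path) -> RunManifest:
    path = Path(path)
    manifest = RunManifest(base_dir=path.parent.resolve())
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if not hasattr(manifest, key) or key == "base_dir":
            raise ValueError(f"{path}:{lineno}: unknown manifest key {key!r}")
        if key in _INT_KEYS:
            setattr(manifest, key, int(value))
        elif key in _FLOAT_KEYS:
            setattr(manifest, key, float(value))
        else:
            setattr(manifest, key, value)
    return manifest


def validate_manifest(manifest: RunManifest) -> list[str]:
    """Collect every problem at once; an empty list means runnable."""
    findings: list[str] = []
    for key in ("marks_manifest", "orthology", "peaks_manifest", "assay_counts",
                "transcription_status", "enhancers", "loci"):
        p = manifest.path(key)
        if not p.exists():
            findings.append(f"missing input file for {key!r}: {p}")
    if not manifest.path("alignments_dir").is_dir():
        findings.append(f"alignments_dir is not a directory: {manifest.path('alignments_dir')}")
    if manifest.motifs and not manifest.path("motifs").exists():
        findings.append(f"motif file not found: {manifest.path('motifs')}")
    if manifest.merge_gap < 0:
        findings.append(f"merge_gap must be >= 0, got {manifest.merge_gap}")
    if not 0 < manifest.activity_threshold < 1:
        findings.append(
            f"activity_threshold must lie in (0, 1), got {manifest.activity_threshold}"
        )
    if not 0 < manifest.coverage_threshold <= 1:
        findings.append(
            f"coverage_threshold must lie in (0, 1], got {manifest.coverage_threshold}"
        )
    if manifest.composite_window < 0:
        findings.append(f"composite_window must be >= 0, got {manifest.composite_window}")
    # Referenced per-dataset paths, when the manifests themselves exist.
    for key, col in (("marks_manifest", "path"), ("peaks_manifest", "path")):
        p = manifest.path(key)
        if p.exists():
            sub = pd.read_csv(p, sep="\t", comment="#")
            for rel in sub[col]:
                if not (manifest.base_dir / rel).exists():
                    findings.append(f"{key} references missing file: {rel}")
    return findings


def _manifest_hash(manifest: RunManifest) -> str:
    payload = json.dumps(
        {k: str(v) for k, v in vars(manifest).items() if k != "base_dir"},
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_table(df: pd.DataFrame, path: Path, manifest: RunManifest) -> None:
    with open(path, "w") as fh:
        fh.write(f"# artenh {__version__}\n")
        fh.write(f"# manifest_hash={_manifest_hash(manifest)}\n")
        fh.write(f"# seed={manifest.seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def _load_mark_tracks(manifest: RunManifest) -> list[MarkTrack]:
    df = pd.read_csv(manifest.path("marks_manifest"), sep="\t", comment="#")
    tracks = []
    for row in df.itertuples(index=False):
        intervals = read_bed(manifest.base_dir / row.path)
        specific = bool(getattr(row, "ec_specific", True))
        tracks.append(
            MarkTrack(
                dataset_id=str(row.dataset_id),
                species=str(row.species),
                intervals=intervals,
                assembly=str(row.species),
                specific=[specific] * len(intervals),
            )
        )
    return tracks


def stage_call_enhancers(manifest: RunManifest) -> pd.DataFrame:
    tracks = _load_mark_tracks(manifest)
    orthology = OrthologyMap.read_tsv(manifest.path("orthology"))
    loci = pd.read_csv(manifest.path("loci"), sep="\t", comment="#")
    tstat = pd.read_csv(manifest.path("transcription_status"), sep="\t", comment="#")
    tstat_by_gene = {
        str(r.gene_name): TranscriptionStatus(
            str(r.gene_name), bool(r.transcribed_human), bool(r.transcribed_mouse)
        )
        for r in tstat.itertuples(index=False)
    }
    mouse_tracks = [t for t in tracks if t.species == MOUSE]
    calls = []
    for row in loci.itertuples(index=False):
        locus = GenomicInterval(str(row.seq_id), int(row.start), int(row.end))
        status = tstat_by_gene.get(str(row.gene))
        if status is None:
            raise ValueError(f"no transcription status for gene {row.gene!r}")
        for region in build_candidate_regions(mouse_tracks, locus, manifest.merge_gap):
            evidence = collect_mark_evidence(region, tracks, orthology)
            calls.append(call_putative(evidence, status))
    df = putative_calls_frame(calls)
    manifest.out.mkdir(parents=True, exist_ok=True)
    _write_table(df, manifest.out / "putative_calls.tsv", manifest)
    log.info("call-enhancers: %d candidates, %d putative",
             len(df), int((df["decision"] == "putative").sum()) if len(df) else 0)
    return df


def _load_profiles(manifest: RunManifest) -> dict[str, AlignmentProfile]:
    profiles = {}
    for fa in sorted(manifest.path("alignments_dir").glob("*.fa")):
        rows = read_fasta(fa)
        species = list(rows)  # file order; reference first
        name = fa.stem
        profiles[name] = AlignmentProfile(name, species, rows, reference=species[0])
    return profiles


def stage_scan_motifs(manifest: RunManifest) -> tuple[pd.DataFrame, pd.DataFrame]:
    motifs = (
        read_motif_tsv(manifest.path("motifs")) if manifest.motifs else list(DEFAULT_MOTIFS)
    )
    profiles = _load_profiles(manifest)
    hit_rows, status_rows = [], []
    families = sorted({m.family for m in motifs if m.composite_of is None})
    for name in sorted(profiles):
        hits = scan_enhancer(
            profiles[name],
            motifs,
            composite_window=manifest.composite_window,
            coverage_threshold=manifest.coverage_threshold,
        )
        for h in hits:
            hit_rows.append(
                {
                    "enhancer": name, "family": h.family, "start": h.start,
                    "end": h.end, "strand": h.strand,
                    "matched_sequence": h.matched_sequence, "tier": h.tier,
                    "composite_member": h.composite_member,
                }
            )
        status = summarize_motifs_per_enhancer(hits)
        row = {"enhancer": name}
        for fam in families + ["FOX:ETS"]:
            row[fam] = status.get(fam) or "absent"
        status_rows.append(row)
    hits_df = pd.DataFrame(
        hit_rows,
        columns=["enhancer", "family", "start", "end", "strand",
                 "matched_sequence", "tier", "composite_member"],
    )
    status_df = pd.DataFrame(status_rows)
    manifest.out.mkdir(parents=True, exist_ok=True)
    _write_table(hits_df, manifest.out / "motif_hits.tsv", manifest)
    _write_table(status_df, manifest.out / "family_status.tsv", manifest)
    log.info("scan-motifs: %d enhancers, %d hits", len(profiles), len(hits_df))
    return hits_df, status_df


def stage_call_binding(manifest: RunManifest) -> pd.DataFrame:
    peaks_df = pd.read_csv(manifest.path("peaks_manifest"), sep="\t", comment="#")
    records = read_enhancer_table(manifest.path("enhancers"))
    status_df = pd.read_csv(manifest.out / "family_status.tsv", sep="\t", comment="#")
    status_by_enh = {
        str(r["enhancer"]): {
            fam: (None if r[fam] == "absent" else r[fam])
            for fam in status_df.columns
            if fam != "enhancer"
        }
        for _, r in status_df.iterrows()
    }
    rows = []
    for prow in peaks_df.itertuples(index=False):
        peaks = PeakSet(str(prow.tf), str(prow.path), read_bed(manifest.base_dir / prow.path))
        family = str(getattr(prow, "family", prow.tf))
        for rec in records:
            safe = rec.name.replace("/", "_")
            call = call_binding(rec, peaks, status_by_enh.get(safe, {}), family=family)
            rows.append({"enhancer": rec.name, "tf": prow.tf, "family": family,
                         "status": call.status})
    df = pd.DataFrame(rows, columns=["enhancer", "tf", "family", "status"])
    _write_table(df, manifest.out / "binding_calls.tsv", manifest)
    log.info("call-binding: %d calls, %d bound", len(df),
             int((df["status"] != "unbound").sum()) if len(df) else 0)
    return df


def stage_classify_activity(manifest: RunManifest) -> pd.DataFrame:
    counts = read_assay_counts(manifest.path("assay_counts"))
    summary = cohort_activity_summary(counts, threshold=manifest.activity_threshold)
    df = summary.to_frame()
    _write_table(df, manifest.out / "activity_calls.tsv", manifest)
    log.info("classify-activity: %d assays, %d active", len(counts), summary.n_active)
    return df


def stage_summarize(manifest: RunManifest) -> dict:
    records = read_enhancer_table(manifest.path("enhancers"))
    status_df = pd.read_csv(manifest.out / "family_status.tsv", sep="\t", comment="#")
    binding_df = pd.read_csv(manifest.out / "binding_calls.tsv", sep="\t", comment="#")
    activity_df = pd.read_csv(manifest.out / "activity_calls.tsv", sep="\t", comment="#")
    putative_df = pd.read_csv(manifest.out / "putative_calls.tsv", sep="\t", comment="#")

    families = [c for c in status_df.columns if c != "enhancer"]
    status_by_enh = {str(r["enhancer"]): r for _, r in status_df.iterrows()}
    binding_by_enh: dict[str, dict[str, str]] = {}
    for r in binding_df.itertuples(index=False):
        binding_by_enh.setdefault(str(r.enhancer), {})[str(r.family)] = str(r.status)

    profiles = []
    for rec in records:
        if rec.in_vivo_class is None:
            continue
        safe = rec.name.replace("/", "_")
        srow = status_by_enh.get(safe)
        fam_status: dict[str, set] = {}
        for fam in families:
            syms: set[str] = set()
            if srow is not None and srow[fam] in ("M", "m"):
                syms.add(str(srow[fam]))
            bstat = binding_by_enh.get(rec.name, {}).get(fam)
            if bstat in ("C", "c"):
                syms.add(bstat)
            fam_status[fam] = syms
        profiles.append(StatusProfile(rec.name, rec.in_vivo_class, fam_status))

    report: dict = {
        "n_candidate_regions": int(len(putative_df)),
        "n_putative": int((putative_df["decision"] == "putative").sum()) if len(putative_df) else 0,
        "n_enhancers_scanned": int(len(status_df)),
        "n_motif_hits": None,
        "activity": {
            "n_assays": int(len(activity_df)),
            "n_active": int((activity_df["decision"] != "inactive").sum()) if len(activity_df) else 0,
            "n_active_strong": int((activity_df["decision"] == "active_strong").sum()) if len(activity_df) else 0,
        },
    }
    hits_df = pd.read_csv(manifest.out / "motif_hits.tsv", sep="\t", comment="#")
    report["n_motif_hits"] = int(len(hits_df))

    if profiles:
        strong = tabulate_status(profiles, {"M"}, families=families)
        conserved = tabulate_status(profiles, {"M", "m"}, families=families)
        bound = tabulate_status(profiles, {"C", "c"}, families=families)
        _write_table(strong.to_frame().reset_index(names="family"),
                     manifest.out / "summary_strong_motifs.tsv", manifest)
        _write_table(conserved.to_frame().reset_index(names="family"),
                     manifest.out / "summary_conserved_motifs.tsv", manifest)
        _write_table(bound.to_frame().reset_index(names="family"),
                     manifest.out / "summary_binding.tsv", manifest)
        report["class_sizes"] = {c: int(n) for c, n in strong.n.items()}

    both_labelled = [r for r in records if r.in_vivo_class and r.in_silico_class]
    if both_labelled:
        table = concordance(both_labelled)
        _write_table(table.counts.reset_index(), manifest.out / "concordance.tsv", manifest)
        report["concordance_rows"] = {k: int(v) for k, v in table.row_totals.items()}

    with open(manifest.out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("summarize: report written to %s", manifest.out / "report.json")
    return report


def run_all(manifest: RunManifest) -> dict:
    """Validate, then execute every stage in order; returns the report.

    A failing stage raises after logging its name; outputs written by
    earlier stages are preserved.
    """
    findings = validate_manifest(manifest)
    if findings:
        raise ValueError("manifest validation failed:\n" + "\n".join(findings))
    stages = (
        ("call-enhancers", stage_call_enhancers),
        ("scan-motifs", stage_scan_motifs),
        ("call-binding", stage_call_binding),
        ("classify-activity", stage_classify_activity),
        ("summarize", stage_summarize),
    )
    result: dict = {}
    for name, fn in stages:
        try:
            result_stage = fn(manifest)
        except Exception:
            log.error("stage %s failed", name)
            raise
        if name == "summarize":
            result = result_stage
    return result
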