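"""Two-species synthetic gene loci with fully known ground truth.

The generator emulates the structure of an arterial gene locus screen:
planted enhancer cores carrying multi-dataset chromatin marks in mouse and
(through an explicit orthology block map) human, planted TF motifs at
controlled conservation tiers against a six-taxon species ladder, TF peak
tracks with controlled co-occupancy, and binomial injection/GFP assay
counts. Every downstream stage of the pipeline can therefore be scored
against an exact truth table without any genome download.

Orthologue rows are simulated by per-base substitution without indels
inside enhancer cores, so alignment columns are trivial: the tier logic,
not aligner behaviour, is what the outputs exercise. Conservation depth is
controlled by a per-enhancer alignment depth (a prefix of the species
ladder); planted motifs are kept intact or destroyed per species exactly
according to the planted tier (strong: intact in all aligning species;
weak: intact in human only; none: disrupted in the human row).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .activity import ACTIVE_STRONG, ACTIVE_WEAK, INACTIVE, AssayCount
from .binding_overlap import PeakSet
from .enhancer_calling import HUMAN, MOUSE, MarkTrack, TranscriptionStatus
from .genome_io import (
    EnhancerRecord,
    GeneAnchor,
    GenomicInterval,
    OrthologyMap,
    name_enhancer,
    write_bed,
    write_enhancer_table,
    write_fasta,
)
from .motif_scan import (
    DEFAULT_MOTIFS,
    IUPAC,
    AlignmentProfile,
    MotifDefinition,
    reverse_complement,
    scan_consensus,
)

# Species ladder ordered by divergence from the reference; the human row
# sits at index 2, so any alignment depth >= 3 includes it.
DEFAULT_SPECIES = ("mouse", "rat", "human", "dog", "chicken", "zebrafish")

# Per-species substitution rates outside motif positions (geometric growth
# with divergence rank, mimicking increasing branch length).
DEFAULT_SUBSTITUTION_RATES = {
    "rat": 0.04,
    "human": 0.08,
    "dog": 0.13,
    "chicken": 0.22,
    "zebrafish": 0.35,
}

MOUSE_DATASETS = ("m_artery_atac", "m_retina_atac", "m_e11_p300")
HUMAN_DATASETS = ("h_dnase", "h_histone")
ALL_DATASETS = MOUSE_DATASETS + HUMAN_DATASETS

DEFAULT_TFS = {"ERG": "ETS", "SOX17": "SOX", "FOXO1": "FOX", "RBPJ": "RBPJ", "MEF2C": "MEF2"}


@dataclass(frozen=True)
class PlantedMotif:
    family: str
    position: int  # 0-based offset within the enhancer core
    strand: str
    tier: str  # strong / weak / none


@dataclass
class PlantedEnhancer:
    """One planted enhancer: span, marks, motifs, peaks and true activity."""

    offset_from_tss: int  # signed bp from TSS to core start
    width: int
    class_label: str  # arterial / pan_EC / venous / weak / inactive
    marks: dict[str, bool]
    motifs: list[PlantedMotif] = field(default_factory=list)
    peaks: dict[str, bool] = field(default_factory=dict)
    activity_rate: float = 0.0
    weak_flag: bool = False
    align_depth: int = 6  # prefix length of the species ladder that aligns


@dataclass
class LocusSpec:
    gene: str
    length: int
    tss_pos: int
    strand: str
    enhancers: list[PlantedEnhancer]
    transcribed_human: bool = True

    def __post_init__(self) -> None:
        for enh in self.enhancers:
            start = self.tss_pos + enh.offset_from_tss
            if not (0 <= start and start + enh.width <= self.length):
                raise ValueError(
                    f"{self.gene}: planted enhancer at offset {enh.offset_from_tss} "
                    "falls outside the locus"
                )
            spans = sorted(
                (m.position, m.position + _motif_width(m.family)) for m in enh.motifs
            )
            for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
                if b0 < a1:
                    raise ValueError(
                        f"{self.gene}: planted motifs overlap within an enhancer core"
                    )
            for m in enh.motifs:
                if m.position + _motif_width(m.family) > enh.width:
                    raise ValueError(f"{self.gene}: planted motif outside its enhancer")


@dataclass
class CohortSpec:
    loci: list[LocusSpec]
    seed: int
    species: tuple[str, ...] = DEFAULT_SPECIES
    noise_marks_per_track: float = 2.0  # expected false marks per track per locus
    noise_mark_length: int = 400
    peak_jitter_sd: float = 50.0
    background_gc: float = 0.45
    n_injected_range: tuple[int, int] = (40, 250)


_MOTIF_BY_FAMILY = {m.family: m for m in DEFAULT_MOTIFS}


def _motif_width(family: str) -> int:
    return _MOTIF_BY_FAMILY[family].width


def _realize_consensus(consensus: str, rng: np.random.Generator) -> str:
    """Choose one concrete ACGT realization of an IUPAC consensus."""
    out = []
    for code in consensus:
        choices = sorted(IUPAC[code] - {"N"}) or list("ACGT")
        out.append(choices[rng.integers(len(choices))])
    return "".join(out)


def _realize_clean(
    motif: MotifDefinition, rng: np.random.Generator, max_tries: int = 200
) -> str:
    """Realize a consensus so the instance contains no match of any other
    default family (degenerate boxes can otherwise embed e.g. a FOX site
    inside a MEF2 realization, which could not be scrubbed later)."""
    for _ in range(max_tries):
        s = _realize_consensus(motif.consensus, rng)
        clean = True
        for other in DEFAULT_MOTIFS:
            if other.composite_of is not None or other.family == motif.family:
                continue
            if scan_consensus(s, other) or scan_consensus(reverse_complement(s), other):
                clean = False
                break
        if clean:
            return s
    raise ValueError(f"could not realize {motif.family} without embedded foreign motifs")


def _random_sequence(n: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def _forward_pattern(motif: MotifDefinition, strand: str) -> str:
    """Column-wise IUPAC pattern in reference orientation for a planted hit."""
    return motif.consensus if strand == "+" else reverse_complement(motif.consensus)


def _scrub_spurious(
    core: list[str],
    plants: Sequence[PlantedMotif],
    motifs: Iterable[MotifDefinition],
    rng: np.random.Generator,
    max_rounds: int = 50,
) -> None:
    """Mutate background bases until the core contains no motif matches
    other than the planted ones (in place)."""
    # Keyed on (family, position) only: a palindromic consensus (e.g. the
    # MEF2 box) matches both strands at the planted position by necessity.
    planted = {(m.family, m.position) for m in plants}
    protected = set()
    for m in plants:
        protected.update(range(m.position, m.position + _motif_width(m.family)))
    for _ in range(max_rounds):
        dirty = False
        seq = "".join(core)
        for motif in motifs:
            if motif.composite_of is not None:
                continue
            for hit in scan_consensus(seq, motif):
                if (motif.family, hit.start) in planted:
                    continue
                editable = [
                    j for j in range(hit.start, hit.end) if j not in protected
                ]
                if not editable:
                    raise ValueError(
                        "cannot scrub a spurious motif match inside a planted span"
                    )
                j = editable[rng.integers(len(editable))]
                pattern = motif.consensus if hit.strand == "+" else reverse_complement(motif.consensus)
                allowed = sorted(set("ACGT") - IUPAC[pattern[j - hit.start]])
                if not allowed:  # N position constrains nothing; try another
                    allowed = [b for b in "ACGT" if b != core[j]]
                core[j] = allowed[rng.integers(len(allowed))]
                dirty = True
        if not dirty:
            return
    raise ValueError("spurious-motif scrub did not converge")


def _destroy_motif(
    row: list[str], plant: PlantedMotif, rng: np.random.Generator
) -> None:
    """Substitute one base so the planted motif no longer matches in this row."""
    motif = _MOTIF_BY_FAMILY[plant.family]
    pattern = _forward_pattern(motif, plant.strand)
    constrained = [
        j for j, code in enumerate(pattern) if len(IUPAC[code] - {"N"}) < 4
    ]
    j = constrained[rng.integers(len(constrained))]
    allowed = sorted(set("ACGT") - IUPAC[pattern[j]])
    row[plant.position + j] = allowed[rng.integers(len(allowed))]


@dataclass
class LocusBundle:
    """Everything generated for one locus, in memory."""

    gene: str
    anchor: GeneAnchor
    locus: GenomicInterval
    human_seq_id: str
    human_shift: int
    ref_sequence: str
    mark_tracks: list[MarkTrack]
    orthology_blocks: list[tuple[GenomicInterval, GenomicInterval]]
    profiles: dict[str, AlignmentProfile]
    peak_sets: dict[str, PeakSet]
    assay_counts: list[AssayCount]
    transcription: TranscriptionStatus
    enhancer_records: list[EnhancerRecord]
    truth: pd.DataFrame


def generate_locus(
    spec: LocusSpec,
    seed: int,
    cohort: Optional[CohortSpec] = None,
    locus_index: int = 0,
) -> LocusBundle:
    """Generate one locus bundle with exact ground truth.

    ``seed`` plus the locus index fully determine the output (same inputs,
    byte-identical bundle).
    """
    cohort = cohort or CohortSpec(loci=[spec], seed=seed)
    rng = np.random.default_rng([seed, locus_index])
    seq_id = f"chr{spec.gene}_m"
    human_seq_id = f"chr{spec.gene}_h"
    human_shift = 5000
    locus = GenomicInterval(seq_id, 0, spec.length)
    anchor = GeneAnchor(
        spec.gene, GenomicInterval(seq_id, spec.tss_pos, spec.tss_pos + 1), spec.strand
    )
    ref_seq = list(_random_sequence(spec.length, cohort.background_gc, rng))

    species = list(cohort.species)
    sub_rates = DEFAULT_SUBSTITUTION_RATES

    profiles: dict[str, AlignmentProfile] = {}
    records: list[EnhancerRecord] = []
    blocks: list[tuple[GenomicInterval, GenomicInterval]] = []
    truth_rows: list[dict] = []
    track_intervals: dict[str, list[GenomicInterval]] = {d: [] for d in ALL_DATASETS}
    peak_intervals: dict[str, list[GenomicInterval]] = {tf: [] for tf in DEFAULT_TFS}
    assay_counts: list[AssayCount] = []

    occupied: list[tuple[int, int]] = []  # mouse-coordinate exclusion zones

    for enh in spec.enhancers:
        start = spec.tss_pos + enh.offset_from_tss
        span = GenomicInterval(seq_id, start, start + enh.width)
        human_span = GenomicInterval(
            human_seq_id, start + human_shift, start + enh.width + human_shift
        )
        blocks.append((span, human_span))
        occupied.append((span.start, span.end))

        # Core sequence: random background, planted motif realizations,
        # then scrub chance matches so recovery is exact.
        core = list("".join(ref_seq[span.start : span.end]))
        for plant in enh.motifs:
            motif = _MOTIF_BY_FAMILY[plant.family]
            realized = _realize_clean(motif, rng)
            oriented = realized if plant.strand == "+" else reverse_complement(realized)
            core[plant.position : plant.position + motif.width] = list(oriented)
        _scrub_spurious(core, enh.motifs, DEFAULT_MOTIFS, rng)
        ref_seq[span.start : span.end] = core

        # Orthologous rows per species.
        if enh.align_depth < 1 or enh.align_depth > len(species):
            raise ValueError("align_depth must lie within the species ladder")
        aligning = set(species[: enh.align_depth])
        rows: dict[str, str] = {species[0]: "".join(core)}
        protected = set()
        for plant in enh.motifs:
            protected.update(
                range(plant.position, plant.position + _motif_width(plant.family))
            )
        for sp in species[1:]:
            if sp not in aligning:
                rows[sp] = "-" * enh.width
                continue
            row = list(core)
            rate = sub_rates.get(sp, 0.1)
            for j in range(enh.width):
                if j in protected:
                    continue
                if rng.random() < rate:
                    alt = [b for b in "ACGT" if b != row[j]]
                    row[j] = alt[rng.integers(3)]
            for plant in enh.motifs:
                if plant.tier == "strong":
                    continue  # intact everywhere it aligns
                if plant.tier == "weak" and sp == "human":
                    continue  # intact in human only
                _destroy_motif(row, plant, rng)
            rows[sp] = "".join(row)

        name = name_enhancer(anchor, span)
        profiles[name] = AlignmentProfile(name, species, rows, reference=species[0])
        records.append(
            EnhancerRecord(
                name=name,
                gene=spec.gene,
                interval=span,
                species=MOUSE,
                orthologue_interval=human_span,
                in_vivo_class=enh.class_label,
            )
        )

        for dataset, present in enh.marks.items():
            if not present:
                continue
            if dataset in MOUSE_DATASETS:
                track_intervals[dataset].append(span)
            else:
                track_intervals[dataset].append(human_span)

        for tf, bound in enh.peaks.items():
            if not bound:
                continue
            j1 = int(round(rng.normal(0, cohort.peak_jitter_sd)))
            j2 = int(round(rng.normal(0, cohort.peak_jitter_sd)))
            p_start = max(0, min(span.start + j1, span.end - 1))
            p_end = max(p_start + 1, max(span.start + 1, span.end + j2))
            peak_intervals[tf].append(GenomicInterval(seq_id, p_start, p_end))

        lo, hi = cohort.n_injected_range
        n_inj = int(rng.integers(lo, hi + 1))
        n_pos = int(rng.binomial(n_inj, enh.activity_rate))
        assay_counts.append(AssayCount(name, n_inj, n_pos, weak_flag=enh.weak_flag))

        n_mouse = sum(enh.marks.get(d, False) for d in MOUSE_DATASETS)
        n_human = sum(enh.marks.get(d, False) for d in HUMAN_DATASETS)
        if spec.transcribed_human:
            expected_putative = n_mouse >= 1 and n_human >= 1
            rule = "both_species"
        else:
            expected_putative = n_mouse >= 2
            rule = "mouse_only_relaxed"
        if enh.activity_rate > 0.05:
            expected_activity = ACTIVE_WEAK if enh.weak_flag else ACTIVE_STRONG
        else:
            expected_activity = INACTIVE
        truth_rows.append(
            {
                "gene": spec.gene,
                "name": name,
                "seq_id": seq_id,
                "start": span.start,
                "end": span.end,
                "class_label": enh.class_label,
                **{d: enh.marks.get(d, False) for d in ALL_DATASETS},
                "expected_putative": expected_putative,
                "rule": rule,
                "motifs": ";".join(
                    f"{m.family}:{m.position}:{m.strand}:{m.tier}" for m in enh.motifs
                ),
                "bound_tfs": ";".join(sorted(tf for tf, b in enh.peaks.items() if b)),
                "activity_rate": enh.activity_rate,
                "weak_flag": enh.weak_flag,
                "expected_activity": expected_activity,
            }
        )

    # Noise marks: single-dataset singletons placed in zones that stay
    # clear of planted spans and of each other (600 bp margin, above the
    # default 500 bp merge gap), so no noise candidate can accumulate a
    # second mark by merging.
    margin = 600
    for dataset in ALL_DATASETS:
        n_noise = rng.poisson(cohort.noise_marks_per_track)
        for _ in range(n_noise):
            length = max(50, int(rng.normal(cohort.noise_mark_length, 50)))
            for _try in range(100):
                pos = int(rng.integers(0, spec.length - length))
                if all(
                    pos + length + margin <= a or pos >= b + margin
                    for a, b in occupied
                ):
                    occupied.append((pos, pos + length))
                    if dataset in MOUSE_DATASETS:
                        track_intervals[dataset].append(
                            GenomicInterval(seq_id, pos, pos + length)
                        )
                    else:
                        track_intervals[dataset].append(
                            GenomicInterval(
                                human_seq_id, pos + human_shift, pos + length + human_shift
                            )
                        )
                    break

    mark_tracks = [
        MarkTrack(
            dataset_id=d,
            species=MOUSE if d in MOUSE_DATASETS else HUMAN,
            intervals=sorted(track_intervals[d]),
            assembly="syn_mm" if d in MOUSE_DATASETS else "syn_hg",
        )
        for d in ALL_DATASETS
    ]
    peak_sets = {
        tf: PeakSet(tf, f"synthetic_{tf}", sorted(peak_intervals[tf]), assembly="syn_mm")
        for tf in DEFAULT_TFS
    }
    return LocusBundle(
        gene=spec.gene,
        anchor=anchor,
        locus=locus,
        human_seq_id=human_seq_id,
        human_shift=human_shift,
        ref_sequence="".join(ref_seq),
        mark_tracks=mark_tracks,
        orthology_blocks=blocks,
        profiles=profiles,
        peak_sets=peak_sets,
        assay_counts=assay_counts,
        transcription=TranscriptionStatus(
            spec.gene, transcribed_human=spec.transcribed_human
        ),
        enhancer_records=records,
        truth=pd.DataFrame(truth_rows),
    )


def default_cohort_spec(seed: int = 0, noise_marks_per_track: float = 2.0) -> CohortSpec:
    """Eight loci named for the screen's arterial target genes, carrying 41
    planted putative enhancers in total; three loci (Cxcr4, Cxcl12, Gja5)
    are flagged poorly transcribed in human ECs and use the relaxed rule."""
    genes = [
        ("Cxcr4", 6, False),
        ("Efnb2", 6, True),
        ("Gja4", 3, True),
        ("Unc5b", 6, True),
        ("Acvrl1", 5, True),
        ("Cxcl12", 6, False),
        ("Gja5", 5, False),
        ("Nrp1", 4, True),
    ]
    tier_cycle = ["strong", "weak", "none"]
    loci = []
    for gi, (gene, n_enh, human_ok) in enumerate(genes):
        enhancers = []
        for i in range(n_enh):
            offset = (-1) ** i * (8000 + 9000 * i)
            if human_ok:
                marks = {
                    "m_artery_atac": True,
                    "m_retina_atac": i % 2 == 0,
                    "m_e11_p300": True,
                    "h_dnase": True,
                    "h_histone": i % 2 == 1,
                }
            else:
                marks = {
                    "m_artery_atac": True,
                    "m_retina_atac": True,
                    "m_e11_p300": i % 2 == 0,
                    "h_dnase": False,
                    "h_histone": False,
                }
            if i % 3 == 0:
                class_label, rate, weak = "arterial", 0.5, False
            elif i % 3 == 1:
                class_label, rate, weak = "inactive", 0.0, False
            else:
                class_label, rate, weak = ("weak", 0.15, True) if i % 2 == 0 else ("pan_EC", 0.5, False)
            motifs = [
                PlantedMotif("ETS", 30, "+", "strong"),
                PlantedMotif("SOX", 70, "-", tier_cycle[i % 3]),
                PlantedMotif("RBPJ", 110, "+", tier_cycle[(i + 1) % 3]),
            ]
            if class_label == "arterial":
                motifs.append(PlantedMotif("MEF2", 150, "+", "strong"))
            peaks = {
                "ERG": True,
                "SOX17": tier_cycle[i % 3] == "strong",
                "MEF2C": class_label == "arterial",
                "FOXO1": i % 2 == 0,
                "RBPJ": False,
            }
            enhancers.append(
                PlantedEnhancer(
                    offset_from_tss=offset,
                    width=350,
                    class_label=class_label,
                    marks=marks,
                    motifs=motifs,
                    peaks=peaks,
                    activity_rate=rate,
                    weak_flag=weak,
                    align_depth=3 + (i + gi) % 4,
                )
            )
        loci.append(
            LocusSpec(
                gene=gene,
                length=130_000,
                tss_pos=65_000,
                strand="+" if gi % 2 == 0 else "-",
                enhancers=enhancers,
                transcribed_human=human_ok,
            )
        )
    return CohortSpec(loci=loci, seed=seed, noise_marks_per_track=noise_marks_per_track)


@dataclass
class CohortBundle:
    spec: CohortSpec
    loci: list[LocusBundle]

    @property
    def truth(self) -> pd.DataFrame:
        frames = [b.truth for b in self.loci if not b.truth.empty]
        if not frames:
            return pd.DataFrame()
        return pd.concat(frames, ignore_index=True)


def generate_cohort(
    spec: CohortSpec, outdir: Optional[str | Path] = None
) -> CohortBundle:
    """Generate every locus; optionally write a complete runnable input set
    (BED tracks, aligned FASTA, TSVs, run manifest, truth table)."""
    bundles = [
        generate_locus(ls, spec.seed, cohort=spec, locus_index=i)
        for i, ls in enumerate(spec.loci)
    ]
    cohort = CohortBundle(spec, bundles)
    if outdir is not None:
        write_cohort(cohort, Path(outdir))
    return cohort


def write_cohort(cohort: CohortBundle, outdir: Path) -> None:
    outdir = Path(outdir)
    (outdir / "marks").mkdir(parents=True, exist_ok=True)
    (outdir / "alignments").mkdir(exist_ok=True)
    (outdir / "peaks").mkdir(exist_ok=True)

    manifest_rows = []
    for dataset in ALL_DATASETS:
        intervals = [
            iv for b in cohort.loci for t in b.mark_tracks
            if t.dataset_id == dataset for iv in t.intervals
        ]
        path = outdir / "marks" / f"{dataset}.bed"
        write_bed(sorted(intervals), path)
        manifest_rows.append(
            {
                "dataset_id": dataset,
                "species": MOUSE if dataset in MOUSE_DATASETS else HUMAN,
                "path": f"marks/{dataset}.bed",
                "ec_specific": True,
            }
        )
    pd.DataFrame(manifest_rows).to_csv(outdir / "marks_manifest.tsv", sep="\t", index=False)

    blocks = [blk for b in cohort.loci for blk in b.orthology_blocks]
    OrthologyMap(blocks).write_tsv(outdir / "orthology.tsv")

    for b in cohort.loci:
        for name, profile in b.profiles.items():
            safe = name.replace("/", "_")
            write_fasta(
                {sp: profile.rows[sp] for sp in profile.species},
                outdir / "alignments" / f"{safe}.fa",
            )

    peak_rows = []
    for tf in DEFAULT_TFS:
        intervals = [iv for b in cohort.loci for iv in b.peak_sets[tf].intervals]
        path = outdir / "peaks" / f"{tf}.bed"
        write_bed(sorted(intervals), path)
        peak_rows.append({"tf": tf, "family": DEFAULT_TFS[tf], "path": f"peaks/{tf}.bed"})
    pd.DataFrame(peak_rows).to_csv(outdir / "peaks_manifest.tsv", sep="\t", index=False)

    counts = [c for b in cohort.loci for c in b.assay_counts]
    pd.DataFrame(
        [
            {
                "enhancer": c.enhancer,
                "n_injected": c.n_injected,
                "n_gfp_positive": c.n_gfp_positive,
                "weak_flag": c.weak_flag,
            }
            for c in counts
        ]
    ).to_csv(outdir / "assay_counts.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {
                "gene_name": b.transcription.gene_name,
                "transcribed_human": b.transcription.transcribed_human,
                "transcribed_mouse": b.transcription.transcribed_mouse,
            }
            for b in cohort.loci
        ]
    ).to_csv(outdir / "transcription_status.tsv", sep="\t", index=False)

    records = [r for b in cohort.loci for r in b.enhancer_records]
    write_enhancer_table(records, outdir / "enhancers.tsv")

    pd.DataFrame(
        [
            {
                "gene": b.gene,
                "seq_id": b.locus.seq_id,
                "start": b.locus.start,
                "end": b.locus.end,
                "tss": b.anchor.tss_pos,
                "strand": b.anchor.gene_strand,
            }
            for b in cohort.loci
        ]
    ).to_csv(outdir / "loci.tsv", sep="\t", index=False)

    cohort.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)

    manifest = {
        "marks_manifest": "marks_manifest.tsv",
        "orthology": "orthology.tsv",
        "alignments_dir": "alignments",
        "peaks_manifest": "peaks_manifest.tsv",
        "assay_counts": "assay_counts.tsv",
        "transcription_status": "transcription_status.tsv",
        "enhancers": "enhancers.tsv",
        "loci": "loci.tsv",
        "out_dir": "pipeline_out",
        "merge_gap": "500",
        "activity_threshold": "0.05",
        "composite_window": "2",
        "coverage_threshold": "0.5",
        "seed": str(cohort.spec.seed),
    }
    with open(outdir / "manifest.txt", "w") as fh:
        for k, v in manifest.items():
            fh.write(f"{k}={v}\n")
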