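"""Ground-truth recovery and determinism of the synthetic generator."""

import filecmp
from pathlib import Path

import pytest

from artenh.activity import classify_activity, cohort_activity_summary
from artenh.enhancer_calling import call_putative, collect_mark_evidence
from artenh.genome_io import OrthologyMap
from artenh.motif_scan import scan_enhancer
from artenh.synthetic import (
    CohortSpec,
    LocusSpec,
    PlantedEnhancer,
    PlantedMotif,
    default_cohort_spec,
    generate_cohort,
    generate_locus,
)


def _single_enhancer_spec(motifs, marks=None, **enh_kwargs):
    marks = marks or {"m_artery_atac": True, "h_dnase": True}
    enh = PlantedEnhancer(
        offset_from_tss=-8000, width=350, class_label="arterial",
        marks=marks, motifs=motifs, activity_rate=0.5, **enh_kwargs,
    )
    return LocusSpec("Gene", 40_000, 20_000, "+", [enh])


class TestGenerateLocus:
    def test_planted_strong_ets_recovered_exactly(self):
        spec = _single_enhancer_spec([PlantedMotif("ETS", 100, "+", "strong")])
        bundle = generate_locus(spec, seed=3)
        [profile] = bundle.profiles.values()
        hits = scan_enhancer(profile)
        assert [(h.family, h.start, h.strand, h.tier) for h in hits] == [
            ("ETS", 100, "+", "strong")
        ]

    @pytest.mark.parametrize("tier", ["strong", "weak", "none"])
    def test_planted_tiers_recovered(self, tier):
        spec = _single_enhancer_spec(
            [PlantedMotif("SOX", 60, "-", tier)], align_depth=5
        )
        bundle = generate_locus(spec, seed=4)
        [profile] = bundle.profiles.values()
        hits = scan_enhancer(profile)
        sox = [h for h in hits if h.family == "SOX"]
        assert {(h.start, h.tier) for h in sox} == {(60, tier)}
        assert any(h.strand == "-" for h in sox)

    def test_overlapping_plants_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            _single_enhancer_spec(
                [PlantedMotif("ETS", 100, "+", "strong"), PlantedMotif("SOX", 102, "+", "strong")]
            )

    def test_plant_outside_enhancer_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            _single_enhancer_spec([PlantedMotif("ETS", 348, "+", "strong")])

    def test_enhancer_outside_locus_rejected(self):
        enh = PlantedEnhancer(offset_from_tss=50_000, width=350,
                              class_label="arterial", marks={})
        with pytest.raises(ValueError, match="outside the locus"):
            LocusSpec("G", 40_000, 20_000, "+", [enh])

    def test_same_seed_identical_bundle(self):
        spec = _single_enhancer_spec([PlantedMotif("ETS", 100, "+", "strong")])
        b1 = generate_locus(spec, seed=5)
        b2 = generate_locus(spec, seed=5)
        assert b1.ref_sequence == b2.ref_sequence
        assert b1.truth.equals(b2.truth)
        assert b1.assay_counts == b2.assay_counts


class TestCohort:
    def test_default_cohort_plants_41_putative_enhancers(self):
        cohort = generate_cohort(default_cohort_spec(seed=0))
        truth = cohort.truth
        assert len(cohort.loci) == 8
        assert len(truth) == 41
        assert int(truth.expected_putative.sum()) == 41

    def test_fixed_seed_byte_identical_outputs(self, tmp_path):
        spec = default_cohort_spec(seed=2)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_cohort(spec, d1)
        generate_cohort(default_cohort_spec(seed=2), d2)
        files = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        assert files
        for rel in files:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes(), rel

    def test_different_seeds_same_schema_different_content(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_cohort(default_cohort_spec(seed=1), d1)
        generate_cohort(default_cohort_spec(seed=2), d2)
        f1 = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        f2 = sorted(p.relative_to(d2) for p in d2.rglob("*") if p.is_file())
        assert f1 == f2  # identical file layout
        assert any((d1 / r).read_bytes() != (d2 / r).read_bytes() for r in f1)

    def test_empty_cohort_is_valid(self, tmp_path):
        cohort = generate_cohort(CohortSpec(loci=[], seed=0), tmp_path / "empty")
        assert cohort.truth.empty
        assert (tmp_path / "empty" / "manifest.txt").exists()


class TestZeroNoiseTruthRecovery:
    def test_calling_recall_and_precision_one(self, clean_cohort_dir):
        _, cohort = clean_cohort_dir
        for bundle in cohort.loci:
            omap = OrthologyMap(bundle.orthology_blocks)
            for rec, truth_row in zip(
                bundle.enhancer_records, bundle.truth.itertuples(index=False)
            ):
                ev = collect_mark_evidence(rec.interval, bundle.mark_tracks, omap)
                call = call_putative(ev, bundle.transcription)
                assert (call.decision == "putative") == truth_row.expected_putative

    def test_motif_positions_strands_tiers_exact(self, clean_cohort_dir):
        _, cohort = clean_cohort_dir
        for bundle in cohort.loci:
            for truth_row in bundle.truth.itertuples(index=False):
                planted = set()
                for part in truth_row.motifs.split(";"):
                    fam, pos, strand, tier = part.split(":")
                    planted.add((fam, int(pos), tier))
                hits = scan_enhancer(bundle.profiles[truth_row.name])
                # Palindromic consensi yield a mirror-strand hit at the same
                # position; compare on (family, position, tier).
                assert {(h.family, h.start, h.tier) for h in hits} == planted

    def test_planted_strands_present(self, clean_cohort_dir):
        _, cohort = clean_cohort_dir
        bundle = cohort.loci[0]
        truth_row = next(bundle.truth.itertuples(index=False))
        hits = scan_enhancer(bundle.profiles[truth_row.name])
        by_pos = {(h.family, h.start): set() for h in hits}
        for h in hits:
            by_pos[(h.family, h.start)].add(h.strand)
        for part in truth_row.motifs.split(";"):
            fam, pos, strand, _ = part.split(":")
            assert strand in by_pos[(fam, int(pos))]

    def test_binding_truth_exact(self, clean_cohort_dir):
        _, cohort = clean_cohort_dir
        for bundle in cohort.loci:
            for rec, truth_row in zip(
                bundle.enhancer_records, bundle.truth.itertuples(index=False)
            ):
                expected = set(truth_row.bound_tfs.split(";")) - {""}
                for tf, peaks in bundle.peak_sets.items():
                    bound = any(rec.interval.overlaps(p) for p in peaks.intervals)
                    assert bound == (tf in expected), (rec.name, tf)

    def test_activity_calls_match_rate_sign_at_large_n(self):
        """With 500 injections the classifier recovers sign(rate - 0.05):
        the binomial tail probability of a miscall is < 1e-9 at the rates
        planted here."""
        spec = default_cohort_spec(seed=13, noise_marks_per_track=0.0)
        spec.n_injected_range = (500, 500)
        cohort = generate_cohort(spec)
        truth = cohort.truth.set_index("name")
        counts = [c for b in cohort.loci for c in b.assay_counts]
        for call in cohort_activity_summary(counts).calls:
            assert call.decision == truth.loc[call.enhancer, "expected_activity"]
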