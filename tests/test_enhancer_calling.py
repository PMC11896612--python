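"""Candidate construction, mark evidence, and the putative-enhancer rule."""

import itertools
import random

import pytest

from artenh.enhancer_calling import (
    BELOW_THRESHOLD,
    BOTH_SPECIES,
    MOUSE_ONLY_RELAXED,
    PUTATIVE,
    MarkEvidence,
    MarkTrack,
    MarkedEnhancer,
    TranscriptionStatus,
    build_candidate_regions,
    call_putative,
    collect_mark_evidence,
    retrospective_mark_summary,
)
from artenh.genome_io import GenomicInterval, OrthologyMap

DATASETS = ["m_artery_atac", "m_retina_atac", "m_e11_p300", "h_dnase", "h_histone"]
SPECIES = {
    "m_artery_atac": "mouse", "m_retina_atac": "mouse", "m_e11_p300": "mouse",
    "h_dnase": "human", "h_histone": "human",
}


def _evidence(**flags):
    marks = {d: flags.get(d, False) for d in DATASETS}
    return MarkEvidence(GenomicInterval("chr1", 0, 100), marks, dict(SPECIES))


class TestCallPutative:
    def test_human_mark_without_mouse_mark_fails(self):
        # The single known EC enhancer failing the both-species criterion:
        # human histone mark only, no mouse mark anywhere.
        ev = _evidence(h_histone=True)
        call = call_putative(ev, TranscriptionStatus("Pdgfrb", True))
        assert call.decision == BELOW_THRESHOLD
        assert call.rule_used == BOTH_SPECIES

    def test_all_marks_is_putative(self):
        ev = _evidence(**{d: True for d in DATASETS})
        assert call_putative(ev, TranscriptionStatus("Dll4", True)).decision == PUTATIVE

    def test_relaxed_rule_two_mouse_marks_no_human(self):
        ev = _evidence(m_artery_atac=True, m_retina_atac=True)
        call = call_putative(ev, TranscriptionStatus("Cxcr4", False))
        assert call.decision == PUTATIVE
        assert call.rule_used == MOUSE_ONLY_RELAXED

    def test_no_marks_below_threshold(self):
        for th in (True, False):
            assert call_putative(_evidence(), TranscriptionStatus("G", th)).decision == BELOW_THRESHOLD

    def test_exhaustive_truth_table(self):
        """All 2^5 evidence patterns x 2 transcription states vs an
        independently coded oracle."""
        for bits in itertools.product([False, True], repeat=5):
            ev = _evidence(**dict(zip(DATASETS, bits)))
            n_mouse = sum(bits[:3])
            n_human = sum(bits[3:])
            for transcribed in (True, False):
                call = call_putative(ev, TranscriptionStatus("G", transcribed))
                if transcribed:
                    expected = n_mouse >= 1 and n_human >= 1
                else:
                    expected = n_mouse >= 2
                assert (call.decision == PUTATIVE) is expected, (bits, transcribed)

    def test_monotonic_in_added_marks(self):
        """Flipping any dataset to True never turns putative into below."""
        for bits in itertools.product([False, True], repeat=5):
            for transcribed in (True, False):
                base = call_putative(
                    _evidence(**dict(zip(DATASETS, bits))),
                    TranscriptionStatus("G", transcribed),
                ).decision
                for i in range(5):
                    if bits[i]:
                        continue
                    up = list(bits)
                    up[i] = True
                    new = call_putative(
                        _evidence(**dict(zip(DATASETS, up))),
                        TranscriptionStatus("G", transcribed),
                    ).decision
                    assert not (base == PUTATIVE and new == BELOW_THRESHOLD)


class TestCandidateRegions:
    def _track(self, ivs, dataset="d1"):
        return MarkTrack(dataset, "mouse", ivs, assembly="mm")

    def test_overlapping_marks_merge(self):
        locus = GenomicInterval("chr1", 0, 10_000)
        t = self._track([GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 199, 300)])
        assert build_candidate_regions([t], locus) == [GenomicInterval("chr1", 100, 300)]

    def test_distant_marks_stay_separate(self):
        locus = GenomicInterval("chr1", 0, 10_000)
        t = self._track([GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 1200, 1300)])
        assert len(build_candidate_regions([t], locus, merge_gap=500)) == 2
        assert len(build_candidate_regions([t], locus, merge_gap=1000)) == 1

    def test_mixed_assemblies_rejected(self):
        locus = GenomicInterval("chr1", 0, 1000)
        t1 = MarkTrack("a", "mouse", [], assembly="mm9")
        t2 = MarkTrack("b", "mouse", [], assembly="mm10")
        with pytest.raises(ValueError, match="assemblies"):
            build_candidate_regions([t1, t2], locus)

    def test_marks_outside_locus_ignored(self):
        locus = GenomicInterval("chr1", 0, 1000)
        t = self._track([GenomicInterval("chr1", 5000, 5100), GenomicInterval("chr2", 10, 20)])
        assert build_candidate_regions([t], locus) == []


class TestCollectEvidence:
    def test_quadratic_oracle_on_random_sets(self):
        rng = random.Random(5)
        tracks = []
        for d in DATASETS:
            ivs = []
            for _ in range(30):
                s = rng.randrange(0, 50_000)
                ivs.append(GenomicInterval("chr1" if SPECIES[d] == "mouse" else "chrH",
                                           s, s + rng.randrange(1, 500)))
            tracks.append(MarkTrack(d, SPECIES[d], ivs, assembly=SPECIES[d]))
        # Identity-like orthology: chr1 -> chrH, same coordinates.
        omap = OrthologyMap([(GenomicInterval("chr1", 0, 50_500), GenomicInterval("chrH", 0, 50_500))])
        for _ in range(50):
            s = rng.randrange(0, 50_000)
            region = GenomicInterval("chr1", s, s + rng.randrange(1, 1000))
            ev = collect_mark_evidence(region, tracks, omap)
            for t in tracks:
                q = region if t.species == "mouse" else GenomicInterval("chrH", region.start, region.end)
                expected = any(q.overlaps(iv) for iv in t.intervals)
                assert ev.marks[t.dataset_id] is expected

    def test_unmappable_region_records_false_with_note(self):
        tracks = [
            MarkTrack("h_dnase", "human", [GenomicInterval("chrH", 0, 10_000)], assembly="hg"),
            MarkTrack("m_artery_atac", "mouse", [GenomicInterval("chr1", 0, 10_000)], assembly="mm"),
        ]
        omap = OrthologyMap([])
        ev = collect_mark_evidence(GenomicInterval("chr1", 100, 200), tracks, omap)
        assert ev.marks["m_artery_atac"] is True
        assert ev.marks["h_dnase"] is False
        assert ev.notes["h_dnase"] == "unmapped"

    def test_nonspecific_marks_count_but_are_flagged(self):
        t = MarkTrack("h_histone", "human", [GenomicInterval("chrH", 0, 500)],
                      assembly="hg", specific=[False])
        omap = OrthologyMap([(GenomicInterval("chr1", 0, 1000), GenomicInterval("chrH", 0, 1000))])
        ev = collect_mark_evidence(GenomicInterval("chr1", 10, 20), [t], omap)
        assert ev.marks["h_histone"] is True
        assert ev.nonspecific.get("h_histone") is True


class TestRetrospectiveSummary:
    def _record(self, name, bits, label=None):
        return MarkedEnhancer(name, _evidence(**dict(zip(DATASETS, bits))), label)

    def test_counts_and_class_restriction(self):
        recs = [
            self._record("a", (1, 1, 1, 1, 1), "arterial"),
            self._record("b", (0, 0, 0, 1, 1)),  # human only
            self._record("c", (1, 0, 0, 0, 0)),  # mouse only
        ]
        s = retrospective_mark_summary(recs, class_label="arterial")
        assert s["overall"]["n_total"] == 3
        assert s["overall"]["n_with_mark_both_species"] == 1
        assert s["overall"]["per_dataset"]["m_artery_atac"] == 2
        assert s["restricted"]["n_total"] == 1
        assert s["restricted"]["n_with_mark_both_species"] == 1

    def test_empty_input_gives_zero_counts(self):
        s = retrospective_mark_summary([])
        assert s["overall"] == {"n_total": 0, "n_with_mark_both_species": 0, "per_dataset": {}}

    def test_missing_evidence_names_record(self):
        rec = MarkedEnhancer("broken", MarkEvidence(GenomicInterval("c", 0, 1), {}, {}))
        with pytest.raises(ValueError, match="broken"):
            retrospective_mark_summary([rec])
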