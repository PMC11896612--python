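"""Consensus scanning, composite detection and conservation tiers."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from artenh.motif_scan import (
    DEFAULT_MOTIFS,
    AlignmentProfile,
    MotifDefinition,
    MotifHit,
    classify_conservation_tier,
    detect_composite_fox_ets,
    reverse_complement,
    scan_consensus,
    summarize_motifs_per_enhancer,
)

# Independent IUPAC semantics for the oracle (not imported from the package).
_ORACLE_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT", "S": "CG",
    "W": "AT", "K": "GT", "M": "AC", "B": "CGT", "D": "AGT", "H": "ACT",
    "V": "ACG", "N": "ACGTN",
}
_ORACLE_COMP = dict(zip("ACGTN", "TGCAN"))


def _oracle_scan(seq, consensus):
    """Brute force: test every window of both strands by set membership."""
    w = len(consensus)
    hits = []
    for i in range(len(seq) - w + 1):
        window = seq[i : i + w]
        if all(b in _ORACLE_IUPAC[c] for b, c in zip(window, consensus)):
            hits.append((i, "+"))
        rc = "".join(_ORACLE_COMP[b] for b in reversed(window))
        if all(b in _ORACLE_IUPAC[c] for b, c in zip(rc, consensus)):
            hits.append((i, "-"))
    return sorted(hits)


class TestScanConsensus:
    def test_forward_hit_position(self):
        hits = scan_consensus("ATGGGAAT", MotifDefinition("RBPJ", "TGGGAA"))
        assert [(h.start, h.end, h.strand, h.matched_sequence) for h in hits] == [
            (1, 7, "+", "TGGGAA")
        ]

    def test_reverse_strand_hit(self):
        # revcomp(ACTTCCTG) contains AGGAAG, matching HGGAAR.
        hits = scan_consensus("ACTTCCTG", MotifDefinition("ETS", "HGGAAR"))
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.strand) == (1, 7, "-")
        assert h.matched_sequence == "AGGAAG"

    def test_empty_sequence(self):
        assert scan_consensus("", MotifDefinition("ETS", "HGGAAR")) == []

    def test_palindromic_match_reported_on_both_strands(self):
        hits = scan_consensus("GAATTC", MotifDefinition("X", "GAATTC"))
        assert [(h.start, h.strand) for h in hits] == [(0, "+"), (0, "-")]

    def test_sequence_n_never_matches_constrained_position(self):
        assert scan_consensus("TGGGNA", MotifDefinition("RBPJ", "TGGGAA")) == []
        # but consensus N accepts sequence N
        assert len(scan_consensus("TGN", MotifDefinition("X", "TGN"))) >= 1

    def test_invalid_consensus_code_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            MotifDefinition("X", "TGQ")

    @settings(max_examples=150, derandomize=True)
    @given(
        st.text(alphabet="ACGTN", max_size=80),
        st.sampled_from([m.consensus for m in DEFAULT_MOTIFS]),
    )
    def test_matches_brute_force_oracle(self, seq, consensus):
        hits = scan_consensus(seq, MotifDefinition("F", consensus))
        assert [(h.start, h.strand) for h in hits] == _oracle_scan(seq, consensus)

    @settings(max_examples=100, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=10, max_size=60))
    def test_strand_symmetry(self, seq):
        """Scanning the reverse complement mirrors the hit set."""
        motif = MotifDefinition("ETS", "HGGAAR")
        fwd = {(h.start, h.end, h.strand) for h in scan_consensus(seq, motif)}
        rc = scan_consensus(reverse_complement(seq), motif)
        flip = {"+": "-", "-": "+"}
        mirrored = {(len(seq) - h.end, len(seq) - h.start, flip[h.strand]) for h in rc}
        assert fwd == mirrored


def _hit(family, start, width, strand="+"):
    return MotifHit("e", family, start, start + width, strand, "A" * width)


class TestCompositeFoxEts:
    def test_adjacent_same_strand_flags_both(self):
        fox, ets = _hit("FOX", 10, 7), _hit("ETS", 18, 6)  # 1 bp gap
        detect_composite_fox_ets([fox], [ets], window=2)
        assert fox.composite_member and ets.composite_member

    def test_distant_hits_stay_independent(self):
        fox, ets = _hit("FOX", 10, 7), _hit("ETS", 60, 6)
        detect_composite_fox_ets([fox], [ets], window=2)
        assert not fox.composite_member and not ets.composite_member

    def test_opposite_strands_not_composite(self):
        fox, ets = _hit("FOX", 10, 7), _hit("ETS", 18, 6, "-")
        detect_composite_fox_ets([fox], [ets], window=2)
        assert not fox.composite_member

    def test_minus_strand_geometry_mirrored(self):
        # On '-', FOX 5' of the ETS core means FOX to the right.
        ets = _hit("ETS", 10, 6, "-")
        fox = _hit("FOX", 17, 7, "-")  # gap = 17 - 16 = 1
        detect_composite_fox_ets([fox], [ets], window=2)
        assert fox.composite_member and ets.composite_member

    def test_random_sets_match_quadratic_oracle(self):
        rng = random.Random(3)
        for _ in range(30):
            foxes = [_hit("FOX", rng.randrange(0, 200), 7, rng.choice("+-")) for _ in range(8)]
            etss = [_hit("ETS", rng.randrange(0, 200), 6, rng.choice("+-")) for _ in range(8)]
            detect_composite_fox_ets(foxes, etss, window=2)
            for fox in foxes:
                expected = any(
                    fox.strand == e.strand
                    and 0 <= ((e.start - fox.end) if fox.strand == "+" else (fox.start - e.end)) <= 2
                    for e in etss
                )
                assert fox.composite_member is expected


def _profile(rows, species=None):
    species = species or list(rows)
    return AlignmentProfile("e", species, rows, reference=species[0])


class TestConservationTier:
    CORE = "AATGGGAATT"  # RBPJ TGGGAA at [2, 8)
    MOTIF = MotifDefinition("RBPJ", "TGGGAA")

    def _hit(self):
        return MotifHit("e", "RBPJ", 2, 8, "+", "TGGGAA")

    def test_conserved_to_full_depth_is_strong(self):
        rows = {
            "mouse": self.CORE,
            "rat": "AATGGGAATT",
            "human": "CATGGGAATT",
            "chicken": "AATGGGAAGG",
        }
        assert classify_conservation_tier(self._hit(), _profile(rows), self.MOTIF) == "strong"

    def test_human_only_is_weak(self):
        rows = {
            "mouse": self.CORE,
            "rat": "AACGGGAATT",  # motif broken (TGGGAA -> CGGGAA)
            "human": "AATGGGAATT",
        }
        assert classify_conservation_tier(self._hit(), _profile(rows), self.MOTIF) == "weak"

    def test_human_mismatch_is_none(self):
        rows = {
            "mouse": self.CORE,
            "rat": "AATGGGAATT",
            "human": "AACGGGAATT",
        }
        assert classify_conservation_tier(self._hit(), _profile(rows), self.MOTIF) == "none"

    def test_no_human_row_is_none(self):
        rows = {"mouse": self.CORE}
        assert classify_conservation_tier(self._hit(), _profile(rows), self.MOTIF) == "none"

    def test_gap_rows_do_not_count_toward_depth(self):
        # Chicken aligns < 50% of the core: excluded from depth, so its
        # broken motif cannot demote the tier.
        rows = {
            "mouse": self.CORE,
            "human": "AATGGGAATT",
            "chicken": "--------GG",
        }
        assert classify_conservation_tier(self._hit(), _profile(rows), self.MOTIF) == "strong"

    def test_gap_inside_motif_fails_match(self):
        rows = {
            "mouse": self.CORE,
            "human": "AATG-GAATT",
        }
        assert classify_conservation_tier(self._hit(), _profile(rows), self.MOTIF) == "none"

    def test_reference_mismatch_rejected(self):
        rows = {"mouse": "AACGGGAATT", "human": "AATGGGAATT"}
        with pytest.raises(ValueError, match="reference"):
            classify_conservation_tier(self._hit(), _profile(rows), self.MOTIF)

    def test_tier_monotonic_in_matching_species(self):
        """Breaking one more species' motif never upgrades the tier;
        restoring one never downgrades it."""
        order = {"strong": 2, "weak": 1, "none": 0}
        base_rows = {
            "mouse": self.CORE,
            "rat": "AATGGGAATT",
            "human": "AATGGGAATT",
            "dog": "AATGGGAATT",
        }
        base = classify_conservation_tier(self._hit(), _profile(base_rows), self.MOTIF)
        for sp in ("rat", "human", "dog"):
            rows = dict(base_rows)
            rows[sp] = rows[sp].replace("TGGGAA", "CGGGAA")
            demoted = classify_conservation_tier(self._hit(), _profile(rows), self.MOTIF)
            assert order[demoted] <= order[base]


class TestSummarize:
    def _tiered(self, family, tier, start=0, composite=False, width=6):
        h = MotifHit("e", family, start, start + width, "+", "A" * width, tier=tier)
        h.composite_member = composite
        return h

    def test_strong_takes_precedence_over_weak(self):
        hits = [
            self._tiered("ETS", "strong", 0),
            self._tiered("ETS", "weak", 10),
            self._tiered("ETS", "weak", 20),
        ]
        assert summarize_motifs_per_enhancer(hits)["ETS"] == "M"

    def test_unconserved_hits_confer_no_status(self):
        assert summarize_motifs_per_enhancer([self._tiered("SOX", "none")])["SOX"] is None

    def test_composite_fox_excluded_from_independent_fox(self):
        hits = [self._tiered("FOX", "strong", 0, composite=True, width=7)]
        status = summarize_motifs_per_enhancer(hits)
        assert "FOX" not in status
        assert status["FOX:ETS"] == "M"

    def test_no_hits_all_absent(self):
        assert summarize_motifs_per_enhancer([]) == {}

    def test_hits_from_multiple_enhancers_rejected(self):
        a = MotifHit("e1", "ETS", 0, 6, "+", "AAAAAA")
        b = MotifHit("e2", "ETS", 0, 6, "+", "AAAAAA")
        with pytest.raises(ValueError):
            summarize_motifs_per_enhancer([a, b])
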