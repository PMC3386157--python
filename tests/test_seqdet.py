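"""Alignment against a brute-force oracle, determinant calls, and dN/dS oracles."""

import math
from functools import lru_cache

import pytest
from Bio.Align import substitution_matrices
from hypothesis import given, settings
from hypothesis import strategies as st

from galphakin import (
    CodonAlignment,
    ProteinRecord,
    ValidationError,
    global_align,
    nei_gojobori_dnds,
    switch1_residue,
    synthetic_grass_galpha,
    synthetic_reference_galpha,
)
from galphakin.seqdet import GAP_EXTEND, GAP_OPEN, _codon_sites

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def brute_force_best_score(a: str, b: str) -> float:
    """Enumerate every global alignment with affine gaps (first gap residue
    costs GAP_OPEN, each extension GAP_EXTEND, end gaps included) and return
    the best achievable score."""

    @lru_cache(maxsize=None)
    def best(i: int, j: int, last: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            options.append(BLOSUM62[a[i], b[j]] + best(i + 1, j + 1, "m"))
        if i < len(a):
            cost = GAP_EXTEND if last == "ga" else GAP_OPEN
            options.append(cost + best(i + 1, j, "ga"))
        if j < len(b):
            cost = GAP_EXTEND if last == "gb" else GAP_OPEN
            options.append(cost + best(i, j + 1, "gb"))
        return max(options)

    return best(0, 0, "m")


class TestGlobalAlign:
    def test_identical_sequences_identity_alignment(self):
        rec = ProteinRecord("r", "MGLLCSRSRHH")
        aln = global_align(rec, rec)
        expected = sum(BLOSUM62[c, c] for c in rec.sequence)
        assert aln.score == expected
        assert aln.aligned_query == rec.sequence
        for i in range(1, len(rec) + 1):
            assert aln.map_ref_to_query(i) == i

    def test_single_deletion_matches_enumeration(self):
        aln = global_align(ProteinRecord("q", "AD"), ProteinRecord("r", "ACD"))
        assert aln.score == brute_force_best_score("ACD", "AD")
        assert aln.score == BLOSUM62["A", "A"] + GAP_OPEN + BLOSUM62["D", "D"]

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            ProteinRecord("x", "")

    def test_illegal_character_position_named(self):
        with pytest.raises(ValidationError, match="position 3"):
            ProteinRecord("x", "AC1D")

    @given(
        a=st.text(alphabet="ACDEFGHIK", min_size=1, max_size=5),
        b=st.text(alphabet="ACDEFGHIK", min_size=1, max_size=5),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_optimal_score_matches_brute_force(self, a, b):
        aln = global_align(ProteinRecord("q", b), ProteinRecord("r", a))
        assert aln.score == pytest.approx(brute_force_best_score(a, b))

    @given(
        a=st.text(alphabet="ACDEFGHIK", min_size=1, max_size=5),
        b=st.text(alphabet="ACDEFGHIK", min_size=1, max_size=5),
    )
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_score_symmetric_under_swap(self, a, b):
        s1 = global_align(ProteinRecord("q", b), ProteinRecord("r", a)).score
        s2 = global_align(ProteinRecord("q", a), ProteinRecord("r", b)).score
        assert s1 == pytest.approx(s2)

    def test_position_mapping_round_trips(self):
        ref = synthetic_reference_galpha()
        grass = synthetic_grass_galpha()
        aln = global_align(grass, ref)
        for pos in (1, 50, 194, 300, len(ref)):
            q = aln.map_ref_to_query(pos)
            if q is not None:
                assert aln.map_query_to_ref(q) == pos


class TestSwitchIDeterminant:
    def test_reference_against_itself_is_couplable_thr(self):
        ref = synthetic_reference_galpha()
        call = switch1_residue(ref, ref)
        assert call.residue == "T"
        assert call.query_position == 194
        assert call.coupling_class == "rgs_couplable"

    def test_grass_stand_in_maps_to_asn_195(self):
        call = switch1_residue(synthetic_grass_galpha(), synthetic_reference_galpha())
        assert call.residue == "N"
        assert call.query_position == 195
        assert call.coupling_class == "grass_uncoupled"

    def test_engineered_lysine_is_g12_like(self):
        ref = synthetic_reference_galpha()
        seq = list(ref.sequence)
        seq[193] = "K"
        call = switch1_residue(ProteinRecord("k_variant", "".join(seq)), ref)
        assert call.coupling_class == "g12_like"

    def test_serine_counts_as_couplable(self):
        ref = synthetic_reference_galpha()
        seq = list(ref.sequence)
        seq[193] = "S"
        call = switch1_residue(ProteinRecord("s_variant", "".join(seq)), ref)
        assert call.coupling_class == "rgs_couplable"

    def test_ref_position_out_of_range(self):
        ref = synthetic_reference_galpha()
        with pytest.raises(ValidationError, match="outside"):
            switch1_residue(ref, ref, ref_position=10_000)


class TestNeiGojobori:
    def test_phe_codon_site_partition(self):
        s, n = _codon_sites("TTT")
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)
        assert s + n == pytest.approx(3.0)

    @pytest.mark.parametrize(
        "codon,syn_sites",
        [("GCT", 1.0), ("TGG", 0.0), ("ATG", 0.0)],
    )
    def test_site_counts_hand_values(self, codon, syn_sites):
        s, n = _codon_sites(codon)
        assert s == pytest.approx(syn_sites)
        assert s + n == pytest.approx(3.0)

    def test_identical_regions_undefined_ratio(self):
        aln = CodonAlignment("TTTGCAAAA", "TTTGCAAAA")
        res = nei_gojobori_dnds(aln)
        assert res.dN == 0.0 and res.dS == 0.0
        assert res.ratio is None
        assert "ratio_undefined_no_substitutions" in res.flags

    def test_single_synonymous_difference(self):
        # TTT→TTC is the 1-syn-difference hand case; padding codons keep the
        # synonymous-site total large enough for the correction to be defined
        aln = CodonAlignment("TTT" + "GGA" * 4, "TTC" + "GGA" * 4)
        res = nei_gojobori_dnds(aln)
        assert res.syn_diffs == pytest.approx(1.0)
        assert res.nonsyn_diffs == pytest.approx(0.0)
        p = 1.0 / res.syn_sites
        assert res.dS == pytest.approx(-0.75 * math.log(1 - 4 * p / 3))
        assert res.dN == 0.0

    def test_single_nonsynonymous_difference_infinite_ratio(self):
        aln = CodonAlignment("TTTGGA", "GTTGGA")
        res = nei_gojobori_dnds(aln)
        assert res.nonsyn_diffs == pytest.approx(1.0)
        assert res.syn_diffs == pytest.approx(0.0)
        assert res.dS == 0.0
        assert res.ratio == math.inf
        assert "ratio_infinite_dS_zero" in res.flags

    def test_two_difference_pathway_average(self):
        # TTT→CTC: one path goes Phe→Leu→Leu (1 non, 1 syn), the other
        # Phe→Phe→Leu (1 syn, 1 non); equal-weight average is (1, 1)
        aln = CodonAlignment("TTT", "CTC")
        res = nei_gojobori_dnds(aln)
        assert res.syn_diffs == pytest.approx(1.0)
        assert res.nonsyn_diffs == pytest.approx(1.0)

    def test_stop_pathway_excluded(self):
        # TAC→TTA: the pathway through TAA (stop) is excluded, leaving the
        # all-nonsynonymous route Tyr→Phe→Leu
        aln = CodonAlignment("TAC", "TTA")
        res = nei_gojobori_dnds(aln)
        assert res.syn_diffs == pytest.approx(0.0)
        assert res.nonsyn_diffs == pytest.approx(2.0)

    def test_pure_synonymous_divergence_gives_zero_dn(self):
        # two third-position synonymous changes among identical codons, so
        # the synonymous-site fraction stays below the correction's domain edge
        s1 = "GGA CTT CCA GCA CGA TCA GTA ACA".replace(" ", "")
        s2 = "GGG CTC CCA GCA CGA TCA GTA ACA".replace(" ", "")
        res = nei_gojobori_dnds(CodonAlignment(s1, s2))
        assert res.dN == 0.0
        assert res.dS > 0.0
        assert res.ratio == 0.0

    def test_pure_nonsynonymous_divergence_gives_zero_ds(self):
        s1 = "GCT AAA GAT TGC ATG".replace(" ", "")
        s2 = "CCT GAA CAT TAC ATA".replace(" ", "")
        res = nei_gojobori_dnds(CodonAlignment(s1, s2))
        assert res.dS == 0.0
        assert res.dN > 0.0
        assert res.ratio == math.inf

    def test_region_slicing_and_gap_skipping(self):
        aln = CodonAlignment(
            "TTTGCA---AAA", "TTCGCACCGAAA",
            {"head": (1, 2), "tail": (4, 4)},
        )
        head = nei_gojobori_dnds(aln, "head")
        assert head.codons_used == 2
        tail = nei_gojobori_dnds(aln, "tail")
        assert tail.codons_used == 1 and tail.syn_diffs == 0.0
        full = nei_gojobori_dnds(aln)
        assert full.codons_skipped == 1
        with pytest.raises(ValidationError, match="not defined"):
            nei_gojobori_dnds(aln, "no_such_region")

    def test_alignment_validation(self):
        with pytest.raises(ValidationError, match="equal length"):
            CodonAlignment("TTT", "TTTAAA")
        with pytest.raises(ValidationError, match="divisible"):
            CodonAlignment("TTTA", "TTTA")
        with pytest.raises(ValidationError, match="stop"):
            CodonAlignment("TAAGCTAAA", "TTTGCTAAA")
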