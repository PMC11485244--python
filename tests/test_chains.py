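"""Segment masses, fragment boundaries, digestion and fold coverage."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_sequence
from densid.chains import (
    Peptide,
    PeptideSet,
    SegmentSpec,
    chymotryptic_peptides,
    count_residue,
    fold_coverage,
    fragment_boundary_from_mass,
    peptide_mass,
    segment_mass,
    water_mass,
)
from densid.data import SYNTHETIC_ANXA11_LIKE, SYNTHETIC_TDP43_LIKE
from oracles import brute_force_digest


class TestMasses:
    def test_single_glycine_average_mass(self):
        seg = SegmentSpec("s", 1, 1)
        assert segment_mass(seg, "G") == pytest.approx(75.07, abs=0.01)

    def test_monoisotopic_mode(self):
        assert peptide_mass("G", mode="monoisotopic") == pytest.approx(75.032, abs=0.001)

    def test_carbamidomethyl_cysteine_fixed_modification(self):
        delta = peptide_mass("C", carbamidomethyl_cys=True) - peptide_mass("C")
        assert delta == pytest.approx(57.05, abs=0.01)

    def test_non_standard_residue_rejected(self):
        with pytest.raises(ValueError):
            peptide_mass("ABZ")

    def test_segment_bounds_validated(self):
        with pytest.raises(ValueError):
            SegmentSpec("s", 5, 3)
        with pytest.raises(ValueError):
            segment_mass(SegmentSpec("s", 1, 10), "GG")

    @given(st.data())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_mass_additivity_over_contiguous_splits(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        seq = random_sequence(rng, int(rng.integers(4, 60)))
        k = int(rng.integers(2, 5))
        cuts = sorted(rng.choice(np.arange(1, len(seq)), size=k - 1, replace=False))
        bounds = [0, *[int(c) for c in cuts], len(seq)]
        parts = [
            segment_mass(SegmentSpec("s", a + 1, b), seq)
            for a, b in zip(bounds[:-1], bounds[1:])
        ]
        total = segment_mass(SegmentSpec("s", 1, len(seq)), seq)
        assert sum(parts) - (k - 1) * water_mass("average") == pytest.approx(total, rel=1e-12)

    def test_synthetic_anxa11_like_fold_segment_is_3_8_kda(self):
        m = segment_mass(SegmentSpec("a", 39, 74), SYNTHETIC_ANXA11_LIKE.residues)
        assert round(m / 1000, 1) == 3.8

    def test_synthetic_tdp43_like_fold_segment_is_6_2_kda(self):
        m = segment_mass(SegmentSpec("t", 284, 345), SYNTHETIC_TDP43_LIKE.residues)
        assert round(m / 1000, 1) == 6.2

    def test_alternative_tdp43_fold_start_reported_alongside(self):
        seq = SYNTHETIC_TDP43_LIKE.residues
        m282 = segment_mass(SegmentSpec("t", 282, 345), seq)
        m284 = segment_mass(SegmentSpec("t", 284, 345), seq)
        assert m282 > m284
        assert m282 - m284 == pytest.approx(2 * 57.05, abs=0.1)  # two glycines


class TestCountResidue:
    def test_counts_exactly(self):
        assert count_residue(SegmentSpec("s", 1, 3), "PPP", "P") == 3

    def test_single_proline_in_synthetic_fold_segment(self):
        seq = SYNTHETIC_ANXA11_LIKE.residues
        assert count_residue(SegmentSpec("a", 39, 74), seq, "P") == 1
        assert seq[70] == "P"  # P71

    def test_proline_free_span_37_70(self):
        assert count_residue(SegmentSpec("a", 37, 70), SYNTHETIC_ANXA11_LIKE.residues, "P") == 0

    def test_invalid_letter_rejected(self):
        with pytest.raises(ValueError):
            count_residue(SegmentSpec("s", 1, 2), "AA", "B")


class TestFragmentBoundary:
    def test_full_chain_target_returns_last_residue(self):
        seq = "GGGGG"
        full = segment_mass(SegmentSpec("s", 1, 5), seq)
        r, residual = fragment_boundary_from_mass(seq, full, "N")
        assert r == 5
        assert residual == pytest.approx(0.0, abs=1e-9)

    def test_toy_pentaglycine_150da(self):
        # cumulative masses by hand: 75.07, 132.12, 189.17, ...
        r, residual = fragment_boundary_from_mass("GGGGG", 150.0, "N")
        assert r == 2
        assert residual == pytest.approx(132.12 - 150.0, abs=0.01)

    def test_boundary_monotone_in_target_mass(self):
        rng = np.random.default_rng(9)
        seq = random_sequence(rng, 80)
        lo = peptide_mass(seq[0])
        hi = peptide_mass(seq)
        targets = np.linspace(lo, hi, 25)
        rs = [fragment_boundary_from_mass(seq, t, "N")[0] for t in targets]
        assert rs == sorted(rs)

    def test_c_terminal_fragments(self):
        seq = "GGGGG"
        r, _ = fragment_boundary_from_mass(seq, 150.0, "C")
        assert r == 4  # suffix of two glycines, ties toward the shorter fragment

    def test_target_outside_range_rejected(self):
        with pytest.raises(ValueError):
            fragment_boundary_from_mass("GGGGG", 10.0, "N")
        with pytest.raises(ValueError):
            fragment_boundary_from_mass("GGGGG", 1e6, "N")

    def test_ntf_boundary_estimate_on_synthetic_chain(self):
        seq = SYNTHETIC_ANXA11_LIKE.residues
        r, residual = fragment_boundary_from_mass(seq, 22_000.0, "N")
        assert 1 <= r <= len(seq)
        # the N-terminal fragment mass is as close to 22 kDa as any neighbour
        m_r = segment_mass(SegmentSpec("a", 1, r), seq)
        m_prev = segment_mass(SegmentSpec("a", 1, r - 1), seq)
        m_next = segment_mass(SegmentSpec("a", 1, r + 1), seq)
        assert abs(m_r - 22_000) <= abs(m_prev - 22_000)
        assert abs(m_r - 22_000) <= abs(m_next - 22_000)


class TestDigestion:
    def test_sequence_without_enzyme_residues_is_one_peptide(self):
        ps = chymotryptic_peptides("GGGGG", max_missed=0)
        assert [(p.start, p.end, p.missed_cleavages) for p in ps.peptides] == [(1, 5, 0)]

    def test_worked_example_zero_missed(self):
        ps = chymotryptic_peptides("AFGAWG", max_missed=0)
        spans = [(p.start, p.end) for p in ps.peptides]
        assert spans == [(1, 2), (3, 5), (6, 6)]  # AF, GAW, G

    def test_worked_example_one_missed_adds_joined_peptides(self):
        ps = chymotryptic_peptides("AFGAWG", max_missed=1)
        seqs = set(ps.sequences("AFGAWG"))
        assert {"AF", "GAW", "G", "AFGAW", "GAWG"} == seqs

    def test_no_proline_rule_suppresses_cleavage(self):
        with_rule = chymotryptic_peptides("AFPG", max_missed=0, no_proline_rule=True)
        assert [(p.start, p.end) for p in with_rule.peptides] == [(1, 4)]
        without = chymotryptic_peptides("AFPG", max_missed=0, no_proline_rule=False)
        assert [(p.start, p.end) for p in without.peptides] == [(1, 2), (3, 4)]

    @pytest.mark.parametrize("max_missed", [0, 1, 2, 3])
    def test_equals_brute_force_enumeration(self, max_missed):
        rng = np.random.default_rng(100 + max_missed)
        for _ in range(20):
            seq = random_sequence(rng, int(rng.integers(1, 40)))
            ps = chymotryptic_peptides(seq, max_missed=max_missed)
            ours = {(p.start, p.end, p.missed_cleavages) for p in ps.peptides}
            assert ours == brute_force_digest(seq, max_missed)

    def test_zero_missed_peptides_tile_the_sequence(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            seq = random_sequence(rng, int(rng.integers(1, 60)))
            ps = chymotryptic_peptides(seq, max_missed=0)
            assert "".join(ps.sequences(seq)) == seq

    def test_length_filters(self):
        ps = chymotryptic_peptides("AFGAWG", max_missed=1, min_length=3)
        assert all(p.end - p.start + 1 >= 3 for p in ps.peptides)


class TestFoldCoverage:
    def test_no_peptides(self):
        ps = PeptideSet("s", (), "FWYLM", 0, True)
        cov = fold_coverage(ps, SegmentSpec("s", 5, 10))
        assert cov == {"n_overlapping": 0, "fraction_of_fold_covered": 0.0}

    def test_exact_fold_peptide(self):
        ps = PeptideSet("s", (Peptide(5, 10, 0),), "FWYLM", 0, True)
        cov = fold_coverage(ps, SegmentSpec("s", 5, 10))
        assert cov == {"n_overlapping": 1, "fraction_of_fold_covered": 1.0}

    def test_mismatched_parent_rejected(self):
        ps = PeptideSet("s", (), "FWYLM", 0, True)
        with pytest.raises(ValueError):
            fold_coverage(ps, SegmentSpec("other", 1, 5))

    def test_random_peptides_match_per_position_tally(self):
        rng = np.random.default_rng(21)
        fold = SegmentSpec("s", 20, 60)
        for _ in range(10):
            peptides = []
            for _ in range(int(rng.integers(0, 15))):
                a = int(rng.integers(1, 90))
                b = int(rng.integers(a, min(a + 25, 100)))
                peptides.append(Peptide(a, b, 0))
            ps = PeptideSet("s", tuple(peptides), "FWYLM", 0, True)
            cov = fold_coverage(ps, fold)
            # brute-force per-position tally
            hit_positions = {
                i for p in peptides for i in range(p.start, p.end + 1)
                if fold.start <= i <= fold.end
            }
            n_overlap = sum(
                1 for p in peptides if p.start <= fold.end and p.end >= fold.start
            )
            assert cov["n_overlapping"] == n_overlap
            assert cov["fraction_of_fold_covered"] == pytest.approx(
                len(hit_positions) / 41
            )
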