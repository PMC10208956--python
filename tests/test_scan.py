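"""Decamer enumeration and additive database scanning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import epitopescan as es
from epitopescan.errors import DomainError, ValidationError
from epitopescan.residues import AA_INDEX, AMINO_ACIDS
from epitopescan.scan import SequenceRecord

from conftest import random_decamers


def rec(seq, pid="P1"):
    return SequenceRecord(protein_id=pid, sequence=seq)


class TestEnumerate:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("ACDEFGHIKL", 1),
            ("ACDEFGHIK", 0),
            ("AAAAAAAAAAA", 1),  # 2 windows, 1 unique
            ("ACDEFXGHIKLMNP", 0),  # every window crosses the X
        ],
    )
    def test_window_arithmetic(self, seq, expected):
        _, n = es.enumerate_decamers([rec(seq)])
        assert n == expected

    def test_matches_bruteforce_on_random_proteins(self):
        records, _ = es.generate_proteome(50, (100, 300), seed=9)
        brute = {
            r.sequence[i : i + 10]
            for r in records
            for i in range(len(r.sequence) - 9)
        }
        uniq, n = es.enumerate_decamers(records)
        assert uniq == brute and n == len(brute)

    def test_noncanonical_invalidates_only_its_windows(self):
        seq = "A" * 12 + "X" + "C" * 12
        uniq, _ = es.enumerate_decamers([rec(seq)])
        assert uniq == {"A" * 10, "C" * 10}


class TestScorePeptide:
    def test_flat_matrix_scores(self, flat_matrix):
        raw, pct = es.score_peptide(flat_matrix, "ACDEFGHIKL")
        assert raw == pytest.approx(20.0) and pct == pytest.approx(100.0)

    def test_matches_hand_sum_on_random_inputs(self, random_matrix):
        for pep in random_decamers(100, seed=10):
            raw, pct = es.score_peptide(random_matrix, pep)
            hand = sum(random_matrix.entries[p, AA_INDEX[c]] for p, c in enumerate(pep))
            assert raw == pytest.approx(hand, rel=1e-12)
            assert pct == pytest.approx(
                100.0 * hand / es.max_theoretical_score(random_matrix), rel=1e-9
            )

    @pytest.mark.parametrize("bad", ["SHORT", "ACDEFGHIKLM", "ACDEFGHIKX", "ACDEFGHIKB"])
    def test_invalid_peptides_rejected(self, random_matrix, bad):
        with pytest.raises(ValidationError):
            es.score_peptide(random_matrix, bad)

    @given(shift=st.floats(-3, 3, allow_nan=False))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_constant_matrix_shift_adds_ten_shifts_to_raw(self, shift):
        rng = np.random.default_rng(0)
        entries = rng.normal(2.0, 0.5, (10, 20))
        pep = random_decamers(1, seed=11)[0]
        raw0, _ = es.score_peptide(es.ScoringMatrix(entries), pep)
        raw1, _ = es.score_peptide(es.ScoringMatrix(entries + shift), pep)
        assert raw1 == pytest.approx(raw0 + 10 * shift, abs=1e-8)


class TestScanDatabase:
    def test_full_band_equals_enumeration(self, random_matrix):
        records, _ = es.generate_proteome(10, (40, 60), seed=12)
        hits = es.scan_database(random_matrix, records, band=(-1000, 1000))
        uniq, _ = es.enumerate_decamers(records)
        assert {h.sequence for h in hits} == uniq

    def test_plant_and_recover_argmax(self, random_matrix):
        best = random_matrix.argmax_decamer()
        records, _ = es.generate_proteome(20, (80, 120), [best], seed=13)
        hits = es.scan_database(random_matrix, records, band=(99.999, 100))
        assert [h.sequence for h in hits] == [best]

    def test_equals_exhaustive_score_then_filter(self, truth):
        plate = es.simulate_pssl_plate(truth, 3, seed=14)
        m = es.build_scoring_matrix(plate)
        planted = es.planted_band_decamers(truth, 30, seed=15)
        records, _ = es.generate_proteome(1000, (80, 120), planted, seed=16)
        hits = es.scan_database(m, records, band=(80, 100))
        uniq, _ = es.enumerate_decamers(records)
        oracle = {
            pep for pep in uniq if 80 <= es.score_peptide(m, pep)[1] <= 100
        }
        assert {h.sequence for h in hits} == oracle
        for h in hits:  # scores agree with the scalar scorer
            raw, pct = es.score_peptide(m, h.sequence)
            assert h.raw_score == pytest.approx(raw, abs=1e-9)
            assert h.percent_of_max == pytest.approx(pct, abs=1e-9)

    def test_record_order_independence(self, random_matrix):
        records, _ = es.generate_proteome(30, (50, 90), seed=17)
        fwd = es.scan_database(random_matrix, records, band=(50, 100))
        rev = es.scan_database(random_matrix, records[::-1], band=(50, 100))
        assert [(h.sequence, h.percent_of_max) for h in fwd] == [
            (h.sequence, h.percent_of_max) for h in rev
        ]
        for a, b in zip(fwd, rev):
            assert sorted(a.sources) == sorted(b.sources)

    def test_band_nesting(self, truth):
        plate = es.simulate_pssl_plate(truth, 3, seed=18)
        m = es.build_scoring_matrix(plate)
        planted = es.planted_band_decamers(truth, 20, seed=19)
        records, _ = es.generate_proteome(50, (80, 120), planted, seed=20)
        narrow = {h.sequence for h in es.scan_database(m, records, band=(85, 100))}
        wide = {h.sequence for h in es.scan_database(m, records, band=(80, 100))}
        assert narrow <= wide

    def test_duplicate_decamer_aggregates_sources(self, flat_matrix):
        records = [rec("ACDEFGHIKL" + "MNPQ", "P1"), rec("WW" + "ACDEFGHIKL", "P2")]
        hits = es.scan_database(flat_matrix, records, band=(0, 100))
        by_seq = {h.sequence: h for h in hits}
        assert by_seq["ACDEFGHIKL"].sources == [("P1", 1), ("P2", 3)]

    def test_ranking_percent_desc_then_lexicographic(self, flat_matrix):
        # flat matrix: every decamer scores 100%, so order is purely lexicographic
        records = [rec("".join(AMINO_ACIDS[(i + k) % 20] for k in range(10)), f"P{i}") for i in range(5)]
        hits = es.scan_database(flat_matrix, records, band=(0, 100))
        seqs = [h.sequence for h in hits]
        assert seqs == sorted(seqs)

    def test_nonpositive_max_score_rejected(self):
        m = es.ScoringMatrix(np.full((10, 20), -1.0))
        with pytest.raises(DomainError):
            es.scan_database(m, [rec("ACDEFGHIKL")])

    def test_limit_truncates_after_ranking(self, random_matrix):
        records, _ = es.generate_proteome(10, (60, 80), seed=21)
        all_hits = es.scan_database(random_matrix, records, band=(0, 100))
        top3 = es.scan_database(random_matrix, records, band=(0, 100), limit=3)
        assert top3 == all_hits[:3]
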