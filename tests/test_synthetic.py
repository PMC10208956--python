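"""Synthetic study generator: determinism, degenerate cases, calibration."""

import numpy as np
import pandas as pd
import pytest

import epitopescan as es
from epitopescan.errors import ValidationError
from epitopescan.repertoire import load_repertoire, overlap_stats
from epitopescan.scan import _encode

from conftest import random_decamers


class TestGroundTruth:
    def test_deterministic_under_fixed_seed(self):
        a, b = es.make_ground_truth(1), es.make_ground_truth(1)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_different_seeds_differ(self):
        a, b = es.make_ground_truth(1), es.make_ground_truth(2)
        assert (a.weights != b.weights).any()

    def test_zero_variance_gives_equal_weights_and_scores(self):
        t = es.make_ground_truth(1, scale=0.0)
        assert (t.weights == t.weights.flat[0]).all()
        scores = {t.true_score(p) for p in random_decamers(20, seed=3)}
        assert len(scores) == 1

    def test_negative_scale_rejected(self):
        with pytest.raises(ValidationError):
            es.make_ground_truth(1, scale=-1.0)

    def test_weights_centred_per_position(self):
        t = es.make_ground_truth(5)
        np.testing.assert_allclose(t.weights.mean(axis=1), 0.0, atol=1e-12)


class TestPsslPlate:
    def test_row_count_and_positivity(self, truth):
        plate = es.simulate_pssl_plate(truth, n_experiments=3, seed=2)
        assert len(plate) == 10 * 20 * 3 * 2
        assert (plate["response_pg_ml"] > 0).all()

    def test_noiseless_median_is_exactly_scaled_weight(self, noiseless_plate, noiseless_truth):
        med = (
            noiseless_plate[noiseless_plate.concentration_ug_ml == 200.0]
            .groupby(["position", "residue"])["response_pg_ml"]
            .median()
        )
        for (p, a), m in med.items():
            w = noiseless_truth.weights[p - 1, _encode(a)[0]]
            assert np.log10(m) == pytest.approx(w + 2.0, abs=1e-9)

    def test_equal_weights_give_equal_expected_responses(self):
        t = es.make_ground_truth(1, scale=0.0, noise_cv=0.0)
        plate = es.simulate_pssl_plate(t, n_experiments=1, seed=0)
        assert plate["response_pg_ml"].nunique() == 1

    def test_noisy_median_accuracy_montecarlo(self):
        # lognormal CV 0.2 gives log10-sd ~0.086 per response; the median of
        # 3 experiments has sd ~0.058, so ~92% of the 200 mixtures should
        # land within 0.1 of W + log10(B); 0.85 is that minus 3 binomial sd
        t = es.make_ground_truth(1, noise_cv=0.2)
        plate = es.simulate_pssl_plate(t, n_experiments=3, seed=101)
        med = (
            plate[plate.concentration_ug_ml == 200.0]
            .groupby(["position", "residue"])["response_pg_ml"]
            .median()
        )
        ok = sum(
            abs(np.log10(m) - (t.weights[p - 1, _encode(a)[0]] + 2.0)) < 0.1
            for (p, a), m in med.items()
        )
        assert ok / len(med) >= 0.85

    def test_n_experiments_validation(self, truth):
        with pytest.raises(ValidationError):
            es.simulate_pssl_plate(truth, n_experiments=0)


class TestProteome:
    def test_single_protein_is_exactly_the_plant(self):
        records, manifest = es.generate_proteome(1, (10, 10), ["ACDEFGHIKL"], seed=1)
        assert len(records) == 1 and records[0].sequence == "ACDEFGHIKL"
        assert manifest.iloc[0]["start_1based"] == 1

    def test_planted_decamers_present_verbatim(self, truth):
        planted = es.planted_band_decamers(truth, 10, seed=4)
        records, manifest = es.generate_proteome(20, (50, 80), planted, seed=5)
        seqs = {r.protein_id: r.sequence for r in records}
        for _, row in manifest.iterrows():
            s = row["start_1based"] - 1
            assert seqs[row["protein_id"]][s : s + 10] == row["decamer"]
        assert set(manifest["decamer"]) == set(planted)

    def test_unique_count_matches_bruteforce(self):
        records, _ = es.generate_proteome(100, (500, 500), seed=6)
        brute = {r.sequence[i : i + 10] for r in records for i in range(len(r.sequence) - 9)}
        _, n = es.enumerate_decamers(records)
        assert n == len(brute)

    def test_too_short_for_plant_rejected(self):
        with pytest.raises(ValidationError):
            es.generate_proteome(5, (5, 9), ["ACDEFGHIKL"], seed=1)


class TestRecognitionAssay:
    def test_zero_gain_means_si_one(self):
        t = es.make_ground_truth(1, noise_cv=0.0)
        t = es.GroundTruthTcc(
            weights=t.weights, activation_gain=0.0, activation_threshold=0.0,
            noise_cv=0.0, seed=1,
        )
        wells = es.simulate_recognition_assay(t, random_decamers(3), n_wells=2, seed=0)
        ctrl = wells[wells.condition == "no_peptide"]["cpm"].mean()
        for cond, grp in wells.groupby("condition"):
            assert grp["cpm"].mean() / ctrl == pytest.approx(1.0, abs=1e-6)

    def test_saturated_peptide_si_is_one_plus_gain(self):
        base = es.make_ground_truth(1, noise_cv=0.0)
        t = es.GroundTruthTcc(  # threshold far below any attainable score
            weights=base.weights, activation_gain=3.0,
            activation_threshold=-1000.0, noise_cv=0.0, seed=1,
        )
        assert t.expected_si(t.argmax_decamer()) == pytest.approx(4.0, rel=1e-6)

    def test_si_calls_match_ground_truth_indicator(self, truth):
        # 50 peptides spanning the score range, 5 wells, CV 15%
        peps = es.planted_band_decamers(truth, 25, seed=7) + random_decamers(25, seed=7)
        wells = es.simulate_recognition_assay(truth, peps, n_wells=5, noise_cv=0.15, seed=8)
        from epitopescan.assays import WellSet, stimulation_index

        groups = {c: WellSet(c, g["cpm"].tolist()) for c, g in wells.groupby("condition")}
        ctrl = groups.pop("no_peptide")
        agree = sum(
            stimulation_index(ws, ctrl).stimulatory == truth.is_activating(c)
            for c, ws in groups.items()
        )
        assert agree / len(groups) >= 0.9

    def test_empty_peptide_list_rejected(self, truth):
        with pytest.raises(ValidationError):
            es.simulate_recognition_assay(truth, [])


class TestDoseResponse:
    def test_midpoint_identity_at_ec50(self):
        c = es.simulate_dose_response(0.2, doses=(0.2, 2.0, 20.0, 0.02), noise_cv=0.0,
                                      top=10.0, bottom=2.0, n_replicates=1, seed=0)
        at_ec50 = c.responses[c.doses.index(0.2)][0]
        assert at_ec50 == pytest.approx(6.0, rel=1e-12)

    def test_upper_asymptote(self):
        c = es.simulate_dose_response(0.01, doses=(1e6,), noise_cv=0.0, top=8.0,
                                      bottom=1.0, n_replicates=1, seed=0)
        assert c.responses[0][0] == pytest.approx(8.0, rel=1e-4)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValidationError):
            es.simulate_dose_response(-1.0)
        with pytest.raises(ValidationError):
            es.simulate_dose_response(0.02, doses=(0.0, 1.0))


class TestRepertoirePair:
    def test_constructed_overlap_is_exact(self):
        a, b = es.simulate_repertoire_pair(1000, 1000, 0.037, seed=1)
        ov = overlap_stats(load_repertoire(a, "A"), load_repertoire(b, "B"))
        assert ov.pct_of_a == pytest.approx(3.7, abs=1e-12)

    def test_zero_and_full_overlap(self):
        a, b = es.simulate_repertoire_pair(50, 50, 0.0, seed=2)
        assert overlap_stats(load_repertoire(a, "A"), load_repertoire(b, "B")).shared == 0
        a, b = es.simulate_repertoire_pair(50, 50, 1.0, seed=3)
        ov = overlap_stats(load_repertoire(a, "A"), load_repertoire(b, "B"))
        assert ov.pct_of_a == 100.0 and ov.pct_of_b == 100.0

    def test_frequencies_normalized(self):
        a, _ = es.simulate_repertoire_pair(200, 100, 0.1, seed=4)
        rep = load_repertoire(a, "A")
        assert sum(c.frequency for c in rep.clones.values()) == pytest.approx(1.0, abs=1e-9)

    def test_impossible_shared_count_rejected(self):
        with pytest.raises(ValidationError):
            es.simulate_repertoire_pair(1000, 10, 0.5, seed=0)


def test_generators_are_byte_deterministic(tmp_path, truth):
    """Identical seeds give byte-identical files for every generator."""
    from epitopescan import io as eio

    for sub in ("one", "two"):
        d = tmp_path / sub
        plate = es.simulate_pssl_plate(truth, 3, seed=11)
        eio.write_plate(plate, d / "plate.tsv")
        records, manifest = es.generate_proteome(10, (60, 90), seed=12)
        eio.write_fasta(records, d / "db.fasta")
        wells = es.simulate_recognition_assay(truth, ["ACDEFGHIKL"], seed=13)
        eio.write_wells(wells, d / "wells.tsv")
    for name in ("plate.tsv", "db.fasta", "wells.tsv"):
        assert (tmp_path / "one" / name).read_bytes() == (tmp_path / "two" / name).read_bytes()
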