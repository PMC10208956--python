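"""Prediction-validation simulation: the full in-silico discovery loop.

Chains every stage on synthetic data: draw a ground-truth clone, screen it
against the ps-SCL (noisy plate), build the scoring matrix, scan a large
synthetic proteome for candidate decamers, sample candidates across
predicted-score bands, simulate the proliferation assay on them, and
compute the recognition rate per band.  The headline readout is the
fraction of top-band (90-100% of maximum theoretical score) peptides called
stimulatory — the regime where additive-score predictions are expected to
be recognized.
"""

from __future__ import annotations

import numpy as np

from .assays import WellSet, recognition_rate_by_band, stimulation_index
from .matrix import build_scoring_matrix
from .scan import enumerate_decamers, scan_database
from .synthetic import (
    generate_proteome,
    make_ground_truth,
    planted_band_decamers,
    simulate_pssl_plate,
    simulate_recognition_assay,
)

__all__ = ["prediction_validation"]


def prediction_validation(
    seed: int,
    n_proteins: int = 2000,
    length_range: tuple = (480, 540),
    n_planted: int = 60,
    per_band: int = 30,
    bins: tuple = (60.0, 70.0, 80.0, 90.0, 100.0),
    n_experiments: int = 3,
    plate_cv: float = 0.2,
    assay_cv: float = 0.15,
    n_wells: int = 5,
) -> dict:
    """Run the end-to-end simulated discovery pipeline.

    The proteome defaults give roughly a million unique decamers; planted
    near-optimal peptides populate the upper score bands that random
    background essentially never reaches.  Up to ``per_band`` hits are
    sampled per band for the simulated proliferation assay.

    Returns a dict with the band table (:class:`~epitopescan.assays.BandRecognition`
    list), the number of unique decamers scanned and the number of peptides
    assayed.
    """
    rng = np.random.default_rng(seed)
    truth = make_ground_truth(seed, noise_cv=plate_cv)
    plate = simulate_pssl_plate(truth, n_experiments=n_experiments, seed=seed + 1)
    matrix = build_scoring_matrix(plate)

    planted = planted_band_decamers(truth, n_planted, seed=seed + 2)
    records, _ = generate_proteome(
        n_proteins, length_range=length_range, planted=planted, seed=seed + 3
    )
    _, n_decamers = enumerate_decamers(records)
    hits = scan_database(matrix, records, band=(bins[0], bins[-1]))

    # sample candidates per predicted band, mirroring synthesize-and-test
    sampled = []
    top = len(bins) - 2
    for i in range(len(bins) - 1):
        lo, hi = bins[i], bins[i + 1]
        in_band = [
            h
            for h in hits
            if (lo <= h.percent_of_max <= hi if i == top else lo <= h.percent_of_max < hi)
        ]
        if len(in_band) > per_band:
            in_band = [in_band[k] for k in rng.choice(len(in_band), per_band, replace=False)]
        sampled.extend(in_band)

    wells = simulate_recognition_assay(
        truth,
        [h.sequence for h in sampled],
        n_wells=n_wells,
        noise_cv=assay_cv,
        seed=seed + 4,
    )
    groups = {
        cond: WellSet(cond, grp["cpm"].tolist())
        for cond, grp in wells.groupby("condition", sort=True)
    }
    control = groups.pop("no_peptide")
    calls = [stimulation_index(ws, control) for ws in groups.values()]
    bands = recognition_rate_by_band(hits, calls, bins=bins)
    return {"bands": bands, "n_decamers": n_decamers, "n_assayed": len(calls)}
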