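"""Synthetic study generator.

Every input the pipeline consumes can be generated here with the
statistical structure the analysis assumes, so the whole pipeline is
testable without any downloads:

* a ground-truth T-cell clone whose recognition is additive over decamer
  positions (a 10x20 weight matrix on a log10 scale);
* noisy ps-SCL plate readouts (>=3 independent experiments, two
  concentrations, multiplicative lognormal noise);
* protein databases (FASTA) with planted high-scoring decamers and a
  manifest of where they were planted;
* replicate proliferation wells with a no-peptide control, driven by a
  sigmoidal activation model on the additive score;
* four-parameter-logistic dose-response data;
* clone-frequency-distributed TCR repertoire pairs with an exactly
  constructed shared fraction.

The activation model (a sigmoid of score minus threshold scaled by a
width) is a modelling stand-in: the additive score is what the analysis
assumes, the link from score to proliferation is invented here and every
parameter of it is explicit.  All randomness flows from a single integer
seed per call; there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .assays import DoseResponseCurve
from .errors import ValidationError
from .matrix import PLATE_COLUMNS
from .residues import AA_INDEX, AMINO_ACIDS, PEPTIDE_LENGTH, is_canonical
from .scan import SequenceRecord

__all__ = [
    "GroundTruthTcc",
    "make_ground_truth",
    "simulate_pssl_plate",
    "generate_proteome",
    "simulate_recognition_assay",
    "simulate_dose_response",
    "simulate_repertoire_pair",
    "planted_band_decamers",
    "lognormal_factors",
]


def lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Median-preserving multiplicative lognormal noise with the given CV.

    log-sd is sqrt(ln(1 + CV^2)) and log-mean 0, so the factor's median is
    exactly 1 — the median-based matrix estimator stays unbiased at any CV.
    """
    if cv < 0:
        raise ValidationError("noise CV must be >= 0")
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(0.0, sigma, size))


@dataclass(frozen=True)
class GroundTruthTcc:
    """A simulated T-cell clone with additive decamer recognition.

    ``weights`` is the true 10x20 matrix W (log10 stimulation units):
    the true score of a decamer is the sum of its ten entries.  Expected
    proliferation follows ``baseline * (1 + gain * sigmoid((score -
    threshold) / width))``, so the maximum expected stimulation index is
    ``1 + gain``.
    """

    weights: np.ndarray
    activation_gain: float = 9.0
    activation_threshold: float = 0.0
    activation_width: float = 1.0
    noise_cv: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (PEPTIDE_LENGTH, len(AMINO_ACIDS)):
            raise ValidationError(f"weights must be 10x20, got {w.shape}")
        if not np.all(np.isfinite(w)):
            raise ValidationError("weights must be finite")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        if self.activation_gain < 0:
            raise ValidationError("activation_gain must be >= 0")
        object.__setattr__(self, "weights", w)

    # -- true quantities -------------------------------------------------

    def true_score(self, peptide: str) -> float:
        if len(peptide) != PEPTIDE_LENGTH or not is_canonical(peptide):
            raise ValidationError(f"not a canonical decamer: {peptide!r}")
        idx = [AA_INDEX[c] for c in peptide]
        return float(self.weights[np.arange(PEPTIDE_LENGTH), idx].sum())

    def max_true_score(self) -> float:
        return float(self.weights.max(axis=1).sum())

    def argmax_decamer(self) -> str:
        return "".join(AMINO_ACIDS[j] for j in self.weights.argmax(axis=1))

    def expected_si(self, peptide: str) -> float:
        """Noise-free stimulation index: 1 + gain * sigmoid of the score margin."""
        z = (self.true_score(peptide) - self.activation_threshold) / self.activation_width
        return 1.0 + self.activation_gain * float(expit(z))

    def is_activating(self, peptide: str) -> bool:
        """Ground-truth activation indicator: expected SI >= 2."""
        return self.expected_si(peptide) >= 2.0


def make_ground_truth(
    seed: int,
    scale: float = 1.0,
    activation_gain: float = 9.0,
    threshold_fraction: float = 0.85,
    activation_width: float = 1.0,
    noise_cv: float = 0.2,
) -> GroundTruthTcc:
    """Draw a ground-truth clone with reproducible weights.

    W[p, a] are i.i.d. exponential with the given scale, then centred per
    position (each position's 20 entries have mean zero), so positions
    contribute symmetrically and the score of a random decamer is centred
    at 0.  ``scale == 0`` is the degenerate all-equal-weights case (every
    decamer scores identically); negative scales are rejected.

    The activation threshold is placed at ``threshold_fraction`` of the
    resulting maximum true score, which makes the clone selective for the
    top of the score range — the regime in which high-scoring predicted
    peptides are recognized.
    """
    if scale < 0:
        raise ValidationError("weight distribution scale must be >= 0")
    rng = np.random.default_rng(seed)
    w = rng.exponential(scale, size=(PEPTIDE_LENGTH, len(AMINO_ACIDS))) if scale > 0 else np.zeros(
        (PEPTIDE_LENGTH, len(AMINO_ACIDS))
    )
    w = w - w.mean(axis=1, keepdims=True)
    threshold = threshold_fraction * float(w.max(axis=1).sum())
    return GroundTruthTcc(
        weights=w,
        activation_gain=activation_gain,
        activation_threshold=threshold,
        activation_width=activation_width,
        noise_cv=noise_cv,
        seed=seed,
    )


def simulate_pssl_plate(
    truth: GroundTruthTcc,
    n_experiments: int = 3,
    concentrations: tuple = (200.0, 100.0),
    baseline: float = 100.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a ps-SCL response plate.

    Each mixture (position p, residue a) reads ``baseline * 10**W[p, a]``
    (pg/ml) times median-preserving lognormal noise at the truth's CV, for
    every experiment and concentration.  The concentration has no
    systematic effect by default (both doses sit on the response plateau,
    as in a screen run at saturating mixture concentrations).

    Returns a long-format table with columns :data:`~epitopescan.matrix.PLATE_COLUMNS`
    and exactly ``10 * 20 * n_experiments * len(concentrations)`` rows.
    """
    if n_experiments < 1:
        raise ValidationError("n_experiments must be >= 1")
    if baseline <= 0:
        raise ValidationError("baseline response must be > 0")
    rng = np.random.default_rng(truth.seed if seed is None else seed)

    rows = []
    mean = baseline * 10.0**truth.weights  # (10, 20)
    for exp in range(1, n_experiments + 1):
        for conc in concentrations:
            noise = lognormal_factors(rng, truth.noise_cv, mean.shape)
            resp = mean * noise
            for p in range(PEPTIDE_LENGTH):
                for a, residue in enumerate(AMINO_ACIDS):
                    rows.append((p + 1, residue, float(conc), f"exp{exp}", resp[p, a]))
    return pd.DataFrame(rows, columns=list(PLATE_COLUMNS))


def generate_proteome(
    n_proteins: int,
    length_range: tuple = (200, 600),
    planted: tuple = (),
    seed: int = 0,
    frequencies: dict | None = None,
) -> tuple[list, pd.DataFrame]:
    """Random protein database with planted decamers.

    Background residues are drawn i.i.d. from ``frequencies`` (uniform over
    the 20 canonical residues by default).  Every planted decamer is
    written intact into at least one protein at a recorded position.

    Returns ``(records, manifest)`` where ``records`` is a list of
    :class:`~epitopescan.scan.SequenceRecord` and ``manifest`` a table with
    columns ``decamer, protein_id, start_1based``.
    """
    lo, hi = int(length_range[0]), int(length_range[1])
    if lo > hi or lo < 1:
        raise ValidationError(f"bad length_range {length_range}")
    planted = [str(p).upper() for p in planted]
    for pep in planted:
        if len(pep) != PEPTIDE_LENGTH or not is_canonical(pep):
            raise ValidationError(f"planted decamer invalid: {pep!r}")
    if planted and hi < PEPTIDE_LENGTH:
        raise ValidationError("length_range too short to hold a planted decamer")
    if planted and n_proteins < 1:
        raise ValidationError("need at least one protein to plant into")

    rng = np.random.default_rng(seed)
    if frequencies is None:
        probs = np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
    else:
        probs = np.array([frequencies.get(a, 0.0) for a in AMINO_ACIDS], dtype=float)
        if probs.sum() <= 0:
            raise ValidationError("background frequencies sum to zero")
        probs = probs / probs.sum()

    alphabet = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    sequences = []
    for i in range(n_proteins):
        length = int(rng.integers(max(lo, PEPTIDE_LENGTH if planted else lo), hi + 1))
        seq = alphabet[rng.choice(len(AMINO_ACIDS), size=length, p=probs)]
        sequences.append(bytearray(seq))

    manifest_rows = []
    # round-robin over proteins; within a protein, slots are spaced so
    # plants never overwrite each other
    per_protein: dict = {}
    for k, pep in enumerate(planted):
        tries = 0
        while True:
            i = (k + tries) % n_proteins
            seq = sequences[i]
            taken = per_protein.setdefault(i, [])
            if len(seq) >= PEPTIDE_LENGTH:
                candidates = [
                    s
                    for s in range(0, len(seq) - PEPTIDE_LENGTH + 1)
                    if all(abs(s - t) >= PEPTIDE_LENGTH for t in taken)
                ]
                if candidates:
                    start = int(rng.choice(candidates))
                    seq[start : start + PEPTIDE_LENGTH] = pep.encode()
                    taken.append(start)
                    manifest_rows.append((pep, f"SYN{i + 1:05d}", start + 1))
                    break
            tries += 1
            if tries > n_proteins:
                raise ValidationError("could not place all planted decamers")

    records = [
        SequenceRecord(
            protein_id=f"SYN{i + 1:05d}",
            sequence=bytes(seq).decode(),
            description=f"synthetic protein {i + 1}",
        )
        for i, seq in enumerate(sequences)
    ]
    manifest = pd.DataFrame(manifest_rows, columns=["decamer", "protein_id", "start_1based"])
    return records, manifest


def planted_band_decamers(
    truth: GroundTruthTcc, n: int, seed: int = 0, max_substitutions: int = 6
) -> list:
    """Decamers spanning the upper score range of a ground-truth clone.

    Starts from the argmax decamer and substitutes 0..max_substitutions
    positions with mid-ranked residues, producing peptides whose true
    percent-of-max spreads roughly over 60-100%.  Used to populate the
    selection bands of a synthetic proteome, which pure random background
    essentially never reaches.
    """
    rng = np.random.default_rng(seed)
    best = truth.argmax_decamer()
    order = np.argsort(-truth.weights, axis=1)  # residues ranked per position
    out = [best]
    while len(out) < n:
        k = int(rng.integers(1, max_substitutions + 1))
        positions = rng.choice(PEPTIDE_LENGTH, size=k, replace=False)
        pep = list(best)
        for p in positions:
            rank = int(rng.integers(1, 9))  # 2nd..9th best residue at that position
            pep[p] = AMINO_ACIDS[order[p, rank]]
        out.append("".join(pep))
    # dedup preserving order, then top up deterministically if collisions occurred
    seen: dict = dict.fromkeys(out)
    out = list(seen)
    while len(out) < n:
        k = 1 + len(out) % max_substitutions
        pep = list(best)
        for p in range(k):
            pep[p] = AMINO_ACIDS[order[p, 1 + (len(out) % 8)]]
        cand = "".join(pep)
        if cand not in seen:
            seen[cand] = None
            out.append(cand)
    return out[:n]


def simulate_recognition_assay(
    truth: GroundTruthTcc,
    peptides: list,
    n_wells: int = 5,
    baseline_cpm: float = 1000.0,
    noise_cv: float | None = None,
    seed: int | None = None,
    control_condition: str = "no_peptide",
) -> pd.DataFrame:
    """Simulate replicate proliferation wells for a peptide panel.

    Expected cpm is ``baseline * (1 + gain * sigmoid((score - threshold) /
    width))`` for each peptide and ``baseline`` for the no-peptide control;
    every well gets multiplicative lognormal noise.  Returns a long table
    with columns ``condition, replicate, cpm`` including the control.
    """
    if not peptides:
        raise ValidationError("peptide list must be non-empty")
    if n_wells < 1:
        raise ValidationError("n_wells must be >= 1")
    cv = truth.noise_cv if noise_cv is None else noise_cv
    rng = np.random.default_rng(truth.seed if seed is None else seed)

    rows = []
    for factor, cond in zip(lognormal_factors(rng, cv, n_wells), range(n_wells)):
        rows.append((control_condition, cond + 1, baseline_cpm * factor))
    for pep in peptides:
        expected = baseline_cpm * truth.expected_si(pep)
        for w, factor in enumerate(lognormal_factors(rng, cv, n_wells), start=1):
            rows.append((pep, w, expected * factor))
    return pd.DataFrame(rows, columns=["condition", "replicate", "cpm"])


def simulate_dose_response(
    ec50: float,
    hill: float = 1.0,
    top: float = 10.0,
    bottom: float = 1.0,
    doses: tuple = (20.0, 2.0, 0.2, 0.02, 0.002),
    n_replicates: int = 5,
    noise_cv: float = 0.05,
    seed: int = 0,
) -> DoseResponseCurve:
    """Simulate a 4PL dose-response titration.

    Mean response at dose d is ``bottom + (top - bottom) / (1 +
    (ec50/d)**hill)``, times lognormal noise per replicate well.  The
    default doses are a five-step log titration from 20 down to 0.002 uM.
    """
    if ec50 <= 0:
        raise ValidationError("ec50 must be > 0 uM")
    if any(d <= 0 for d in doses):
        raise ValidationError("doses must be > 0 uM")
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    responses = []
    for d in doses:
        mean = bottom + (top - bottom) / (1.0 + (ec50 / d) ** hill)
        responses.append(list(mean * lognormal_factors(rng, noise_cv, n_replicates)))
    return DoseResponseCurve(doses=list(doses), responses=responses)


# -- TCR repertoires --------------------------------------------------------

_V_GENES = [f"TCRBV{i:02d}-01" for i in range(1, 31)]
_J_GENES = [f"TCRBJ{i:02d}-0{j}" for i in (1, 2) for j in range(1, 8)]
_CDR3_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def _random_clone_keys(rng: np.random.Generator, n: int) -> list:
    keys = []
    seen = set()
    while len(keys) < n:
        length = int(rng.integers(8, 17))
        cdr3 = "C" + "".join(
            _CDR3_ALPHABET[i] for i in rng.integers(0, len(_CDR3_ALPHABET), length)
        ) + "F"
        key = (
            cdr3,
            _V_GENES[int(rng.integers(len(_V_GENES)))],
            _J_GENES[int(rng.integers(len(_J_GENES)))],
        )
        if key not in seen:
            seen.add(key)
            keys.append(key)
    return keys


def _repertoire_table(rng, keys, exponent, total_templates) -> pd.DataFrame:
    n = len(keys)
    ranks = rng.permutation(n) + 1
    probs = ranks.astype(float) ** -exponent
    probs /= probs.sum()
    templates = np.maximum(1, np.round(probs * total_templates)).astype(int)
    return pd.DataFrame(
        {
            "cdr3_aa": [k[0] for k in keys],
            "v_gene": [k[1] for k in keys],
            "j_gene": [k[2] for k in keys],
            "productive": ["true"] * n,
            "templates": templates,
        }
    )


def simulate_repertoire_pair(
    n_a: int,
    n_b: int,
    shared_fraction_of_a: float,
    freq_exponent: float = 1.0,
    seed: int = 0,
    total_templates: int = 100_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two immunoSEQ-style repertoire tables with a constructed overlap.

    Exactly ``round(shared_fraction_of_a * n_a)`` clone keys (CDR3 aa + V +
    J identical) are placed in both repertoires, so
    :func:`~epitopescan.repertoire.overlap_stats` on the loaded pair
    returns ``pct_of_a = 100 * shared_fraction_of_a`` by construction
    (exactly, whenever the product is an integer).  Clone frequencies
    follow a power law with the given exponent over a random rank
    permutation.
    """
    if not 0 <= shared_fraction_of_a <= 1:
        raise ValidationError("shared_fraction_of_a must lie in [0, 1]")
    if n_a < 1 or n_b < 1:
        raise ValidationError("repertoire sizes must be >= 1")
    n_shared = round(shared_fraction_of_a * n_a)
    if n_shared > n_b:
        raise ValidationError(
            f"shared clone count {n_shared} exceeds repertoire B size {n_b}"
        )
    rng = np.random.default_rng(seed)
    keys = _random_clone_keys(rng, n_a + n_b - n_shared)
    shared = keys[:n_shared]
    a_keys = shared + keys[n_shared:n_a]
    b_keys = shared + keys[n_a:]
    table_a = _repertoire_table(rng, a_keys, freq_exponent, total_templates)
    table_b = _repertoire_table(rng, b_keys, freq_exponent, total_templates)
    return table_a, table_b
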