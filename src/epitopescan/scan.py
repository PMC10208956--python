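"""Additive scoring of decamers and streaming protein-database scans.

Under the additive recognition model a decamer ``s`` scores

    raw(s) = sum_p M[p, s_p]

against a scoring matrix ``M`` and is reported as a percentage of the
matrix's maximum theoretical score.  Candidate epitopes are the decamers
whose percent-of-maximum falls in a selection band (the field convention is
80-100%).  The scan streams the database record by record: memory is
bounded by the result set, never by the database size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from .errors import DomainError, ValidationError
from .matrix import ScoringMatrix
from .residues import AA_INDEX, AMINO_ACIDS, PEPTIDE_LENGTH

__all__ = [
    "SequenceRecord",
    "ScoredPeptide",
    "enumerate_decamers",
    "score_peptide",
    "scan_database",
]

# fast residue -> column lookup; non-canonical codes map to -1
_CODE = np.full(128, -1, dtype=np.int64)
for _aa, _i in AA_INDEX.items():
    _CODE[ord(_aa)] = _i


@dataclass
class SequenceRecord:
    """One protein from a FASTA database; sequence is upper-cased on ingest."""

    protein_id: str
    sequence: str
    description: str = ""
    organism: str | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValidationError(f"record {self.protein_id!r} has an empty sequence")


@dataclass
class ScoredPeptide:
    """A decamer with its additive score and all source locations.

    ``sources`` holds ``(protein_id, start)`` pairs with 1-based inclusive
    start coordinates; a decamer found in k proteins appears once with k
    source entries.
    """

    sequence: str
    raw_score: float
    percent_of_max: float
    sources: list = field(default_factory=list)
    database: str | None = None


def _encode(sequence: str) -> np.ndarray:
    """Residues as matrix column indices; -1 marks non-canonical codes."""
    raw = np.frombuffer(sequence.encode("ascii", errors="replace"), dtype=np.uint8)
    return _CODE[np.minimum(raw, 127)]


def _window_scores(entries: np.ndarray, idx: np.ndarray):
    """Scores and validity mask of every decamer window of an encoded sequence."""
    n_win = idx.size - PEPTIDE_LENGTH + 1
    if n_win <= 0:
        return np.empty(0), np.empty(0, dtype=bool)
    scores = np.zeros(n_win)
    valid = np.ones(n_win, dtype=bool)
    for p in range(PEPTIDE_LENGTH):
        col = idx[p : p + n_win]
        ok = col >= 0
        valid &= ok
        scores += entries[p, np.where(ok, col, 0)]
    return scores, valid


def enumerate_decamers(db: Iterable[SequenceRecord]) -> tuple[set, int]:
    """All unique decamers over every length-10 window of every sequence.

    Windows containing non-canonical residues (B, J, O, U, X, Z, ``*``) are
    skipped; only those windows are lost, not the whole protein.  Returns
    the deduplicated decamer set and its size.
    """
    unique: set = set()
    for rec in db:
        seq = rec.sequence
        idx = _encode(seq)
        _, valid = _window_scores(np.zeros((PEPTIDE_LENGTH, len(AMINO_ACIDS))), idx)
        for start in np.nonzero(valid)[0]:
            unique.add(seq[start : start + PEPTIDE_LENGTH])
    return unique, len(unique)


def score_peptide(matrix: ScoringMatrix, peptide: str) -> tuple[float, float]:
    """Raw additive score and percent-of-maximum of one decamer.

    Raises :class:`~epitopescan.errors.ValidationError` for a wrong length
    or non-canonical residues, and :class:`~epitopescan.errors.DomainError`
    if the matrix maximum is not positive (percent undefined).
    """
    peptide = peptide.upper()
    if len(peptide) != PEPTIDE_LENGTH:
        raise ValidationError(
            f"peptide must be a decamer, got length {len(peptide)}: {peptide!r}"
        )
    idx = _encode(peptide)
    if (idx < 0).any():
        bad = sorted({c for c, i in zip(peptide, idx) if i < 0})
        raise ValidationError(f"peptide {peptide!r} has non-canonical residues {bad}")
    raw = float(matrix.entries[np.arange(PEPTIDE_LENGTH), idx].sum())
    max_score = matrix.max_theoretical_score()
    if max_score <= 0:
        raise DomainError("maximum theoretical score <= 0: percent-of-max undefined")
    return raw, 100.0 * raw / max_score


def scan_database(
    matrix: ScoringMatrix,
    db: Iterable[SequenceRecord],
    band: tuple = (80.0, 100.0),
    limit: int | None = None,
    database: str | None = None,
) -> list:
    """Scan a protein database for decamers inside a percent-of-max band.

    Parameters
    ----------
    matrix
        The positional scoring matrix.
    db
        Iterable of :class:`SequenceRecord` (a generator streams fine).
    band
        ``(lo, hi)`` selection band in percent of the maximum theoretical
        score, inclusive at both ends.
    limit
        Optional cap on the number of returned peptides (applied after
        ranking).
    database
        Label stored on every hit for provenance.

    Returns
    -------
    list of :class:`ScoredPeptide`
        Unique decamers with all source locations aggregated, sorted by
        percent-of-max descending then lexicographically by sequence.
    """
    lo, hi = float(band[0]), float(band[1])
    if lo > hi:
        raise ValidationError(f"band lower edge {lo} exceeds upper edge {hi}")
    max_score = matrix.max_theoretical_score()
    if max_score <= 0:
        raise DomainError("maximum theoretical score <= 0: percent-of-max undefined")

    hits: dict = {}
    for rec in db:
        seq = rec.sequence
        idx = _encode(seq)
        scores, valid = _window_scores(matrix.entries, idx)
        pct = 100.0 * scores / max_score
        keep = valid & (pct >= lo) & (pct <= hi)
        for start in np.nonzero(keep)[0]:
            pep = seq[start : start + PEPTIDE_LENGTH]
            entry = hits.get(pep)
            if entry is None:
                entry = hits[pep] = ScoredPeptide(
                    sequence=pep,
                    raw_score=float(scores[start]),
                    percent_of_max=float(pct[start]),
                    sources=[],
                    database=database,
                )
            entry.sources.append((rec.protein_id, int(start) + 1))

    ranked = sorted(hits.values(), key=lambda h: (-h.percent_of_max, h.sequence))
    return ranked[:limit] if limit is not None else ranked
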