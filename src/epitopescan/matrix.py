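"""Positional scoring matrices from ps-SCL (positional-scanning synthetic
combinatorial peptide library) assay responses.

A ps-SCL screen tests a T-cell clone against 200 decapeptide mixtures, each
fixing one of the 20 L-amino acids at one of 10 positions while the other
nine positions are randomized.  The readout (typically IFN-gamma in pg/ml,
but proliferation cpm works the same way) for mixture (p, a) estimates how
much residue ``a`` at position ``p`` contributes to recognition.  The
scoring matrix is the log10 of the per-mixture median response across
independent experiments:

    M[p, a] = log10(max(floor, median_e response(p, a, e)))

Under the additive model a decamer's score is the sum of its ten matrix
entries, and the maximum theoretical score is the sum of the per-position
column maxima.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, IncompletePlateError, ValidationError
from .residues import AMINO_ACIDS, PEPTIDE_LENGTH

__all__ = [
    "ScoringMatrix",
    "build_scoring_matrix",
    "max_theoretical_score",
    "PLATE_COLUMNS",
]

#: Required columns of a ps-SCL plate table.
PLATE_COLUMNS = (
    "position",
    "residue",
    "concentration_ug_ml",
    "experiment",
    "response_pg_ml",
)

#: Concentration policies accepted by :func:`build_scoring_matrix`.
CONCENTRATION_POLICIES = ("single", "max-over-concentrations", "pool-as-experiments")


@dataclass
class ScoringMatrix:
    """A 10 x 20 positional scoring matrix in log10 stimulation units.

    Rows are decamer positions 1..10, columns the canonical residues in
    :data:`~epitopescan.residues.AMINO_ACIDS` order.
    """

    entries: np.ndarray
    floor_value: float = 1.0
    readout: str = "IFNg_pg_ml"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        if self.entries.shape != (PEPTIDE_LENGTH, len(AMINO_ACIDS)):
            raise ValidationError(
                f"scoring matrix must be {PEPTIDE_LENGTH}x{len(AMINO_ACIDS)}, "
                f"got {self.entries.shape}"
            )
        if not np.all(np.isfinite(self.entries)):
            raise ValidationError("scoring matrix entries must all be finite")

    # -- views -----------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Matrix as a DataFrame indexed by 1-based position."""
        return pd.DataFrame(
            self.entries,
            index=pd.RangeIndex(1, PEPTIDE_LENGTH + 1, name="position"),
            columns=list(AMINO_ACIDS),
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, **kwargs) -> "ScoringMatrix":
        missing = [a for a in AMINO_ACIDS if a not in frame.columns]
        if missing:
            raise ValidationError(f"matrix frame missing residue columns {missing}")
        return cls(frame[list(AMINO_ACIDS)].to_numpy(dtype=float), **kwargs)

    # -- derived quantities ---------------------------------------------

    def max_theoretical_score(self) -> float:
        """Sum over positions of the best residue entry at that position."""
        return float(self.entries.max(axis=1).sum())

    def argmax_decamer(self) -> str:
        """The decamer built from the per-position argmax residues.

        It attains exactly the maximum theoretical score; ties break toward
        the alphabetically first residue.
        """
        return "".join(AMINO_ACIDS[j] for j in self.entries.argmax(axis=1))


def max_theoretical_score(matrix: ScoringMatrix) -> float:
    """Maximum theoretical score of ``matrix`` (module-level convenience)."""
    return matrix.max_theoretical_score()


def _validate_plate(plate: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PLATE_COLUMNS if c not in plate.columns]
    if missing:
        raise IncompletePlateError(f"plate table missing columns {missing}")
    bad = plate[~plate["residue"].isin(list(AMINO_ACIDS))]
    if len(bad):
        raise ValidationError(
            f"plate contains non-canonical residues: {sorted(bad['residue'].unique())}"
        )
    pos = plate["position"].to_numpy()
    if ((pos < 1) | (pos > PEPTIDE_LENGTH)).any():
        raise ValidationError("plate positions must lie in 1..10")
    return plate


def build_scoring_matrix(
    plate: pd.DataFrame,
    concentration: float = 200.0,
    policy: str = "single",
    floor: float = 1.0,
    blank: float = 0.0,
    readout: str = "IFNg_pg_ml",
) -> ScoringMatrix:
    """Build a :class:`ScoringMatrix` from a ps-SCL plate table.

    Parameters
    ----------
    plate
        Long-format table with columns :data:`PLATE_COLUMNS`; one row per
        mixture x concentration x experiment.
    concentration
        Which concentration (ug/ml) to use under the ``"single"`` policy.
    policy
        ``"single"``            use only rows at ``concentration`` (default);
        ``"max-over-concentrations"``  per (position, residue, experiment)
                                take the max response over concentrations;
        ``"pool-as-experiments"``      treat every (experiment,
                                concentration) pair as its own replicate.
    floor
        Detection floor applied before the log10, so that zero or weak
        responses map to log10(floor) instead of -inf.
    blank
        Optional background (no-peptide) readout subtracted from every
        response before flooring.  Off (0.0) by default.

    Notes
    -----
    The matrix entry is ``log10(max(floor, median over replicates))``; the
    median with an even replicate count is the mean of the two central
    values.
    """
    plate = _validate_plate(plate)
    if policy not in CONCENTRATION_POLICIES:
        raise ValidationError(
            f"unknown concentration policy {policy!r}; choose from {CONCENTRATION_POLICIES}"
        )

    work = plate.copy()
    if blank:
        work["response_pg_ml"] = work["response_pg_ml"] - blank

    if policy == "single":
        work = work[np.isclose(work["concentration_ug_ml"], concentration)]
        if work.empty:
            raise ValidationError(
                f"no plate rows at concentration {concentration} ug/ml"
            )
        replicates = work.groupby(["position", "residue"])["response_pg_ml"]
    elif policy == "max-over-concentrations":
        work = (
            work.groupby(["position", "residue", "experiment"])["response_pg_ml"]
            .max()
            .reset_index()
        )
        replicates = work.groupby(["position", "residue"])["response_pg_ml"]
    else:  # pool-as-experiments
        replicates = work.groupby(["position", "residue"])["response_pg_ml"]

    medians = replicates.median()

    entries = np.full((PEPTIDE_LENGTH, len(AMINO_ACIDS)), np.nan)
    for (p, a), med in medians.items():
        entries[int(p) - 1, AMINO_ACIDS.index(a)] = med

    nan_p, nan_a = np.nonzero(np.isnan(entries))
    if len(nan_p):
        p, a = int(nan_p[0]) + 1, AMINO_ACIDS[nan_a[0]]
        raise IncompletePlateError(
            f"plate is missing responses for position {p}, residue {a} "
            f"({len(nan_p)} empty cells in total)"
        )

    if floor <= 0 and (entries <= 0).any():
        raise DomainError(
            "non-positive median response with a non-positive floor: log10 undefined"
        )

    return ScoringMatrix(
        entries=np.log10(np.maximum(floor, entries)),
        floor_value=floor,
        readout=readout,
        provenance={
            "policy": policy,
            "concentration_ug_ml": concentration,
            "floor": floor,
            "blank": blank,
            "n_rows": int(len(plate)),
        },
    )
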