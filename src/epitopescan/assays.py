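"""T-cell assay analytics.

Derived quantities used throughout epitope-validation work:

* **Stimulation index (SI)** — mean cpm of 3H-thymidine incorporation with
  peptide divided by the mean cpm of the no-peptide control; SI >= 2 is
  called stimulatory (threshold inclusive).
* **Net cytokine** — condition minus negative-control pg/ml, floored at 0.
* **EC50** — four-parameter logistic (4PL) dose-response fit in log-dose
  space.
* **Recognition rate by predicted-score band** — fraction of tested
  peptides called stimulatory within each percent-of-maximum band.
* **Specific cytotoxicity** — percent dead targets with effectors minus
  the unspecific background death without effectors, floored at 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import (
    DomainError,
    InsufficientDataError,
    ReconciliationError,
    ValidationError,
)

__all__ = [
    "WellSet",
    "SIResult",
    "DoseResponseCurve",
    "EC50Fit",
    "CytokinePanel",
    "BandRecognition",
    "stimulation_index",
    "net_cytokine",
    "fit_ec50",
    "recognition_rate_by_band",
    "specific_cytotoxicity",
]

SI_THRESHOLD_DEFAULT = 2.0


@dataclass
class WellSet:
    """Replicate cpm readings for one culture condition."""

    condition: str
    replicates: list

    def __post_init__(self) -> None:
        self.replicates = [float(x) for x in self.replicates]
        if not self.replicates:
            raise ValidationError(f"condition {self.condition!r} has no replicates")
        if any(x < 0 for x in self.replicates):
            raise ValidationError(f"condition {self.condition!r} has negative cpm")

    @property
    def mean(self) -> float:
        return float(np.mean(self.replicates))


@dataclass
class SIResult:
    condition: str
    si: float
    stimulatory: bool
    n_replicates: int


@dataclass
class DoseResponseCurve:
    """Doses in uM and per-dose replicate responses (a list per dose)."""

    doses: list
    responses: list  # list of replicate lists, aligned with doses

    def __post_init__(self) -> None:
        if len(self.doses) != len(self.responses):
            raise ValidationError("doses and response groups must align")
        if any(d <= 0 for d in self.doses):
            raise ValidationError("doses must be positive (uM)")

    def mean_responses(self) -> np.ndarray:
        return np.array([np.mean(r) for r in self.responses])


@dataclass
class EC50Fit:
    ec50: float
    hill: float
    top: float
    bottom: float
    converged: bool


@dataclass
class CytokinePanel:
    """A single analyte with its condition and negative-control readouts."""

    analyte: str
    condition_pg_ml: float
    control_pg_ml: float
    net: float = field(init=False)

    def __post_init__(self) -> None:
        self.net = net_cytokine(self.condition_pg_ml, self.control_pg_ml)


@dataclass
class BandRecognition:
    lo: float
    hi: float
    n_tested: int
    n_stimulatory: int

    @property
    def fraction(self) -> float:
        return self.n_stimulatory / self.n_tested if self.n_tested else float("nan")


# ---------------------------------------------------------------------------


def stimulation_index(
    condition: WellSet,
    control: WellSet,
    threshold: float = SI_THRESHOLD_DEFAULT,
) -> SIResult:
    """SI = mean(condition cpm) / mean(control cpm), stimulatory iff SI >= threshold."""
    if control.mean <= 0:
        raise DomainError(
            f"control {control.condition!r} has mean cpm {control.mean}: SI undefined"
        )
    si = condition.mean / control.mean
    return SIResult(
        condition=condition.condition,
        si=si,
        stimulatory=si >= threshold,
        n_replicates=len(condition.replicates),
    )


def net_cytokine(condition: float, control: float) -> float:
    """Background-subtracted cytokine amount, floored at zero pg/ml."""
    if condition < 0 or control < 0:
        raise ValidationError("cytokine readouts must be non-negative pg/ml")
    return max(0.0, condition - control)


def specific_cytotoxicity(dead_with_effector: float, dead_without_effector: float) -> float:
    """Specific killing: measured death minus unspecific background, floored at 0.

    Both arguments are percentages of dead target cells in [0, 100].
    """
    for v in (dead_with_effector, dead_without_effector):
        if not 0 <= v <= 100:
            raise ValidationError(f"death percentage {v} outside [0, 100]")
    return max(0.0, dead_with_effector - dead_without_effector)


def _four_pl(log_dose, log_ec50, hill, top, bottom):
    # response = bottom + (top-bottom) / (1 + (ec50/dose)^hill), in log10-dose space
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_ec50 - log_dose)))


def fit_ec50(curve: DoseResponseCurve) -> EC50Fit:
    """Least-squares 4PL fit; deterministic given the data.

    Initialization: bottom and top from the extreme mean responses, hill 1,
    EC50 at the dose whose mean response is closest to the midpoint.  The
    fitted EC50 is constrained to [min dose / 100, max dose * 100]; a fit at
    those limits, a failed optimisation or flat data returns
    ``converged=False`` rather than raising.
    """
    doses = np.asarray(curve.doses, dtype=float)
    if len(np.unique(doses)) < 4:
        raise InsufficientDataError("EC50 fit needs >= 4 distinct doses")

    log_d = np.repeat(np.log10(doses), [len(r) for r in curve.responses])
    y = np.concatenate([np.asarray(r, dtype=float) for r in curve.responses])

    means = curve.mean_responses()
    span = means.max() - means.min()
    if span <= 1e-12 * max(1.0, abs(means.max())):
        return EC50Fit(float("nan"), float("nan"), means.max(), means.min(), False)

    mid = (means.max() + means.min()) / 2.0
    log_ec50_0 = np.log10(doses[np.argmin(np.abs(means - mid))])
    lo_e, hi_e = np.log10(doses.min()) - 2.0, np.log10(doses.max()) + 2.0
    # assay readouts are non-negative, so the lower plateau is bounded at 0
    p0 = [np.clip(log_ec50_0, lo_e, hi_e), 1.0, means.max(), max(0.0, means.min())]
    bounds = (
        [lo_e, 0.05, 0.0, 0.0],
        [hi_e, 20.0, np.inf, np.inf],
    )
    try:
        popt, _ = curve_fit(
            _four_pl, log_d, y, p0=p0, bounds=bounds, maxfev=20000, xtol=1e-12, ftol=1e-12
        )
    except RuntimeError:
        return EC50Fit(float("nan"), float("nan"), float("nan"), float("nan"), False)

    log_ec50, hill, top, bottom = popt
    ec50 = float(10.0**log_ec50)
    converged = bool(
        np.isfinite(popt).all()
        and top > bottom
        and lo_e + 1e-6 < log_ec50 < hi_e - 1e-6
    )
    return EC50Fit(ec50, float(hill), float(top), float(bottom), converged)


def recognition_rate_by_band(hits, calls, bins=(60.0, 70.0, 80.0, 90.0, 100.0)) -> list:
    """Fraction of tested peptides called stimulatory per predicted-score band.

    Parameters
    ----------
    hits
        :class:`~epitopescan.scan.ScoredPeptide` list from a database scan.
    calls
        :class:`SIResult` list; each call's ``condition`` must equal the
        sequence of one hit, otherwise a
        :class:`~epitopescan.errors.ReconciliationError` lists the orphans.
    bins
        Ascending percent band edges.  Bands are half-open ``[lo, hi)``
        except the top band, which is closed ``[lo, hi]``.

    Only peptides with a call count as tested; hits without calls are
    ignored (they were never assayed).
    """
    edges = [float(b) for b in bins]
    if sorted(edges) != edges or len(edges) < 2:
        raise ValidationError("bins must be >= 2 ascending band edges")

    pct_by_seq = {h.sequence: h.percent_of_max for h in hits}
    orphans = [c.condition for c in calls if c.condition not in pct_by_seq]
    if orphans:
        raise ReconciliationError(
            f"{len(orphans)} assay call(s) without a matching scanned peptide: "
            f"{sorted(orphans)[:10]}"
        )

    bands = [
        BandRecognition(lo=edges[i], hi=edges[i + 1], n_tested=0, n_stimulatory=0)
        for i in range(len(edges) - 1)
    ]
    top = len(bands) - 1
    for call in calls:
        pct = pct_by_seq[call.condition]
        for i, b in enumerate(bands):
            in_band = b.lo <= pct <= b.hi if i == top else b.lo <= pct < b.hi
            if in_band:
                b.n_tested += 1
                b.n_stimulatory += int(call.stimulatory)
                break
    return bands
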