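"""Exception hierarchy.

Validation / format problems (bad inputs, malformed files) and domain
problems (mathematically undefined results) are kept distinct so that the
CLI can map them to different exit codes (2 and 3 respectively).
"""


class EpitopeScanError(Exception):
    """Base class for all package errors."""


class ValidationError(EpitopeScanError):
    """Invalid parameter or input value (CLI exit code 2)."""


class FormatError(ValidationError):
    """Malformed input file: wrong header, ragged rows, bad numerics."""


class IncompletePlateError(FormatError):
    """A ps-SCL plate is missing one or more (position, residue) cells."""


class InsufficientDataError(ValidationError):
    """Too few observations for the requested fit or statistic."""


class ReconciliationError(ValidationError):
    """Assay calls could not be matched to scanned peptides."""


class DomainError(EpitopeScanError):
    """Result undefined for these values, e.g. percent-of-max with a
    non-positive maximum theoretical score (CLI exit code 3)."""
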