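"""Canonical amino-acid alphabet shared across the package.

The fixed residue order defines the column order of every 10x20 matrix
(scoring matrices and ground-truth weight matrices alike).
"""

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
"""The 20 canonical L-amino acids, one-letter codes, alphabetical."""

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Residue codes that invalidate a decamer window when scanning databases:
#: ambiguity codes, non-standard residues and stop markers.
NON_CANONICAL: frozenset = frozenset("BJOUXZ*")

PEPTIDE_LENGTH: int = 10
"""All library peptides and scanned windows are decamers."""


def is_canonical(peptide: str) -> bool:
    """True if every residue of ``peptide`` is one of the 20 canonical codes."""
    return all(c in AA_INDEX for c in peptide)
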