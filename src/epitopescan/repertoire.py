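"""TCRVbeta repertoire parsing and overlap statistics.

Repertoires arrive as immunoSEQ-style TSV exports.  A clone is identified
by the (CDR3 amino-acid sequence, V gene, J gene) triple; non-productive
rearrangements are excluded, duplicate clone rows are merged with their
template counts summed, and clone frequencies are recomputed over the
retained (productive) templates so they always sum to 1.

Overlap between two sorted T-cell fractions is reported three ways: the
shared-clone count, the percentage of each repertoire's unique clones that
are shared (the focal-population convention: "X% of population A is also
found in B" uses A's unique clone count as denominator), and the Jaccard
index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import DomainError, FormatError

__all__ = [
    "TcrClone",
    "TcrRepertoire",
    "OverlapStats",
    "DEFAULT_COLUMN_MAP",
    "load_repertoire",
    "overlap_stats",
    "shared_frequency",
]

#: Logical field -> candidate column names in immunoSEQ-style exports.
DEFAULT_COLUMN_MAP = {
    "cdr3_aa": ("cdr3_aa", "amino_acid", "aminoAcid"),
    "v_gene": ("v_gene", "vGeneName", "v_resolved"),
    "j_gene": ("j_gene", "jGeneName", "j_resolved"),
    "productive": ("productive", "frame_type", "sequenceStatus"),
    "templates": ("templates", "count (templates/reads)", "count"),
}

#: Values of a productive-status column that mark a productive rearrangement.
_PRODUCTIVE_TRUE = {"true", "1", "in", "productive", "yes", "t"}


@dataclass(frozen=True)
class TcrClone:
    cdr3_aa: str
    v_gene: str
    j_gene: str
    templates: int
    frequency: float

    @property
    def key(self) -> tuple:
        return (self.cdr3_aa, self.v_gene, self.j_gene)


@dataclass
class TcrRepertoire:
    """Unique productive clones of one sample, keyed by (CDR3 aa, V, J)."""

    sample: str
    clones: dict = field(default_factory=dict)  # key -> TcrClone
    total_templates: int = 0

    @property
    def keys(self) -> set:
        return set(self.clones)

    def __len__(self) -> int:
        return len(self.clones)


@dataclass
class OverlapStats:
    shared: int
    pct_of_a: float
    pct_of_b: float
    jaccard: float
    shared_keys: set = field(default_factory=set)


def _resolve_columns(df: pd.DataFrame, column_map: dict | None) -> dict:
    resolved = {}
    merged = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        for k, v in column_map.items():
            merged[k] = (v,) if isinstance(v, str) else tuple(v)
    for logical, candidates in merged.items():
        found = next((c for c in candidates if c in df.columns), None)
        if found is None:
            raise FormatError(
                f"repertoire table missing a column for {logical!r} "
                f"(looked for {list(candidates)})"
            )
        resolved[logical] = found
    return resolved


def _is_productive(value) -> bool:
    return str(value).strip().lower() in _PRODUCTIVE_TRUE


def load_repertoire(
    table: pd.DataFrame,
    sample: str = "sample",
    column_map: dict | None = None,
) -> TcrRepertoire:
    """Build a :class:`TcrRepertoire` from an immunoSEQ-style table.

    Non-productive rows are dropped; rows with an identical clone key are
    merged (templates summed); frequencies are recomputed over the retained
    templates.  Mapping ``cdr3_aa`` to a nucleotide-sequence column via
    ``column_map`` switches clone identity to nucleotide resolution.
    """
    cols = _resolve_columns(table, column_map)
    work = table[[cols[k] for k in ("cdr3_aa", "v_gene", "j_gene", "productive", "templates")]]
    work = work.set_axis(["cdr3_aa", "v_gene", "j_gene", "productive", "templates"], axis=1)
    work = work[work["productive"].map(_is_productive)].copy()
    work["templates"] = pd.to_numeric(work["templates"], errors="raise").astype(int)

    grouped = (
        work.groupby(["cdr3_aa", "v_gene", "j_gene"], sort=False)["templates"].sum()
    )
    total = int(grouped.sum())
    clones = {
        key: TcrClone(
            cdr3_aa=key[0],
            v_gene=key[1],
            j_gene=key[2],
            templates=int(n),
            frequency=(n / total) if total else 0.0,
        )
        for key, n in grouped.items()
    }
    return TcrRepertoire(sample=sample, clones=clones, total_templates=total)


def overlap_stats(a: TcrRepertoire, b: TcrRepertoire) -> OverlapStats:
    """Clone-key overlap between two repertoires.

    ``pct_of_a`` = 100 * shared / |unique clones of A| (the focal
    convention), symmetrically for B; Jaccard over the key union.
    """
    if not len(a) or not len(b):
        raise DomainError("overlap percentages undefined for an empty repertoire")
    shared_keys = a.keys & b.keys
    shared = len(shared_keys)
    return OverlapStats(
        shared=shared,
        pct_of_a=100.0 * shared / len(a),
        pct_of_b=100.0 * shared / len(b),
        jaccard=shared / len(a.keys | b.keys),
        shared_keys=shared_keys,
    )


def shared_frequency(shared_keys: set, reference: TcrRepertoire) -> float:
    """Cumulative frequency in ``reference`` of the clones in ``shared_keys``.

    Keys absent from the reference contribute zero; the result lies in
    [0, 1] because reference frequencies are normalized.
    """
    return float(
        sum(c.frequency for key, c in reference.clones.items() if key in shared_keys)
    )
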