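"""Set algebra and annotation over eluted / candidate peptide lists.

Works on long-format peptide tables (one row per peptide observation) with
columns ``sequence``, ``sample_id`` and optional annotations
``source_protein``, ``organism`` and the taxonomic lineage ranks
``phylum``..``species``.  Peptide identity is the exact upper-cased
amino-acid string throughout (no I/L equivalence unless requested), which
is also how control-cohort subtraction is defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from .errors import ValidationError

__all__ = [
    "LINEAGE_RANKS",
    "unique_per_sample",
    "subtract_control",
    "merge_samples",
    "MergeResult",
    "source_summary",
    "SourceSummary",
    "phylum_composition",
    "match_taxa",
    "TaxaMatch",
]

logger = logging.getLogger(__name__)

#: Lineage ranks ordered coarse -> fine, as stored in peptide tables.
LINEAGE_RANKS = ("phylum", "class", "order", "family", "genus", "species")

UNASSIGNED = "unassigned"


def _normalize(df: pd.DataFrame, il_equivalence: bool = False) -> pd.DataFrame:
    if "sequence" not in df.columns:
        raise ValidationError("peptide table needs a 'sequence' column")
    out = df.copy()
    out["sequence"] = out["sequence"].astype(str).str.upper()
    if il_equivalence:
        out["sequence"] = out["sequence"].str.replace("I", "L")
    return out


def unique_per_sample(records: pd.DataFrame, il_equivalence: bool = False) -> dict:
    """Deduplicated sequence set and count per sample.

    Returns ``{"sets": {sample: set}, "counts": {sample: int},
    "min": int|None, "max": int|None}``.  An empty table yields empty
    results, not an error.  ``il_equivalence`` folds I into L before
    deduplication (off by default; identity is the exact string).
    """
    if records.empty:
        return {"sets": {}, "counts": {}, "min": None, "max": None}
    records = _normalize(records, il_equivalence=il_equivalence)
    if "sample_id" not in records.columns:
        raise ValidationError("peptide table needs a 'sample_id' column")
    sets = {
        sample: set(group["sequence"])
        for sample, group in records.groupby("sample_id", sort=True)
    }
    counts = {s: len(v) for s, v in sets.items()}
    return {
        "sets": sets,
        "counts": counts,
        "min": min(counts.values()),
        "max": max(counts.values()),
    }


def subtract_control(case: set, control: set) -> tuple[set, int]:
    """Remove control-cohort sequences from a case set by exact match.

    Returns the filtered set and the number of sequences removed.
    """
    case, control = set(case), set(control)
    removed = len(case & control)
    return case - control, removed


@dataclass
class MergeResult:
    union: set
    pairwise_intersections: dict = field(default_factory=dict)

    @property
    def union_size(self) -> int:
        return len(self.union)


def merge_samples(sets: list) -> MergeResult:
    """Union of sequence sets with all pairwise intersections.

    Inclusion-exclusion (|A u B| = |A| + |B| - |A n B|) is verified
    internally for every pair.
    """
    if not sets:
        raise ValidationError("merge_samples needs at least one set")
    sets = [set(s) for s in sets]
    union: set = set().union(*sets)
    pairwise = {}
    for (i, a), (j, b) in combinations(enumerate(sets), 2):
        inter = a & b
        assert len(a | b) == len(a) + len(b) - len(inter)  # inclusion-exclusion
        pairwise[(i, j)] = inter
    return MergeResult(union=union, pairwise_intersections=pairwise)


@dataclass
class SourceSummary:
    n_proteins: int
    n_organisms: int
    n_unannotated_peptides: int


def source_summary(records: pd.DataFrame) -> SourceSummary:
    """Unique source-protein and organism counts over the deduplicated peptides.

    Rows lacking a source annotation are reported separately (counted as
    unannotated peptides), never silently mixed into the counts.
    """
    records = _normalize(records)
    dedup = records.drop_duplicates(subset="sequence")
    for col in ("source_protein", "organism"):
        if col not in dedup.columns:
            dedup = dedup.assign(**{col: pd.NA})
    annotated = dedup.dropna(subset=["source_protein", "organism"], how="all")
    return SourceSummary(
        n_proteins=int(annotated["source_protein"].dropna().nunique()),
        n_organisms=int(annotated["organism"].dropna().nunique()),
        n_unannotated_peptides=int(len(dedup) - len(annotated)),
    )


def phylum_composition(records: pd.DataFrame) -> pd.DataFrame:
    """Per-phylum counts and fractions over the deduplicated peptide set.

    Rows without a phylum annotation land in an ``unassigned`` bucket and
    are logged.  Fractions are over all deduplicated peptides and sum to 1.
    """
    records = _normalize(records)
    dedup = records.drop_duplicates(subset="sequence").copy()
    if "phylum" not in dedup.columns:
        dedup["phylum"] = pd.NA
    missing = dedup["phylum"].isna() | (dedup["phylum"].astype(str).str.strip() == "")
    if missing.any():
        logger.info("%d peptide(s) lack a phylum annotation", int(missing.sum()))
    dedup.loc[missing, "phylum"] = UNASSIGNED
    counts = dedup.groupby("phylum", sort=True)["sequence"].count()
    out = counts.rename("count").to_frame()
    out["fraction"] = out["count"] / out["count"].sum()
    return out.reset_index()


@dataclass
class TaxaMatch:
    sample_id: str
    matched: bool
    matched_names: set


def _name_at_rank(organism: str, rank: str, lineage: dict | None = None) -> str | None:
    """Extract the rank-level name from a free-text organism name.

    Genus defaults to the first whitespace token, species to the first two;
    an explicit lineage mapping (organism -> {rank: name}) overrides both.
    """
    if lineage and organism in lineage and rank in lineage[organism]:
        return lineage[organism][rank]
    tokens = organism.strip().split()
    if not tokens:
        return None
    if rank == "genus":
        return tokens[0]
    if len(tokens) >= 2:
        return f"{tokens[0]} {tokens[1]}"
    return None


def match_taxa(
    peptide_organisms: dict,
    taxa: pd.DataFrame,
    rank: str = "genus",
    lineage: dict | None = None,
) -> tuple[dict, int]:
    """Cross-match per-sample peptide source organisms against 16S taxa.

    Parameters
    ----------
    peptide_organisms
        ``{sample_id: iterable of organism names}`` from the peptide lists.
    taxa
        Table with columns ``sample_id``, ``rank``, ``name`` (one detected
        taxon per row, e.g. from 16S rRNA sequencing).
    rank
        ``"species"`` or ``"genus"``.
    lineage
        Optional ``{organism: {rank: name}}`` override of the default
        name-token parsing.

    Returns
    -------
    (matches, tally)
        ``matches`` maps sample_id to a :class:`TaxaMatch`; ``tally`` is the
        number of samples with at least one exact (case-insensitive) match
        at the requested rank.
    """
    if rank not in ("species", "genus"):
        raise ValidationError(f"rank must be 'species' or 'genus', got {rank!r}")
    for col in ("sample_id", "rank", "name"):
        if col not in taxa.columns:
            raise ValidationError(f"taxa table missing column {col!r}")

    taxa_by_sample: dict = {}
    sel = taxa[taxa["rank"].str.lower() == rank]
    for sample, group in sel.groupby("sample_id"):
        taxa_by_sample[sample] = {n.strip().lower() for n in group["name"].astype(str)}

    matches = {}
    for sample, organisms in peptide_organisms.items():
        names = set()
        detected = taxa_by_sample.get(sample, set())
        for org in organisms:
            name = _name_at_rank(str(org), rank, lineage)
            if name and name.strip().lower() in detected:
                names.add(name)
        matches[sample] = TaxaMatch(sample_id=sample, matched=bool(names), matched_names=names)
    tally = sum(m.matched for m in matches.values())
    return matches, tally
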