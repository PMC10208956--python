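"""Readers and writers for every on-disk format the pipeline touches.

All tabular formats are TSV with a header row, UTF-8, ``.`` decimal
separator.  Reads validate the column contract and report malformed rows
with 1-based file line numbers; writes are deterministic (fixed float
formatting, stable row order) so that a rerun with identical inputs is
byte-identical.  FASTA goes through Biopython with sequences wrapped at 62
characters on output.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .errors import FormatError
from .matrix import PLATE_COLUMNS, ScoringMatrix
from .residues import AMINO_ACIDS
from .scan import ScoredPeptide, SequenceRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_plate",
    "write_plate",
    "read_matrix",
    "write_matrix",
    "read_wells",
    "write_wells",
    "read_peptides",
    "write_peptides",
    "read_taxa",
    "read_repertoire_table",
    "read_hits",
    "write_hits",
]

FASTA_WRAP = 62

WELLS_COLUMNS = ("condition", "replicate", "cpm")
PEPTIDE_COLUMNS = ("sequence", "sample_id")  # annotations optional
TAXA_COLUMNS = ("sample_id", "rank", "name")
HITS_COLUMNS = ("sequence", "raw_score", "percent_of_max", "database", "sources")

_OS_RE = re.compile(r"OS=(.+?)(?:\s+[A-Z]{2}=|$)")


# -- generic TSV helpers ----------------------------------------------------


def _read_tsv(path, required, numeric=()) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse as TSV: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    for col in numeric:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() & (df[col].str.strip() != "")
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise FormatError(
                f"{path}: non-numeric value {df.loc[bad.idxmax(), col]!r} "
                f"in column {col!r} at line {line}"
            )
        if values.isna().any():
            line = int(values.isna().idxmax()) + 2
            raise FormatError(f"{path}: empty value in column {col!r} at line {line}")
        df[col] = values
    return df


def _write_tsv(df: pd.DataFrame, path, float_format="%.10g") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=float_format, lineterminator="\n")


# -- FASTA ------------------------------------------------------------------


def read_fasta(path) -> list:
    """Parse a FASTA protein database into :class:`SequenceRecord` objects.

    The organism is taken from a UniProt-style ``OS=`` tag in the
    description when present.
    """
    path = Path(path)
    records = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            desc = rec.description
            m = _OS_RE.search(desc)
            records.append(
                SequenceRecord(
                    protein_id=rec.id,
                    sequence=str(rec.seq),
                    description=desc,
                    organism=m.group(1) if m else None,
                )
            )
    except Exception as exc:
        raise FormatError(f"{path}: unreadable FASTA: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records, path, width: int = FASTA_WRAP) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for rec in records:
            bio = _BioRecord(Seq(rec.sequence), id=rec.protein_id, description=rec.description)
            fh.write(f">{bio.id} {bio.description}".rstrip() + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# -- typed tables -----------------------------------------------------------


def read_plate(path) -> pd.DataFrame:
    df = _read_tsv(
        path,
        required=PLATE_COLUMNS,
        numeric=("position", "concentration_ug_ml", "response_pg_ml"),
    )
    df["position"] = df["position"].astype(int)
    return df


def write_plate(plate: pd.DataFrame, path) -> None:
    _write_tsv(plate, path)


def read_matrix(path) -> ScoringMatrix:
    df = _read_tsv(path, required=("position", *AMINO_ACIDS), numeric=tuple(AMINO_ACIDS))
    df["position"] = df["position"].astype(int)
    df = df.sort_values("position").set_index("position")
    return ScoringMatrix.from_frame(df)


def write_matrix(matrix: ScoringMatrix, path) -> None:
    # full float precision: round-trip lossless to < 1e-12
    _write_tsv(matrix.to_frame().reset_index(), path, float_format="%.17g")


def read_wells(path) -> pd.DataFrame:
    df = _read_tsv(path, required=WELLS_COLUMNS, numeric=("replicate", "cpm"))
    df["replicate"] = df["replicate"].astype(int)
    return df


def write_wells(wells: pd.DataFrame, path) -> None:
    _write_tsv(wells, path)


def read_peptides(path) -> pd.DataFrame:
    return _read_tsv(path, required=PEPTIDE_COLUMNS)


def write_peptides(peptides: pd.DataFrame, path) -> None:
    _write_tsv(peptides, path)


def read_taxa(path) -> pd.DataFrame:
    return _read_tsv(path, required=TAXA_COLUMNS)


def read_repertoire_table(path) -> pd.DataFrame:
    # column mapping is handled downstream by load_repertoire
    path = Path(path)
    try:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse as TSV: {exc}") from exc


def write_repertoire(table: pd.DataFrame, path) -> None:
    _write_tsv(table, path)


def read_hits(path) -> list:
    df = _read_tsv(path, required=HITS_COLUMNS, numeric=("raw_score", "percent_of_max"))
    hits = []
    for _, row in df.iterrows():
        sources = []
        for token in str(row["sources"]).split(";"):
            if token:
                pid, start = token.rsplit(":", 1)
                sources.append((pid, int(start)))
        hits.append(
            ScoredPeptide(
                sequence=row["sequence"],
                raw_score=float(row["raw_score"]),
                percent_of_max=float(row["percent_of_max"]),
                sources=sources,
                database=row["database"] or None,
            )
        )
    return hits


def write_hits(hits, path) -> None:
    df = pd.DataFrame(
        {
            "sequence": [h.sequence for h in hits],
            "raw_score": [h.raw_score for h in hits],
            "percent_of_max": [h.percent_of_max for h in hits],
            "database": [h.database or "" for h in hits],
            "sources": [
                ";".join(f"{pid}:{start}" for pid, start in h.sources) for h in hits
            ],
        }
    )
    _write_tsv(df, path, float_format="%.10g")
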