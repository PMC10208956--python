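"""Synthetic cohort tables (stand-ins for unavailable study supplements).

The published per-patient peptide lists, SI tables and 16S taxon lists are
not redistributable here, so this module constructs deterministic synthetic
tables that realize the same marginal statistics the study reports:

* a 19-sample HLA class II immunopeptidome cohort with 344 unique
  bacteria-annotated peptides after control subtraction, per-sample unique
  counts spanning 5..54 (patient ``1635WI`` contributing a merged 37), 255
  unique source proteins, 199 unique source organisms, and a control
  cohort sharing exactly 7 peptides;
* a recognition table of 226 candidate peptides (126 bacterial + 100 gut
  microbiota) of which exactly 63 (21 + 42) reach SI >= 2;
* a ten-patient 16S cross-match fixture with species-level matches in 5
  patients and genus-level matches in 7;
* the primary/recurrent tumour peptide pair (18 and 23 unique peptides, 4
  shared, union 37).

Every sequence, accession and organism name is synthetic; only the set
arithmetic is meant to be faithful.  The builders are pure functions of
nothing — no randomness — so tests and examples get identical tables.
"""

from __future__ import annotations

import pandas as pd

from .residues import AMINO_ACIDS

__all__ = [
    "peptide_sequence",
    "immunopeptidome_cohort",
    "si_wells_table",
    "taxa_crossmatch_fixture",
    "primary_recurrent_sets",
]

# per-sample unique peptide counts after control subtraction; 19 samples,
# min 5, max 54, sum 344, with the merged primary+recurrent patient at 37
_SAMPLE_COUNTS = {
    "1635WI": 37,
    "GBM02": 5,
    "GBM03": 54,
    **{f"GBM{i:02d}": 15 for i in range(4, 19)},
    "GBM19": 23,
}

_N_PROTEINS = 255
_N_ORGANISMS = 199
_N_CONTROL_SHARED = 7

_PHYLA = ("Proteobacteria", "Firmicutes", "Actinobacteria")


def peptide_sequence(index: int) -> str:
    """Deterministic unique decamer for a non-negative integer index."""
    digits = []
    value = index
    for _ in range(10):
        digits.append(AMINO_ACIDS[value % 20])
        value //= 20
    return "".join(reversed(digits))


def _organism(index: int) -> str:
    return f"Genus{index:03d} species{index:03d}"


def _phylum(org_index: int) -> str:
    # roughly the reported skew: Proteobacteria and Firmicutes dominate
    if org_index < 115:
        return _PHYLA[0]
    if org_index < 175:
        return _PHYLA[1]
    return _PHYLA[2]


def immunopeptidome_cohort() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort peptide table and control-cohort table.

    Returns ``(records, control)``: ``records`` has columns ``sequence,
    sample_id, source_protein, organism, phylum``; ``control`` has a
    ``sequence`` column (peptides eluted from non-tumour control brain
    tissue).  Exactly 7 control sequences also occur in the cohort.
    """
    rows = []
    k = 0  # global unique-peptide index
    for sample, count in _SAMPLE_COUNTS.items():
        for _ in range(count):
            protein_idx = k if k < _N_PROTEINS else (k - _N_PROTEINS) % _N_PROTEINS
            org_idx = (
                protein_idx
                if protein_idx < _N_ORGANISMS
                else (protein_idx - _N_ORGANISMS) % _N_ORGANISMS
            )
            rows.append(
                {
                    "sequence": peptide_sequence(k),
                    "sample_id": sample,
                    "source_protein": f"BPRO{protein_idx:04d}",
                    "organism": _organism(org_idx),
                    "phylum": _phylum(org_idx),
                }
            )
            k += 1

    # seven peptides shared with the control cohorts, spread over samples;
    # they disappear again under exact-match control subtraction
    shared_control = [peptide_sequence(10_000 + i) for i in range(_N_CONTROL_SHARED)]
    for i, seq in enumerate(shared_control):
        rows.append(
            {
                "sequence": seq,
                "sample_id": f"GBM{(i % 7) + 2:02d}",
                "source_protein": f"CPRO{i:04d}",
                "organism": f"Controlus species{i:03d}",
                "phylum": _PHYLA[0],
            }
        )

    control_only = [peptide_sequence(20_000 + i) for i in range(23)]
    control = pd.DataFrame({"sequence": shared_control + control_only})
    return pd.DataFrame(rows), control


def si_wells_table() -> pd.DataFrame:
    """Replicate proliferation wells for 226 candidate peptides.

    126 bacterial (HB) and 100 gut-microbiota (HGM) peptides plus a
    no-peptide control; replicate cpm values are constructed so that
    exactly 21 HB and 42 HGM peptides have a mean-based SI >= 2 (one of
    them exactly at the inclusive threshold).
    """
    rows = [("no_peptide", r + 1, 1000.0) for r in range(3)]

    def add(condition: str, si: float) -> None:
        base = si * 1000.0
        for r, delta in enumerate((-50.0, 0.0, 50.0), start=1):
            rows.append((condition, r, base + delta))

    for i in range(126):
        name = f"HB{i + 1:03d}"
        if i < 21:
            add(name, 2.0 + (i % 20) * 0.45)  # stimulatory, includes SI == 2.0
        else:
            add(name, 0.3 + (i % 17) * 0.1)  # max 1.9 < 2
    for i in range(100):
        name = f"HGM{i + 1:03d}"
        if i < 42:
            add(name, 2.1 + (i % 18) * 0.5)
        else:
            add(name, 0.4 + (i % 16) * 0.1)
    return pd.DataFrame(rows, columns=["condition", "replicate", "cpm"])


def taxa_crossmatch_fixture() -> tuple[dict, pd.DataFrame]:
    """Per-patient peptide source organisms and 16S taxon lists.

    Built so that exact species-level matches occur in 5 of 10 patients and
    genus-level matches in 7 of 10 (species resolution of 16S being the
    limiting factor for two patients).
    """
    organisms = {}
    taxa_rows = []
    for i in range(1, 11):
        patient = f"P{i:02d}"
        if i <= 5:  # species and genus both match
            organisms[patient] = ["Bacillus subtilis", "Staphylococcus aureus"]
            taxa_rows += [
                (patient, "species", "Bacillus subtilis"),
                (patient, "genus", "Bacillus"),
            ]
        elif i <= 7:  # genus matches, species does not
            organisms[patient] = ["Escherichia coli"]
            taxa_rows += [
                (patient, "species", "Escherichia fergusonii"),
                (patient, "genus", "Escherichia"),
            ]
        else:  # no match at either rank
            organisms[patient] = ["Prevotella copri"]
            taxa_rows += [
                (patient, "species", "Akkermansia muciniphila"),
                (patient, "genus", "Akkermansia"),
            ]
    taxa = pd.DataFrame(taxa_rows, columns=["sample_id", "rank", "name"])
    return organisms, taxa


def primary_recurrent_sets() -> tuple[set, set]:
    """Primary (18) and recurrent (23) tumour peptide sets sharing 4."""
    primary = {peptide_sequence(i) for i in range(18)}
    recurrent = {peptide_sequence(i) for i in range(4)} | {
        peptide_sequence(i) for i in range(18, 37)
    }
    return primary, recurrent
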