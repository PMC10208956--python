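"""End-to-end pipeline driver.

Runs the six analysis stages — scoring matrix, database scan, SI calls,
recognition-by-band report, peptide-set summaries and TCR overlap — from a
single configuration, writes each stage's output and a manifest with
checksums of every input and output, the configuration snapshot and the
package version.  Outputs are deterministic: a rerun with identical inputs
is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from . import io as eio
from .assays import WellSet, recognition_rate_by_band, stimulation_index
from .errors import EpitopeScanError, ValidationError
from .matrix import build_scoring_matrix
from .peptide_sets import (
    match_taxa,
    phylum_composition,
    source_summary,
    subtract_control,
    unique_per_sample,
)
from .repertoire import load_repertoire, overlap_stats, shared_frequency
from .scan import scan_database

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and parameters for a full pipeline run.

    All inputs are required; thresholds default to the field conventions
    (SI >= 2 stimulatory, selection band 80-100% of the maximum theoretical
    score).
    """

    plate: str
    db: str
    wells: str
    peptides: str
    control_peptides: str
    taxa: str
    repertoire_a: str
    repertoire_b: str
    out_dir: str
    concentration: float = 200.0
    policy: str = "single"
    floor: float = 1.0
    band: tuple = (80.0, 100.0)
    bins: tuple = (60.0, 70.0, 80.0, 90.0, 100.0)
    si_threshold: float = 2.0
    control_condition: str = "no_peptide"
    taxa_rank: str = "genus"
    limit: int | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for key in ("band", "bins"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name):
    """Decorator: re-raise stage failures with the stage name attached."""

    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except EpitopeScanError as exc:
                raise type(exc)(f"stage {name!r}: {exc}") from exc

        return inner

    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and return the result bundle.

    Returns a dict with keys ``matrix, hits, si, bands, sets, overlap,
    manifest``; each stage's table is also written under
    ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = {
        "plate": config.plate,
        "db": config.db,
        "wells": config.wells,
        "peptides": config.peptides,
        "control_peptides": config.control_peptides,
        "taxa": config.taxa,
        "repertoire_a": config.repertoire_a,
        "repertoire_b": config.repertoire_b,
    }
    for name, path in inputs.items():
        if not Path(path).exists():
            raise ValidationError(f"input {name!r} not found: {path}")

    outputs: dict = {}

    # 1. scoring matrix
    @_stage("matrix")
    def stage_matrix():
        plate = eio.read_plate(config.plate)
        m = build_scoring_matrix(
            plate,
            concentration=config.concentration,
            policy=config.policy,
            floor=config.floor,
        )
        eio.write_matrix(m, out / "matrix.tsv")
        logger.info("matrix built from %d plate rows", len(plate))
        return m

    matrix = stage_matrix()
    outputs["matrix"] = out / "matrix.tsv"

    # 2. database scan
    @_stage("scan")
    def stage_scan():
        db = eio.read_fasta(config.db)
        hits = scan_database(
            matrix, db, band=config.band, limit=config.limit, database=Path(config.db).stem
        )
        eio.write_hits(hits, out / "hits.tsv")
        logger.info("scan: %d hits in band %s", len(hits), config.band)
        return hits

    hits = stage_scan()
    outputs["hits"] = out / "hits.tsv"

    # 3. stimulation indices
    @_stage("si")
    def stage_si():
        wells = eio.read_wells(config.wells)
        groups = {
            cond: WellSet(cond, grp["cpm"].tolist())
            for cond, grp in wells.groupby("condition", sort=True)
        }
        if config.control_condition not in groups:
            raise ValidationError(
                f"no control condition {config.control_condition!r} in wells table"
            )
        control = groups.pop(config.control_condition)
        calls = [
            stimulation_index(ws, control, threshold=config.si_threshold)
            for _, ws in sorted(groups.items())
        ]
        import pandas as pd

        table = pd.DataFrame(
            {
                "condition": [c.condition for c in calls],
                "si": [c.si for c in calls],
                "stimulatory": [c.stimulatory for c in calls],
                "n": [c.n_replicates for c in calls],
            }
        )
        eio._write_tsv(table, out / "si.tsv")
        return calls

    calls = stage_si()
    outputs["si"] = out / "si.tsv"

    # 4. recognition by predicted-score band
    @_stage("bands")
    def stage_bands():
        scanned = {h.sequence for h in hits}
        tested = [c for c in calls if c.condition in scanned]
        bands = recognition_rate_by_band(hits, tested, bins=config.bins)
        import pandas as pd

        table = pd.DataFrame(
            {
                "band_lo": [b.lo for b in bands],
                "band_hi": [b.hi for b in bands],
                "n_tested": [b.n_tested for b in bands],
                "n_stimulatory": [b.n_stimulatory for b in bands],
                "fraction": [b.fraction for b in bands],
            }
        )
        eio._write_tsv(table, out / "bands.tsv")
        return bands

    bands = stage_bands()
    outputs["bands"] = out / "bands.tsv"

    # 5. peptide-set summaries
    @_stage("sets")
    def stage_sets():
        peptides = eio.read_peptides(config.peptides)
        control = eio.read_peptides(config.control_peptides)
        per_sample = unique_per_sample(peptides)
        union = set().union(*per_sample["sets"].values()) if per_sample["sets"] else set()
        filtered, removed = subtract_control(union, set(control["sequence"].str.upper()))
        summary = source_summary(peptides[peptides["sequence"].str.upper().isin(filtered)])
        comp = phylum_composition(peptides[peptides["sequence"].str.upper().isin(filtered)])
        taxa = eio.read_taxa(config.taxa)
        organisms = {
            s: set(g["organism"].dropna())
            for s, g in peptides.groupby("sample_id")
            if "organism" in peptides.columns
        }
        _, tally = match_taxa(organisms, taxa, rank=config.taxa_rank)
        result = {
            "per_sample_counts": {
                k: len(v - set(control["sequence"].str.upper()))
                for k, v in sorted(per_sample["sets"].items())
            },
            "unique_after_control_subtraction": len(filtered),
            "control_matched_removed": removed,
            "n_source_proteins": summary.n_proteins,
            "n_source_organisms": summary.n_organisms,
            "phylum_composition": {
                row["phylum"]: row["count"] for _, row in comp.iterrows()
            },
            "taxa_rank": config.taxa_rank,
            "taxa_matched_samples": tally,
        }
        with open(out / "sets_summary.json", "w") as fh:
            json.dump(result, fh, indent=2, sort_keys=True, default=int)
            fh.write("\n")
        return result

    sets_summary = stage_sets()
    outputs["sets"] = out / "sets_summary.json"

    # 6. TCR repertoire overlap
    @_stage("overlap")
    def stage_overlap():
        rep_a = load_repertoire(
            eio.read_repertoire_table(config.repertoire_a), sample="A"
        )
        rep_b = load_repertoire(
            eio.read_repertoire_table(config.repertoire_b), sample="B"
        )
        ov = overlap_stats(rep_a, rep_b)
        result = {
            "shared": ov.shared,
            "pct_of_a": ov.pct_of_a,
            "pct_of_b": ov.pct_of_b,
            "jaccard": ov.jaccard,
            "shared_frequency_in_a": shared_frequency(ov.shared_keys, rep_a),
            "shared_frequency_in_b": shared_frequency(ov.shared_keys, rep_b),
        }
        with open(out / "overlap.json", "w") as fh:
            json.dump(result, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return result

    overlap = stage_overlap()
    outputs["overlap"] = out / "overlap.json"

    manifest = {
        "version": __version__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "inputs": {k: {"path": str(v), "sha256": _sha256(v)} for k, v in inputs.items()},
        "outputs": {
            k: {"path": str(v), "sha256": _sha256(v)} for k, v in outputs.items()
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return {
        "matrix": matrix,
        "hits": hits,
        "si": calls,
        "bands": bands,
        "sets": sets_summary,
        "overlap": overlap,
        "manifest": manifest,
    }
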