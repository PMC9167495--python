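"""End-to-end orchestration of the domain-evolution analysis.

A :class:`RunConfig` (YAML with a versioned schema) names the inputs —
protein and CDS FASTA, a domain hit table, a family map — and the analysis
thresholds.  :func:`run_domain_evolution` validates the inputs, segments
every protein, classifies EGF subtypes, optionally checks sushi key
residues, estimates per-domain Ka/Ks over all species pairs, and writes
deterministic TSV outputs.  Every skipped record is logged with a reason;
identical inputs, config and seed give byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from . import architecture, kaks, logo as logo_mod
from .codons import strip_terminal_stop

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

DEFAULT_THRESHOLDS = {
    "phospho_score": 0.5,
    "window_bp": 20_000_000,
    "min_families": 15,
    "retained_fraction": 0.5,
}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    inputs: dict
    families: dict  # protein_id -> {family, species[, taxon_group]}
    thresholds: dict = field(default_factory=dict)
    method: str = "yn00"
    seed: int = 0
    flank: int = 10
    sushi: dict | None = None  # {reference_id, key_columns: [[pos, class], ...]}
    logo: dict | None = None  # {halfwidth, rendering, residue}

    def __post_init__(self):
        merged = dict(DEFAULT_THRESHOLDS)
        merged.update(self.thresholds)
        self.thresholds = merged
        for name, value in self.thresholds.items():
            if not value > 0:
                raise ConfigError(f"threshold {name} must be positive (got {value})")
        if self.method not in kaks.ESTIMATORS:
            raise ConfigError(f"unknown method {self.method!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        data = yaml.safe_load(path.read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: not a mapping")
        version = data.pop("schema_version", None)
        if version != SCHEMA_VERSION:
            raise ConfigError(f"{path}: schema_version {version!r} != {SCHEMA_VERSION}")
        config = cls(
            inputs=data.get("inputs", {}),
            families=data.get("families", {}),
            thresholds=data.get("thresholds", {}),
            method=data.get("method", "yn00"),
            seed=int(data.get("seed", 0)),
            flank=int(data.get("flank", 10)),
            sushi=data.get("sushi"),
            logo=data.get("logo"),
        )
        base = path.parent
        config.inputs = {
            key: str((base / value)) if not Path(value).is_absolute() else value
            for key, value in config.inputs.items()
        }
        for key, value in config.inputs.items():
            if not Path(value).exists():
                raise ConfigError(f"input {key}: {value} does not exist")
        return config


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    logger.info("wrote %s (%d rows)", path, len(df))


def run_domain_evolution(config: RunConfig, out_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Run segmentation, EGF classification, sushi check and Ka/Ks; write TSVs.

    Returns the result tables keyed by output name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    proteins = read_fasta(config.inputs["protein_fasta"])
    cds = read_fasta(config.inputs["cds_fasta"])
    annotations = architecture.load_domain_table(config.inputs["domain_table"])
    by_protein: dict[str, list] = {}
    for ann in annotations:
        by_protein.setdefault(ann.protein_id, []).append(ann)

    region_frames = []
    records = []
    region_sets: dict[str, architecture.RegionSet] = {}
    for pid in sorted(config.families):
        meta = config.families[pid]
        family = meta.get("family", "other")
        species = meta.get("species", pid)
        if pid not in proteins:
            logger.warning("skip %s: not in protein FASTA", pid)
            continue
        if pid not in cds:
            logger.warning("skip %s: not in CDS FASTA", pid)
            continue
        seq = proteins[pid]
        expected = 3 * len(seq)
        if len(strip_terminal_stop(cds[pid])) != expected:
            logger.warning(
                "skip %s: CDS length %d != 3 x %d residues",
                pid, len(strip_terminal_stop(cds[pid])), len(seq),
            )
            continue
        rs = architecture.segment_protein(
            by_protein.get(pid, []),
            protein_length=len(seq),
            family=family,
            sequence=seq,
            flank=config.flank,
        )
        rs.protein_id = pid
        region_sets[pid] = rs
        region_frames.append(rs.to_frame())
        records.append(
            {
                "species": species,
                "family": family,
                "protein": seq,
                "cds": cds[pid],
                "region_set": rs,
            }
        )
    regions_df = (
        pd.concat(region_frames, ignore_index=True)
        if region_frames
        else pd.DataFrame(columns=["protein_id", "region", "start", "end", "subtype"])
    )
    egf_df = regions_df[regions_df["region"].str.startswith("EGF_")].reset_index(drop=True)

    results = {"regions": regions_df, "egf_subtypes": egf_df}
    _write(regions_df, out / "regions.tsv")
    _write(egf_df, out / "egf_subtypes.tsv")

    if config.sushi:
        ref_id = config.sushi["reference_id"]
        key_columns = [(int(p), frozenset(str(c))) for p, c in config.sushi["key_columns"]]
        seqs = []
        for pid, rs in sorted(region_sets.items()):
            if rs.sushi is None:
                logger.warning("sushi check: %s has no sushi region; skipped", pid)
                continue
            start, end = rs.sushi
            seqs.append((pid, proteins[pid][start - 1 : end]))
        report = architecture.check_sushi_residues(
            seqs, ref_id, key_columns, tolerance=int(config.sushi.get("tolerance", 0))
        )
        results["sushi_report"] = report.to_frame()
        _write(results["sushi_report"], out / "sushi_report.tsv")

    long_df, summary_df = kaks.aggregate_domain_kaks(records, method=config.method)
    results["kaks_long"] = long_df
    results["kaks_summary"] = summary_df
    _write(long_df, out / "kaks_long.tsv")
    _write(summary_df, out / "kaks_summary.tsv")

    if config.logo and "phospho_table" in config.inputs:
        params = config.logo or {}
        sites = logo_mod.load_phospho_table(config.inputs["phospho_table"], proteins)
        selected = logo_mod.select_phospho_sites(
            sites,
            threshold=config.thresholds["phospho_score"],
            residue_filter=params.get("residue", "Y"),
        )
        windows = logo_mod.extract_windows(
            proteins, selected, halfwidth=int(params.get("halfwidth", 5))
        )
        if windows:
            matrix = logo_mod.logo_matrix(
                windows, rendering=params.get("rendering", "entropy")
            )
            logo_df = matrix.freqs.copy()
            logo_df["bits"] = matrix.info_bits
            logo_df = logo_df.reset_index()
            results["logo_matrix"] = logo_df
            _write(logo_df, out / "logo_matrix.tsv")
        else:
            logger.warning("logo: no reliable sites after filtering")
    return results


__all__ = ["ConfigError", "RunConfig", "read_fasta", "run_domain_evolution"]
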