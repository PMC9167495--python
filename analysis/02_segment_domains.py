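#!/usr/bin/env python
"""Segment every simulated protein into regions and classify EGF subtypes.

Reads the cohorts written by 01_simulate_inputs.py, derives the
CTLD / sushi / EGF / mucin / TM / cytotail partition of each protein, checks
sushi key-residue conservation within each cohort, and writes per-family
region and subtype tables plus a pooled EGF subtype census under results/.
"""

from pathlib import Path

import pandas as pd

from ctldcp.architecture import check_sushi_residues, load_domain_table, segment_protein
from ctldcp.pipeline import read_fasta
from ctldcp.simulate import DEFAULT_TEMPLATES

SIM = Path("results/simulated")
OUT = Path("results")

# key residues of the sushi fold in generator coordinates (Cys/Trp/Gly/Pro)
SUSHI_KEYS = [(12, "C"), (20, "W"), (30, "G"), (38, "P")]


def main() -> None:
    all_regions = []
    sushi_frames = []
    for family in DEFAULT_TEMPLATES:
        base = SIM / family
        proteins = read_fasta(base / "proteins.fasta")
        annotations = load_domain_table(base / "domains.tsv")
        by_protein: dict[str, list] = {}
        for ann in annotations:
            by_protein.setdefault(ann.protein_id, []).append(ann)
        region_sets = {}
        for pid, seq in proteins.items():
            rs = segment_protein(
                by_protein[pid], len(seq), family=family, sequence=seq
            )
            rs.protein_id = pid
            region_sets[pid] = rs
            frame = rs.to_frame()
            frame.insert(0, "family", family)
            all_regions.append(frame)
        sushi_seqs = [
            (pid, proteins[pid][rs.sushi[0] - 1 : rs.sushi[1]])
            for pid, rs in sorted(region_sets.items())
            if rs.sushi is not None
        ]
        report = check_sushi_residues(sushi_seqs, sushi_seqs[0][0], SUSHI_KEYS)
        frame = report.to_frame()
        frame.insert(0, "family", family)
        sushi_frames.append(frame)
    regions = pd.concat(all_regions, ignore_index=True)
    regions.to_csv(OUT / "regions.tsv", sep="\t", index=False)
    egf = regions[regions["region"].str.startswith("EGF_")]
    egf.to_csv(OUT / "egf_subtypes.tsv", sep="\t", index=False)
    census = egf.groupby(["family", "subtype"]).size().rename("count").reset_index()
    census.to_csv(OUT / "egf_subtype_census.tsv", sep="\t", index=False)
    sushi = pd.concat(sushi_frames, ignore_index=True)
    sushi.to_csv(OUT / "sushi_report.tsv", sep="\t", index=False)

    print("EGF subtype census:")
    print(census.to_string(index=False))
    lost = sushi[~sushi["conserved"]]
    print(f"\nsushi key residues: {len(lost)} of {len(sushi)} checks not conserved")


if __name__ == "__main__":
    main()
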