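#!/usr/bin/env python
"""Generate the synthetic study inputs for the downstream analysis scripts.

Writes, under results/simulated/: one four-species cohort per CTLDcp family
(protein + CDS FASTA, domain hit table, truth JSON), a NetPhos-style
phospho-site table for the CD93 cohort, and two synteny histories with known
gene-loss mechanisms.  Everything is seeded, so reruns are byte-identical.
"""

import json
from pathlib import Path

import pandas as pd

from ctldcp.simulate import (
    DEFAULT_TEMPLATES,
    simulate_cohort,
    simulate_phospho_table,
    simulate_synteny_history,
)

SEED = 20220604
OUT = Path("results/simulated")


def write_cohort(family: str, seed: int) -> None:
    out = OUT / family
    out.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(DEFAULT_TEMPLATES[family], n_species=4, seed=seed)
    with open(out / "proteins.fasta", "w") as fh:
        for m in cohort.members:
            fh.write(f">{m.species}\n{m.protein}\n")
    with open(out / "cds.fasta", "w") as fh:
        for m in cohort.members:
            fh.write(f">{m.species}\n{m.cds}\n")
    rows = [
        {"protein_id": m.species, "name": ann.name, "start": ann.start, "end": ann.end}
        for m in cohort.members
        for ann in cohort.annotations
    ]
    pd.DataFrame(rows).to_csv(out / "domains.tsv", sep="\t", index=False)
    truth = {
        "family": family,
        "seed": seed,
        "regions": [
            {"label": lab, "start": s, "end": e, "subtype": sub.value if sub else None}
            for lab, s, e, sub in cohort.ancestor.truth.regions
        ],
        "omegas": cohort.ancestor.truth.omegas,
        "kappa": cohort.ancestor.truth.kappa,
        "t": cohort.ancestor.truth.t,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    if family == "CD93":
        phospho = simulate_phospho_table(
            cohort.members, cohort.ancestor.truth, seed=seed + 1
        )
        phospho.to_csv(out / "phospho.tsv", sep="\t", index=False)
    print(f"{family}: {len(cohort.members)} species, "
          f"protein length {len(cohort.ancestor.protein)} aa")


def write_synteny(mechanism: str, seed: int) -> None:
    out = OUT / "synteny"
    out.mkdir(parents=True, exist_ok=True)
    ref, derived, truth = simulate_synteny_history(15, mechanism, seed=seed)
    for tag, genes in (("reference", ref), ("derived", derived)):
        pd.DataFrame(
            [
                {"chromosome": g.chromosome, "start": g.start, "end": g.end,
                 "gene_id": g.gene_id, "family": g.family}
                for g in genes
            ]
        ).to_csv(out / f"{mechanism}.{tag}.tsv", sep="\t", index=False)
    n_events = sum(1 for e in truth.events if e[0] in ("deletion", "relocation"))
    print(f"synteny/{mechanism}: {n_events} neighbor families affected")


def main() -> None:
    for i, family in enumerate(DEFAULT_TEMPLATES):
        write_cohort(family, SEED + i)
    write_synteny("chromosome_disruption", SEED + 10)
    write_synteny("locus_preserved_loss", SEED + 11)


if __name__ == "__main__":
    main()
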