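"""Synthetic-data generators: determinism, construction guarantees, and the
statistical behavior of the codon evolution process."""

import math

import numpy as np
import pytest

from ctldcp.architecture import segment_protein
from ctldcp.codons import CODON_TO_AA, STOP_CODONS, translate_cds
from ctldcp.kaks import codon_alignment_from_cds, ng86
from ctldcp.patterns import EgfSubtype
from ctldcp.simulate import (
    DEFAULT_TEMPLATES,
    ArchitectureTemplate,
    evolve_lineage,
    omega_regions_from_truth,
    simulate_architecture,
    simulate_codon_evolution,
    simulate_cohort,
    simulate_phospho_table,
    simulate_synteny_history,
)

from conftest import random_cds


class TestArchitectureGenerator:
    @pytest.mark.parametrize("family,n_egf", [
        ("CD93", 5), ("Clec14A", 1), ("CD248", 3), ("Thrombomodulin", 6),
    ])
    def test_family_egf_counts(self, family, n_egf):
        sim = simulate_architecture(DEFAULT_TEMPLATES[family], seed=1)
        egf_regions = [r for r in sim.truth.regions if r[0].startswith("EGF_")]
        assert len(egf_regions) == n_egf

    def test_cds_translates_to_protein(self):
        sim = simulate_architecture(DEFAULT_TEMPLATES["CD93"], seed=2)
        assert translate_cds(sim.cds) == sim.protein

    def test_seed_determinism(self):
        a = simulate_architecture(DEFAULT_TEMPLATES["CD248"], seed=5)
        b = simulate_architecture(DEFAULT_TEMPLATES["CD248"], seed=5)
        assert (a.protein, a.cds) == (b.protein, b.cds)
        assert a.truth.regions == b.truth.regions

    def test_segmentation_roundtrip_recovers_truth(self):
        """segment_protein recovers the generator's intervals and EGF plan."""
        for family, template in DEFAULT_TEMPLATES.items():
            sim = simulate_architecture(template, seed=9)
            rs = segment_protein(
                sim.annotations, len(sim.protein), family=family, sequence=sim.protein
            )
            truth = {
                lab: (s, e) for lab, s, e, _ in sim.truth.regions if lab != "signal"
            }
            got = {lab: (s, e) for lab, s, e, _ in rs.iter_regions()}
            assert got == truth
            planned = [sub for lab, _, _, sub in sim.truth.regions if sub is not None]
            assert [sub for _, sub in rs.egfs] == planned

    def test_mucin_stp_enrichment(self):
        sim = simulate_architecture(DEFAULT_TEMPLATES["CD248"], seed=3)
        start, end = sim.truth.find("mucin")
        mucin = sim.protein[start - 1 : end]
        stp = sum(mucin.count(c) for c in "STP")
        assert stp / len(mucin) >= 0.5

    def test_impossible_plan_raises(self):
        with pytest.raises(ValueError, match="core length"):
            ArchitectureTemplate("bad", (EgfSubtype.CBEGF,), egf_length=20)


class TestCodonEvolution:
    def test_zero_time_identity(self, rng):
        cds = random_cds(rng, 100)
        a, b = simulate_codon_evolution(cds, omega=1.0, kappa=2.0, t=0.0, rng=rng)
        assert a == cds and b == cds

    def test_omega_zero_only_synonymous_changes(self, rng):
        cds = random_cds(rng, 300)
        a, b = simulate_codon_evolution(cds, omega=0.0, kappa=1.0, t=1.0, rng=rng)
        for evolved in (a, b):
            assert translate_cds(evolved) == translate_cds(cds)

    def test_no_stop_codons_ever(self, rng):
        cds = random_cds(rng, 200)
        a, b = simulate_codon_evolution(cds, omega=3.0, kappa=2.0, t=2.0, rng=rng)
        for evolved in (a, b):
            assert all(
                evolved[i : i + 3] not in STOP_CODONS for i in range(0, len(evolved), 3)
            )

    def test_neutral_evolution_ratio_near_one(self, rng):
        """omega=1, kappa=1: mean NG86 ratio falls in [0.9, 1.1]."""
        ratios = []
        for _ in range(60):
            cds = random_cds(rng, 500)
            a, b = simulate_codon_evolution(cds, omega=1.0, kappa=1.0, t=0.3, rng=rng)
            r = ng86(codon_alignment_from_cds(a, b))
            if math.isfinite(r.ratio):
                ratios.append(r.ratio)
        assert 0.9 <= np.mean(ratios) <= 1.1

    def test_divergence_scales_with_t(self, rng):
        cds = random_cds(rng, 400)
        diffs = []
        for t in (0.1, 0.5, 1.5):
            a, b = simulate_codon_evolution(cds, omega=1.0, kappa=2.0, t=t, rng=rng)
            diffs.append(sum(x != y for x, y in zip(a, b)))
        assert diffs[0] < diffs[1] < diffs[2]

    def test_invalid_parameters_raise(self, rng):
        cds = random_cds(rng, 10)
        with pytest.raises(ValueError):
            simulate_codon_evolution(cds, omega=-1.0, rng=rng)
        with pytest.raises(ValueError):
            simulate_codon_evolution(cds, kappa=0.0, rng=rng)
        with pytest.raises(ValueError):
            simulate_codon_evolution(cds, t=-0.1, rng=rng)

    def test_per_region_omega_contrast(self, rng):
        """A high-omega interval accumulates more amino-acid change."""
        cds = random_cds(rng, 400)
        regions = [(1, 200, 0.0), (201, 400, 5.0)]
        evolved = evolve_lineage(cds, 0.5, kappa=2.0, regions=regions, rng=rng)
        p0, p1 = translate_cds(cds), translate_cds(evolved)
        left = sum(a != b for a, b in zip(p0[:200], p1[:200]))
        right = sum(a != b for a, b in zip(p0[200:], p1[200:]))
        assert left == 0 and right > 0


class TestCohort:
    def test_pairwise_divergence_near_t(self, rng):
        template = DEFAULT_TEMPLATES["Clec14A"]
        cohort = simulate_cohort(template, 3, seed=4)
        assert len(cohort.members) == 3
        for m in cohort.members:
            assert len(m.cds) == len(cohort.ancestor.cds)
            translate_cds(m.cds)  # no stops, valid frame

    def test_determinism(self):
        a = simulate_cohort(DEFAULT_TEMPLATES["CD93"], 3, seed=12)
        b = simulate_cohort(DEFAULT_TEMPLATES["CD93"], 3, seed=12)
        assert [m.cds for m in a.members] == [m.cds for m in b.members]

    def test_phospho_table_planted_site_scores_high(self, rng):
        cohort = simulate_cohort(DEFAULT_TEMPLATES["CD93"], 4, seed=6)
        table = simulate_phospho_table(cohort.members, cohort.ancestor.truth, seed=7)
        tail = cohort.ancestor.truth.find("cytotail")
        planted_rows = table[
            (table["position"] >= tail[0]) & (table["score"] > 0.5)
        ]
        # the planted consensus survives codon evolution in most lineages
        assert len(planted_rows) >= 2
        low = table[table["position"] < tail[0]]
        assert (low["score"] <= 0.5).all()


class TestSyntenyHistory:
    def test_mechanisms_recovered_by_construction(self):
        from ctldcp.synteny import build_block, classify_absence

        for seed in range(5):
            for mech in ("chromosome_disruption", "locus_preserved_loss"):
                ref, derived, truth = simulate_synteny_history(15, mech, seed=seed)
                assert not any(g.family == "TARGET" for g in derived)
                block = build_block(ref, "TARGET")
                assert classify_absence("TARGET", block, derived).absence_call == mech

    def test_intensity_counts(self):
        ref, derived, truth = simulate_synteny_history(
            15, "chromosome_disruption", intensity=0.8, seed=3
        )
        affected = [e for e in truth.events if e[0] in ("deletion", "relocation")]
        assert len(affected) >= 12  # ceil(0.8 * 15)

    def test_event_log_deterministic(self):
        _, _, t1 = simulate_synteny_history(15, "chromosome_disruption", seed=8)
        _, _, t2 = simulate_synteny_history(15, "chromosome_disruption", seed=8)
        assert t1.events == t2.events

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            simulate_synteny_history(15, "meteor_strike", seed=0)
        with pytest.raises(ValueError):
            simulate_synteny_history(15, "chromosome_disruption", intensity=0.0, seed=0)
        with pytest.raises(ValueError):
            simulate_synteny_history(5, "chromosome_disruption", seed=0)
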