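"""Synteny blocks, shared families, and absence-mechanism classification."""

import pytest

from ctldcp.synteny import (
    AnchorError,
    GeneRecord,
    build_block,
    classify_absence,
    shared_families,
)


def gene(family, chrom, start_mb, gene_id=None, species="sp"):
    start = int(start_mb * 1_000_000)
    return GeneRecord(
        gene_id=gene_id or f"{family}@{chrom}:{start}",
        family=family,
        chromosome=chrom,
        start=start,
        end=start + 10_000,
        species=species,
    )


def neighborhood(n=15, chrom="chr1", center_mb=30.0):
    genes = [gene("TARGET", chrom, center_mb)]
    for i in range(n):
        offset = (i // 2 + 1) * (1 if i % 2 == 0 else -1)
        genes.append(gene(f"fam{i:02d}", chrom, center_mb + offset))
    return genes


class TestBuildBlock:
    def test_window_includes_only_nearby_genes(self):
        genes = [
            gene("ANCHOR", "chr1", 30),
            gene("far_left", "chr1", 5),
            gene("near", "chr1", 25),
            gene("far_right", "chr1", 55),
        ]
        block = build_block(genes, "ANCHOR", window_bp=20_000_000)
        assert {g.family for g in block.members} == {"ANCHOR", "near"}

    def test_other_chromosomes_excluded(self):
        genes = [gene("ANCHOR", "chr1", 30), gene("elsewhere", "chr2", 30)]
        block = build_block(genes, "ANCHOR")
        assert {g.family for g in block.members} == {"ANCHOR"}

    def test_window_covering_whole_chromosome(self):
        genes = [gene("ANCHOR", "chr1", 30)] + [
            gene(f"f{i}", "chr1", i) for i in range(1, 50, 5)
        ]
        block = build_block(genes, "ANCHOR", window_bp=10**9)
        assert len(block.members) == len(genes)

    def test_duplicate_anchor_raises(self):
        genes = [gene("ANCHOR", "chr1", 10, "a1"), gene("ANCHOR", "chr1", 40, "a2")]
        with pytest.raises(AnchorError, match="ambiguous"):
            build_block(genes, "ANCHOR")

    def test_missing_anchor_raises(self):
        with pytest.raises(AnchorError, match="not found"):
            build_block([gene("other", "chr1", 10)], "ANCHOR")

    def test_members_sorted_and_input_order_invariant(self):
        genes = neighborhood()
        a = build_block(genes, "TARGET")
        b = build_block(list(reversed(genes)), "TARGET")
        assert [g.gene_id for g in a.members] == [g.gene_id for g in b.members]
        assert all(
            g1.start <= g2.start for g1, g2 in zip(a.members, a.members[1:])
        )


class TestSharedFamilies:
    def test_intersection_count_and_threshold(self):
        a_genes = [gene(f"f{i}", "chr1", 10 + i * 0.1) for i in range(20)]
        b_genes = [gene(f"f{i}", "chr5", 10 + i * 0.1) for i in range(15)] + [
            gene(f"g{i}", "chr5", 20 + i * 0.1) for i in range(5)
        ]
        a = build_block(a_genes + [gene("A", "chr1", 10)], "A")
        b = build_block(b_genes + [gene("B", "chr5", 10)], "B")
        report = shared_families(a, b)
        assert report.count == 15
        assert report.meets_threshold

    def test_disjoint_blocks(self):
        a = build_block([gene("A", "chr1", 10)], "A")
        b = build_block([gene("B", "chr2", 10)], "B")
        report = shared_families(a, b)
        assert report.count == 0 and not report.meets_threshold

    def test_symmetric(self):
        genes = neighborhood()
        a = build_block(genes, "TARGET")
        other = [gene(f"fam{i:02d}", "chr9", 10 + i) for i in range(8)]
        b = build_block(other + [gene("OTHER", "chr9", 14)], "OTHER")
        assert shared_families(a, b).count == shared_families(b, a).count


class TestClassifyAbsence:
    def test_intact_neighborhood_is_locus_preserved(self):
        ref = neighborhood()
        block = build_block(ref, "TARGET")
        query = [g for g in ref if g.family != "TARGET"]
        report = classify_absence("TARGET", block, query)
        assert report.absence_call == "locus_preserved_loss"
        assert report.retained == 15 and report.missing == 0

    def test_dispersed_neighborhood_is_disruption(self):
        ref = neighborhood()
        block = build_block(ref, "TARGET")
        query = []
        for i, g in enumerate(g for g in ref if g.family != "TARGET"):
            if i < 3:
                query.append(g)  # retained in place
            elif i < 10:
                query.append(gene(g.family, f"chr{2 + i % 3}", 5 + i))  # relocated
            # else: deleted
        report = classify_absence("TARGET", block, query)
        assert report.absence_call == "chromosome_disruption"
        assert (report.retained, report.relocated, report.missing) == (3, 7, 5)

    def test_threshold_boundary_retained_wins(self):
        # 8 of 15 retained (0.533 >= 0.5) -> locus preserved
        ref = neighborhood()
        block = build_block(ref, "TARGET")
        neighbors = [g for g in ref if g.family != "TARGET"]
        query = neighbors[:8] + [
            gene(g.family, "chr7", 5 + i) for i, g in enumerate(neighbors[8:])
        ]
        report = classify_absence("TARGET", block, query)
        assert report.retained == 8
        assert report.absence_call == "locus_preserved_loss"

    def test_target_still_present(self):
        ref = neighborhood()
        block = build_block(ref, "TARGET")
        report = classify_absence("TARGET", block, ref)
        assert report.absence_call == "present"

    def test_small_reference_block_indeterminate(self):
        genes = neighborhood(n=5)
        block = build_block(genes, "TARGET")
        report = classify_absence("TARGET", block, [])
        assert report.absence_call == "indeterminate"

    def test_row_order_invariance(self):
        ref = neighborhood()
        block = build_block(ref, "TARGET")
        query = [g for g in ref if g.family != "TARGET"]
        a = classify_absence("TARGET", block, query)
        b = classify_absence("TARGET", block, list(reversed(query)))
        assert (a.absence_call, a.retained, a.relocated, a.missing) == (
            b.absence_call, b.retained, b.relocated, b.missing,
        )
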