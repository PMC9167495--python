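"""Domain-table loading, region segmentation, sushi key-residue checks."""

import numpy as np
import pytest

from ctldcp.architecture import (
    AnnotationError,
    ArchitectureError,
    DomainAnnotation,
    check_sushi_residues,
    load_domain_table,
    segment_protein,
)
from ctldcp.patterns import EgfSubtype
from ctldcp.simulate import DEFAULT_TEMPLATES, simulate_architecture


def ann(name, start, end, pid="P1"):
    return DomainAnnotation(pid, name, start, end)


class TestLoadDomainTable:
    def test_basic_row(self, tmp_path):
        p = tmp_path / "domains.tsv"
        p.write_text("protein_id\tname\tstart\tend\nP1\tCLECT\t22\t150\n")
        anns = load_domain_table(p)
        assert anns == [DomainAnnotation("P1", "CLECT", 22, 150)]

    def test_cdsearch_column_dialect(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("Query\tShort name\tFrom\tTo\nP1\tEGF\t10\t40\n")
        anns = load_domain_table(p)
        assert anns[0].name == "EGF" and (anns[0].start, anns[0].end) == (10, 40)

    def test_overlap_raises_listing_offenders(self, tmp_path):
        p = tmp_path / "domains.tsv"
        p.write_text(
            "protein_id\tname\tstart\tend\n"
            "P1\tEGF\t210\t250\nP1\tEGF\t240\t280\n"
        )
        with pytest.raises(AnnotationError, match="overlap"):
            load_domain_table(p)

    def test_end_before_start_raises(self, tmp_path):
        p = tmp_path / "domains.tsv"
        p.write_text("protein_id\tname\tstart\tend\nP1\tEGF\t50\t40\n")
        with pytest.raises(AnnotationError):
            load_domain_table(p)

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        assert load_domain_table(p) == []


class TestSegmentProtein:
    def test_full_architecture_interval_arithmetic(self):
        rs = segment_protein(
            [ann("CLECT", 22, 150), ann("EGF", 210, 250), ann("EGF", 251, 290),
             ann("TM", 580, 602)],
            protein_length=650,
        )
        assert rs.sushi == (151, 209)
        assert rs.mucin == (291, 579)
        assert rs.cytotail == (603, 650)

    def test_no_egf_sushi_extends_to_tm(self):
        # mirrors a lamprey paralog that lost its EGF-like repeats
        rs = segment_protein(
            [ann("CLECT", 22, 150), ann("TM", 180, 202)], protein_length=230
        )
        assert rs.sushi == (151, 179)
        assert rs.mucin is None
        assert rs.cytotail == (203, 230)

    def test_adjacent_anchors_give_absent_region(self):
        rs = segment_protein(
            [ann("CLECT", 1, 100), ann("EGF", 101, 140)], protein_length=200
        )
        assert rs.sushi is None

    def test_inconsistent_order_raises(self):
        with pytest.raises(ArchitectureError):
            segment_protein(
                [ann("EGF", 10, 40), ann("CLECT", 50, 150)], protein_length=200
            )
        with pytest.raises(ArchitectureError):
            segment_protein(
                [ann("TM", 10, 30), ann("EGF", 50, 90)], protein_length=200
            )

    def test_annotation_order_invariance(self):
        anns = [ann("CLECT", 22, 150), ann("EGF", 210, 250), ann("TM", 580, 602)]
        forward = segment_protein(anns, 650)
        backward = segment_protein(list(reversed(anns)), 650)
        assert list(forward.iter_regions()) == list(backward.iter_regions())

    def test_thrombomodulin_sushi_label(self):
        rs = segment_protein(
            [ann("CLECT", 1, 100), ann("EGF", 160, 200)],
            protein_length=300,
            family="Thrombomodulin",
        )
        assert rs.sushi_label == "hydrophobic stretch"
        assert rs.sushi == (101, 159)

    def test_cl07616_becomes_tme5(self):
        rs = segment_protein(
            [ann("CLECT", 1, 100), ann("cl07616", 160, 200)],
            protein_length=300,
            sequence="A" * 300,
        )
        assert rs.egfs[0][1] is EgfSubtype.TME5EGF

    def test_regions_tile_protein_with_anchors(self):
        """Derived regions + anchors + the unlabeled N-terminal stretch tile
        the protein without overlap."""
        sim = simulate_architecture(DEFAULT_TEMPLATES["CD248"], seed=11)
        rs = segment_protein(
            sim.annotations, len(sim.protein), family="CD248", sequence=sim.protein
        )
        intervals = sorted(
            (start, end) for _, start, end, _ in rs.iter_regions()
        )
        signal_end = intervals[0][0] - 1
        covered = signal_end
        prev_end = signal_end
        for start, end in intervals:
            assert start == prev_end + 1  # no gaps, no overlap
            covered += end - start + 1
            prev_end = end
        assert covered == len(sim.protein)


class TestSushiCheck:
    KEYS = [(1, "C"), (3, "W"), (5, "G"), (7, "P"), (9, "C")]

    def test_identical_query_conserved(self):
        report = check_sushi_residues(
            [("ref", "CAWAGAPAC"), ("q", "CAWAGAPAC")], "ref", self.KEYS
        )
        assert report.calls == {"ref": "has_sushi", "q": "has_sushi"}

    def test_substituted_key_residue_lost(self):
        report = check_sushi_residues(
            [("ref", "CAWAGAPAC"), ("q", "CAAAGAPAC")], "ref", self.KEYS
        )
        checks = {c.column: c for c in report.checks["q"]}
        assert not checks[3].conserved and checks[3].observed == "A"
        assert report.calls["q"] == "lacks_sushi"

    def test_deletion_counts_as_not_conserved(self):
        report = check_sushi_residues(
            [("ref", "CAWAGAPAC"), ("q", "CAWAGAPA")], "ref", self.KEYS
        )
        checks = {c.column: c for c in report.checks["q"]}
        assert checks[9].observed == "-" and not checks[9].conserved
        assert report.calls["q"] == "lacks_sushi"

    def test_tolerance_allows_losses(self):
        report = check_sushi_residues(
            [("ref", "CAWAGAPAC"), ("q", "CAAAGAPAC")], "ref", self.KEYS, tolerance=1
        )
        assert report.calls["q"] == "has_sushi"

    def test_key_position_outside_reference_raises(self):
        with pytest.raises(ValueError, match="key column"):
            check_sushi_residues([("ref", "CAW")], "ref", [(10, "C")])

    def test_missing_reference_raises(self):
        with pytest.raises(ValueError, match="reference"):
            check_sushi_residues([("q", "CAW")], "ref", [(1, "C")])
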