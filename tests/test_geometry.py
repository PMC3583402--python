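"""Geometry container, coordinate conventions, file formats, fixtures."""

import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitotx import (GenomeGeometry, dumps_geometry, frog_promoter_intensities,
                    load_geometry, loads_geometry, make_toy_genome,
                    merge_overlay)
from mitotx._circular import arcs_overlap, forward_gap
from mitotx.fixtures import (frog_geometry, human_geometry, rat_geometry,
                             PROMOTER_TSS)
from mitotx.geometry import Gene, GeometryFormatError, Promoter


class TestCircularArithmetic:
    def test_forward_gap_wraps_origin(self):
        assert forward_gap(1900, 100, +1, 2000) == 200
        assert forward_gap(100, 1900, -1, 2000) == 200
        assert forward_gap(100, 1900, +1, 2000) == 1800

    @settings(max_examples=200, derandomize=True)
    @given(st.integers(0, 299), st.integers(1, 300), st.integers(0, 299),
           st.integers(1, 300))
    def test_arc_overlap_matches_pointwise(self, a0, la, b0, lb):
        L = 300
        expected = any(((p % L - b0) % L) < lb for p in range(a0, a0 + la))
        assert arcs_overlap((a0, la), (b0, lb), L) == expected


class TestTsvDialect:
    def test_round_trip_toy(self, toy_convergent):
        text = dumps_geometry(toy_convergent)
        assert loads_geometry(text) == toy_convergent

    @pytest.mark.parametrize("builder", [human_geometry, rat_geometry,
                                         frog_geometry])
    def test_round_trip_fixtures(self, builder):
        geom = builder()
        assert loads_geometry(dumps_geometry(geom)) == geom

    def test_simple_two_gene_file(self):
        text = ("#length=1000 circular=1\n"
                "gene\tA\t10\t200\theavy\t\n"
                "gene\tB\t300\t450\tlight\t\n")
        geom = loads_geometry(text)
        assert geom.length == 1000 and len(geom.genes) == 2
        # 1-based inclusive -> 0-based half-open
        assert geom.genes[0].start == 9 and geom.genes[0].end == 200

    def test_coordinate_out_of_range_names_line(self):
        text = "#length=100 circular=1\ngene\tA\t10\t200\theavy\t\n"
        with pytest.raises(GeometryFormatError, match="2"):
            loads_geometry(text)

    def test_missing_header_is_format_error(self):
        with pytest.raises(GeometryFormatError, match="length"):
            loads_geometry("gene\tA\t1\t5\theavy\t\n")


class TestNormalization:
    def test_normalize_is_idempotent(self):
        g = GenomeGeometry(1000, [Gene("A", 1100, 1250, "heavy")])
        first = [(x.start, x.end) for x in g.genes]
        g.normalize()
        assert [(x.start, x.end) for x in g.genes] == first == [(100, 250)]

    def test_origin_spanning_gene_preserved(self):
        g = GenomeGeometry(1000, [Gene("A", 900, 50, "heavy")])
        assert g.genes[0].length_on(1000) == 150
        assert loads_geometry(dumps_geometry(g)) == g

    def test_duplicate_promoter_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            GenomeGeometry(1000, promoters=[Promoter("a", 10, "heavy"),
                                            Promoter("b", 10, "heavy")])


class TestToyGenome:
    def test_deterministic(self):
        spec = dict(length=2000,
                    promoter_specs=[("PH", 100, "heavy"), ("PL", 1900, "light")],
                    gene_specs=[("A", 200, 700, "heavy"), ("B", 1000, 1500, "light")])
        assert make_toy_genome(**spec) == make_toy_genome(**spec)

    def test_empty_gene_list_is_usable(self):
        from mitotx import SimulationParams, run_trajectory
        g = make_toy_genome(2000, promoter_specs=[("P", 100, "heavy")])
        tc = run_trajectory(g, SimulationParams(
            promoter_intensities={"P": 0.01}, t_end=50.0), seed=0)
        assert tc.per_gene_transcripts == {}

    def test_overlapping_same_strand_footprints_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            make_toy_genome(2000, promoter_specs=[("A", 100, "heavy"),
                                                  ("B", 110, "heavy")])

    def test_adjacent_opposite_strand_promoters_allowed(self):
        g = make_toy_genome(2000, promoter_specs=[("A", 100, "heavy"),
                                                  ("B", 101, "light")])
        assert len(g.promoters) == 2


class TestBundledFixtures:
    def test_human_promoter_positions(self):
        g = human_geometry()
        # experimentally mapped TSSs (1-based): HSP1 561, HSP2 646, LSP 407
        assert g.promoter("HSP1").tss == 560
        assert g.promoter("HSP2").tss == 645
        assert g.promoter("LSP").tss == 406
        assert g.promoter("LSP").strand == "light"
        assert g.length == 16569

    def test_rat_promoter_positions(self):
        g = rat_geometry()
        assert g.promoter("HSP1").tss == 16297
        assert g.promoter("HSP2").tss == 65
        assert g.promoter("LSP").tss == 16192

    def test_frog_has_five_promoters(self):
        g = frog_geometry()
        assert {p.name for p in g.promoters} == set(PROMOTER_TSS["frog"])

    def test_human_mterf_inside_trna_leu(self):
        g = human_geometry()
        site = g.factor_site("mTERF")
        leu = g.gene("tRNA-Leu(UUR)")
        assert site.length_on(g.length) == 28
        assert leu.start <= site.start and site.end <= leu.end


class TestFrogIntensities:
    def test_ratios_scale_with_lsp1(self):
        m = frog_promoter_intensities(1.0)
        assert m["HSP2"] == pytest.approx(0.600)
        assert m["LSP1"] == 1.0
        assert frog_promoter_intensities(0.0) == {k: 0.0 for k in m}
        # 0.382 * 0.0034, by hand
        assert frog_promoter_intensities(0.0034)["LSP2B"] == pytest.approx(0.0012988)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            frog_promoter_intensities(-1.0)


class TestExternalFormats:
    def test_genbank_genes(self, tmp_path):
        # build a tiny GenBank record programmatically, then parse it back
        from Bio.Seq import Seq
        from Bio.SeqFeature import SeqFeature, SimpleLocation
        from Bio.SeqRecord import SeqRecord
        from Bio import SeqIO
        rec = SeqRecord(Seq("AT" * 500), id="TOY1", name="TOY1",
                        description="toy circular genome",
                        annotations={"molecule_type": "DNA",
                                     "topology": "circular"})
        rec.features = [
            SeqFeature(SimpleLocation(9, 200, strand=1), type="gene",
                       qualifiers={"gene": ["A"]}),
            SeqFeature(SimpleLocation(299, 450, strand=-1), type="gene",
                       qualifiers={"gene": ["B"]}),
        ]
        path = tmp_path / "toy.gb"
        SeqIO.write(rec, path, "genbank")
        geom = load_geometry(path, format="genbank")
        assert geom.length == 1000
        assert geom.gene("A").strand == "heavy"
        assert geom.gene("B").strand == "light"
        assert (geom.gene("A").start, geom.gene("A").end) == (9, 200)

    def test_gff3_genes(self, tmp_path):
        gff = ("##gff-version 3\n"
               "##sequence-region toy 1 1000\n"
               "toy\ttest\tgene\t10\t200\t.\t+\t.\tID=gene:A;Name=A\n"
               "toy\ttest\tgene\t300\t450\t.\t-\t.\tID=gene:B;Name=B\n")
        path = tmp_path / "toy.gff3"
        path.write_text(gff)
        geom = load_geometry(path, format="gff3")
        assert geom.length == 1000
        assert geom.gene("B").strand == "light"

    def test_overlay_merges_promoters_onto_genes(self):
        base = GenomeGeometry(1000, [Gene("A", 9, 200, "heavy")])
        overlay = loads_geometry("#length=1000 circular=1\n"
                                 "promoter\tP\t5\t5\theavy\t\n")
        merged = merge_overlay(base, overlay)
        assert len(merged.genes) == 1 and len(merged.promoters) == 1
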