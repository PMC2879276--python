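"""Format round-trips and markup semantics of the matrix dialects, the
newick tree reader, and GFF3 gene-model ingestion."""

import textwrap

import pytest

from retromove import data_io
from retromove.types import ParseError, SPECIES_12


class TestLocationCells:
    @pytest.mark.parametrize(
        "token, states, retro, degraded, secondary, footnote",
        [
            ("A", ("A",), False, False, (), False),
            ("***C***", ("C",), True, False, (), False),
            ("A^†^", ("A",), False, True, (), False),
            ("***C/B***", ("C", "B"), True, False, (), False),
            ("***A^†^***", ("A",), True, True, (), False),
            ("A (C)^‡^", ("A",), False, False, ("C",), True),
            ("X^†^", ("X",), False, True, (), False),
            ("-", (), False, False, (), False),
        ],
    )
    def test_markup_semantics(self, token, states, retro, degraded,
                              secondary, footnote):
        cell = data_io.parse_location_cell(token)
        assert cell.states == states
        assert cell.retro is retro
        assert cell.degraded is degraded
        assert cell.secondary == secondary
        assert cell.footnote is footnote

    @pytest.mark.parametrize("token", ["Q", "**A", "A*", "A;B", "1.5"])
    def test_unknown_markup_rejected(self, token):
        with pytest.raises(ParseError):
            data_io.parse_location_cell(token)

    def test_serialization_inverts_parsing(self):
        for token in ["A", "***C***", "A^†^", "***C/B***", "***A^†^***",
                      "A (C)^‡^", "-"]:
            assert data_io.format_location_cell(
                data_io.parse_location_cell(token)) == token


class TestLocationMatrix:
    def test_packaged_fixture_dimensions(self, table1):
        assert len(table1.genes) == 21
        assert table1.species == SPECIES_12

    def test_ambiguity_cell(self, table1):
        cell = table1.cell("CG16771", "Dyak")
        assert cell.state_set == {"C", "B"}
        assert cell.retro

    def test_single_gene_no_markup(self, tmp_path):
        p = tmp_path / "one.tsv"
        p.write_text("gene\tDmel\tDsim\nG1\tA\tA\n")
        m = data_io.read_location_matrix(p)
        assert m.genes == ("G1",)
        assert all(m.cell("G1", sp).states == ("A",) for sp in m.species)
        assert not any(m.cell("G1", sp).retro for sp in m.species)

    def test_duplicate_gene_rejected(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text("gene\tDmel\nG1\tA\nG1\tB\n")
        with pytest.raises(ParseError, match="duplicate"):
            data_io.read_location_matrix(p)

    def test_undeclared_species_rejected(self, tmp_path):
        p = tmp_path / "sp.tsv"
        p.write_text("gene\tDxyz\nG1\tA\n")
        with pytest.raises(ParseError, match="unknown species"):
            data_io.read_location_matrix(p, species=SPECIES_12)

    def test_round_trip_is_cell_identical(self, table1, tmp_path):
        out = tmp_path / "rt.tsv"
        data_io.write_location_matrix(table1, out)
        again = data_io.read_location_matrix(out)
        assert again.cells == table1.cells
        # and the serialized body matches the fixture's data lines exactly
        fixture_lines = [
            l for l in data_io._fixture("table1_locations.tsv")
            .read_text().splitlines() if l and not l.startswith("#")
        ]
        assert out.read_text().splitlines() == fixture_lines


class TestExpressionMatrix:
    def test_packaged_fixture_dimensions(self, table2):
        assert len(table2.genes) == 21
        assert len(table2.species) == 6
        n_missing = sum(
            1 for g in table2.genes for sp in table2.species
            if table2.values[g][sp] is None
        )
        assert n_missing == 14
        assert 21 * 6 == 126

    def test_significant_negative_cell(self, table2):
        assert table2.values["CG4918"]["Dsim"] == pytest.approx(-0.807)
        assert table2.significant["CG4918"]["Dsim"] is True
        assert table2.retro_copy["CG4918"]["Dsim"] is True

    def test_cell_tokens(self):
        assert data_io.parse_expression_cell("-0.807*") == (-0.807, True, False)
        assert data_io.parse_expression_cell("**-0.822***") == (-0.822, True, True)
        assert data_io.parse_expression_cell("**0.062**") == (0.062, False, True)
        assert data_io.parse_expression_cell("-") == (None, False, False)
        with pytest.raises(ParseError):
            data_io.parse_expression_cell("abc")

    def test_empty_body_gives_zero_genes(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("gene\tDsim\tDyak\n")
        m = data_io.read_expression_matrix(p)
        assert m.genes == ()

    def test_round_trip_is_cell_identical(self, table2, tmp_path):
        out = tmp_path / "rt.tsv"
        data_io.write_expression_matrix(table2, out)
        again = data_io.read_expression_matrix(out)
        assert again.values == table2.values
        assert again.significant == table2.significant
        assert again.retro_copy == table2.retro_copy
        fixture_lines = [
            l for l in data_io._fixture("table2_expression.tsv")
            .read_text().splitlines() if l and not l.startswith("#")
        ]
        assert out.read_text().splitlines() == fixture_lines


class TestSpeciesTree:
    def test_packaged_tree_has_12_leaves(self, tree, table1, table2):
        leaves = set(data_io.tree_leaf_labels(tree))
        assert len(leaves) == 12
        # every species in any fixture is a leaf
        assert set(table1.species) <= leaves
        assert set(table2.species) <= leaves

    def test_two_leaf_tree(self):
        t = data_io.read_species_tree(data="(A,B);")
        assert len(data_io.tree_leaf_labels(t)) == 2

    def test_duplicate_leaf_rejected(self):
        with pytest.raises(ParseError, match="duplicate"):
            data_io.read_species_tree(data="(A,(B,A));")

    def test_unrooted_rejected(self):
        with pytest.raises(ParseError, match="rooted"):
            data_io.read_species_tree(data="[&U] (A,(B,C));")


GFF_THREE_EXON = textwrap.dedent("""\
    ##gff-version 3
    s1\tsrc\tgene\t100\t1000\t.\t+\t.\tID=g1
    s1\tsrc\tmRNA\t100\t1000\t.\t+\t.\tID=g1.t1;Parent=g1
    s1\tsrc\texon\t100\t300\t.\t+\t.\tID=e1;Parent=g1.t1
    s1\tsrc\texon\t400\t600\t.\t+\t.\tID=e2;Parent=g1.t1
    s1\tsrc\texon\t700\t1000\t.\t+\t.\tID=e3;Parent=g1.t1
    s1\tsrc\tCDS\t100\t300\t.\t+\t0\tID=c1;Parent=g1.t1
    s1\tsrc\tCDS\t400\t600\t.\t+\t0\tID=c2;Parent=g1.t1
    s1\tsrc\tCDS\t700\t1000\t.\t+\t0\tID=c3;Parent=g1.t1
    """)

GFF_UTR_INTRONS = textwrap.dedent("""\
    ##gff-version 3
    s1\tsrc\tgene\t100\t1000\t.\t+\t.\tID=g2
    s1\tsrc\tmRNA\t100\t1000\t.\t+\t.\tID=g2.t1;Parent=g2
    s1\tsrc\texon\t100\t150\t.\t+\t.\tID=e1;Parent=g2.t1
    s1\tsrc\texon\t200\t600\t.\t+\t.\tID=e2;Parent=g2.t1
    s1\tsrc\texon\t700\t1000\t.\t+\t.\tID=e3;Parent=g2.t1
    s1\tsrc\tCDS\t300\t500\t.\t+\t0\tID=c1;Parent=g2.t1
    """)


class TestGeneModels:
    def test_three_exon_gene_has_two_cds_introns(self, tmp_path):
        gff = tmp_path / "a.gff3"
        gff.write_text(GFF_THREE_EXON)
        orth = tmp_path / "o.tsv"
        orth.write_text("family\tspecies\tgene\nF1\tDmel\tg1\n")
        cohort = data_io.read_gene_models({"Dmel": gff}, orth)
        model = cohort.families[0].members["Dmel"][0]
        assert model.cds_introns == 2
        assert model.utr_introns == 0

    def test_utr_only_introns_counted_separately(self, tmp_path):
        # both introns lie outside the CDS span: a retroposed ORF whose UTR
        # exons are spliced
        gff = tmp_path / "b.gff3"
        gff.write_text(GFF_UTR_INTRONS)
        orth = tmp_path / "o.tsv"
        orth.write_text("family\tspecies\tgene\nF1\tDmel\tg2\n")
        cohort = data_io.read_gene_models({"Dmel": gff}, orth)
        model = cohort.families[0].members["Dmel"][0]
        assert model.cds_introns == 0
        assert model.utr_introns == 2

    def test_min_cds_intron_isoform_chosen(self, tmp_path):
        two_isoforms = GFF_THREE_EXON + textwrap.dedent("""\
            s1\tsrc\tmRNA\t100\t1000\t.\t+\t.\tID=g1.t2;Parent=g1
            s1\tsrc\texon\t100\t1000\t.\t+\t.\tID=e4;Parent=g1.t2
            s1\tsrc\tCDS\t100\t1000\t.\t+\t0\tID=c4;Parent=g1.t2
            """)
        gff = tmp_path / "c.gff3"
        gff.write_text(two_isoforms)
        orth = tmp_path / "o.tsv"
        orth.write_text("family\tspecies\tgene\nF1\tDmel\tg1\n")
        cohort = data_io.read_gene_models({"Dmel": gff}, orth)
        assert cohort.families[0].members["Dmel"][0].cds_introns == 0

    def test_absent_gene_in_ortholog_map_rejected(self, tmp_path):
        gff = tmp_path / "d.gff3"
        gff.write_text(GFF_THREE_EXON)
        orth = tmp_path / "o.tsv"
        orth.write_text("family\tspecies\tgene\nF1\tDmel\tnope\n")
        with pytest.raises(ParseError, match="absent gene"):
            data_io.read_gene_models({"Dmel": gff}, orth)
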