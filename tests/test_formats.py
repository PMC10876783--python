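"""I/O round trips and the fixed coordinate conventions."""

import textwrap

import networkx as nx
import pytest
from Bio import Phylo

from pollen_lncrna.formats import (
    BlastHit,
    FormatError,
    GenomicInterval,
    TranscriptModel,
    read_blast6,
    read_fasta,
    read_gtf,
    read_obo,
    write_fasta,
    write_gtf,
    write_newick,
)
from pollen_lncrna.phylo import Node


def write(path, text):
    path.write_text(textwrap.dedent(text))
    return path


class TestGtf:
    def test_coordinates_become_zero_based_half_open(self, tmp_path):
        gtf = write(tmp_path / "a.gtf", """\
        1A\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
        """)
        (tx,) = read_gtf(gtf)
        assert (tx.interval.start, tx.interval.end) == (100, 200)

    def test_spliced_length_sums_exons(self, tmp_path):
        gtf = write(tmp_path / "a.gtf", """\
        1A\ts\texon\t101\t200\t.\t+\t.\tgene_id "g"; transcript_id "t";
        1A\ts\texon\t301\t450\t.\t+\t.\tgene_id "g"; transcript_id "t";
        """)
        (tx,) = read_gtf(gtf)
        assert tx.spliced_length == 250

    def test_class_code_attribute_and_default(self, tmp_path):
        gtf = write(tmp_path / "a.gtf", """\
        1A\ts\texon\t1\t50\t.\t+\t.\tgene_id "g1"; transcript_id "t1"; class_code "u";
        1A\ts\texon\t100\t150\t.\t+\t.\tgene_id "g2"; transcript_id "t2";
        """)
        by_id = {t.transcript_id: t for t in read_gtf(gtf)}
        assert by_id["t1"].class_code == "u"
        assert by_id["t2"].class_code == "="

    def test_round_trip_preserves_one_based_coordinates(self, tmp_path):
        tx = TranscriptModel(
            "t1", "g1", GenomicInterval("2B", 99, 520, "-"),
            exons=[GenomicInterval("2B", 99, 200, "-"),
                   GenomicInterval("2B", 400, 520, "-")],
            class_code="x",
        )
        path = tmp_path / "out.gtf"
        write_gtf([tx], path)
        assert '\t100\t200\t' in path.read_text()
        (back,) = read_gtf(path)
        assert back.exons == tx.exons
        assert back.class_code == "x"

    def test_malformed_line_names_line_number(self, tmp_path):
        gtf = write(tmp_path / "bad.gtf", """\
        1A\ts\texon\t1\t50\t.\t+\t.\tgene_id "g"; transcript_id "t";
        not-a-gtf-line
        """)
        with pytest.raises(FormatError, match="line 2"):
            read_gtf(gtf)


class TestFasta:
    def test_read_normalizes_u_and_case(self, tmp_path):
        fa = write(tmp_path / "a.fa", ">a\nacGU\n")
        assert read_fasta(fa) == {"a": "ACGT"}

    def test_round_trip_preserves_order_and_sequence(self, tmp_path):
        seqs = {"x": "ACGT" * 30, "a": "TTTTT", "m": "ACACAC"}
        path = tmp_path / "rt.fa"
        write_fasta(seqs, path)
        assert read_fasta(path) == seqs
        assert list(read_fasta(path)) == ["x", "a", "m"]

    def test_duplicate_id_rejected(self, tmp_path):
        fa = write(tmp_path / "d.fa", ">a\nACGT\n>a\nTTTT\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_fasta(fa)


class TestBlast6:
    def test_fields_mapped(self, tmp_path):
        path = write(tmp_path / "h.tsv",
                     "q1\ts1\t65.0\t120\t30\t2\t1\t120\t5\t124\t1e-6\t88.3\n")
        (hit,) = read_blast6(path)
        assert hit.percent_identity == 65.0
        assert hit.alignment_length == 120
        assert hit.evalue == 1e-6

    def test_empty_file_gives_empty_list(self, tmp_path):
        assert read_blast6(write(tmp_path / "e.tsv", "")) == []

    def test_wrong_column_count_rejected(self, tmp_path):
        path = write(tmp_path / "w.tsv", "q1\ts1\t65.0\n")
        with pytest.raises(FormatError, match="12 columns"):
            read_blast6(path)

    def test_invariants(self):
        with pytest.raises(ValueError):
            BlastHit("q", "s", 120.0, 10, 1e-3)
        with pytest.raises(ValueError):
            BlastHit("q", "s", 50.0, 10, -1.0)


class TestObo:
    def test_is_a_edges_point_to_parent(self, tmp_path):
        obo = write(tmp_path / "a.obo", """\
        format-version: 1.2
        ontology: test

        [Term]
        id: T:1
        name: root
        namespace: bp

        [Term]
        id: T:2
        name: child
        namespace: bp
        is_a: T:1
        """)
        dag = read_obo(obo)
        assert set(dag.successors("T:2")) == {"T:1"}
        assert dag.nodes["T:2"]["name"] == "child"

    def test_cycle_rejected(self, tmp_path):
        obo = write(tmp_path / "c.obo", """\
        format-version: 1.2
        ontology: test

        [Term]
        id: T:1
        name: a
        is_a: T:2

        [Term]
        id: T:2
        name: b
        is_a: T:1
        """)
        with pytest.raises(FormatError, match="cycle"):
            read_obo(obo)


class TestNewick:
    def test_three_leaf_star(self, tmp_path):
        tree = Node(children=[
            (Node(name="A"), 1.0), (Node(name="B"), 2.0), (Node(name="C"), 3.0),
        ])
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        assert path.read_text().strip() == "(A:1,B:2,C:3);"
        parsed = Phylo.read(str(path), "newick")
        assert sorted(l.name for l in parsed.get_terminals()) == ["A", "B", "C"]


class TestGenomicInterval:
    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("1A", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("1A", 5, 10, "?")

    @pytest.mark.parametrize(
        "other, expected",
        [((300, 400), 100), ((0, 50), -50), ((50, 150), 0)],
    )
    def test_signed_distance(self, other, expected):
        a = GenomicInterval("1A", 100, 200)
        assert a.distance_to(GenomicInterval("1A", *other)) == expected
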