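import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agioskit.agios import AgiosMatrix
from agioskit.orthology import HomologyHit
from agioskit.seqio import (
    Assembly,
    Gene,
    GeneCoords,
    GeneSet,
    SeqIOError,
    SequenceRecord,
    load_geneset,
    read_fasta,
    read_gene_coords,
    read_hits_tsv,
    read_matrix_tsv,
    write_fasta,
    write_hits_tsv,
    write_matrix_tsv,
)


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadFasta:
    def test_case_folding(self, tmp_path):
        p = write(tmp_path, "a.fna", ">g1\nacgt\n")
        recs = read_fasta(p, "nucleotide")
        assert [(r.id, r.residues) for r in recs] == [("g1", "ACGT")]

    def test_duplicate_id_error_names_id(self, tmp_path):
        p = write(tmp_path, "a.fna", ">a\nAC\n>a\nGG\n")
        with pytest.raises(SeqIOError, match="'a'"):
            read_fasta(p, "nucleotide")

    def test_empty_file_error(self, tmp_path):
        p = write(tmp_path, "a.fna", "")
        with pytest.raises(SeqIOError):
            read_fasta(p, "nucleotide")

    def test_bad_residue_reports_position(self, tmp_path):
        p = write(tmp_path, "a.fna", ">g1\nACQT\n")
        with pytest.raises(SeqIOError, match="position 3"):
            read_fasta(p, "nucleotide")

    def test_header_splits_id_and_description(self, tmp_path):
        p = write(tmp_path, "a.fna", ">g1 some description here\nACGT\n")
        (rec,) = read_fasta(p, "nucleotide")
        assert rec.id == "g1"
        assert rec.description == "some description here"

    def test_multiline_records(self, tmp_path):
        p = write(tmp_path, "a.fna", ">g1\nACGT\nACGT\n>g2\nTT\n")
        recs = read_fasta(p, "nucleotide")
        assert recs[0].residues == "ACGTACGT"
        assert recs[1].id == "g2"


_nt_seq = st.text(alphabet="ACGT", min_size=1, max_size=120)


class TestRoundTrip:
    @given(
        seqs=st.lists(_nt_seq, min_size=1, max_size=5),
        width=st.integers(min_value=1, max_value=90),
    )
    @settings(max_examples=40, deadline=None)
    def test_fasta_roundtrip_identity(self, tmp_path_factory, seqs, width):
        tmp = tmp_path_factory.mktemp("rt")
        recs = [
            SequenceRecord(id=f"r{i}", residues=s, alphabet="nucleotide",
                           description="d" if i % 2 else "")
            for i, s in enumerate(seqs)
        ]
        path = tmp / "out.fna"
        write_fasta(recs, path, width=width)
        back = read_fasta(path, "nucleotide")
        assert [(r.id, r.description, r.residues) for r in back] == \
            [(r.id, r.description, r.residues) for r in recs]

    def test_three_record_roundtrip(self, tmp_path):
        recs = [
            SequenceRecord(id=f"g{i}", residues="ACGT" * (i + 1),
                           alphabet="nucleotide")
            for i in range(3)
        ]
        path = tmp_path / "x.fna"
        write_fasta(recs, path)
        assert [(r.id, r.residues) for r in read_fasta(path, "nucleotide")] \
            == [(r.id, r.residues) for r in recs]


class TestLoadGeneset:
    def _files(self, tmp_path, fna_ids, faa_ids):
        fna = write(tmp_path, "g.fna",
                    "".join(f">{i}\nATGGCT\n" for i in fna_ids))
        faa = write(tmp_path, "g.faa",
                    "".join(f">{i}\nMA\n" for i in faa_ids))
        return fna, faa

    def test_full_overlap(self, tmp_path):
        fna, faa = self._files(tmp_path, ["g1", "g2"], ["g1", "g2"])
        gs = load_geneset(fna, faa, "G")
        assert len(gs) == 2
        assert gs.gene_ids == ["g1", "g2"]

    def test_partial_overlap_drops_and_logs(self, tmp_path, caplog):
        fna, faa = self._files(tmp_path, ["g1", "g2"], ["g2", "g3"])
        with caplog.at_level("WARNING"):
            gs = load_geneset(fna, faa, "G")
        assert gs.gene_ids == ["g2"]
        assert "dropped 2" in caplog.text

    def test_zero_overlap_error(self, tmp_path):
        fna, faa = self._files(tmp_path, ["g1"], ["x1"])
        with pytest.raises(SeqIOError, match="no gene IDs shared"):
            load_geneset(fna, faa, "G")

    def test_size_is_intersection(self, tmp_path):
        fna, faa = self._files(tmp_path, ["a", "b", "c"], ["b", "c", "d", "e"])
        gs = load_geneset(fna, faa, "G")
        assert len(gs) == len({"a", "b", "c"} & {"b", "c", "d", "e"})


class TestGeneSetInvariants:
    def _gene(self, gid, cds="ATGGCT", prot="MA"):
        return Gene(
            gene_id=gid,
            cds=SequenceRecord(id=gid, residues=cds, alphabet="nucleotide"),
            protein=SequenceRecord(id=gid, residues=prot, alphabet="protein"),
        )

    def test_duplicate_gene_ids_rejected(self):
        with pytest.raises(SeqIOError, match="duplicate gene ID"):
            GeneSet(genome_id="G", genes=[self._gene("g1"), self._gene("g1")])

    def test_short_cds_rejected(self):
        with pytest.raises(SeqIOError, match="shorter than one codon"):
            GeneSet(genome_id="G", genes=[self._gene("g1", cds="AT")])

    def test_translation_mismatch_warns_but_keeps(self, caplog):
        with caplog.at_level("WARNING"):
            gs = GeneSet(genome_id="G",
                         genes=[self._gene("g1", cds="ATGGCT", prot="MM")])
        assert len(gs) == 1
        assert "does not match CDS translation" in caplog.text

    def test_assembly_requires_contigs(self):
        with pytest.raises(SeqIOError):
            Assembly(genome_id="G", contigs=[])


class TestGeneCoords:
    def test_read_tsv(self, tmp_path):
        p = write(tmp_path, "g.tsv", "g1\tc1\t1\t30\t+\ng2\tc1\t40\t60\t-\n")
        coords = read_gene_coords(p)
        assert coords["g1"] == GeneCoords("c1", 1, 30, "+")
        assert coords["g2"].strand == "-"

    def test_bad_strand(self):
        with pytest.raises(SeqIOError):
            GeneCoords("c1", 1, 10, "?")

    def test_start_after_end(self):
        with pytest.raises(SeqIOError):
            GeneCoords("c1", 10, 1, "+")


def _paper_shape_matrix():
    # Table-style 5-genome layout: diagonal gene counts with upper-triangle
    # ortholog counts and lower-triangle mean identities
    ids = ["Et", "Em", "Ca", "Cg", "Ct"]
    m = AgiosMatrix(genome_ids=ids,
                    gene_counts=[2006, 1901, 2159, 1768, 2195])
    orth = {
        (0, 1): 1109, (0, 2): 1026, (0, 3): 880, (0, 4): 1077,
        (1, 2): 1046, (1, 3): 899, (1, 4): 1103,
        (2, 3): 880, (2, 4): 1062, (3, 4): 913,
    }
    agios = {
        (0, 1): 79.44, (0, 2): 66.37, (0, 3): 73.39, (0, 4): 74.02,
        (1, 2): 66.01, (1, 3): 72.38, (1, 4): 73.43,
        (2, 3): 66.15, (2, 4): 64.96, (3, 4): 71.27,
    }
    for (i, j), v in orth.items():
        m.set_ortholog_count(i, j, v)
    for (i, j), v in agios.items():
        m.set_agios(i, j, v)
    return m


class TestMatrixTsv:
    def test_five_genome_layout(self, tmp_path):
        m = _paper_shape_matrix()
        path = tmp_path / "m.tsv"
        write_matrix_tsv(m, path)
        lines = path.read_text().splitlines()
        assert len(lines) == 6
        rows = [ln.split("\t") for ln in lines]
        diag = [rows[i + 1][i + 1] for i in range(5)]
        assert diag == ["2006", "1901", "2159", "1768", "2195"]
        assert rows[1][2] == "1109"  # upper triangle: ortholog count
        assert rows[2][1] == "79.44"  # lower triangle: 2-decimal identity

    def test_single_genome_matrix(self, tmp_path):
        m = AgiosMatrix(genome_ids=["G"], gene_counts=[10])
        path = tmp_path / "m.tsv"
        write_matrix_tsv(m, path)
        rows = [ln.split("\t") for ln in path.read_text().splitlines()]
        assert rows[1] == ["G", "10"]

    def test_roundtrip_reproduces_values(self, tmp_path):
        m = _paper_shape_matrix()
        path = tmp_path / "m.tsv"
        write_matrix_tsv(m, path)
        back = read_matrix_tsv(path)
        assert back.genome_ids == m.genome_ids
        assert back.gene_counts == m.gene_counts
        for i in range(5):
            for j in range(i + 1, 5):
                assert back.ortholog_count_at(i, j) == \
                    m.ortholog_count_at(i, j)
                assert back.agios_at(i, j) == pytest.approx(
                    m.agios_at(i, j), abs=0.005
                )

    def test_na_cells_roundtrip(self, tmp_path):
        m = AgiosMatrix(genome_ids=["A", "B"], gene_counts=[3, 4])
        m.set_ortholog_count(0, 1, 0)
        m.set_agios(0, 1, None)
        path = tmp_path / "m.tsv"
        write_matrix_tsv(m, path)
        assert "NA" in path.read_text()
        back = read_matrix_tsv(path)
        assert back.agios_at(0, 1) is None


class TestHitsTsv:
    def _hit(self, q="q1", s="s1"):
        return HomologyHit(
            query_id=q, subject_id=s, raw_score=120.0, bit_score=50.9,
            e_value=3.2e-09, alignment_length=95, identity_pct=48.42,
            query_coverage=0.95, subject_coverage=0.9, mismatches=49,
            gap_opens=1, qstart=2, qend=96, sstart=5, send=99,
        )

    def test_roundtrip_12_columns(self, tmp_path):
        path = tmp_path / "hits.tsv"
        write_hits_tsv([self._hit()], path)
        line = path.read_text().strip().split("\t")
        assert len(line) == 12
        (back,) = read_hits_tsv(path, query_lengths={"q1": 100},
                                subject_lengths={"s1": 105})
        assert back.query_id == "q1"
        assert back.alignment_length == 95
        assert back.e_value == pytest.approx(3.2e-09, rel=0.01)
        assert back.query_coverage == pytest.approx(0.95)

    def test_coverage_defaults_without_lengths(self, tmp_path):
        path = tmp_path / "hits.tsv"
        write_hits_tsv([self._hit()], path)
        (back,) = read_hits_tsv(path)
        assert back.query_coverage == 1.0

    def test_malformed_width_rejected(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("q1\ts1\t50\n")
        with pytest.raises(SeqIOError, match="12"):
            read_hits_tsv(path)
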