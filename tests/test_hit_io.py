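"""hit_io: format parsing, validation, and report round-trips."""

import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from domarch import hit_io
from domarch.arch_resolve import Architecture, ResolvedDomain
from domarch.chea_analysis import CheACall
from domarch.errors import (
    DuplicateProteinId,
    EmptySequence,
    MalformedRecord,
    MissingHeader,
)

DOMTBL_ROW = (
    "CheW                 -            140 P001                 -            900 "
    "  1.2e-40  55.0   0.1   1   1   2.1e-41   1.1e-40  55.0   0.1 "
    "    1   140    12   158    10   160 0.90 synthetic CheW match"
)


class TestParseDomtblout:
    def test_comment_only_stream_is_empty(self):
        assert hit_io.parse_domtblout("# one\n# two\n") == []

    def test_empty_stream_is_empty(self):
        assert hit_io.parse_domtblout("") == []

    def test_well_formed_row_maps_hmmscan_columns(self):
        (hit,) = hit_io.parse_domtblout(DOMTBL_ROW + "\n")
        assert hit.protein_id == "P001"
        assert hit.model_name == "CheW"
        assert hit.source == hit_io.HMMER
        assert (hit.env_start, hit.env_end) == (10, 160)
        assert (hit.ali_start, hit.ali_end) == (12, 158)
        assert (hit.hmm_start, hit.hmm_end) == (1, 140)
        assert hit.model_length == 140
        assert hit.score == 55.0
        assert hit.i_evalue == pytest.approx(1.1e-40)

    def test_too_few_columns_aborts(self):
        with pytest.raises(MalformedRecord):
            hit_io.parse_domtblout("CheW - 140 P001 - 900 1e-4\n")

    def test_non_numeric_coordinate_aborts(self):
        bad = DOMTBL_ROW.replace("    1   140 ", "    x   140 ")
        with pytest.raises(MalformedRecord):
            hit_io.parse_domtblout(bad + "\n")

    def test_duplicate_rows_deduplicated_with_warning(self):
        stream = DOMTBL_ROW + "\n" + DOMTBL_ROW + "\n"
        with pytest.warns(UserWarning, match="duplicate"):
            hits = hit_io.parse_domtblout(stream)
        assert len(hits) == 1

    def test_hmmscan_output_from_real_hmmer_parses(self, tmp_path):
        """Round-trip through the actual hmmer 3.4 binary on a toy profile,
        confirming bit-exact column semantics."""
        import shutil
        import subprocess

        if shutil.which("hmmscan") is None or shutil.which("hmmbuild") is None:
            pytest.skip("hmmer binaries unavailable")
        msa = tmp_path / "toy.sto"
        msa.write_text(
            "# STOCKHOLM 1.0\n"
            "seq1 MKVLAEGHRTWQNDPLFY\n"
            "seq2 MKVLAEGHKTWQNDPLFY\n"
            "seq3 MKVLADGHRTWQNEPLFY\n"
            "//\n"
        )
        hmm = tmp_path / "toy.hmm"
        subprocess.run(
            ["hmmbuild", "-n", "ToyDom", str(hmm), str(msa)],
            check=True, capture_output=True,
        )
        subprocess.run(["hmmpress", str(hmm)], check=True, capture_output=True)
        fasta = tmp_path / "q.fasta"
        fasta.write_text(">Q1\nGGGGMKVLAEGHRTWQNDPLFYGGGG\n")
        out = tmp_path / "hits.domtblout"
        subprocess.run(
            ["hmmscan", "--domtblout", str(out), "-E", "1000",
             "--domE", "1000", str(hmm), str(fasta)],
            check=True, capture_output=True,
        )
        with open(out) as fh:
            hits = hit_io.parse_domtblout(fh)
        assert hits, "expected at least one hit"
        assert hits[0].model_name == "ToyDom"
        assert hits[0].protein_id == "Q1"
        assert 1 <= hits[0].env_start <= hits[0].env_end <= 26


class TestParseRescueTable:
    HEADER = "\t".join(hit_io.RESCUE_COLUMNS)

    def test_header_only_is_empty(self):
        assert hit_io.parse_rescue_table(self.HEADER + "\n") == []

    def test_row_yields_profile_profile_hit(self):
        row = "P001\tH-kinase_dim\t98.14\t200\t330\t1\t64\t64"
        (hit,) = hit_io.parse_rescue_table(f"{self.HEADER}\n{row}\n")
        assert hit.source == hit_io.PROFILE_PROFILE
        assert hit.probability == pytest.approx(98.14)
        assert (hit.env_start, hit.env_end) == (200, 330)
        assert hit.score is None and hit.i_evalue is None

    def test_non_numeric_probability_raises(self):
        row = "P001\tHpt\tx\t10\t100\t1\t90\t90"
        with pytest.raises(MalformedRecord):
            hit_io.parse_rescue_table(f"{self.HEADER}\n{row}\n")

    def test_missing_header_raises(self):
        with pytest.raises(MissingHeader):
            hit_io.parse_rescue_table("P001\tHpt\t95.0\t10\t100\t1\t90\t90\n")
        with pytest.raises(MissingHeader):
            hit_io.parse_rescue_table("")


class TestParseGeneTable:
    HEADER = "\t".join(hit_io.GENE_TSV_COLUMNS)

    def _tsv(self, rows):
        return self.HEADER + "\n" + "\n".join("\t".join(r) for r in rows) + "\n"

    def test_rank_by_start(self):
        genes = hit_io.parse_gene_table(self._tsv([
            ("A", "G1", "C1", "100", "400", "+"),
            ("B", "G1", "C1", "900", "1200", "+"),
        ]))
        assert [g.gene_index for g in genes] == [1, 2]

    def test_empty_file_is_empty(self):
        assert hit_io.parse_gene_table("") == []

    def test_indices_restart_per_contig_with_interleaved_input(self):
        genes = hit_io.parse_gene_table(self._tsv([
            ("A", "G1", "C1", "500", "700", "+"),
            ("B", "G1", "C2", "100", "300", "-"),
            ("C", "G1", "C1", "100", "300", "+"),
            ("D", "G1", "C2", "900", "1000", "-"),
        ]))
        by_pid = {g.protein_id: g.gene_index for g in genes}
        assert by_pid == {"A": 2, "C": 1, "B": 1, "D": 2}

    def test_duplicate_protein_id_raises(self):
        with pytest.raises(DuplicateProteinId):
            hit_io.parse_gene_table(self._tsv([
                ("A", "G1", "C1", "100", "400", "+"),
                ("A", "G1", "C1", "900", "1200", "+"),
            ]))

    def test_gff3_cds_subset(self):
        gff = (
            "##gff-version 3\n"
            "C1\tsrc\tCDS\t100\t400\t.\t+\t0\tID=cds1;protein_id=A\n"
            "C1\tsrc\tgene\t90\t410\t.\t+\t.\tID=gene1\n"
            "C1\tsrc\tCDS\t900\t1200\t.\t-\t0\tID=B\n"
        )
        genes = hit_io.parse_gene_table(gff, genome_id="G9")
        assert [(g.protein_id, g.gene_index, g.strand) for g in genes] == [
            ("A", 1, "+"), ("B", 2, "-"),
        ]
        assert all(g.genome_id == "G9" for g in genes)

    @given(starts=st.lists(st.integers(1, 10_000), min_size=1, max_size=20,
                           unique=True))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_gene_index_is_permutation_within_contig(self, starts):
        rows = [
            (f"P{i}", "G1", "C1", str(s), str(s + 10), "+")
            for i, s in enumerate(starts)
        ]
        genes = hit_io.parse_gene_table(self._tsv(rows))
        assert sorted(g.gene_index for g in genes) == list(range(1, len(starts) + 1))
        ranked = sorted(genes, key=lambda g: g.gene_index)
        assert all(a.start < b.start for a, b in zip(ranked, ranked[1:]))


class TestReadFasta:
    def test_basic(self):
        assert hit_io.read_fasta(">a\nMKV\n") == [("a", "MKV")]

    def test_normalization(self):
        assert hit_io.read_fasta(">a desc here\nmkv*\n") == [("a", "MKV")]

    def test_two_records_in_order(self):
        recs = hit_io.read_fasta(">a\nMK\n>b\nVW\n")
        assert recs == [("a", "MK"), ("b", "VW")]

    def test_empty_sequence_raises(self):
        with pytest.raises(EmptySequence):
            hit_io.read_fasta(">a\n\n>b\nMK\n")


def _annotated(pid="P1", canonical="Hpt|CheW", genome="G1"):
    labels = canonical.split("|") if canonical else []
    pos = 1
    domains = []
    for lab in labels:
        domains.append(ResolvedDomain(label=lab, start=pos, end=pos + 99,
                                      evidence="hmmer", source_hits=[]))
        pos += 150
    arch = Architecture(protein_id=pid, domains=domains, canonical=canonical)
    call = CheACall(protein_id=pid, is_chea="CheW" in labels and "HATPase_c" in labels,
                    counts={lab: labels.count(lab) for lab in set(labels)})
    prot = hit_io.ProteinRecord(protein_id=pid, genome_id=genome, length=pos + 100)
    return hit_io.AnnotatedProtein(protein=prot, architecture=arch, call=call)


class TestArchitectureReport:
    def test_empty_records_give_header_only(self):
        buf = io.StringIO()
        hit_io.write_architecture_report([], buf)
        assert buf.getvalue() == "\t".join(hit_io.REPORT_COLUMNS) + "\n"

    def test_round_trip_preserves_architecture(self):
        rec = _annotated(canonical="Hpt|P2/CheY-binding|H-kinase_dim|HATPase_c|CheW")
        buf = io.StringIO()
        hit_io.write_architecture_report([rec], buf)
        (row,) = hit_io.read_architecture_report(buf.getvalue())
        assert row["architecture"] == rec.architecture.canonical
        assert row["n_domains"] == 5
        assert row["is_chea"] is True

    def test_two_runs_byte_identical(self):
        recs = [_annotated("P1"), _annotated("P2", canonical="CheW")]
        out = []
        for _ in range(2):
            tsv, sidecar = io.StringIO(), io.StringIO()
            hit_io.write_architecture_report(recs, tsv, sidecar)
            out.append(tsv.getvalue() + sidecar.getvalue())
        assert out[0] == out[1]
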