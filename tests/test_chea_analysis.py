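"""chea_analysis: identity, copy counting, His projection, gene context."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from domarch.arch_resolve import Architecture, ResolvedDomain, Thresholds, \
    build_architecture
from domarch.chea_analysis import (
    FLAG_BIPARTITE,
    FLAG_CLASSICAL,
    FLAG_MULTI_HPT,
    CheACall,
    ReferenceSite,
    count_domain_copies,
    detect_bipartite_hpt,
    detect_conserved_histidine,
    flag_contig_end_truncation,
    identify_chea,
    map_label,
)
from domarch.errors import EmptySequence, InvalidContigLength
from domarch.hit_io import GeneRecord, ProteinRecord
from domarch.vocab import CLASSICAL_ARCHITECTURE, DomainVocabulary

from conftest import make_hit

AA = list("ACDEFGHIKLMNPQRSTVWY")


def arch_from(labels, pid="P1"):
    domains = [
        ResolvedDomain(label=lab, start=1 + i * 150, end=120 + i * 150,
                       evidence="hmmer", source_hits=[])
        for i, lab in enumerate(labels)
    ]
    return Architecture(protein_id=pid, domains=domains,
                        canonical="|".join(labels))


class TestMapLabel:
    @pytest.mark.parametrize("model,expected", [
        ("CheY-binding", "P2/CheY-binding"),
        ("P2", "P2/CheY-binding"),
        ("Response_reg", "CheY-like"),
        ("CheC", "CheC/CheX"),
        ("CheX", "CheC/CheX"),
        ("PAS", "other:PAS"),
    ])
    def test_vocabulary_collapse(self, model, expected):
        assert map_label(model) == expected

    def test_packaged_tsv_matches_builtin(self):
        vocab = DomainVocabulary.default()
        for model in ("P2", "CheY-binding", "Response_reg", "CheW", "Hpt"):
            assert vocab.map_label(model) == map_label(model)


class TestIdentifyChea:
    def test_classical_is_chea(self):
        assert identify_chea(arch_from(CLASSICAL_ARCHITECTURE.split("|")))

    def test_lone_chew_adaptor_is_not(self):
        assert not identify_chea(arch_from(["CheW"]))

    def test_kinase_without_chew_is_not(self):
        assert not identify_chea(arch_from(["H-kinase_dim", "HATPase_c"]))

    @given(st.lists(st.sampled_from(
        ["Hpt", "P2/CheY-binding", "H-kinase_dim", "HATPase_c", "CheW",
         "CheY-like", "other:PAS"]), max_size=6))
    @settings(derandomize=True, max_examples=60)
    def test_monotone_under_domain_addition(self, extra):
        base = ["HATPase_c", "CheW"]
        assert identify_chea(arch_from(base))
        assert identify_chea(arch_from(base + extra))


class TestCountDomainCopies:
    def test_fourteen_hpt_copies_flagged(self):
        labels = ["Hpt"] * 14 + ["H-kinase_dim", "HATPase_c", "CheW", "CheY-like"]
        call = count_domain_copies(arch_from(labels))
        assert call.counts["Hpt"] == 14
        assert FLAG_MULTI_HPT in call.flags
        assert call.is_chea

    def test_classical_architecture_all_single(self):
        call = count_domain_copies(arch_from(CLASSICAL_ARCHITECTURE.split("|")))
        assert set(call.counts.values()) == {1}
        assert FLAG_CLASSICAL in call.flags

    def test_merged_split_counts_once(self, thresholds):
        # one split CheW (two collinear halves) + one normal CheW -> 2 copies
        hits = [
            make_hit(env=(10, 70), hmm=(1, 60), model_length=140),
            make_hit(env=(121, 200), hmm=(61, 140), model_length=140),
            make_hit(env=(260, 400), hmm=(1, 140), model_length=140),
            make_hit(model="HATPase_c", env=(450, 660), hmm=(1, 210),
                     model_length=210),
        ]
        arch = build_architecture(ProteinRecord("P1", length=700, hits=hits))
        call = count_domain_copies(arch)
        assert call.counts["CheW"] == 2
        assert call.is_chea

    def test_counts_sum_equals_resolved_domains(self):
        labels = ["Hpt", "Hpt", "CheW", "other:PAS"]
        call = count_domain_copies(arch_from(labels))
        assert sum(call.counts.values()) == len(labels)


class TestConservedHistidine:
    def test_self_alignment_maps_to_site(self):
        ref = ReferenceSite.default()
        assert detect_conserved_histidine(ref.reference_sequence, ref) == (48, True)

    def test_site_mutation_detected(self):
        ref = ReferenceSite.default()
        seq = list(ref.reference_sequence)
        seq[47] = "A"
        assert detect_conserved_histidine("".join(seq), ref) == (48, False)

    def test_n_terminal_extension_shifts_position(self):
        ref = ReferenceSite.default()
        assert detect_conserved_histidine(
            "MGSGS" + ref.reference_sequence, ref) == (53, True)

    def test_agrees_with_independent_aligner(self):
        """Cross-check the projected site against biotite's global aligner."""
        biotite_seq = pytest.importorskip("biotite.sequence")
        import biotite.sequence.align as balign

        ref = ReferenceSite.default()
        rng = np.random.default_rng(11)
        matrix = balign.SubstitutionMatrix.std_protein_matrix()
        for _ in range(10):
            seq = list(ref.reference_sequence)
            for i in rng.choice(len(seq), size=15, replace=False):
                seq[i] = AA[rng.integers(0, 20)]
            query = "".join(["M"] * int(rng.integers(0, 6))) + "".join(seq)
            pos, present = detect_conserved_histidine(query, ref)
            aln = balign.align_optimal(
                biotite_seq.ProteinSequence(ref.reference_sequence),
                biotite_seq.ProteinSequence(query),
                matrix, gap_penalty=(-11, -1), terminal_penalty=True,
            )[0]
            trace = aln.trace
            rows = trace[trace[:, 0] == 47]
            oracle_q = int(rows[0][1])
            oracle_pos = None if oracle_q < 0 else oracle_q + 1
            assert pos == oracle_pos
            if oracle_pos is not None:
                assert present == (query[oracle_q] == "H")

    @given(suffix=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", max_size=30))
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_invariant_to_c_terminal_extension(self, suffix):
        ref = ReferenceSite.default()
        pos, present = detect_conserved_histidine(
            ref.reference_sequence + suffix, ref)
        assert (pos, present) == (48, True)

    def test_empty_query_rejected(self):
        with pytest.raises(EmptySequence):
            detect_conserved_histidine("", ReferenceSite.default())


def _call(pid, counts, is_chea=True):
    return CheACall(protein_id=pid, is_chea=is_chea, counts=counts)


def _gene(pid, idx_start, strand="+", contig="C1"):
    return GeneRecord(protein_id=pid, genome_id="G1", contig_id=contig,
                      start=idx_start, end=idx_start + 999, strand=strand,
                      gene_index=(idx_start - 1) // 1000 + 1)


class TestBipartiteHpt:
    def test_adjacent_same_strand_pair_found(self):
        chea = _call("A", {"HATPase_c": 1, "CheW": 1})
        hpt = _call("B", {"Hpt": 1}, is_chea=False)
        genes = [_gene("A", 4001), _gene("B", 5001)]
        pairs = detect_bipartite_hpt([chea, hpt], genes)
        assert pairs == [("A", "B")]
        assert FLAG_BIPARTITE in chea.flags

    def test_no_hpt_only_protein_no_pair(self):
        chea = _call("A", {"HATPase_c": 1, "CheW": 1})
        other = _call("B", {"HATPase_c": 1, "CheW": 1, "Hpt": 1})
        genes = [_gene("A", 1), _gene("B", 1001)]
        assert detect_bipartite_hpt([chea, other], genes) == []

    def test_opposite_strand_excluded(self):
        chea = _call("A", {"HATPase_c": 1, "CheW": 1})
        hpt = _call("B", {"Hpt": 1}, is_chea=False)
        genes = [_gene("A", 4001), _gene("B", 5001, strand="-")]
        assert detect_bipartite_hpt([chea, hpt], genes) == []

    def test_outside_window_excluded(self):
        chea = _call("A", {"HATPase_c": 1, "CheW": 1})
        hpt = _call("B", {"Hpt": 1}, is_chea=False)
        genes = [_gene("A", 1), _gene("B", 9001)]  # gene ranks 1 and 10
        assert detect_bipartite_hpt([chea, hpt], genes) == []

    def test_result_independent_of_input_order(self):
        chea = _call("A", {"HATPase_c": 1, "CheW": 1})
        hpt1 = _call("B", {"Hpt": 1}, is_chea=False)
        hpt2 = _call("C", {"Hpt": 2}, is_chea=False)
        genes = [_gene("A", 3001), _gene("B", 4001), _gene("C", 2001)]
        expected = detect_bipartite_hpt([chea, hpt1, hpt2], genes)
        assert detect_bipartite_hpt([hpt2, chea, hpt1], genes) == expected
        assert expected == [("A", "B"), ("A", "C")]

    def test_missing_gene_record_warns_and_skips(self):
        chea = _call("A", {"HATPase_c": 1, "CheW": 1})
        hpt = _call("B", {"Hpt": 1}, is_chea=False)
        with pytest.warns(UserWarning, match="no gene record"):
            assert detect_bipartite_hpt([chea, hpt], [_gene("B", 1)]) == []


class TestContigEndTruncation:
    def test_hpt_less_chea_at_contig_edge(self):
        call = _call("A", {"HATPase_c": 1, "CheW": 1})
        gene = GeneRecord("A", "G1", "C1", 5000, 8000, "+", 3)
        assert flag_contig_end_truncation(call, gene, contig_length=8000)
        assert "contig_end_truncation" in call.flags

    def test_mid_contig_not_flagged(self):
        call = _call("A", {"HATPase_c": 1, "CheW": 1})
        gene = GeneRecord("A", "G1", "C1", 5000, 8000, "+", 3)
        assert not flag_contig_end_truncation(call, gene, contig_length=20000)

    def test_complete_chea_at_edge_not_flagged(self):
        call = _call("A", {"HATPase_c": 1, "CheW": 1, "Hpt": 1})
        gene = GeneRecord("A", "G1", "C1", 5000, 8000, "+", 3)
        assert not flag_contig_end_truncation(call, gene, contig_length=8000)

    def test_contig_shorter_than_gene_rejected(self):
        call = _call("A", {"HATPase_c": 1, "CheW": 1})
        gene = GeneRecord("A", "G1", "C1", 5000, 8000, "+", 3)
        with pytest.raises(InvalidContigLength):
            flag_contig_end_truncation(call, gene, contig_length=7000)
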