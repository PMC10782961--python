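"""End-to-end orchestration: evidence tables in, annotated cohort out.

This is the library layer the CLI wraps: it assembles ProteinRecords from
the hit tables (optionally attaching sequences, class labels and gene
context), resolves every architecture, makes CheA calls, runs the
genome-context analyses (bipartite Hpt, contig-end truncation), and rolls
genomes up into a CohortSummary.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

from .arch_resolve import Thresholds, build_architecture
from .chea_analysis import (
    CheACall,
    ReferenceSite,
    count_domain_copies,
    detect_bipartite_hpt,
    detect_conserved_histidine,
    flag_contig_end_truncation,
)
from .cohort_stats import CohortSummary, GenomeRecord, summarize_cohort
from .hit_io import AnnotatedProtein, DomainHit, GeneRecord, ProteinRecord
from .vocab import HPT, DomainVocabulary


def assemble_proteins(
    hits: Iterable[DomainHit],
    sequences: Optional[Mapping[str, str]] = None,
    class_labels: Optional[Mapping[str, str]] = None,
    genes: Optional[Sequence[GeneRecord]] = None,
) -> list[ProteinRecord]:
    """Group hits by protein and attach sequence / class / genome metadata.

    Protein length comes from the sequence when available, otherwise from
    the furthest hit envelope. Proteins are returned sorted by id."""
    sequences = sequences or {}
    class_labels = class_labels or {}
    genome_by_pid = {g.protein_id: g.genome_id for g in genes} if genes else {}
    by_pid: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_pid.setdefault(h.protein_id, []).append(h)
    for pid in sequences:
        by_pid.setdefault(pid, [])
    out = []
    for pid in sorted(by_pid):
        seq = sequences.get(pid)
        length = len(seq) if seq else max(
            (h.env_end for h in by_pid[pid]), default=0
        )
        out.append(
            ProteinRecord(
                protein_id=pid,
                genome_id=genome_by_pid.get(pid, ""),
                sequence=seq,
                length=length,
                hits=by_pid[pid],
                class_label=class_labels.get(pid, "unknown"),
            )
        )
    return out


def annotate_proteins(
    proteins: Sequence[ProteinRecord],
    thresholds: Thresholds | None = None,
    vocab: DomainVocabulary | None = None,
    genes: Optional[Sequence[GeneRecord]] = None,
    reference: ReferenceSite | None = None,
    check_his: bool = False,
) -> list[AnnotatedProtein]:
    """Resolve every protein and make its CheA call; when gene context is
    supplied, run the bipartite-Hpt and contig-edge analyses per genome."""
    thresholds = thresholds or Thresholds()
    vocab = vocab or DomainVocabulary()
    annotated: list[AnnotatedProtein] = []
    for p in proteins:
        arch = build_architecture(p, thresholds, vocab)
        call = count_domain_copies(arch, vocab)
        if check_his and p.sequence:
            reference = reference or ReferenceSite.default()
            call.conserved_his = [
                detect_conserved_histidine(
                    p.sequence[d.start - 1 : d.end], reference
                )[1]
                for d in arch.domains
                if d.label == HPT
            ]
        annotated.append(AnnotatedProtein(protein=p, architecture=arch, call=call))

    if genes:
        gene_by_pid = {g.protein_id: g for g in genes}
        contig_len: dict[tuple[str, str], int] = {}
        for g in genes:
            key = (g.genome_id, g.contig_id)
            contig_len[key] = max(contig_len.get(key, 0), g.end)
        by_genome: dict[str, list[AnnotatedProtein]] = {}
        for a in annotated:
            by_genome.setdefault(a.protein.genome_id, []).append(a)
        for genome_id, members in by_genome.items():
            calls = [m.call for m in members]
            member_genes = [
                gene_by_pid[m.protein.protein_id]
                for m in members
                if m.protein.protein_id in gene_by_pid
            ]
            detect_bipartite_hpt(calls, member_genes)
            for m in members:
                g = gene_by_pid.get(m.protein.protein_id)
                if g is not None and m.call.is_chea:
                    flag_contig_end_truncation(
                        m.call, g, contig_len[(g.genome_id, g.contig_id)]
                    )
    return annotated


def build_genome_records(
    annotated: Sequence[AnnotatedProtein],
    phosphatase_by_genome: Optional[Mapping[str, dict[str, bool]]] = None,
) -> list[GenomeRecord]:
    """Group calls into GenomeRecords (sorted by genome id)."""
    by_genome: dict[str, list[CheACall]] = {}
    for a in annotated:
        by_genome.setdefault(a.protein.genome_id, []).append(a.call)
    genomes = []
    for gid in sorted(by_genome):
        genomes.append(
            GenomeRecord(
                genome_id=gid,
                chea_calls=by_genome[gid],
                phosphatase_presence=(
                    phosphatase_by_genome.get(gid) if phosphatase_by_genome else None
                ),
            )
        )
    return genomes


def summarize_annotated(
    annotated: Sequence[AnnotatedProtein],
    phosphatase_by_genome: Optional[Mapping[str, dict[str, bool]]] = None,
) -> CohortSummary:
    """CohortSummary straight from annotated proteins."""
    genomes = build_genome_records(annotated, phosphatase_by_genome)
    canonical = {a.protein.protein_id: a.architecture.canonical for a in annotated}
    classes = {a.protein.protein_id: a.protein.class_label for a in annotated}
    return summarize_cohort(genomes, canonical, classes)


def observed_architectures(
    annotated: Sequence[AnnotatedProtein],
) -> dict[str, str]:
    """protein_id -> observed canonical string (recovery-scoring input)."""
    return {a.protein.protein_id: a.architecture.canonical for a in annotated}
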