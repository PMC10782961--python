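"""CheA-specific interpretation of resolved architectures.

A CheA homolog is identified by the joint presence of the two domains whose
profile models are both sensitive and specific — the HATPase_c kinase domain
and the CheW adaptor domain — in one protein. On identified CheAs this
module counts domain copies, flags noteworthy configurations (multiple Hpt
copies, duplicated CheW, receiver-domain appendages, phosphatase fusions),
projects the phospho-accepting histidine of each Hpt copy onto a reference
numbering by pairwise alignment, and inspects gene neighborhoods for
bipartite kinases (an Hpt-only gene standing in for a missing Hpt domain)
and for contig-edge truncation artifacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .arch_resolve import Architecture
from .errors import EmptySequence, InvalidContigLength
from .hit_io import GeneRecord
from .vocab import (
    CHEC_CHEX,
    CHEW,
    CHEY_LIKE,
    CLASSICAL_ARCHITECTURE,
    HPT,
    KINASE,
    P2,
    DomainVocabulary,
    map_label,
)

__all__ = [
    "DomainVocabulary",
    "map_label",
    "CheACall",
    "ReferenceSite",
    "identify_chea",
    "count_domain_copies",
    "detect_conserved_histidine",
    "detect_bipartite_hpt",
    "flag_contig_end_truncation",
]

FLAG_MULTI_HPT = "multi_hpt"
FLAG_DUAL_CHEW = "dual_chew"
FLAG_HAS_CHEY_LIKE = "has_cheY_like"
FLAG_HAS_P2 = "has_P2"
FLAG_BIPARTITE = "bipartite_hpt_candidate"
FLAG_CONTIG_END = "contig_end_truncation"
FLAG_CHEC_FUSION = "chec_chex_fusion"
FLAG_CLASSICAL = "classical_architecture"


@dataclass
class CheACall:
    """Per-protein CheA verdict: identity, copy counts, and flags."""

    protein_id: str
    is_chea: bool = False
    counts: dict[str, int] = field(default_factory=dict)
    flags: set[str] = field(default_factory=set)
    conserved_his: list[bool] = field(default_factory=list)


@dataclass
class ReferenceSite:
    """A reference sequence with one marked residue (the phospho-histidine,
    His-48 in the reference numbering)."""

    reference_id: str
    reference_sequence: str
    site_position: int = 48
    site_residue: str = "H"

    def __post_init__(self) -> None:
        if self.reference_sequence[self.site_position - 1] != self.site_residue:
            raise ValueError(
                f"reference residue at {self.site_position} is not "
                f"{self.site_residue!r}"
            )

    @classmethod
    def default(cls) -> "ReferenceSite":
        """The packaged synthetic Hpt reference (H at position 48)."""
        ref = resources.files("domarch").joinpath("data/synthetic_reference_hpt.fasta")
        with ref.open("r") as fh:
            from .hit_io import read_fasta

            rid, seq = read_fasta(fh)[0]
        return cls(reference_id=rid, reference_sequence=seq)


def identify_chea(a: Architecture, vocab: DomainVocabulary | None = None) -> bool:
    """True iff the protein carries ≥1 HATPase_c and ≥1 CheW domain."""
    labels = {d.label for d in a.domains}
    return KINASE in labels and CHEW in labels


def count_domain_copies(
    a: Architecture, vocab: DomainVocabulary | None = None
) -> CheACall:
    """Count unified-label copies (a merged split hit counts once) and set
    the architecture flags."""
    counts: dict[str, int] = {}
    for d in a.domains:
        counts[d.label] = counts.get(d.label, 0) + 1
    call = CheACall(protein_id=a.protein_id, is_chea=identify_chea(a), counts=counts)
    if counts.get(HPT, 0) >= 2:
        call.flags.add(FLAG_MULTI_HPT)
    if counts.get(CHEW, 0) >= 2:
        call.flags.add(FLAG_DUAL_CHEW)
    if counts.get(CHEY_LIKE, 0) >= 1:
        call.flags.add(FLAG_HAS_CHEY_LIKE)
    if counts.get(P2, 0) >= 1:
        call.flags.add(FLAG_HAS_P2)
    if call.is_chea and counts.get(CHEC_CHEX, 0) >= 1:
        call.flags.add(FLAG_CHEC_FUSION)
    if a.canonical == CLASSICAL_ARCHITECTURE:
        call.flags.add(FLAG_CLASSICAL)
    return call


def _default_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def detect_conserved_histidine(
    hpt_seq: str,
    ref: ReferenceSite | None = None,
    aligner: Align.PairwiseAligner | None = None,
) -> tuple[Optional[int], bool]:
    """Locate the query residue corresponding to the reference phospho-site.

    Globally aligns ``hpt_seq`` against the reference (BLOSUM62, affine gaps
    open 11 / extend 1) and returns the 1-based query position aligned to
    the reference site, plus whether that residue is the conserved
    histidine. A query gap at the site column yields ``(None, False)``.
    """
    if not hpt_seq:
        raise EmptySequence("empty Hpt query")
    ref = ref or ReferenceSite.default()
    aligner = aligner or _default_aligner()
    aln = aligner.align(ref.reference_sequence, hpt_seq)[0]
    indices = aln.indices  # 2 x ncol; row 0 = reference, row 1 = query; -1 = gap
    cols = np.where(indices[0] == ref.site_position - 1)[0]
    qidx = int(indices[1][cols[0]])
    if qidx < 0:
        return None, False
    return qidx + 1, hpt_seq[qidx] == ref.site_residue


def _is_hpt_only(call: CheACall) -> bool:
    return (
        call.counts.get(HPT, 0) >= 1
        and call.counts.get(KINASE, 0) == 0
        and call.counts.get(CHEW, 0) == 0
    )


def detect_bipartite_hpt(
    genome_calls: Sequence[CheACall],
    genes: Sequence[GeneRecord],
    window: int = 3,
) -> list[tuple[str, str]]:
    """Find (CheA, Hpt-only partner) gene pairs within one genome.

    A CheA lacking any Hpt domain is paired with every standalone Hpt-only
    protein (≥1 Hpt, no kinase, no CheW) on the same contig and strand
    within ``window`` gene ranks — the operon proxy for a bipartite kinase.
    CheAs in a pair get the bipartite flag. Proteins without a gene-table
    entry are skipped with a warning. The result is sorted, independent of
    input order.
    """
    gene_by_pid = {g.protein_id: g for g in genes}
    calls_by_pid = {c.protein_id: c for c in genome_calls}
    pairs: set[tuple[str, str]] = set()
    for call in genome_calls:
        if not call.is_chea or call.counts.get(HPT, 0) != 0:
            continue
        gene = gene_by_pid.get(call.protein_id)
        if gene is None:
            warnings.warn(f"no gene record for {call.protein_id}; skipped")
            continue
        for other in genome_calls:
            if other.protein_id == call.protein_id or not _is_hpt_only(other):
                continue
            og = gene_by_pid.get(other.protein_id)
            if og is None:
                warnings.warn(f"no gene record for {other.protein_id}; skipped")
                continue
            if (
                og.contig_id == gene.contig_id
                and og.strand == gene.strand
                and abs(og.gene_index - gene.gene_index) <= window
            ):
                pairs.add((call.protein_id, other.protein_id))
                call.flags.add(FLAG_BIPARTITE)
    return sorted(pairs)


def flag_contig_end_truncation(
    call: CheACall,
    gene: GeneRecord,
    contig_length: int,
    margin: int = 100,
) -> bool:
    """True iff an Hpt-less CheA gene sits within ``margin`` bp of a contig
    edge — the signature of an assembly-truncation artifact."""
    if contig_length < gene.end:
        raise InvalidContigLength(
            f"contig length {contig_length} < gene end {gene.end}"
        )
    truncated = call.counts.get(HPT, 0) == 0 and (
        gene.start <= margin or gene.end >= contig_length - margin + 1
    )
    if truncated:
        call.flags.add(FLAG_CONTIG_END)
    return truncated
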