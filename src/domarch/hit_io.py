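"""Readers and writers for every external format the pipeline touches.

Inputs
------
* HMMER3 ``hmmscan --domtblout`` tables (tier-1 sequence-to-profile hits).
* A tabular "rescue" table carrying profile-profile hits (HHpred-style
  probabilities) for regions the first tier left unannotated.
* Per-genome gene tables (plain TSV or a GFF3 CDS subset) that supply the
  gene order and contig layout used by operon-proximity analyses.
* Protein FASTA.

Outputs
-------
* The architecture report: a TSV with one row per protein plus a JSON
  sidecar with full per-domain detail. Writing is deterministic
  (byte-identical for identical inputs).

All residue and nucleotide coordinates are 1-based inclusive, matching the
HMMER domtblout convention.
"""

from __future__ import annotations

import gzip
import io
import json
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterator, Optional, Sequence

from Bio import SeqIO

from .errors import (
    DuplicateProteinId,
    EmptySequence,
    MalformedRecord,
    MissingHeader,
)

HMMER = "hmmer"
PROFILE_PROFILE = "profile_profile"

RESCUE_COLUMNS = (
    "protein_id",
    "model_name",
    "probability",
    "env_start",
    "env_end",
    "hmm_start",
    "hmm_end",
    "model_length",
)

GENE_TSV_COLUMNS = ("protein_id", "genome_id", "contig_id", "start", "end", "strand")

REPORT_COLUMNS = (
    "protein_id",
    "genome_id",
    "class",
    "is_chea",
    "architecture",
    "n_domains",
    "flags",
)


@dataclass(frozen=True)
class DomainHit:
    """One raw evidence row: a model matched to a protein interval.

    Exactly one scoring system is populated depending on ``source``:
    HMMER hits carry a bit score and independent E-value; profile-profile
    (rescue) hits carry a probability in percent.
    """

    protein_id: str
    model_name: str
    model_accession: str
    source: str  # HMMER or PROFILE_PROFILE
    env_start: int
    env_end: int
    ali_start: int
    ali_end: int
    hmm_start: int
    hmm_end: int
    model_length: int
    score: Optional[float] = None
    i_evalue: Optional[float] = None
    probability: Optional[float] = None

    def __post_init__(self) -> None:
        if not (1 <= self.env_start <= self.ali_start <= self.ali_end <= self.env_end):
            raise MalformedRecord(
                f"{self.protein_id}/{self.model_name}: envelope must contain the "
                f"alignment: env {self.env_start}-{self.env_end}, "
                f"ali {self.ali_start}-{self.ali_end}"
            )
        if not (1 <= self.hmm_start <= self.hmm_end <= self.model_length):
            raise MalformedRecord(
                f"{self.protein_id}/{self.model_name}: model coordinates "
                f"{self.hmm_start}-{self.hmm_end} outside 1-{self.model_length}"
            )
        if self.source == HMMER:
            if self.score is None or self.i_evalue is None or self.probability is not None:
                raise MalformedRecord("hmmer hits carry score + i_evalue only")
        elif self.source == PROFILE_PROFILE:
            if self.probability is None or self.score is not None or self.i_evalue is not None:
                raise MalformedRecord("profile_profile hits carry probability only")
        else:
            raise MalformedRecord(f"unknown hit source {self.source!r}")

    @property
    def env_length(self) -> int:
        return self.env_end - self.env_start + 1


@dataclass(frozen=True)
class GeneRecord:
    """A protein-coding gene placed on a contig; gene_index is the rank of
    its start among genes of the same contig (1-based)."""

    protein_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    gene_index: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise MalformedRecord(
                f"{self.protein_id}: gene start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise MalformedRecord(f"{self.protein_id}: bad strand {self.strand!r}")


@dataclass
class ProteinRecord:
    """A protein plus all domain-hit evidence gathered for it."""

    protein_id: str
    genome_id: str = ""
    sequence: Optional[str] = None
    length: int = 0
    hits: list[DomainHit] = field(default_factory=list)
    class_label: str = "unknown"

    def __post_init__(self) -> None:
        if self.sequence is not None and self.length == 0:
            self.length = len(self.sequence)


def _as_lines(stream: IO[str] | str) -> Iterator[str]:
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    return iter(stream)


def open_text(path) -> IO[str]:
    """Open a path as text, transparently decompressing ``.gz``."""
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _dedupe(hits: list[DomainHit]) -> list[DomainHit]:
    """Drop duplicate (protein, model, envelope) rows, keeping the first."""
    seen: set[tuple] = set()
    out = []
    for h in hits:
        key = (h.protein_id, h.model_name, h.env_start, h.env_end)
        if key in seen:
            warnings.warn(
                f"duplicate hit dropped: {h.protein_id} {h.model_name} "
                f"{h.env_start}-{h.env_end}",
                stacklevel=3,
            )
            continue
        seen.add(key)
        out.append(h)
    return out


def parse_domtblout(stream: IO[str] | str) -> list[DomainHit]:
    """Parse HMMER3 ``hmmscan --domtblout`` text into :class:`DomainHit`.

    In hmmscan output the profile is the *target* (columns 1-3) and the
    protein is the *query* (columns 4-6). Columns are whitespace-delimited
    with a free-text description last; ``#`` lines are comments. Rows are
    returned in input order after duplicate removal.
    """
    hits: list[DomainHit] = []
    for lineno, line in enumerate(_as_lines(stream), 1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) < 22:
            raise MalformedRecord(f"domtblout line {lineno}: {len(cols)} columns < 22")
        try:
            hit = DomainHit(
                protein_id=cols[3],
                model_name=cols[0],
                model_accession="" if cols[1] == "-" else cols[1],
                source=HMMER,
                model_length=int(cols[2]),
                score=float(cols[13]),
                i_evalue=float(cols[12]),
                hmm_start=int(cols[15]),
                hmm_end=int(cols[16]),
                ali_start=int(cols[17]),
                ali_end=int(cols[18]),
                env_start=int(cols[19]),
                env_end=int(cols[20]),
            )
        except ValueError as exc:
            raise MalformedRecord(f"domtblout line {lineno}: {exc}") from exc
        hits.append(hit)
    return _dedupe(hits)


def parse_rescue_table(stream: IO[str] | str) -> list[DomainHit]:
    """Parse the profile-profile rescue table (TSV with a fixed header).

    Columns: ``protein_id model_name probability env_start env_end
    hmm_start hmm_end model_length``. Probabilities are percentages.
    """
    lines = _as_lines(stream)
    try:
        header = next(lines)
    except StopIteration:
        raise MissingHeader("rescue table is empty (header required)")
    cols = header.rstrip("\n").split("\t")
    if tuple(cols) != RESCUE_COLUMNS:
        raise MissingHeader(f"rescue table header {cols!r} != {list(RESCUE_COLUMNS)!r}")
    hits: list[DomainHit] = []
    for lineno, line in enumerate(lines, 2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != len(RESCUE_COLUMNS):
            raise MalformedRecord(f"rescue line {lineno}: expected 8 columns")
        try:
            env_start, env_end = int(parts[3]), int(parts[4])
            hit = DomainHit(
                protein_id=parts[0],
                model_name=parts[1],
                model_accession="",
                source=PROFILE_PROFILE,
                probability=float(parts[2]),
                env_start=env_start,
                env_end=env_end,
                # the rescue tier reports a single extent; alignment == envelope
                ali_start=env_start,
                ali_end=env_end,
                hmm_start=int(parts[5]),
                hmm_end=int(parts[6]),
                model_length=int(parts[7]),
            )
        except ValueError as exc:
            raise MalformedRecord(f"rescue line {lineno}: {exc}") from exc
        hits.append(hit)
    return _dedupe(hits)


def _assign_gene_indices(genes: list[GeneRecord]) -> list[GeneRecord]:
    """Assign gene_index per contig by ascending start (ties by protein_id),
    preserving the input order of the returned list."""
    from dataclasses import replace

    by_contig: dict[tuple[str, str], list[int]] = {}
    for i, g in enumerate(genes):
        by_contig.setdefault((g.genome_id, g.contig_id), []).append(i)
    indexed: list[GeneRecord] = list(genes)
    for idxs in by_contig.values():
        ranked = sorted(idxs, key=lambda i: (genes[i].start, genes[i].protein_id))
        for rank, i in enumerate(ranked, 1):
            indexed[i] = replace(genes[i], gene_index=rank)
    return indexed


def _parse_gff_attributes(attr: str) -> dict[str, str]:
    out = {}
    for part in attr.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def parse_gene_table(stream: IO[str] | str, genome_id: str = "") -> list[GeneRecord]:
    """Parse a gene table into :class:`GeneRecord` with per-contig gene ranks.

    Accepts either the plain TSV dialect (header ``protein_id genome_id
    contig_id start end strand``) or a GFF3 subset restricted to CDS
    features, where the protein id comes from the ``protein_id`` or ``ID``
    attribute and ``genome_id`` (argument) names the genome.
    """
    lines = [ln for ln in _as_lines(stream)]
    genes: list[GeneRecord] = []
    seen_ids: set[str] = set()

    def add(rec: GeneRecord) -> None:
        if rec.protein_id in seen_ids:
            raise DuplicateProteinId(rec.protein_id)
        seen_ids.add(rec.protein_id)
        genes.append(rec)

    data = [ln for ln in lines if ln.strip()]
    if not data:
        return []
    is_gff = data[0].startswith("##gff-version") or (
        len(data[0].split("\t")) == 9 and not data[0].startswith("protein_id")
    )
    if is_gff:
        for lineno, line in enumerate(data, 1):
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise MalformedRecord(f"GFF line {lineno}: expected 9 columns")
            if parts[2] != "CDS":
                continue
            attrs = _parse_gff_attributes(parts[8])
            pid = attrs.get("protein_id") or attrs.get("ID")
            if not pid:
                raise MalformedRecord(f"GFF line {lineno}: no protein_id/ID attribute")
            try:
                add(
                    GeneRecord(
                        protein_id=pid,
                        genome_id=genome_id,
                        contig_id=parts[0],
                        start=int(parts[3]),
                        end=int(parts[4]),
                        strand=parts[6],
                    )
                )
            except ValueError as exc:
                raise MalformedRecord(f"GFF line {lineno}: {exc}") from exc
    else:
        header = data[0].rstrip("\n").split("\t")
        body = data[1:]
        if tuple(header) != GENE_TSV_COLUMNS:
            raise MalformedRecord(
                f"gene table header {header!r} != {list(GENE_TSV_COLUMNS)!r}"
            )
        for lineno, line in enumerate(body, 2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 6:
                raise MalformedRecord(f"gene table line {lineno}: expected 6 columns")
            try:
                add(
                    GeneRecord(
                        protein_id=parts[0],
                        genome_id=parts[1],
                        contig_id=parts[2],
                        start=int(parts[3]),
                        end=int(parts[4]),
                        strand=parts[5],
                    )
                )
            except ValueError as exc:
                raise MalformedRecord(f"gene table line {lineno}: {exc}") from exc
    return _assign_gene_indices(genes)


def read_fasta(stream: IO[str] | str) -> list[tuple[str, str]]:
    """Read FASTA into ``(id, sequence)`` tuples in file order.

    Sequences are uppercased and terminal ``*`` stop characters stripped;
    the id is the first whitespace-delimited token of the header.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    out: list[tuple[str, str]] = []
    for rec in SeqIO.parse(stream, "fasta"):
        seq = str(rec.seq).upper().strip("*")
        if not seq:
            raise EmptySequence(rec.id)
        out.append((rec.id, seq))
    return out


@dataclass
class AnnotatedProtein:
    """A protein together with its resolved architecture and CheA call.

    ``architecture`` and ``call`` are duck-typed (arch_resolve.Architecture
    and chea_analysis.CheACall); only their public fields are used here.
    """

    protein: ProteinRecord
    architecture: object
    call: object


def _domain_payload(d) -> dict:
    return {
        "label": d.label,
        "start": d.start,
        "end": d.end,
        "evidence": d.evidence,
        "n_source_hits": len(d.source_hits),
    }


def write_architecture_report(
    records: Sequence[AnnotatedProtein],
    stream: IO[str],
    sidecar_stream: Optional[IO[str]] = None,
) -> None:
    """Write the per-protein architecture report TSV (+ JSON sidecar).

    Output is byte-identical for identical inputs: fixed column order,
    booleans as 0/1, flags sorted and ';'-joined, floats at 2 decimals.
    """
    stream.write("\t".join(REPORT_COLUMNS) + "\n")
    sidecar = []
    for rec in records:
        arch = rec.architecture
        call = rec.call
        flags = ";".join(sorted(call.flags)) if call.flags else "-"
        row = (
            rec.protein.protein_id,
            rec.protein.genome_id,
            rec.protein.class_label,
            "1" if call.is_chea else "0",
            arch.canonical or "-",
            str(len(arch.domains)),
            flags,
        )
        stream.write("\t".join(row) + "\n")
        sidecar.append(
            {
                "protein_id": rec.protein.protein_id,
                "genome_id": rec.protein.genome_id,
                "class": rec.protein.class_label,
                "length": rec.protein.length,
                "is_chea": call.is_chea,
                "architecture": arch.canonical,
                "domains": [_domain_payload(d) for d in arch.domains],
                "unannotated": [list(g) for g in arch.unannotated],
                "counts": dict(sorted(call.counts.items())),
                "flags": sorted(call.flags),
                "conserved_his": call.conserved_his,
            }
        )
    if sidecar_stream is not None:
        json.dump(sidecar, sidecar_stream, indent=1, sort_keys=True)
        sidecar_stream.write("\n")


def read_architecture_report(stream: IO[str] | str) -> list[dict]:
    """Read the report TSV back into row dictionaries (typed fields)."""
    lines = _as_lines(stream)
    try:
        header = next(lines).rstrip("\n").split("\t")
    except StopIteration:
        raise MissingHeader("architecture report is empty")
    if tuple(header) != REPORT_COLUMNS:
        raise MalformedRecord(f"unexpected report header {header!r}")
    rows = []
    for line in lines:
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != len(REPORT_COLUMNS):
            raise MalformedRecord("report row with wrong column count")
        rows.append(
            {
                "protein_id": parts[0],
                "genome_id": parts[1],
                "class": parts[2],
                "is_chea": parts[3] == "1",
                "architecture": "" if parts[4] == "-" else parts[4],
                "n_domains": int(parts[5]),
                "flags": set() if parts[6] == "-" else set(parts[6].split(";")),
            }
        )
    return rows
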