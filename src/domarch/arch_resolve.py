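"""Resolve a protein's raw domain hits into an ordered architecture.

The two-tier annotation model: sensitive, specific profile HMMs (HATPase_c,
CheW) find their domains by straight sequence-to-profile search, while the
weakly conserved CheA domains (Hpt, P2/CheY-binding, H-kinase_dim) are often
missed and recovered only by profile-profile searches of long unannotated
regions. The resolver therefore

1. filters hits by tier-appropriate significance (i-Evalue for HMMER hits,
   probability for profile-profile hits),
2. competes overlapping hits, keeping the maximum-total-score compatible
   subset (small envelope overlaps tolerated),
3. re-joins split hits — two collinear partial matches to the same model
   separated by a short insertion are one domain, not two copies — and
4. reports the left-to-right canonical architecture string plus any long
   unannotated gaps (the regions one would submit to the rescue tier).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .errors import WrongLabel
from .hit_io import HMMER, PROFILE_PROFILE, DomainHit, ProteinRecord
from .vocab import DIM, DomainVocabulary

EVIDENCE_HMMER = "hmmer"
EVIDENCE_RESCUE = "rescue"
EVIDENCE_MERGED = "merged"


@dataclass(frozen=True)
class Thresholds:
    """All tunable constants of the resolution procedure.

    hmmer_max_i_evalue : per-domain independent E-value cutoff for tier-1
        hits (1e-5, a conservative choice typical of architecture surveys).
    rescue_min_probability : minimum profile-profile probability (percent)
        for a rescue hit to count (90.0, inclusive).
    gap_min_length : minimum length of an uncovered region worth a rescue
        query (100 aa, roughly the average domain size).
    merge_max_gap : maximum sequence gap between two partial hits that may
        be halves of one inserted-into domain (75 aa; the motivating case
        is a 50-aa insertion mid-CheW).
    merge_hmm_overlap_tol : how far back into the first half's model span
        the second half may start while still reading as collinear (20).
    overlap_tol : residues two accepted domains may share (15).
    dim_classical_max : dimerization domains at most this long are
        "classical"; longer ones are "extended" (70 aa).
    """

    hmmer_max_i_evalue: float = 1e-5
    rescue_min_probability: float = 90.0
    gap_min_length: int = 100
    merge_max_gap: int = 75
    merge_hmm_overlap_tol: int = 20
    overlap_tol: int = 15
    dim_classical_max: int = 70

    def __post_init__(self) -> None:
        vals = (
            self.hmmer_max_i_evalue,
            self.rescue_min_probability,
            self.gap_min_length,
            self.merge_max_gap,
            self.merge_hmm_overlap_tol,
            self.dim_classical_max,
        )
        if any(v <= 0 for v in vals) or self.overlap_tol < 0:
            raise ValueError("thresholds must be positive")
        if self.dim_classical_max >= 170:
            raise ValueError("dim_classical_max must be < 170")


@dataclass
class ResolvedDomain:
    """A final domain call; merged calls carry every contributing hit."""

    label: str
    start: int
    end: int
    evidence: str
    source_hits: list[DomainHit] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Architecture:
    """Ordered domain calls for one protein plus long unannotated gaps."""

    protein_id: str
    domains: list[ResolvedDomain] = field(default_factory=list)
    canonical: str = ""
    unannotated: list[tuple[int, int]] = field(default_factory=list)


def hit_score(hit: DomainHit) -> float:
    """Commensurate score across tiers: bits, or probability/10 as
    bits-equivalent for profile-profile hits."""
    if hit.source == HMMER:
        return float(hit.score)
    return float(hit.probability) / 10.0


def filter_hits(hits: Sequence[DomainHit], t: Thresholds) -> list[DomainHit]:
    """Keep significant hits from either tier, preserving order."""
    kept = []
    for h in hits:
        if h.source == HMMER and h.i_evalue <= t.hmmer_max_i_evalue:
            kept.append(h)
        elif h.source == PROFILE_PROFILE and h.probability >= t.rescue_min_probability:
            kept.append(h)
    return kept


def _overlap(a: DomainHit, b: DomainHit) -> int:
    return min(a.env_end, b.env_end) - max(a.env_start, b.env_start) + 1


def resolve_overlaps(hits: Sequence[DomainHit], t: Thresholds) -> list[DomainHit]:
    """Select the maximum-total-score subset with pairwise envelope overlap
    ≤ overlap_tol.

    Exact branch-and-bound over hits in a canonical order (score desc,
    envelope length desc, env_start asc), so ties resolve deterministically
    toward higher-scoring, longer, earlier hits, independent of input order.
    Hit counts per protein are small (a handful of domains plus noise), so
    exact search is cheap.
    """
    n = len(hits)
    if n <= 1:
        return list(hits)
    order = sorted(
        range(n),
        key=lambda i: (-hit_score(hits[i]), -hits[i].env_length, hits[i].env_start,
                       hits[i].model_name, hits[i].hmm_start),
    )
    scores = [hit_score(hits[i]) for i in order]
    conflict = [0] * n  # bitmask over canonical positions
    for a in range(n):
        for b in range(a + 1, n):
            if _overlap(hits[order[a]], hits[order[b]]) > t.overlap_tol:
                conflict[a] |= 1 << b
                conflict[b] |= 1 << a
    suffix = [0.0] * (n + 1)
    for i in range(n - 1, -1, -1):
        suffix[i] = suffix[i + 1] + scores[i]

    best_total = -1.0
    best_sel: tuple[int, ...] = ()

    def dfs(i: int, chosen_mask: int, chosen: list[int], total: float) -> None:
        nonlocal best_total, best_sel
        if total + suffix[i] < best_total:
            return
        if i == n:
            # strict improvement keeps the lexicographically earliest
            # (greedy-by-canonical-order) selection among ties
            if total > best_total + 1e-12:
                best_total = total
                best_sel = tuple(chosen)
            return
        if not conflict[i] & chosen_mask:
            chosen.append(i)
            dfs(i + 1, chosen_mask | (1 << i), chosen, total + scores[i])
            chosen.pop()
        dfs(i + 1, chosen_mask, chosen, total)

    dfs(0, 0, [], 0.0)
    selected = {order[i] for i in best_sel}
    return [h for i, h in enumerate(hits) if i in selected]


def merge_split_hits(hits: Sequence[DomainHit], t: Thresholds) -> list[ResolvedDomain]:
    """Merge consecutive collinear partial hits to the same model.

    Two hits are halves of one domain when the sequence gap between them is
    at most ``merge_max_gap`` and their model coordinates read on: the later
    hit's hmm_start must be at least the earlier hit's hmm_end minus
    ``merge_hmm_overlap_tol``. Two full-length matches fail the collinearity
    test and stay separate copies. Merging runs left-to-right and chains
    transitively; input must be non-overlapping.
    """
    ordered = sorted(hits, key=lambda h: (h.env_start, h.env_end))
    out: list[ResolvedDomain] = []
    for h in ordered:
        evidence = EVIDENCE_HMMER if h.source == HMMER else EVIDENCE_RESCUE
        if out:
            prev = out[-1]
            last_hit = prev.source_hits[-1]
            gap = h.env_start - prev.end - 1
            collinear = h.hmm_start >= last_hit.hmm_end - t.merge_hmm_overlap_tol
            if (
                h.model_name == last_hit.model_name
                and gap <= t.merge_max_gap
                and collinear
            ):
                prev.end = max(prev.end, h.env_end)
                prev.evidence = EVIDENCE_MERGED
                prev.source_hits.append(h)
                continue
        out.append(
            ResolvedDomain(
                label=h.model_name,
                start=h.env_start,
                end=h.env_end,
                evidence=evidence,
                source_hits=[h],
            )
        )
    return out


def find_unannotated_regions(
    protein_length: int,
    domains: Sequence[ResolvedDomain],
    t: Thresholds,
) -> list[tuple[int, int]]:
    """Maximal uncovered intervals (termini included) of length ≥
    gap_min_length — the regions worth a rescue-tier query."""
    gaps: list[tuple[int, int]] = []
    cursor = 1
    for d in sorted(domains, key=lambda d: d.start):
        if d.start > cursor:
            gaps.append((cursor, d.start - 1))
        cursor = max(cursor, d.end + 1)
    if cursor <= protein_length:
        gaps.append((cursor, protein_length))
    return [(s, e) for s, e in gaps if e - s + 1 >= t.gap_min_length]


def build_architecture(
    protein: ProteinRecord,
    t: Thresholds | None = None,
    vocab: DomainVocabulary | None = None,
) -> Architecture:
    """Full resolution for one protein: filter, compete overlaps, merge
    split hits, map model names onto unified labels, and record gaps."""
    t = t or Thresholds()
    vocab = vocab or DomainVocabulary()
    kept = filter_hits(protein.hits, t)
    kept = resolve_overlaps(kept, t)
    domains = merge_split_hits(kept, t)
    for d in domains:
        d.label = vocab.map_label(d.label)
    domains.sort(key=lambda d: (d.start, d.end))
    length = protein.length or (max((d.end for d in domains), default=0))
    return Architecture(
        protein_id=protein.protein_id,
        domains=domains,
        canonical="|".join(d.label for d in domains),
        unannotated=find_unannotated_regions(length, domains, t),
    )


def classify_dimerization_length(
    d: ResolvedDomain, t: Thresholds | None = None
) -> tuple[str, int]:
    """Classify a dimerization domain as classical (≤ dim_classical_max aa)
    or extended, returning (class, length)."""
    t = t or Thresholds()
    if d.label != DIM:
        raise WrongLabel(f"expected {DIM}, got {d.label}")
    return ("classical" if d.length <= t.dim_classical_max else "extended", d.length)
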