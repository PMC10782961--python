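"""Cohort-level summaries over CheA calls and genomes.

Denominators follow the survey convention: domain and architecture
frequencies are fractions of CheA *proteins*; the phosphate-sink test is a
fraction of eligible *genomes* (exactly one CheA, carrying a CheY-like
receiver domain) that lack all three dedicated CheY phosphatases
(CheZ, CheC, CheX) — the genomic signature supporting a phosphate-sink role
for the receiver appendage.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Mapping, Optional, Sequence

from scipy import stats

from .chea_analysis import FLAG_HAS_CHEY_LIKE, FLAG_MULTI_HPT, CheACall
from .errors import EmptyClass, EmptyCohort, MissingPhosphataseData
from .vocab import CANONICAL_LABELS


@dataclass
class GenomeRecord:
    """One genome: its CheA calls and phosphatase-gene presence."""

    genome_id: str
    chea_calls: list[CheACall] = field(default_factory=list)
    phosphatase_presence: Optional[dict[str, bool]] = None  # keys CheZ, CheC, CheX
    taxon: Optional[str] = None


@dataclass
class CohortSummary:
    """All dataset-level statistics in one serializable bundle."""

    n_proteins: int = 0
    n_genomes: int = 0
    n_chea: int = 0
    domain_frequency: dict[str, dict[str, float]] = field(default_factory=dict)
    architecture_frequency: dict[str, float] = field(default_factory=dict)
    class_consensus: dict[str, dict] = field(default_factory=dict)
    cooccurrence: dict = field(default_factory=dict)
    phosphate_sink: dict = field(default_factory=dict)

    def to_json(self, stream: IO[str]) -> None:
        json.dump(self.__dict__, stream, indent=1, sort_keys=True)
        stream.write("\n")


def _chea_only(calls: Sequence[CheACall]) -> list[CheACall]:
    calls = [c for c in calls if c.is_chea]
    if not calls:
        raise EmptyCohort("no CheA calls in cohort")
    return calls


def domain_frequency_table(calls: Sequence[CheACall]) -> dict[str, dict[str, float]]:
    """Per unified label: fraction of CheAs with ≥1, exactly 1, and >1
    copies (denominator = number of CheA proteins)."""
    calls = _chea_only(calls)
    n = len(calls)
    labels = sorted({lab for c in calls for lab in c.counts} | set(CANONICAL_LABELS))
    table = {}
    for lab in labels:
        ks = [c.counts.get(lab, 0) for c in calls]
        table[lab] = {
            "fraction_with_ge1": sum(k >= 1 for k in ks) / n,
            "fraction_with_1": sum(k == 1 for k in ks) / n,
            "fraction_with_gt1": sum(k > 1 for k in ks) / n,
        }
    return table


def architecture_frequency(
    calls: Sequence[CheACall],
    canonical_by_pid: Mapping[str, str],
) -> dict[str, float]:
    """Relative frequency of each canonical architecture string among
    CheAs; fractions sum to 1."""
    calls = _chea_only(calls)
    counter = Counter(canonical_by_pid[c.protein_id] for c in calls)
    n = len(calls)
    return {arch: k / n for arch, k in sorted(counter.items())}


def hpt_cheylike_cooccurrence(
    calls: Sequence[CheACall], fisher: bool = False
) -> dict:
    """2x2 association of multi-Hpt with a CheY-like appendage.

    Returns the table, P(CheY-like | multi-Hpt), and the odds ratio
    (Haldane-Anscombe +0.5 in every cell when any cell is zero). A Fisher
    exact p-value is optional; the association is primarily descriptive.
    """
    calls = _chea_only(calls)
    a = b = c = d = 0  # rows: multi-Hpt yes/no; cols: CheY-like yes/no
    for call in calls:
        multi = FLAG_MULTI_HPT in call.flags
        chey = FLAG_HAS_CHEY_LIKE in call.flags
        if multi and chey:
            a += 1
        elif multi:
            b += 1
        elif chey:
            c += 1
        else:
            d += 1
    frac = a / (a + b) if (a + b) else None
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    out = {
        "table": [[a, b], [c, d]],
        "p_cheylike_given_multi_hpt": frac,
        "odds_ratio": odds,
    }
    if fisher:
        out["fisher_p"] = float(stats.fisher_exact([[a, b], [c, d]])[1])
    return out


def class_consensus(
    calls: Sequence[CheACall],
    canonical_by_pid: Mapping[str, str],
    class_by_pid: Mapping[str, str],
) -> dict[str, dict]:
    """Per chemosensory class: modal architecture, homogeneity (fraction of
    members with the modal string) and n. Ties break lexicographically;
    unknown-class members aggregate under 'unknown'."""
    calls = _chea_only(calls)
    members: dict[str, list[str]] = {}
    for c in calls:
        cls = class_by_pid.get(c.protein_id, "unknown")
        members.setdefault(cls, []).append(canonical_by_pid[c.protein_id])
    out = {}
    for cls in sorted(members):
        archs = members[cls]
        if not archs:
            raise EmptyClass(cls)
        counter = Counter(archs)
        best_count = max(counter.values())
        modal = min(a for a, k in counter.items() if k == best_count)
        out[cls] = {
            "modal_architecture": modal,
            "homogeneity": counter[modal] / len(archs),
            "n": len(archs),
        }
    return out


def phosphate_sink_test(
    genomes: Sequence[GenomeRecord], relaxed: bool = False
) -> dict:
    """Fraction of eligible genomes lacking all dedicated CheY phosphatases.

    Eligible: exactly one CheA, carrying a CheY-like domain (``relaxed``
    accepts ≥1 CheA provided all carry CheY-like). Returns (n_eligible,
    n_lacking_phosphatase, fraction); fraction is None for zero eligible.
    """
    n_eligible = n_lacking = 0
    for g in genomes:
        cheas = [c for c in g.chea_calls if c.is_chea]
        if relaxed:
            eligible = len(cheas) >= 1 and all(
                FLAG_HAS_CHEY_LIKE in c.flags for c in cheas
            )
        else:
            eligible = len(cheas) == 1 and FLAG_HAS_CHEY_LIKE in cheas[0].flags
        if not eligible:
            continue
        if g.phosphatase_presence is None:
            raise MissingPhosphataseData(g.genome_id)
        n_eligible += 1
        if not any(g.phosphatase_presence.get(k, False) for k in ("CheZ", "CheC", "CheX")):
            n_lacking += 1
    return {
        "n_eligible": n_eligible,
        "n_lacking_phosphatase": n_lacking,
        "fraction": (n_lacking / n_eligible) if n_eligible else None,
    }


def summarize_cohort(
    genomes: Sequence[GenomeRecord],
    canonical_by_pid: Mapping[str, str],
    class_by_pid: Mapping[str, str] | None = None,
    n_proteins: int | None = None,
) -> CohortSummary:
    """Assemble the full CohortSummary from per-genome calls."""
    calls = [c for g in genomes for c in g.chea_calls]
    chea = [c for c in calls if c.is_chea]
    class_by_pid = class_by_pid or {}
    summary = CohortSummary(
        n_proteins=n_proteins if n_proteins is not None else len(calls),
        n_genomes=len(genomes),
        n_chea=len(chea),
    )
    if chea:
        summary.domain_frequency = domain_frequency_table(calls)
        summary.architecture_frequency = architecture_frequency(calls, canonical_by_pid)
        summary.class_consensus = class_consensus(calls, canonical_by_pid, class_by_pid)
        summary.cooccurrence = hpt_cheylike_cooccurrence(calls)
        if all(g.phosphatase_presence is not None for g in genomes):
            summary.phosphate_sink = phosphate_sink_test(genomes)
    return summary


def write_summary_tables(summary: CohortSummary, outdir) -> None:
    """Serialize the summary to JSON plus three TSV tables."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "cohort_summary.json", "w") as fh:
        summary.to_json(fh)
    with open(outdir / "domain_frequency.tsv", "w") as fh:
        fh.write("label\tfraction_with_ge1\tfraction_with_1\tfraction_with_gt1\n")
        for lab, row in sorted(summary.domain_frequency.items()):
            fh.write(
                f"{lab}\t{row['fraction_with_ge1']:.6f}\t"
                f"{row['fraction_with_1']:.6f}\t{row['fraction_with_gt1']:.6f}\n"
            )
    with open(outdir / "architecture_frequency.tsv", "w") as fh:
        fh.write("architecture\tfraction\n")
        for arch, frac in sorted(summary.architecture_frequency.items()):
            fh.write(f"{arch}\t{frac:.6f}\n")
    with open(outdir / "class_consensus.tsv", "w") as fh:
        fh.write("class\tmodal_architecture\thomogeneity\tn\n")
        for cls, row in sorted(summary.class_consensus.items()):
            fh.write(
                f"{cls}\t{row['modal_architecture']}\t"
                f"{row['homogeneity']:.6f}\t{row['n']}\n"
            )


def read_phosphatase_table(stream) -> dict[str, dict[str, bool]]:
    """Read the ``genome_id cheZ cheC cheX`` 0/1 TSV."""
    import io

    if isinstance(stream, str):
        stream = io.StringIO(stream)
    lines = iter(stream)
    header = next(lines).rstrip("\n").split("\t")
    if [h.lower() for h in header] != ["genome_id", "chez", "chec", "chex"]:
        raise MissingPhosphataseData(f"bad phosphatase header {header!r}")
    out = {}
    for line in lines:
        if not line.strip():
            continue
        gid, z, c, x = line.rstrip("\n").split("\t")
        out[gid] = {"CheZ": z == "1", "CheC": c == "1", "CheX": x == "1"}
    return out
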