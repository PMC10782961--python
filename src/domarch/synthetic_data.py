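"""Synthetic cohorts with planted ground truth.

The generator emulates the pipeline's whole input universe — hmmscan
domtblout tables, a profile-profile rescue table, gene tables, protein
FASTA, class labels, and phosphatase presence — for a cohort of genomes
whose CheA proteins are drawn from class-conditional architecture
templates. Planted features mirror the structure of real survey data:

* per-model detection sensitivity: the weakly conserved Hpt,
  P2/CheY-binding and H-kinase_dim models miss their domains at
  configurable rates, and a configurable fraction of those misses is
  recovered by the rescue tier (probability drawn above the 90% cutoff);
* insertion-induced split hits: a CheW or Hpt hit is sometimes emitted as
  two collinear halves around a short insertion (30-70 aa, below the
  merge gap), the artifact that inflates naive copy counts;
* Hpt copy-number variation by class (up to 14 copies in the Tfp class),
  duplicated CheW in class F5, receiver-domain appendages in F3/F5/ACF/Tfp;
* bipartite plantings (an Hpt-less CheA with an adjacent same-strand
  Hpt-only gene) and contig-end truncations (an Hpt-less CheA gene ending
  exactly at the contig edge);
* phosphatase absence conditioned on phosphate-sink eligibility.

Every emission is a pure function of the seeded generator state, so runs
with equal configs are byte-identical. The TruthManifest records every
planted fact for downstream recovery scoring.

The default parameters are chosen so the planted cohort marginals match the
shape of a real CheA survey: 46% classical architectures, 8% dual CheW,
18% multi-Hpt, 34% CheY-like, 93% phosphatase absence among sink-eligible
genomes, and ≈98% Hpt presence (the deficit split between truncation and
bipartite plantings).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .chea_analysis import ReferenceSite
from .errors import InvalidConfig, ManifestMismatch
from .vocab import (
    CHEC_CHEX,
    CHEW,
    CHEY_LIKE,
    CLASSICAL_ARCHITECTURE,
    DIM,
    HPT,
    KINASE,
    P2,
)

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

# model names as the two search tiers report them (unified downstream)
MODEL_FOR_LABEL = {
    HPT: ("Hpt",),
    P2: ("P2", "CheY-binding"),
    DIM: ("H-kinase_dim",),
    KINASE: ("HATPase_c",),
    CHEW: ("CheW",),
    CHEY_LIKE: ("Response_reg",),
    CHEC_CHEX: ("CheC",),
}

DECOY_MODELS = ("PAS", "GAF", "HAMP", "TPR_1")

DOMAIN_LENGTH_MEANS = {
    HPT: 130,  # fixed: Hpt copies are mutated copies of the packaged reference
    P2: 75,
    DIM: 62,
    KINASE: 220,
    CHEW: 140,
    CHEY_LIKE: 115,
    CHEC_CHEX: 190,
}


@dataclass(frozen=True)
class ArchitectureTemplate:
    """A class-conditional CheA blueprint: an N-terminal Hpt block with a
    copy-number distribution, followed by a fixed body of domains."""

    name: str
    hpt_copies: dict[int, float]
    body: tuple[str, ...]
    p_extended_dim: float = 0.10

    def canonical(self, n_hpt: int) -> str:
        return "|".join([HPT] * n_hpt + list(self.body))


def default_templates() -> dict[str, ArchitectureTemplate]:
    """Per-class predominant architectures shaped like a real survey:
    classical five-domain CheAs in F1/F6, P2-less CheAs in F2/F7, receiver
    appendages in F3, three Hpt copies in F4, duplicated CheW in F5, and
    multi-Hpt receiver-bearing CheAs in ACF and Tfp."""
    core = (DIM, KINASE, CHEW)
    classical_body = (P2,) + core
    return {
        "F1": ArchitectureTemplate("F1", {1: 1.0}, classical_body),
        "F6": ArchitectureTemplate("F6", {1: 1.0}, classical_body),
        "F2": ArchitectureTemplate("F2", {1: 1.0}, core),
        "F7": ArchitectureTemplate("F7", {1: 1.0}, core),
        "F3": ArchitectureTemplate("F3", {1: 1.0}, core + (CHEY_LIKE,)),
        "F4": ArchitectureTemplate("F4", {3: 1.0}, core),
        "F5": ArchitectureTemplate("F5", {1: 1.0}, (DIM, KINASE, CHEW, CHEW, CHEY_LIKE)),
        "ACF": ArchitectureTemplate("ACF", {2: 1.0}, core + (CHEY_LIKE,)),
        "Tfp": ArchitectureTemplate(
            "Tfp",
            {2: 0.10, 3: 0.10, 4: 0.15, 5: 0.20, 6: 0.20,
             7: 0.10, 8: 0.05, 10: 0.04, 12: 0.03, 14: 0.03},
            core + (CHEY_LIKE,),
            p_extended_dim=0.30,
        ),
    }


DEFAULT_CLASS_FREQUENCIES = {
    "F1": 0.26, "F6": 0.20, "F2": 0.08, "F7": 0.06, "F3": 0.14,
    "F4": 0.06, "F5": 0.08, "ACF": 0.04, "Tfp": 0.08,
}


@dataclass
class GeneratorConfig:
    """Everything the generator needs; defaults are the study conditions.

    Noise knobs (``miss_probability``, ``rescue_probability``,
    ``split_probability``, ``decoy_rate``) model annotation imperfection;
    plantings (``bipartite_rate``, ``truncation_rate``) are real cohort
    features recorded as truth, not noise.
    """

    seed: int = 0
    n_genomes: int = 100
    chea_per_genome: dict[int, float] = field(
        default_factory=lambda: {0: 0.20, 1: 0.40, 2: 0.20, 3: 0.12, 4: 0.08}
    )
    class_frequencies: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FREQUENCIES)
    )
    architecture_templates: dict[str, ArchitectureTemplate] = field(
        default_factory=default_templates
    )
    miss_probability: dict[str, float] = field(
        default_factory=lambda: {HPT: 0.30, P2: 0.40, DIM: 0.30}
    )
    rescue_probability: float = 0.90
    split_probability: float = 0.05
    decoy_rate: float = 0.10
    phosphatase_absence_given_sink: float = 0.93
    bipartite_rate: float = 0.01
    truncation_rate: float = 0.01
    p_conserved_his: float = 0.90
    hpt_mutation_rate: float = 0.20
    domain_length_means: dict[str, int] = field(
        default_factory=lambda: dict(DOMAIN_LENGTH_MEANS)
    )

    def validate(self) -> None:
        probs = (
            [self.rescue_probability, self.split_probability,
             self.phosphatase_absence_given_sink, self.bipartite_rate,
             self.truncation_rate, self.p_conserved_his, self.hpt_mutation_rate]
            + list(self.miss_probability.values())
            + list(self.class_frequencies.values())
            + list(self.chea_per_genome.values())
        )
        if any(not (0.0 <= p <= 1.0) for p in probs) or self.decoy_rate < 0:
            raise InvalidConfig("probabilities must lie in [0, 1]")
        if abs(sum(self.class_frequencies.values()) - 1.0) > 1e-9:
            raise InvalidConfig("class_frequencies must sum to 1")
        if abs(sum(self.chea_per_genome.values()) - 1.0) > 1e-9:
            raise InvalidConfig("chea_per_genome must sum to 1")
        for cls in self.class_frequencies:
            if cls not in self.architecture_templates:
                raise InvalidConfig(f"no template for class {cls}")
            tpl = self.architecture_templates[cls]
            if KINASE not in tpl.body or CHEW not in tpl.body:
                raise InvalidConfig(f"template {cls} lacks HATPase_c/CheW core")
            if abs(sum(tpl.hpt_copies.values()) - 1.0) > 1e-9:
                raise InvalidConfig(f"template {cls} Hpt distribution must sum to 1")

    def noise_free(self) -> "GeneratorConfig":
        """Copy with every annotation-noise knob at zero."""
        return replace(
            self,
            miss_probability={},
            split_probability=0.0,
            decoy_rate=0.0,
        )


@dataclass
class SyntheticCohort:
    """All generated artifacts, as text plus the truth manifest."""

    domtblout: str
    rescue_table: str
    gene_table: str
    fasta: str
    class_labels: str
    phosphatase_table: str
    manifest: dict

    def manifest_json(self) -> str:
        return json.dumps(self.manifest, indent=1, sort_keys=True) + "\n"

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "hits.domtblout").write_text(self.domtblout)
        (outdir / "rescue.tsv").write_text(self.rescue_table)
        (outdir / "genes.tsv").write_text(self.gene_table)
        (outdir / "proteins.fasta").write_text(self.fasta)
        (outdir / "classes.tsv").write_text(self.class_labels)
        (outdir / "phosphatases.tsv").write_text(self.phosphatase_table)
        (outdir / "truth_manifest.json").write_text(self.manifest_json())


def _sample(rng: np.random.Generator, dist: dict) -> object:
    keys = sorted(dist)
    p = np.array([dist[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=p / p.sum()))]


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return AMINO_ACIDS[rng.integers(0, len(AMINO_ACIDS), size=n)]


def _mutated_hpt(
    rng: np.random.Generator, ref: ReferenceSite, rate: float, his: bool
) -> np.ndarray:
    """A point-mutated copy of the reference Hpt; the phospho-site carries H
    or (when planting a degenerate copy) a forced non-H residue."""
    seq = np.array(list(ref.reference_sequence))
    mask = rng.random(len(seq)) < rate
    seq[mask] = _random_seq(rng, int(mask.sum()))
    site = ref.site_position - 1
    if his:
        seq[site] = ref.site_residue
    else:
        alternatives = AMINO_ACIDS[AMINO_ACIDS != ref.site_residue]
        seq[site] = alternatives[rng.integers(0, len(alternatives))]
    return seq


def _domtblout_row(
    model: str, model_len: int, pid: str, prot_len: int,
    score: float, i_evalue: float,
    hmm: tuple[int, int], ali: tuple[int, int], env: tuple[int, int],
) -> str:
    cols = [
        model, "-", str(model_len), pid, "-", str(prot_len),
        f"{i_evalue:.1e}", f"{score:.1f}", "0.0", "1", "1",
        f"{i_evalue:.1e}", f"{i_evalue:.1e}", f"{score:.1f}", "0.0",
        str(hmm[0]), str(hmm[1]), str(ali[0]), str(ali[1]),
        str(env[0]), str(env[1]), "0.90", "-",
    ]
    return " ".join(cols)


def generate_cohort(cfg: GeneratorConfig) -> SyntheticCohort:
    """Generate a full cohort; deterministic under ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    ref = ReferenceSite.default()

    dom_rows: list[str] = []
    rescue_rows: list[str] = ["\t".join(
        ("protein_id", "model_name", "probability", "env_start", "env_end",
         "hmm_start", "hmm_end", "model_length"))]
    gene_rows: list[str] = ["\t".join(
        ("protein_id", "genome_id", "contig_id", "start", "end", "strand"))]
    fasta_chunks: list[str] = []
    class_rows: list[str] = ["protein_id\tclass"]
    phos_rows: list[str] = ["genome_id\tcheZ\tcheC\tcheX"]
    man_proteins: dict[str, dict] = {}
    man_genomes: dict[str, dict] = {}

    for g in range(cfg.n_genomes):
        gid = f"G{g:05d}"
        n_chea = int(_sample(rng, cfg.chea_per_genome))
        genome_protein_specs = []  # (pid, kind, payload)
        for k in range(n_chea):
            pid = f"{gid}_P{k:02d}"
            cls = str(_sample(rng, cfg.class_frequencies))
            tpl = cfg.architecture_templates[cls]
            n_hpt = int(_sample(rng, tpl.hpt_copies))
            planting = "none"
            partner_pid = None
            if n_hpt > 0 and rng.random() < cfg.truncation_rate:
                planting, n_hpt = "truncation", 0
            elif n_hpt > 0 and rng.random() < cfg.bipartite_rate:
                planting, n_hpt = "bipartite", 0
                partner_pid = f"{gid}_H{k:02d}"
            labels = [HPT] * n_hpt + list(tpl.body)
            spec = _plant_protein(rng, cfg, ref, pid, labels, tpl)
            spec.update(
                {"class": cls, "planting": planting, "partner": partner_pid,
                 "template": tpl.name}
            )
            genome_protein_specs.append(spec)
            if partner_pid is not None:
                pspec = _plant_protein(rng, cfg, ref, partner_pid, [HPT], tpl)
                pspec.update({"class": cls, "planting": "bipartite_partner",
                              "partner": pid, "template": tpl.name})
                genome_protein_specs.append(pspec)

        _emit_genome(
            rng, cfg, ref, gid, genome_protein_specs,
            dom_rows, rescue_rows, gene_rows, fasta_chunks, class_rows,
            man_proteins,
        )

        # phosphatase presence, conditioned on planted sink eligibility
        chea_specs = [s for s in genome_protein_specs
                      if s["planting"] != "bipartite_partner"]
        eligible = (
            len(chea_specs) == 1 and CHEY_LIKE in chea_specs[0]["labels"]
        )
        if eligible:
            all_absent = rng.random() < cfg.phosphatase_absence_given_sink
            if all_absent:
                pres = {"CheZ": False, "CheC": False, "CheX": False}
            else:
                which = int(rng.integers(0, 3))
                pres = {k: (i == which) for i, k in enumerate(("CheZ", "CheC", "CheX"))}
        else:
            pres = {
                "CheZ": bool(rng.random() < 0.5),
                "CheC": bool(rng.random() < 0.3),
                "CheX": bool(rng.random() < 0.2),
            }
        phos_rows.append(
            f"{gid}\t{int(pres['CheZ'])}\t{int(pres['CheC'])}\t{int(pres['CheX'])}"
        )
        man_genomes[gid] = {
            "n_chea": len(chea_specs),
            "sink_eligible": eligible,
            "phosphatase_presence": pres,
        }

    manifest = {
        "config": _config_echo(cfg),
        "proteins": man_proteins,
        "genomes": man_genomes,
    }
    return SyntheticCohort(
        domtblout="\n".join(
            ["# synthetic hmmscan --domtblout"] + dom_rows) + "\n",
        rescue_table="\n".join(rescue_rows) + "\n",
        gene_table="\n".join(gene_rows) + "\n",
        fasta="".join(fasta_chunks),
        class_labels="\n".join(class_rows) + "\n",
        phosphatase_table="\n".join(phos_rows) + "\n",
        manifest=manifest,
    )


def _plant_protein(rng, cfg, ref, pid, labels, tpl) -> dict:
    """Lay out one protein's true domains and draw per-domain emission
    decisions (miss / rescue / split) and Hpt His truth."""
    domains = []
    pos = 1 + int(rng.integers(0, 10))
    for label in labels:
        if label == HPT:
            length = len(ref.reference_sequence)
        elif label == DIM:
            if rng.random() < tpl.p_extended_dim:
                length = int(rng.integers(75, 171))
            else:
                length = int(rng.integers(58, 69))
        else:
            mean = cfg.domain_length_means[label]
            length = max(40, int(round(rng.normal(mean, 0.08 * mean))))
        missed = rng.random() < cfg.miss_probability.get(label, 0.0)
        rescued = missed and (rng.random() < cfg.rescue_probability)
        split = (
            not missed
            and label in (CHEW, HPT)
            and rng.random() < cfg.split_probability
        )
        insertion = int(rng.integers(30, 71)) if split else 0
        his = bool(rng.random() < cfg.p_conserved_his) if label == HPT else None
        start = pos
        end = pos + length + insertion - 1
        domains.append(
            {"label": label, "start": start, "end": end, "model_span": length,
             "missed": missed, "rescued": rescued, "split": split,
             "insertion": insertion, "conserved_his": his}
        )
        pos = end + 1 + int(rng.integers(20, 61))
    prot_len = (domains[-1]["end"] if domains else 60) + int(rng.integers(5, 31))
    return {"pid": pid, "labels": labels, "domains": domains, "length": prot_len}


def _emit_genome(
    rng, cfg, ref, gid, specs,
    dom_rows, rescue_rows, gene_rows, fasta_chunks, class_rows, man_proteins,
) -> None:
    """Emit hit rows, sequence, gene placement and manifest entries for one
    genome's proteins."""
    # --- per-protein evidence + sequence
    for spec in specs:
        pid, prot_len = spec["pid"], spec["length"]
        seq = _random_seq(rng, prot_len)
        for d in spec["domains"]:
            label, L = d["label"], d["model_span"]
            model = MODEL_FOR_LABEL[label][
                int(rng.integers(0, len(MODEL_FOR_LABEL[label])))
            ]
            if label == HPT:
                hseq = _mutated_hpt(rng, ref, cfg.hpt_mutation_rate, d["conserved_his"])
                if d["split"]:
                    cut = d["_cut"] = int(round(L * rng.uniform(0.35, 0.65)))
                    ins = d["insertion"]
                    block = np.concatenate(
                        [hseq[:cut], _random_seq(rng, ins), hseq[cut:]]
                    )
                else:
                    block = hseq
                seq[d["start"] - 1 : d["start"] - 1 + len(block)] = block
            elif d["split"]:
                d["_cut"] = int(round(L * rng.uniform(0.35, 0.65)))
            if d["missed"]:
                if d["rescued"]:
                    prob = rng.uniform(90.5, 99.9)
                    rescue_rows.append(
                        "\t".join(map(str, (
                            pid, model, f"{prob:.2f}", d["start"], d["end"],
                            1, L, L)))
                    )
                continue
            score = rng.uniform(25.0, 120.0)
            i_ev = 10.0 ** -rng.uniform(6.0, 30.0)
            if d["split"]:
                cut, ins = d["_cut"], d["insertion"]
                s = d["start"]
                halves = [
                    ((1, cut), (s, s + cut - 1)),
                    ((cut + 1, L), (s + cut + ins, d["end"])),
                ]
                for hmm, env in halves:
                    dom_rows.append(_domtblout_row(
                        model, L, pid, prot_len,
                        rng.uniform(12.0, 45.0), 10.0 ** -rng.uniform(6.0, 15.0),
                        hmm, env, env,
                    ))
            else:
                hmm_s = int(rng.integers(1, 4))
                hmm_e = L - int(rng.integers(0, 3))
                env = (d["start"], d["end"])
                shrink = min(2, (env[1] - env[0]) // 2)
                ali = (env[0] + int(rng.integers(0, shrink + 1)),
                       env[1] - int(rng.integers(0, shrink + 1)))
                dom_rows.append(_domtblout_row(
                    model, L, pid, prot_len, score, i_ev, (hmm_s, hmm_e), ali, env,
                ))
        # decoy off-target hits
        n_dec = int(rng.poisson(cfg.decoy_rate))
        for _ in range(n_dec):
            dl = int(rng.integers(60, 101))
            if prot_len <= dl + 1:
                continue
            ds = int(rng.integers(1, prot_len - dl))
            dom_rows.append(_domtblout_row(
                DECOY_MODELS[int(rng.integers(0, len(DECOY_MODELS)))], dl,
                pid, prot_len,
                rng.uniform(10.0, 40.0), 10.0 ** -rng.uniform(2.0, 8.0),
                (1, dl), (ds, ds + dl - 1), (ds, ds + dl - 1),
            ))
        seq_str = "".join(seq)
        fasta_chunks.append(f">{pid} {gid}\n")
        fasta_chunks.append(
            "\n".join(seq_str[i : i + 70] for i in range(0, len(seq_str), 70)) + "\n"
        )
        class_rows.append(f"{pid}\t{spec['class']}")
        man_proteins[pid] = {
            "genome_id": gid,
            "class": spec["class"],
            "planted_architecture": "|".join(spec["labels"]),
            "planting": spec["planting"],
            "partner": spec["partner"],
            "length": prot_len,
            "domains": [
                {k: d[k] for k in
                 ("label", "start", "end", "missed", "rescued", "split",
                  "insertion", "conserved_his")}
                for d in spec["domains"]
            ],
        }

    # --- gene placement
    contig = "C1"
    pos_bp = 1
    gene_specs = []
    n_filler = 0

    def add_gene(pid_, plen_bp, strand, contig_id):
        nonlocal pos_bp
        start = pos_bp + int(rng.integers(50, 401))
        end = start + plen_bp - 1
        pos_bp = end
        gene_specs.append((pid_, contig_id, start, end, strand))
        return start, end

    ordinary = [s for s in specs if s["planting"] != "truncation"]
    truncated = [s for s in specs if s["planting"] == "truncation"]
    emitted = set()
    for spec in ordinary:
        if spec["pid"] in emitted:
            continue
        for _ in range(int(rng.integers(1, 4))):
            n_filler += 1
            add_gene(f"{gid}_F{n_filler:03d}", int(rng.integers(300, 3001)),
                     "+-"[int(rng.integers(0, 2))], contig)
        strand = "+-"[int(rng.integers(0, 2))]
        add_gene(spec["pid"], 3 * (spec["length"] + 1), strand, contig)
        emitted.add(spec["pid"])
        if spec["planting"] == "bipartite":
            partner = next(s for s in specs if s["pid"] == spec["partner"])
            add_gene(partner["pid"], 3 * (partner["length"] + 1), strand, contig)
            emitted.add(partner["pid"])
    for _ in range(int(rng.integers(1, 4))):
        n_filler += 1
        add_gene(f"{gid}_F{n_filler:03d}", int(rng.integers(300, 3001)),
                 "+-"[int(rng.integers(0, 2))], contig)
    # truncation plantings end exactly at their own contig's edge
    for t, spec in enumerate(truncated, 1):
        pos_bp = 1
        add_gene(spec["pid"], 3 * (spec["length"] + 1),
                 "+-"[int(rng.integers(0, 2))], f"Ct{t}")
    for pid_, contig_id, start, end, strand in gene_specs:
        gene_rows.append(f"{pid_}\t{gid}\t{contig_id}\t{start}\t{end}\t{strand}")


def _config_echo(cfg: GeneratorConfig) -> dict:
    echo = asdict(cfg)
    echo["architecture_templates"] = {
        k: {"hpt_copies": {str(c): p for c, p in v.hpt_copies.items()},
            "body": list(v.body), "p_extended_dim": v.p_extended_dim}
        for k, v in cfg.architecture_templates.items()
    }
    echo["chea_per_genome"] = {str(k): v for k, v in cfg.chea_per_genome.items()}
    return echo


# --------------------------------------------------------------------------
# recovery scoring


def planted_statistics(manifest: dict) -> dict:
    """Brute-force tallies of the planted cohort (the oracle side of
    recovery scoring)."""
    cheas = [
        p for p in manifest["proteins"].values()
        if p["planting"] != "bipartite_partner"
    ]
    n = len(cheas)

    def frac(pred) -> Optional[float]:
        return (sum(1 for p in cheas if pred(p)) / n) if n else None

    def count_label(p, label):
        return sum(1 for d in p["domains"] if d["label"] == label)

    genomes = manifest["genomes"].values()
    eligible = [g for g in genomes if g["sink_eligible"]]
    lacking = [
        g for g in eligible if not any(g["phosphatase_presence"].values())
    ]
    return {
        "n_chea": n,
        "classical_fraction": frac(
            lambda p: p["planted_architecture"] == CLASSICAL_ARCHITECTURE
        ),
        "dual_chew_fraction": frac(lambda p: count_label(p, CHEW) >= 2),
        "multi_hpt_fraction": frac(lambda p: count_label(p, HPT) >= 2),
        "cheylike_fraction": frac(lambda p: count_label(p, CHEY_LIKE) >= 1),
        "hpt_presence_fraction": frac(lambda p: count_label(p, HPT) >= 1),
        "sink_n_eligible": len(eligible),
        "sink_fraction": (len(lacking) / len(eligible)) if eligible else None,
    }


def evaluate_against_truth(
    summary, manifest: dict, architectures: Optional[dict[str, str]] = None
) -> dict:
    """Planted-vs-observed comparison for every cohort statistic.

    ``summary`` is a cohort_stats.CohortSummary computed from the generated
    cohort; ``architectures`` optionally maps protein_id -> observed
    canonical string, enabling the exact-match accuracy score. Each
    statistic reports planted value, observed value, absolute error, and
    whether the observation falls in the 99% binomial interval around the
    planted rate at the observed denominator.
    """
    from scipy.stats import binom

    planted = planted_statistics(manifest)
    n = summary.n_chea

    def check(name, planted_p, observed, denom):
        if planted_p is None or observed is None:
            return {"planted": planted_p, "observed": observed,
                    "abs_error": None, "within_99ci": None, "n": denom}
        lo, hi = binom.interval(0.99, denom, planted_p)
        return {
            "planted": planted_p,
            "observed": observed,
            "abs_error": abs(observed - planted_p),
            "within_99ci": bool(lo / denom <= observed <= hi / denom),
            "n": denom,
        }

    freq = summary.domain_frequency
    report = {
        "classical_fraction": check(
            "classical", planted["classical_fraction"],
            summary.architecture_frequency.get(CLASSICAL_ARCHITECTURE, 0.0), n),
        "dual_chew_fraction": check(
            "dual_chew", planted["dual_chew_fraction"],
            freq.get(CHEW, {}).get("fraction_with_gt1"), n),
        "multi_hpt_fraction": check(
            "multi_hpt", planted["multi_hpt_fraction"],
            freq.get(HPT, {}).get("fraction_with_gt1"), n),
        "cheylike_fraction": check(
            "cheylike", planted["cheylike_fraction"],
            freq.get(CHEY_LIKE, {}).get("fraction_with_ge1"), n),
        "phosphate_sink_fraction": check(
            "sink", planted["sink_fraction"],
            summary.phosphate_sink.get("fraction"),
            max(summary.phosphate_sink.get("n_eligible", 0), 1)),
    }
    if architectures is not None:
        planted_arch = {
            pid: p["planted_architecture"]
            for pid, p in manifest["proteins"].items()
        }
        if set(architectures) != set(planted_arch):
            raise ManifestMismatch(
                f"{len(architectures)} observed vs {len(planted_arch)} planted proteins"
            )
        correct = sum(
            1 for pid, arch in architectures.items() if arch == planted_arch[pid]
        )
        report["architecture_accuracy"] = {
            "planted": 1.0,
            "observed": correct / len(planted_arch) if planted_arch else None,
            "n": len(planted_arch),
        }
    return report
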