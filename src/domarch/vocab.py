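"""Unified domain vocabulary.

Pfam represents some CheA domains by more than one model: the docking
domain has two clan-mate models (P2 built on Thermotoga-like sequences,
CheY-binding on E. coli-like ones) that are one domain; receiver domains
appear as Response_reg or other CheY-like-superfamily members; CheC and
CheX are clan mates with the same fold. This module collapses model names
onto the unified labels used everywhere downstream:

    Hpt, P2/CheY-binding, H-kinase_dim, HATPase_c, CheW, CheY-like,
    CheC/CheX, other:<model_name>

Unknown models fall through to ``other:<model_name>`` so the mapping is a
total function.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import IO, Mapping

HPT = "Hpt"
P2 = "P2/CheY-binding"
DIM = "H-kinase_dim"
KINASE = "HATPase_c"
CHEW = "CheW"
CHEY_LIKE = "CheY-like"
CHEC_CHEX = "CheC/CheX"

CANONICAL_LABELS = (HPT, P2, DIM, KINASE, CHEW)
CLASSICAL_ARCHITECTURE = "|".join(CANONICAL_LABELS)

CLASS_LABELS = tuple(f"F{i}" for i in range(1, 18)) + ("ACF", "Tfp", "unknown")

_DEFAULT_MAPPING: dict[str, str] = {
    "Hpt": HPT,
    "HPT": HPT,
    "P2": P2,
    "CheY-binding": P2,
    "H-kinase_dim": DIM,
    "H_kinase_dim": DIM,
    "HATPase_c": KINASE,
    "CheW": CHEW,
    "CheW_2": CHEW,
    "Response_reg": CHEY_LIKE,
    "CheY-like": CHEY_LIKE,
    "CheC": CHEC_CHEX,
    "CheX": CHEC_CHEX,
}


@dataclass
class DomainVocabulary:
    """Total mapping model name/accession -> unified label."""

    mapping: Mapping[str, str] = field(default_factory=lambda: dict(_DEFAULT_MAPPING))

    def map_label(self, model_name: str) -> str:
        return self.mapping.get(model_name, f"other:{model_name}")

    @classmethod
    def from_tsv(cls, stream: IO[str]) -> "DomainVocabulary":
        """Load a two-column ``model_name<TAB>unified_label`` table."""
        mapping = {}
        for line in stream:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            model, label = line.split("\t")[:2]
            mapping[model] = label
        return cls(mapping=mapping)

    @classmethod
    def default(cls) -> "DomainVocabulary":
        """Vocabulary shipped with the package (data/vocabulary.tsv)."""
        ref = resources.files("domarch").joinpath("data/vocabulary.tsv")
        with ref.open("r") as fh:
            return cls.from_tsv(fh)


def map_label(model_name: str, vocab: DomainVocabulary | None = None) -> str:
    """Map a model name to its unified label (total function)."""
    return (vocab or DomainVocabulary()).map_label(model_name)
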