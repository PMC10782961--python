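"""Shared builders for hit-level and architecture-level tests."""

from __future__ import annotations

import numpy as np
import pytest

from domarch.arch_resolve import Thresholds, hit_score
from domarch.hit_io import HMMER, PROFILE_PROFILE, DomainHit


def make_hit(
    pid="P001",
    model="CheW",
    env=(10, 160),
    hmm=None,
    model_length=None,
    score=55.0,
    i_evalue=1e-10,
    probability=None,
    source=HMMER,
    ali=None,
):
    """A valid DomainHit with sensible defaults (ali == env)."""
    if model_length is None:
        model_length = (hmm[1] if hmm else 140)
    if hmm is None:
        hmm = (1, model_length)
    ali = ali or env
    if source == PROFILE_PROFILE:
        return DomainHit(
            protein_id=pid, model_name=model, model_accession="",
            source=source, probability=probability if probability is not None else 95.0,
            env_start=env[0], env_end=env[1], ali_start=ali[0], ali_end=ali[1],
            hmm_start=hmm[0], hmm_end=hmm[1], model_length=model_length,
        )
    return DomainHit(
        protein_id=pid, model_name=model, model_accession="",
        source=source, score=score, i_evalue=i_evalue,
        env_start=env[0], env_end=env[1], ali_start=ali[0], ali_end=ali[1],
        hmm_start=hmm[0], hmm_end=hmm[1], model_length=model_length,
    )


def brute_force_max_score(hits, t: Thresholds) -> float:
    """Exhaustive maximum-total-score compatible subset (oracle for
    resolve_overlaps); subset validity tracked incrementally by bitmask."""
    n = len(hits)
    conflict = [0] * n
    for a in range(n):
        for b in range(a + 1, n):
            ov = (min(hits[a].env_end, hits[b].env_end)
                  - max(hits[a].env_start, hits[b].env_start) + 1)
            if ov > t.overlap_tol:
                conflict[a] |= 1 << b
                conflict[b] |= 1 << a
    scores = [hit_score(h) for h in hits]
    best = 0.0
    valid = np.ones(1 << n, dtype=bool)
    totals = np.zeros(1 << n)
    for s in range(1, 1 << n):
        low = (s & -s).bit_length() - 1
        rest = s & (s - 1)
        valid[s] = valid[rest] and not (conflict[low] & rest)
        if valid[s]:
            totals[s] = totals[rest] + scores[low]
            if totals[s] > best:
                best = totals[s]
    return best


def random_hit_instance(rng: np.random.Generator, max_hits=10):
    """A random single-protein hit list mixing both evidence tiers."""
    n = int(rng.integers(1, max_hits + 1))
    hits = []
    for _ in range(n):
        s = int(rng.integers(1, 350))
        length = int(rng.integers(30, 200))
        model = str(rng.choice(["CheW", "Hpt", "HATPase_c", "PAS"]))
        if rng.random() < 0.2:
            hits.append(make_hit(
                model=model, env=(s, s + length - 1), hmm=(1, min(length, 120)),
                model_length=120 if length >= 120 else length,
                probability=float(rng.uniform(90.0, 99.9)),
                source=PROFILE_PROFILE,
            ))
        else:
            hits.append(make_hit(
                model=model, env=(s, s + length - 1), hmm=(1, min(length, 120)),
                model_length=120 if length >= 120 else length,
                score=float(rng.uniform(10.0, 120.0)), i_evalue=1e-10,
            ))
    return hits


@pytest.fixture
def thresholds():
    return Thresholds()
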