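"""Sequence similarity: percent identity, the HSSP-curve distance HVAL,
redundancy reduction of interaction sets, and constrained negative sampling.

HVAL measures how far an alignment sits above the length-dependent HSSP
homology-threshold curve, in percentage-identity points.  HVAL > 20 marks a
pair as clearly homologous; the redundancy reducer removes interactions whose
proteins reach HVAL > 20 to anything already kept, and the negative sampler
only pairs proteins with HVAL < 20 to every positive-set protein (so a
homology shortcut can never link negatives to positives).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._align import global_alignment
from .io_formats import EvidencedInteraction, ProteinRecord, canonical_pair


@dataclass(frozen=True)
class AlignmentSummary:
    """Percent identity (over all aligned columns, gaps included) and alignment length."""

    pide: float
    length: int
    score: float = 0.0
    identities: int = 0

    def __post_init__(self):
        if not 0.0 <= self.pide <= 100.0:
            raise ValueError(f"pide {self.pide} outside [0, 100]")
        if self.length < 1:
            raise ValueError("alignment length must be >= 1")


@dataclass
class SamplingConfig:
    """Negative-sampling parameters: 10 negatives per positive by default,
    endpoints constrained to HVAL < 20 against all positive-set proteins."""

    negative_ratio: int = 10
    hval_similar_cut: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if self.negative_ratio < 1:
            raise ValueError("negative_ratio must be >= 1")


def align_identity(seq_a: str, seq_b: str) -> AlignmentSummary:
    """Global Needleman-Wunsch alignment (BLOSUM62, gap open 10 / extend 0.5).

    ``pide = 100 * identities / alignment_length`` with the alignment length
    counting every column, gapped columns included.  Symmetric in its
    arguments by construction.
    """
    score, identities, length = global_alignment(seq_a, seq_b)
    return AlignmentSummary(
        pide=100.0 * identities / length,
        length=length,
        score=score,
        identities=identities,
    )


def hssp_threshold(length: int) -> float:
    """Percent-identity homology threshold of the HSSP curve at a given
    alignment length.

    100 for length <= 11; ``480 * L**(-0.32 * (1 + exp(-L / 1000)))`` for
    11 < L <= 450; constant 19.5 beyond 450 residues.
    """
    if length < 1:
        raise ValueError("alignment length must be positive")
    if length <= 11:
        return 100.0
    if length > 450:
        return 19.5
    return 480.0 * length ** (-0.32 * (1.0 + math.exp(-length / 1000.0)))


def hval(seq_a: str, seq_b: str) -> float:
    """HSSP-curve distance: pide minus the curve threshold at the alignment length."""
    summary = align_identity(seq_a, seq_b)
    return summary.pide - hssp_threshold(summary.length)


class HvalCache:
    """Memoizes HVALs by unordered id pair within one pipeline run.

    Purely an efficiency device; results are identical with or without it.
    """

    def __init__(self, sequences: Mapping[str, str]):
        self._sequences = sequences
        self._cache: dict[tuple[str, str], float] = {}

    def __call__(self, id_a: str, id_b: str) -> float:
        key = canonical_pair(id_a, id_b)
        if key not in self._cache:
            self._cache[key] = hval(self._sequences[key[0]], self._sequences[key[1]])
        return self._cache[key]


def reduce_redundancy(
    interactions: Sequence[EvidencedInteraction],
    sequences: Mapping[str, str],
    hval_similar_cut: float = 20.0,
) -> list[EvidencedInteraction]:
    """Greedy redundancy reduction of an interaction set.

    Interactions are visited sorted by descending evidence score and then by
    pair id (so the best-evidenced representative of each similarity cluster
    survives and the pass is independent of input file order).  An interaction
    is retained iff both of its proteins have HVAL <= cut to every protein of
    every previously retained interaction.
    """
    for inter in interactions:
        for pid in inter.pair:
            if pid not in sequences:
                raise KeyError(f"no sequence for interaction partner {pid!r}")

    ordered = sorted(interactions, key=lambda it: (-it.max_score(), it.pair))
    cache = HvalCache(sequences)
    retained: list[EvidencedInteraction] = []
    retained_proteins: list[str] = []
    retained_seen: set[str] = set()
    for inter in ordered:
        ok = True
        for pid in inter.pair:
            if pid in retained_seen:
                ok = False
                break
            if any(cache(pid, rid) > hval_similar_cut for rid in retained_proteins):
                ok = False
                break
        if ok:
            retained.append(inter)
            for pid in set(inter.pair):
                if pid not in retained_seen:
                    retained_seen.add(pid)
                    retained_proteins.append(pid)
    return retained


def eligible_dissimilar_proteins(
    proteome: Sequence[ProteinRecord],
    positive_proteins: Mapping[str, str],
    hval_cut: float = 20.0,
    cache: HvalCache | None = None,
) -> list[str]:
    """Proteins of the proteome with HVAL < cut to every positive-set protein.

    Shared by negative sampling and interactome candidate enumeration, which
    both require candidates dissimilar to everything used as a positive.
    """
    if cache is None:
        sequences = dict(positive_proteins)
        for rec in proteome:
            sequences.setdefault(rec.id, rec.sequence)
        cache = HvalCache(sequences)
    eligible = []
    for rec in proteome:
        if rec.id in positive_proteins:
            continue  # HVAL to itself is far above any sensible cut
        if all(cache(rec.id, pid) < hval_cut for pid in positive_proteins):
            eligible.append(rec.id)
    return eligible


def sample_negatives(
    positives: Sequence[EvidencedInteraction] | Sequence[tuple[str, str]],
    proteome: Sequence[ProteinRecord],
    config: SamplingConfig,
) -> list[tuple[str, str]]:
    """Sample negative pairs uniformly among eligible protein combinations.

    Returns exactly ``negative_ratio * len(positives)`` distinct unordered
    pairs, none equal to a positive pair, with both endpoints at HVAL < cut to
    every protein of the positive set.  Reproducible from ``config.seed``.
    """
    positive_pairs = {
        p.pair if isinstance(p, EvidencedInteraction) else canonical_pair(*p)
        for p in positives
    }
    positive_ids = {pid for pair in positive_pairs for pid in pair}
    seq_by_id = {rec.id: rec.sequence for rec in proteome}
    missing = positive_ids - seq_by_id.keys()
    if missing:
        raise KeyError(f"positive proteins missing from proteome: {sorted(missing)[:5]}")
    positive_seqs = {pid: seq_by_id[pid] for pid in positive_ids}

    pool = eligible_dissimilar_proteins(proteome, positive_seqs, config.hval_similar_cut)
    n_needed = config.negative_ratio * len(positive_pairs)
    n = len(pool)
    n_pairs = n * (n - 1) // 2
    available = n_pairs - sum(1 for p in positive_pairs if p[0] in pool and p[1] in pool)
    if available < n_needed:
        raise ValueError(
            f"cannot sample {n_needed} negatives: only {available} eligible pairs "
            f"({n} eligible proteins after the HVAL < {config.hval_similar_cut} constraint)"
        )

    rng = np.random.default_rng(config.seed)
    pool = sorted(pool)  # independence from proteome ordering
    chosen: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    if available <= 4 * n_needed:
        # dense regime: enumerate and draw without replacement
        all_pairs = [
            (pool[i], pool[j])
            for i in range(n)
            for j in range(i + 1, n)
            if (pool[i], pool[j]) not in positive_pairs
        ]
        idx = rng.choice(len(all_pairs), size=n_needed, replace=False)
        chosen = [all_pairs[i] for i in idx]
    else:
        while len(chosen) < n_needed:
            i, j = rng.integers(0, n, size=2)
            if i == j:
                continue
            pair = canonical_pair(pool[i], pool[j])
            if pair in seen or pair in positive_pairs:
                continue
            seen.add(pair)
            chosen.append(pair)
    return chosen
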