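"""Whole-interactome prediction: candidate enumeration among proteins
dissimilar to the training positives, batched all-vs-all scoring, top-set
selection at about 10 interactions per protein, and accuracy bookkeeping
against an external reference set."""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .io_formats import PredictionRecord, ProteinRecord, canonical_pair
from .kernel import PairVector, kmer_features, pair_vector
from .model import PairKernelModel, predict
from .profiles import ProfileStore
from .similarity import eligible_dissimilar_proteins

logger = logging.getLogger(__name__)


@dataclass
class CandidateSet:
    """Eligible proteins for whole-interactome scoring and why others dropped out."""

    eligible: list[str]
    exclusions: dict[str, str] = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        n = len(self.eligible)
        return n * (n - 1) // 2

    def pairs(self) -> Iterator[tuple[str, str]]:
        ordered = sorted(self.eligible)
        return itertools.combinations(ordered, 2)


def candidate_pairs(
    proteome: Sequence[ProteinRecord],
    positive_proteins: Mapping[str, str],
    hval_cut: float = 20.0,
) -> CandidateSet:
    """Candidates = all pairs among proteins with HVAL < cut to every protein
    that appeared in a training positive (so no prediction can lean on a
    homolog of something the model was trained on)."""
    eligible = eligible_dissimilar_proteins(proteome, positive_proteins, hval_cut)
    eligible_set = set(eligible)
    exclusions = {}
    for rec in proteome:
        if rec.id in eligible_set:
            continue
        reason = (
            "member of a training positive"
            if rec.id in positive_proteins
            else f"HVAL >= {hval_cut} to a training positive"
        )
        exclusions[rec.id] = reason
    return CandidateSet(eligible=eligible, exclusions=exclusions)


def predict_all(
    model: PairKernelModel,
    candidates: CandidateSet,
    proteome: Sequence[ProteinRecord],
    profiles: ProfileStore,
    batch_size: int = 10_000,
) -> list[PredictionRecord]:
    """Score every candidate pair and return records ranked by probability.

    Per-protein feature vectors are computed once and reused across all their
    pairs; scoring proceeds in batches of ``batch_size`` pairs.  The output is
    sorted by descending probability, ties broken by pair id, with 1-based
    ranks assigned after the sort.  Batch size never changes the result.
    """
    by_id = {rec.id: rec for rec in proteome}
    vectors = {}
    for pid in candidates.eligible:
        profile = profiles.get(by_id[pid])
        vectors[pid] = kmer_features(profile, model.hp)

    scored: list[tuple[float, float, str, str]] = []
    batch: list[tuple[str, str]] = []

    def flush():
        if not batch:
            return
        pair_vecs = [pair_vector(vectors[a], vectors[b]) for a, b in batch]
        decision, probs = predict(model, pair_vecs)
        for (a, b), d, p in zip(batch, decision, probs):
            scored.append((float(p), float(d), a, b))
        batch.clear()

    for a, b in candidates.pairs():
        batch.append(canonical_pair(a, b))
        if len(batch) >= batch_size:
            flush()
    flush()

    scored.sort(key=lambda t: (-t[0], t[2], t[3]))
    return [
        PredictionRecord(id_a=a, id_b=b, decision_value=d, probability=p, rank=i + 1)
        for i, (p, d, a, b) in enumerate(scored)
    ]


def select_top(
    predictions: Sequence[PredictionRecord],
    n_proteins: int,
    per_protein: int = 10,
    round_to: int | None = None,
) -> list[PredictionRecord]:
    """Global top predictions with a budget of about per_protein per protein.

    The exact budget is ``per_protein * n_proteins``; ``round_to`` optionally
    rounds the budget down to a multiple (published prediction sets are
    conventionally round numbers).  Fewer candidates than the budget returns
    everything.
    """
    if per_protein < 1:
        raise ValueError("per_protein must be >= 1")
    budget = per_protein * n_proteins
    if round_to:
        budget = max(round_to, (budget // round_to) * round_to)
    ordered = sorted(predictions, key=lambda r: (-r.probability, r.id_a, r.id_b))
    return ordered[:budget]


@dataclass
class ComparisonReport:
    """Accuracy of predictions against an external reference set.

    accuracy = 100 * n_correct / n_evidence (percent, undefined without
    evidenced predictions).
    """

    n_pred: int
    n_evidence: int
    n_correct: int

    def __post_init__(self):
        if not 0 <= self.n_correct <= self.n_evidence <= self.n_pred:
            raise ValueError(
                f"inconsistent counts: correct {self.n_correct} <= evidenced "
                f"{self.n_evidence} <= checked {self.n_pred} must hold"
            )

    @property
    def accuracy(self) -> float | None:
        if self.n_evidence == 0:
            return None
        return round(100.0 * self.n_correct / self.n_evidence, 2)


def compare_with_reference(
    predictions: Sequence[PredictionRecord],
    reference: Mapping[tuple[str, str], bool],
    probability_threshold: float = 0.5,
) -> ComparisonReport:
    """Tally predictions against reference interact / not-interact calls.

    A prediction counts as evidenced when its pair appears in the reference;
    it counts as correct when its predicted class (probability >= threshold)
    matches the reference call.
    """
    ref = {canonical_pair(*pair): bool(call) for pair, call in reference.items()}
    n_evidence = 0
    n_correct = 0
    for rec in predictions:
        call = ref.get((rec.id_a, rec.id_b))
        if call is None:
            continue
        n_evidence += 1
        predicted = rec.probability >= probability_threshold
        if predicted == call:
            n_correct += 1
    return ComparisonReport(n_pred=len(predictions), n_evidence=n_evidence, n_correct=n_correct)
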