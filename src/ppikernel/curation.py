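"""Data-quality pipeline: evidence scoring, the >= 5 reliability filter,
mapping of interaction partners onto a reference proteome, and tiering of
organisms by how many non-redundant interactions they retain.

Boundary semantics follow the curation protocol exactly: evidence ">= 5" and
mapping identity "at least 95%" and the 200-interaction floor are inclusive;
the grid-search tier requires strictly "more than 500".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

from .io_formats import EvidencedInteraction, ProteinRecord
from .similarity import align_identity

logger = logging.getLogger(__name__)


@dataclass
class CurationConfig:
    min_evidence_score: float = 5.0
    min_mapping_identity: float = 95.0
    min_ppis_per_organism: int = 200
    grid_search_min_ppis: int = 500

    def __post_init__(self):
        if not 1.0 <= self.min_evidence_score <= 10.0:
            raise ValueError("min_evidence_score must be within [1, 10]")
        if not 0.0 < self.min_mapping_identity <= 100.0:
            raise ValueError("min_mapping_identity must be within (0, 100]")
        if self.min_ppis_per_organism > self.grid_search_min_ppis:
            raise ValueError("min_ppis_per_organism must not exceed grid_search_min_ppis")


class OrganismTier(str, Enum):
    """Training regime an organism qualifies for, by non-redundant PPI count."""

    NONE = "none"
    FIXED_HYPERPARAMS = "fixed_hyperparams"
    GRID_SEARCH = "grid_search"


def evidence_score(interaction: EvidencedInteraction) -> float:
    """Reliability of an interaction: the maximum score over its evidence entries."""
    return interaction.max_score()


def filter_by_evidence(
    interactions: Sequence[EvidencedInteraction], config: CurationConfig
) -> list[EvidencedInteraction]:
    """Keep interactions with at least one experimental evidence >= the threshold.

    Input order is preserved; the filter is a fixed point on its own output.
    """
    return [
        inter
        for inter in interactions
        if evidence_score(inter) >= config.min_evidence_score
    ]


def map_to_reference(
    protein: ProteinRecord,
    reference_proteome: Sequence[ProteinRecord],
    config: CurationConfig,
) -> str | None:
    """Map a protein onto the reference proteome by highest percent identity.

    Returns the best-matching reference id provided the identity reaches
    ``min_mapping_identity`` (inclusive); ties go to the lexicographically
    smallest reference id; returns None when nothing aligns well enough.
    """
    if not reference_proteome:
        raise ValueError("reference proteome is empty")
    best_id: str | None = None
    best_pide = -1.0
    for ref in reference_proteome:
        pide = align_identity(protein.sequence, ref.sequence).pide
        if pide > best_pide or (pide == best_pide and (best_id is None or ref.id < best_id)):
            best_id, best_pide = ref.id, pide
    if best_pide >= config.min_mapping_identity:
        return best_id
    logger.info(
        "protein %s unmapped: best identity %.1f%% below %.1f%%",
        protein.id,
        best_pide,
        config.min_mapping_identity,
    )
    return None


def map_interactions_to_reference(
    interactions: Sequence[EvidencedInteraction],
    sequences: Mapping[str, str],
    reference_proteome: Sequence[ProteinRecord],
    config: CurationConfig,
) -> list[EvidencedInteraction]:
    """Re-key interactions onto reference-proteome ids; drop unmappable pairs.

    Pairs whose partners collapse onto a single reference protein become self
    pairs and are discarded along with unmapped ones (both are logged).
    """
    mapping: dict[str, str | None] = {}
    mapped = []
    for inter in interactions:
        ids = []
        for pid in inter.pair:
            if pid not in mapping:
                mapping[pid] = map_to_reference(
                    ProteinRecord(pid, sequences[pid]), reference_proteome, config
                )
            ids.append(mapping[pid])
        if ids[0] is None or ids[1] is None:
            logger.info("interaction %s dropped: unmappable partner", inter.pair)
            continue
        if ids[0] == ids[1]:
            logger.info("interaction %s collapsed to a self pair; dropped", inter.pair)
            continue
        mapped.append(EvidencedInteraction(ids[0], ids[1], list(inter.evidence)))
    return mapped


def select_model_organisms(
    per_organism_counts: Mapping[str, int], config: CurationConfig
) -> dict[str, OrganismTier]:
    """Tier organisms by non-redundant interaction count.

    Fewer than 200 -> no model; 200..500 -> fixed default hyperparameters with
    cross-validation only; more than 500 -> full hyperparameter grid search.
    """
    tiers = {}
    for organism, count in per_organism_counts.items():
        if count < 0:
            raise ValueError(f"negative PPI count for {organism!r}")
        if count < config.min_ppis_per_organism:
            tiers[organism] = OrganismTier.NONE
        elif count <= config.grid_search_min_ppis:
            tiers[organism] = OrganismTier.FIXED_HYPERPARAMS
        else:
            tiers[organism] = OrganismTier.GRID_SEARCH
    return tiers
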