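"""Published per-organism reference statistics for the eight model organisms.

These numbers are inputs to the bookkeeping arithmetic (candidate-pair counts,
published prediction-set budgets, accuracy-versus-reference tallies), not
outputs of this package: proteome sizes come from the EBI reference proteomes,
the remaining columns from the published whole-interactome prediction runs and
their comparison against an external evidence set.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class OrganismStats:
    name: str
    proteome_size: int               # proteins in the reference proteome
    eligible_proteins: int           # proteins dissimilar to all training positives
    candidate_pairs: int             # all pairs among eligible proteins
    published_budget: int            # size of the published top-prediction set
    n_evidence: int | None = None    # published predictions with external evidence
    n_correct: int | None = None     # evidenced predictions classified correctly


ORGANISMS: dict[str, OrganismStats] = {
    "A. thaliana": OrganismStats("A. thaliana", 27064, 20320, 206441040, 250000, 1138, 1138),
    "C. elegans": OrganismStats("C. elegans", 20137, 16863, 142171953, 200000, 1818, 1671),
    "D. melanogaster": OrganismStats("D. melanogaster", 13707, 7990, 31916055, 100000, 2049, 1763),
    "E. coli": OrganismStats("E. coli", 4306, 2337, 2729616, 40000, 2196, 1807),
    "M. musculus": OrganismStats("M. musculus", 22136, 16207, 131325321, 200000, 0, 0),
    "P. falciparum": OrganismStats("P. falciparum", 5159, 4253, 9041878, 50000, 0, 0),
    "S. pombe": OrganismStats("S. pombe", 5121, 4087, 8349741, 50000, 1447, 1088),
    "R. norvegicus": OrganismStats("R. norvegicus", 21330, 20588, 211922578, 200000, 0, 0),
}

#: Aggregate over the eight organisms: evidenced predictions and correct calls.
AGGREGATE_EVIDENCE = (8648, 7467)
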