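"""Synthetic organisms with planted interaction signal.

Generates proteomes (homolog families plus unrelated singletons), evidence-
annotated interactions carrying a learnable sequence signal (pairs of short
motifs written into interacting partners), and profile fixtures — so every
pipeline stage is exercisable without any database download.

Statistical design: family founders are i.i.d. uniform over the 20 residues;
family members substitute each founder position independently at the family
mutation rate.  At the default rate (0.15, length ~250) family members stay
far above the HSSP curve (HVAL > 20, clearly homologous) while unrelated
random sequences share only ~5% identity and stay far below it — mirroring
the homology structure that redundancy reduction and negative sampling
assume.  Network structure is deliberately absent: the prediction method
itself ignores it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (
    EvidencedInteraction,
    ProteinRecord,
    STANDARD_AA,
    ScoreTable,
    write_fasta,
    write_interactions,
)
from .profiles import ProfileStore, pseudo_profile, save_profile

#: Miniature experimental-method reliability table used for generated evidence.
MINI_SCORE_TABLE = {
    "x-ray crystallography": 10.0,
    "electron tomography": 9.0,
    "enzyme linked immunosorbent assay": 5.0,
    "blue native page": 3.0,
    "pull down": 2.5,
}

_PASSING_METHODS = [m for m, s in MINI_SCORE_TABLE.items() if s >= 5.0]
_FAILING_METHODS = [m for m, s in MINI_SCORE_TABLE.items() if s < 5.0]


@dataclass
class SyntheticSpec:
    """Generation parameters for one synthetic organism.

    Defaults give 500 proteins of 200-300 residues, 50 two-member homolog
    families (per-residue substitution rate 0.15, keeping within-family HVAL
    comfortably above 20), 50 planted interactions sharing 4 distinct motif
    pairs of length 4, and evidence such that a fifth of the planted
    interactions fail the reliability filter.
    """

    n_proteins: int = 500
    length_range: tuple[int, int] = (200, 300)
    n_families: int = 50
    family_size: int = 2
    mutation_rate: float = 0.15
    n_positives: int = 50
    motif_length: int = 4
    n_motif_pairs: int = 4
    fraction_failing: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be within [0, 1]")
        if not 0.0 <= self.fraction_failing <= 1.0:
            raise ValueError("fraction_failing must be within [0, 1]")
        if self.n_families * self.family_size > self.n_proteins:
            raise ValueError("families do not fit into the proteome")
        if self.motif_length > self.length_range[0]:
            raise ValueError("motif longer than the shortest sequence")
        if 2 * self.n_positives > self.n_proteins:
            raise ValueError("not enough proteins for disjoint planted interactions")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(STANDARD_AA[i] for i in rng.integers(0, 20, size=length))


def _mutate(rng: np.random.Generator, founder: str, rate: float) -> str:
    out = []
    for ch in founder:
        if rng.random() < rate:
            out.append(STANDARD_AA[int(rng.integers(0, 20))])
        else:
            out.append(ch)
    return "".join(out)


def simulate_proteome(spec: SyntheticSpec) -> tuple[list[ProteinRecord], dict[str, int | None]]:
    """Generate the proteome: family members first, then independent singletons.

    Returns the records and a map protein id -> family index (None for
    singletons).  Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 1)))
    records: list[ProteinRecord] = []
    family_of: dict[str, int | None] = {}
    lo, hi = spec.length_range
    counter = 0
    for fam in range(spec.n_families):
        founder = _random_sequence(rng, int(rng.integers(lo, hi + 1)))
        for member in range(spec.family_size):
            counter += 1
            pid = f"sp{counter:05d}"
            seq = founder if member == 0 else _mutate(rng, founder, spec.mutation_rate)
            records.append(ProteinRecord(pid, seq))
            family_of[pid] = fam
    while counter < spec.n_proteins:
        counter += 1
        pid = f"sp{counter:05d}"
        records.append(ProteinRecord(pid, _random_sequence(rng, int(rng.integers(lo, hi + 1)))))
        family_of[pid] = None
    return records, family_of


@dataclass
class PlantedTruth:
    """Ground truth of one generated interaction set."""

    motif_pairs: list[tuple[str, str]]
    motif_of_pair: dict[tuple[str, str], tuple[str, str]] = field(default_factory=dict)
    passes_filter: dict[tuple[str, str], bool] = field(default_factory=dict)


def plant_interactions(
    proteome: list[ProteinRecord], spec: SyntheticSpec
) -> tuple[list[ProteinRecord], list[EvidencedInteraction], PlantedTruth]:
    """Plant interactions carrying motif-pair signal into the proteome.

    Picks ``2 * n_positives`` distinct proteins (each protein participates in
    at most one interaction, so the planted set is already redundancy-free for
    unrelated partners), writes one motif of a randomly chosen motif pair into
    each partner at a random position, and attaches evidence so that a
    ``fraction_failing`` share of the interactions carries only low-score
    evidence.  Returns the modified proteome, the interactions, and the
    ground truth.
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 2)))
    motif_pairs = [
        (_random_sequence(rng, spec.motif_length), _random_sequence(rng, spec.motif_length))
        for _ in range(spec.n_motif_pairs)
    ]
    truth = PlantedTruth(motif_pairs=motif_pairs)

    chosen = rng.choice(len(proteome), size=2 * spec.n_positives, replace=False)
    sequences = {rec.id: rec.sequence for rec in proteome}
    interactions: list[EvidencedInteraction] = []
    n_failing = int(round(spec.fraction_failing * spec.n_positives))

    for i in range(spec.n_positives):
        rec_a = proteome[chosen[2 * i]]
        rec_b = proteome[chosen[2 * i + 1]]
        m1, m2 = motif_pairs[int(rng.integers(0, spec.n_motif_pairs))]
        for rec, motif in ((rec_a, m1), (rec_b, m2)):
            seq = sequences[rec.id]
            pos = int(rng.integers(0, len(seq) - spec.motif_length + 1))
            sequences[rec.id] = seq[:pos] + motif + seq[pos + spec.motif_length :]
        failing = i < n_failing
        if failing and _FAILING_METHODS:
            methods = [_FAILING_METHODS[int(rng.integers(0, len(_FAILING_METHODS)))]]
        else:
            methods = [_PASSING_METHODS[int(rng.integers(0, len(_PASSING_METHODS)))]]
            if rng.random() < 0.3:  # occasional second, weaker evidence line
                methods.append(_FAILING_METHODS[int(rng.integers(0, len(_FAILING_METHODS)))])
        evidence = [(m, MINI_SCORE_TABLE[m]) for m in methods]
        inter = EvidencedInteraction(rec_a.id, rec_b.id, evidence)
        interactions.append(inter)
        truth.motif_of_pair[inter.pair] = (m1, m2)
        truth.passes_filter[inter.pair] = not failing

    updated = [ProteinRecord(rec.id, sequences[rec.id]) for rec in proteome]
    return updated, interactions, truth


def synthetic_pssm(
    protein: ProteinRecord, seed: int = 0, concentration: float = 20.0
) -> np.ndarray:
    """Integer percentage table (L x 20, PSI-BLAST column convention is up to
    the writer) emulating a profile peaked on the query sequence.

    Rows are Dirichlet draws centred on the query residue, scaled to integer
    percentages — the level of quantization an ASCII PSSM actually carries.
    """
    import zlib

    from .profiles import AA_ORDER

    rng = np.random.default_rng(
        np.random.SeedSequence((seed, zlib.crc32(protein.id.encode())))
    )
    L = len(protein.sequence)
    pct = np.zeros((L, 20), dtype=np.int64)
    for i, residue in enumerate(protein.sequence):
        alpha = np.ones(20)
        idx = AA_ORDER.index(residue) if residue in AA_ORDER else None
        if idx is not None:
            alpha[idx] = concentration
        row = rng.dirichlet(alpha)
        pct[i] = np.floor(row * 100).astype(np.int64)
    return pct


def generate_dataset(spec: SyntheticSpec):
    """Convenience wrapper: proteome with planted signal, interactions, truth."""
    proteome, families = simulate_proteome(spec)
    proteome, interactions, truth = plant_interactions(proteome, spec)
    return proteome, families, interactions, truth


def write_dataset(spec: SyntheticSpec, out_dir, profile_alpha: float | None = 0.1) -> dict:
    """Materialize a synthetic organism on disk.

    Writes proteome FASTA, interactions TSV, the miniature score table, and
    (when ``profile_alpha`` is not None) one profile TSV per protein derived
    from the sequence alone.  Returns the paths written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    proteome, families, interactions, truth = generate_dataset(spec)

    fasta = out_dir / "proteome.fasta"
    write_fasta(proteome, fasta)
    inter_path = out_dir / "interactions.tsv"
    write_interactions(interactions, inter_path)
    scores_path = out_dir / "scores.tsv"
    ScoreTable(MINI_SCORE_TABLE).to_tsv(scores_path)

    profile_dir = None
    if profile_alpha is not None:
        profile_dir = out_dir / "profiles"
        profile_dir.mkdir(exist_ok=True)
        for rec in proteome:
            save_profile(pseudo_profile(rec, profile_alpha), profile_dir)

    return {
        "fasta": fasta,
        "interactions": inter_path,
        "scores": scores_path,
        "profiles": profile_dir,
        "n_proteins": len(proteome),
        "n_interactions": len(interactions),
    }
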