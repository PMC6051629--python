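"""Per-protein evolutionary profiles.

A profile is an L x 20 table of per-position amino-acid probabilities derived
from a multiple alignment of homologs (in practice PSI-BLAST weighted
percentages).  The kernel consumes profiles through their negative natural
log, so every entry is floored at a small epsilon before renormalization: a
conservation score must stay finite even for residues never observed.

When no PSSM exists, :func:`pseudo_profile` builds a profile from the sequence
alone by mixing a point mass on the observed residue with the BLOSUM62
conditional substitution distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

from .io_formats import STANDARD_AA, ProteinRecord

logger = logging.getLogger(__name__)

#: Canonical residue column order for all in-memory profiles.
AA_ORDER = STANDARD_AA
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

#: Probability floor applied before renormalization (keeps -log p finite).
PROB_FLOOR = 1e-4


def floor_and_renormalize(rows: np.ndarray, eps: float = PROB_FLOOR) -> np.ndarray:
    """Clamp entries to eps from below and rescale each row to sum to 1."""
    rows = np.clip(np.asarray(rows, dtype=np.float64), eps, None)
    return rows / rows.sum(axis=1, keepdims=True)


@dataclass
class Profile:
    """Position-wise amino-acid probability distribution for one protein.

    ``probs[i, a]`` is the probability of residue ``AA_ORDER[a]`` at position
    ``i``; every row sums to 1 and no entry is zero.
    """

    protein_id: str
    probs: np.ndarray
    query: str
    _neg_log: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 2 or self.probs.shape[1] != 20:
            raise ValueError(f"profile table must be L x 20, got {self.probs.shape}")
        if self.probs.shape[0] != len(self.query):
            raise ValueError(
                f"profile length {self.probs.shape[0]} != query length {len(self.query)}"
            )
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("profile rows must sum to 1")
        if np.any(self.probs <= 0.0):
            raise ValueError("profile entries must be strictly positive")

    def __len__(self) -> int:
        return len(self.query)

    @property
    def neg_log(self) -> np.ndarray:
        """-ln p, the per-position conservation cost consumed by the kernel."""
        if self._neg_log is None:
            self._neg_log = -np.log(self.probs)
        return self._neg_log


def pssm_to_profile(
    query: str, percentages: np.ndarray, residue_order: str, protein_id: str
) -> Profile:
    """Convert PSI-BLAST percentage columns into a :class:`Profile`.

    Percentages are divided by 100, floored at epsilon and renormalized.  A
    position with all-zero percentages (PSI-BLAST prints these where the
    alignment had no coverage) falls back to a point mass on the query
    residue.
    """
    percentages = np.asarray(percentages, dtype=np.float64)
    if sorted(residue_order) != sorted(AA_ORDER):
        raise ValueError(f"unexpected residue order {residue_order!r}")
    order = [residue_order.index(aa) for aa in AA_ORDER]
    rows = percentages[:, order] / 100.0

    zero_rows = np.flatnonzero(rows.sum(axis=1) == 0.0)
    for i in zero_rows:
        residue = query[i]
        if residue in _AA_INDEX:
            rows[i, _AA_INDEX[residue]] = 1.0
            logger.info(
                "profile %s position %d: all-zero row replaced by delta on %s",
                protein_id, i + 1, residue,
            )
        else:
            rows[i, :] = 1.0 / 20.0
    return Profile(protein_id, floor_and_renormalize(rows), query)


def _blosum62_conditional() -> np.ndarray:
    """q(b | a): substitution distribution implied by BLOSUM62 half-bit scores.

    Rows are conditioned on the observed residue a: q(b|a) proportional to
    2**(s(a,b)/2) with a flat background, normalized per row.
    """
    blosum = substitution_matrices.load("BLOSUM62")
    q = np.empty((20, 20), dtype=np.float64)
    for i, a in enumerate(AA_ORDER):
        for j, b in enumerate(AA_ORDER):
            q[i, j] = 2.0 ** (blosum[a, b] / 2.0)
    return q / q.sum(axis=1, keepdims=True)


_BLOSUM_CONDITIONAL = _blosum62_conditional()


def pseudo_profile(protein: ProteinRecord, alpha: float = 0.1) -> Profile:
    """Sequence-only profile: (1 - alpha) * delta(residue) + alpha * q(.|residue).

    alpha = 0 gives a pure point-mass ("delta") profile, alpha = 1 the pure
    BLOSUM62 substitution-conditional rows.  Nonstandard residues (X)
    contribute uniform rows so they never manufacture conserved k-mers.
    Deterministic: identical input always yields the identical table.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be within [0, 1]")
    L = len(protein.sequence)
    rows = np.empty((L, 20), dtype=np.float64)
    for i, residue in enumerate(protein.sequence):
        if residue not in _AA_INDEX:
            rows[i, :] = 1.0 / 20.0
            continue
        a = _AA_INDEX[residue]
        rows[i, :] = alpha * _BLOSUM_CONDITIONAL[a]
        rows[i, a] += 1.0 - alpha
    return Profile(protein.id, floor_and_renormalize(rows), protein.sequence)


# ---------------------------------------------------------------------------
# Profile cache directory (one plain TSV per protein)

def save_profile(profile: Profile, directory) -> Path:
    path = Path(directory) / f"{profile.protein_id}.profile.tsv"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("position\tresidue\t" + "\t".join(AA_ORDER) + "\n")
        for i, residue in enumerate(profile.query):
            probs = "\t".join(f"{p:.10g}" for p in profile.probs[i])
            fh.write(f"{i + 1}\t{residue}\t{probs}\n")
    return path


def load_profile(path) -> Profile:
    path = Path(path)
    query = []
    rows = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["position", "residue"] or "".join(header[2:]) != AA_ORDER:
            raise ValueError(f"{path}: not a profile table")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            query.append(parts[1])
            rows.append([float(v) for v in parts[2:]])
    protein_id = path.name.removesuffix(".profile.tsv")
    return Profile(protein_id, np.asarray(rows), "".join(query))


class ProfileStore:
    """Profiles for a proteome: loaded from a cache directory when present,
    generated as pseudo-profiles otherwise (if a fallback alpha is given)."""

    def __init__(self, directory=None, pseudo_alpha: float | None = 0.1):
        self.directory = Path(directory) if directory is not None else None
        self.pseudo_alpha = pseudo_alpha
        self._cache: dict[str, Profile] = {}

    def add(self, profile: Profile) -> None:
        self._cache[profile.protein_id] = profile

    def get(self, protein: ProteinRecord) -> Profile:
        pid = protein.id
        if pid in self._cache:
            return self._cache[pid]
        if self.directory is not None:
            path = self.directory / f"{pid}.profile.tsv"
            if path.exists():
                profile = load_profile(path)
                self._cache[pid] = profile
                return profile
        if self.pseudo_alpha is None:
            raise KeyError(f"no profile for {pid!r} and pseudo-profile fallback disabled")
        profile = pseudo_profile(protein, self.pseudo_alpha)
        self._cache[pid] = profile
        return profile
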