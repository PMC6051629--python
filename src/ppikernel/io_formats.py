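"""Readers and writers for every external representation the pipeline touches.

All other modules operate purely on the in-memory domain types defined here:
:class:`ProteinRecord`, :class:`EvidencedInteraction`, :class:`ScoreTable` and
:class:`PredictionRecord`.  Supported formats: FASTA, the PSI-BLAST ASCII PSSM
layout (``-out_ascii_pssm``), a minimal MITAB 2.5 column subset (ids + detection
method), simple tab-separated interaction/score/prediction tables.  All TSVs
are UTF-8 with a header line.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

logger = logging.getLogger(__name__)

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_AA)

#: Column order of residues in a PSI-BLAST ASCII PSSM.
PSSM_RESIDUE_ORDER = "ARNDCQEGHILKMFPSTWYV"


class ParseError(ValueError):
    """Malformed input file; carries the offending path and line number."""

    def __init__(self, path, line_no: int | None, message: str):
        loc = f"{path}" if line_no is None else f"{path}:{line_no}"
        super().__init__(f"{loc}: {message}")
        self.path = path
        self.line_no = line_no


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: a stable accession and an upper-case residue string.

    Residues outside the 20 standard letters are stored as ``X``.
    """

    id: str
    sequence: str

    def __post_init__(self):
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: sequence must be non-empty")

    def __len__(self) -> int:
        return len(self.sequence)


def canonical_pair(id_a: str, id_b: str) -> tuple[str, str]:
    """Unordered-pair key: lexicographically smaller id first."""
    return (id_a, id_b) if id_a <= id_b else (id_b, id_a)


@dataclass
class EvidencedInteraction:
    """An unordered protein pair with (experimental method, reliability score) evidence.

    ``id_a <= id_b`` always holds; scores are in reliability units 1 (lowest)
    to 10 (highest).  Self pairs may exist after parsing but are excluded from
    all training and prediction sets downstream.
    """

    id_a: str
    id_b: str
    evidence: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self):
        self.id_a, self.id_b = canonical_pair(self.id_a, self.id_b)
        for method, score in self.evidence:
            if not 1.0 <= score <= 10.0:
                raise ValueError(
                    f"evidence score {score} for {method!r} outside [1, 10]"
                )

    @property
    def pair(self) -> tuple[str, str]:
        return (self.id_a, self.id_b)

    @property
    def is_self(self) -> bool:
        return self.id_a == self.id_b

    def max_score(self) -> float:
        if not self.evidence:
            raise ValueError(f"interaction {self.pair} has no evidence to score")
        return max(score for _, score in self.evidence)


def _normalize_method(name: str) -> str:
    return re.sub(r"\s+", " ", name.strip()).lower()


class ScoreTable:
    """Experimental-method -> reliability score (1-10) lookup.

    Lookups are case-insensitive after whitespace normalization.  Methods
    absent from the table resolve to a configurable default (lowest
    reliability by default, so missing annotation quality can never promote an
    interaction past the evidence filter).
    """

    def __init__(self, scores: Mapping[str, float], default_score: float = 1.0):
        self._scores: dict[str, float] = {}
        for method, score in scores.items():
            if not 1.0 <= float(score) <= 10.0:
                raise ValueError(f"score {score} for {method!r} outside [1, 10]")
            self._scores[_normalize_method(method)] = float(score)
        if not 1.0 <= default_score <= 10.0:
            raise ValueError("default score must be within [1, 10]")
        self.default_score = default_score

    def __contains__(self, method: str) -> bool:
        return _normalize_method(method) in self._scores

    def __len__(self) -> int:
        return len(self._scores)

    def lookup(self, method: str) -> float:
        key = _normalize_method(method)
        if key not in self._scores:
            logger.warning(
                "method %r not in score table; using default score %s",
                method,
                self.default_score,
            )
            return self.default_score
        return self._scores[key]

    def items(self):
        return self._scores.items()

    @classmethod
    def from_tsv(cls, path, default_score: float = 1.0) -> "ScoreTable":
        scores = {}
        with open(path, encoding="utf-8") as fh:
            for line_no, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if line_no == 1 and parts[0].lower() in ("method", "experiment"):
                    continue
                if len(parts) < 2:
                    raise ParseError(path, line_no, "expected columns: method, score")
                try:
                    scores[parts[0]] = float(parts[1])
                except ValueError as exc:
                    raise ParseError(path, line_no, f"non-numeric score {parts[1]!r}") from exc
        return cls(scores, default_score=default_score)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("method\tscore\n")
            for method, score in sorted(self._scores.items()):
                fh.write(f"{method}\t{score:g}\n")


@dataclass(frozen=True)
class PredictionRecord:
    """A scored candidate pair: signed SVM margin, calibrated probability, rank."""

    id_a: str
    id_b: str
    decision_value: float
    probability: float
    rank: int

    def __post_init__(self):
        if not 0.0 < self.probability < 1.0:
            raise ValueError(
                f"probability must lie strictly in (0, 1); got {self.probability}"
            )
        if self.rank < 1:
            raise ValueError("rank must be a positive integer")


# ---------------------------------------------------------------------------
# FASTA

def clean_sequence(raw: str) -> str:
    """Upper-case a residue string and map non-standard letters to X."""
    out = []
    for ch in raw.upper():
        out.append(ch if ch in _STANDARD_SET else "X")
    return "".join(out)


def read_fasta(path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    Sequences are upper-cased, characters outside the standard 20-letter
    alphabet become ``X``, and duplicate ids are rejected.  Parsing is done
    directly (rather than delegated) so errors can name the offending line.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    current_id: str | None = None
    current_parts: list[str] = []
    header_line = 0

    def flush(line_no):
        if current_id is None:
            return
        seq = clean_sequence("".join(current_parts))
        if not seq:
            raise ParseError(path, header_line, f"entry {current_id!r} has an empty sequence")
        records.append(ProteinRecord(current_id, seq))

    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(line_no)
                current_id = line[1:].split()[0] if len(line) > 1 else ""
                if not current_id:
                    raise ParseError(path, line_no, "FASTA header with no identifier")
                if current_id in seen:
                    raise ParseError(path, line_no, f"duplicate id {current_id!r}")
                seen.add(current_id)
                header_line = line_no
                current_parts = []
            else:
                if current_id is None:
                    raise ParseError(path, line_no, "sequence data before any FASTA header")
                current_parts.append(line)
        flush(None)
    return records


def write_fasta(records: Iterable[ProteinRecord], path, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM

def read_pssm(path) -> tuple[str, np.ndarray, str]:
    """Read a PSI-BLAST ``-out_ascii_pssm`` file.

    Returns ``(query, percentages, residue_order)``: the query residue string,
    an L x 20 array of the weighted-percentage columns, and the residue order
    of those columns as found in the file header.
    """
    query_chars: list[str] = []
    rows: list[list[float]] = []
    residue_order: str | None = None
    expected_pos = 0

    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            parts = stripped.split()
            if residue_order is None:
                # header row listing residue letters twice (log-odds + percentages)
                if len(parts) >= 40 and all(len(p) == 1 and p.isalpha() for p in parts[:40]):
                    residue_order = "".join(parts[:20])
                    if "".join(parts[20:40]) != residue_order:
                        raise ParseError(path, line_no, "inconsistent residue header")
                continue
            if not parts[0].isdigit():
                continue  # trailing K/lambda statistics block
            pos = int(parts[0])
            expected_pos += 1
            if pos != expected_pos:
                raise ParseError(
                    path, line_no, f"position {pos} out of order (expected {expected_pos})"
                )
            residue = parts[1]
            if len(residue) != 1:
                raise ParseError(path, line_no, f"bad residue field {residue!r}")
            values = parts[2:]
            if len(values) < 40:
                raise ParseError(
                    path, line_no, f"expected 40 numeric columns, found {len(values)}"
                )
            try:
                percents = [float(v) for v in values[20:40]]
            except ValueError as exc:
                raise ParseError(path, line_no, "non-numeric percentage cell") from exc
            query_chars.append(residue)
            rows.append(percents)

    if residue_order is None or not rows:
        raise ParseError(path, None, "no PSSM data found (truncated file?)")
    return "".join(query_chars), np.asarray(rows, dtype=np.float64), residue_order


def write_pssm(query: str, percentages: np.ndarray, path) -> None:
    """Write an L x 20 percentage table in the PSI-BLAST ASCII PSSM layout.

    The log-odds block is emitted as zeros; only the percentage block carries
    information.  Reading the file back with :func:`read_pssm` recovers the
    query and percentages exactly (percentages are printed as integers, as
    PSI-BLAST does, so inputs should already be integral).
    """
    percentages = np.asarray(percentages)
    if percentages.shape != (len(query), 20):
        raise ValueError(
            f"percentage table shape {percentages.shape} does not match query length {len(query)}"
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n")
        fh.write(
            "Last position-specific scoring matrix computed, weighted observed "
            "percentages rounded down, information per position, and relative "
            "weight of gapless real matches to pseudocounts\n"
        )
        letters = "  ".join(PSSM_RESIDUE_ORDER)
        fh.write("            " + letters + "   " + letters + "\n")
        for i, residue in enumerate(query):
            logodds = " ".join(f"{0:3d}" for _ in range(20))
            pcts = " ".join(f"{int(round(v)):3d}" for v in percentages[i])
            fh.write(f"{i + 1:5d} {residue}  {logodds}  {pcts}  0.00 0.00\n")


# ---------------------------------------------------------------------------
# Interaction tables

_MITAB_METHOD_RE = re.compile(r"\(([^()]*)\)")


def _mitab_first_id(cell: str) -> str:
    first = cell.split("|")[0].strip()
    if ":" in first:
        first = first.split(":", 1)[1]
    return first


def _mitab_method_name(cell: str) -> str:
    first = cell.split("|")[0].strip()
    match = _MITAB_METHOD_RE.search(first)
    if match:
        return match.group(1).strip().strip('"')
    return first


def read_interactions(path, dialect: str, score_table: ScoreTable) -> list[EvidencedInteraction]:
    """Read interaction records with evidence annotations.

    ``dialect`` is ``"tsv"`` (columns id_a, id_b, method; repeated lines for a
    pair accumulate evidence) or ``"mitab"`` (MITAB 2.5; columns 1 and 2 carry
    the interactor ids, column 7 the detection method whose free-text name is
    taken from the parenthesized part).  Pairs are canonicalized so the result
    is invariant under (B, A) vs (A, B) listing and line order.
    """
    if dialect not in ("tsv", "mitab"):
        raise ValueError(f"unknown interaction dialect {dialect!r}")

    grouped: dict[tuple[str, str], list[tuple[str, float]]] = {}
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if dialect == "tsv":
                if line_no == 1 and parts[0].lower() in ("id_a", "ida", "protein_a"):
                    continue
                if len(parts) < 3:
                    raise ParseError(path, line_no, "expected columns: id_a, id_b, method")
                id_a, id_b, method = parts[0].strip(), parts[1].strip(), parts[2]
            else:
                if len(parts) < 7:
                    raise ParseError(path, line_no, "MITAB line with fewer than 7 columns")
                id_a = _mitab_first_id(parts[0])
                id_b = _mitab_first_id(parts[1])
                method = _mitab_method_name(parts[6])
            if not id_a or not id_b:
                raise ParseError(path, line_no, "empty interactor identifier")
            key = canonical_pair(id_a, id_b)
            grouped.setdefault(key, []).append((method, score_table.lookup(method)))

    interactions = []
    for (id_a, id_b), evidence in sorted(grouped.items()):
        inter = EvidencedInteraction(id_a, id_b, evidence)
        if inter.is_self:
            logger.warning("self-interaction %s parsed; excluded downstream", id_a)
        interactions.append(inter)
    return interactions


def write_interactions(interactions: Iterable[EvidencedInteraction], path) -> None:
    """One line per evidence entry: id_a, id_b, method, score."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id_a\tid_b\tmethod\tscore\n")
        for inter in interactions:
            for method, score in inter.evidence:
                fh.write(f"{inter.id_a}\t{inter.id_b}\t{method}\t{score:g}\n")


# ---------------------------------------------------------------------------
# Predictions

def write_predictions(records: Iterable[PredictionRecord], path) -> None:
    """Write ranked predictions as TSV (probability printed with 6 decimals)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rank\tid_a\tid_b\tdecision_value\tprobability\n")
        for rec in records:
            fh.write(
                f"{rec.rank}\t{rec.id_a}\t{rec.id_b}\t"
                f"{rec.decision_value:.6g}\t{rec.probability:.6f}\n"
            )


def read_predictions(path) -> list[PredictionRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if line_no == 1 and parts[0] == "rank":
                continue
            if len(parts) != 5:
                raise ParseError(path, line_no, "expected 5 prediction columns")
            try:
                records.append(
                    PredictionRecord(
                        id_a=parts[1],
                        id_b=parts[2],
                        decision_value=float(parts[3]),
                        probability=float(parts[4]),
                        rank=int(parts[0]),
                    )
                )
            except ValueError as exc:
                raise ParseError(path, line_no, str(exc)) from exc
    return records
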