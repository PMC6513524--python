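"""All-vs-all protein similarity as BLAST score ratios (BSR).

The clustering pipeline scores every coat protein against every other,
converts raw Smith–Waterman scores to bit scores with the Karlin–Altschul
rescaling ``bits = (lambda * raw - ln K) / ln 2``, forms the BSR
``bsr[q][s] = bits[q][s] / bits[q][q]`` and the distance ``1 - BSR``.

The internal aligner (Bio.Align.PairwiseAligner, local mode, BLOSUM62,
affine gaps) is a documented approximation of blastp scoring; externally
computed blastp tabular output (outfmt 6/10) can be ingested instead for
full fidelity to an actual BLAST run.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .io import ProteinSequence

#: Published gapped-BLOSUM62 Karlin–Altschul constants (gap 11/1).
DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring system for local alignment and bit-score conversion.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lambda_: float = DEFAULT_LAMBDA
    k_: float = DEFAULT_K

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")
        if self.lambda_ <= 0 or self.k_ <= 0:
            raise ValueError("lambda and K must be positive")

    def substitution_matrix(self):
        return substitution_matrices.load(self.matrix_name)

    def aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = self.substitution_matrix()
        aligner.open_gap_score = -self.gap_open
        aligner.extend_gap_score = -self.gap_extend
        aligner.mode = "local"
        return aligner


DEFAULT_PARAMS = AlignmentParams()


def align_local(
    a: ProteinSequence,
    b: ProteinSequence,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> int:
    """Optimal Smith–Waterman local alignment raw score (affine gaps).

    The score is symmetric and never negative (the empty alignment scores 0).
    """
    matrix = params.substitution_matrix()
    alphabet = set(str(matrix.alphabet))
    for seq in (a, b):
        missing = set(seq.seq) - alphabet
        if missing:
            raise ValueError(
                f"residues absent from {params.matrix_name}: {sorted(missing)}"
            )
    score = params.aligner().score(a.seq, b.seq)
    return max(0, int(round(score)))


def raw_to_bits(raw: int, params: AlignmentParams = DEFAULT_PARAMS) -> float:
    """Karlin–Altschul bit score: ``(lambda * raw - ln K) / ln 2``."""
    if raw < 0:
        raise ValueError("raw score must be >= 0")
    return (params.lambda_ * raw - math.log(params.k_)) / math.log(2)


def _check_ids(ids: Sequence[str]) -> list[str]:
    ids = list(ids)
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sequence ids: {dupes}")
    return ids


@dataclass
class ScoreMatrix:
    """All-vs-all bit scores; ``bits[q, s]`` is query-vs-subject."""

    ids: list[str]
    bits: np.ndarray
    no_hit: np.ndarray | None = None  # mask of pairs with no positive hit

    def __post_init__(self) -> None:
        self.ids = _check_ids(self.ids)
        self.bits = np.asarray(self.bits, dtype=float)
        n = len(self.ids)
        if self.bits.shape != (n, n):
            raise ValueError("bits must be square over ids")
        if np.any(np.diag(self.bits) <= 0):
            bad = [self.ids[i] for i in np.flatnonzero(np.diag(self.bits) <= 0)]
            raise ValueError(f"non-positive self bit score for: {bad}")

    @property
    def self_bits(self) -> np.ndarray:
        return np.diag(self.bits)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.bits, index=self.ids, columns=self.ids)


@dataclass
class BsrMatrix:
    """BSR values; asymmetric because of per-query self-score denominators."""

    ids: list[str]
    bsr: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.bsr, index=self.ids, columns=self.ids)


@dataclass
class DistanceMatrix:
    """Symmetric 1−BSR dissimilarity, clamped to [0, 1], zero diagonal."""

    ids: list[str]
    dist: np.ndarray

    def __post_init__(self) -> None:
        self.dist = np.asarray(self.dist, dtype=float)
        n = len(self.ids)
        if self.dist.shape != (n, n):
            raise ValueError("distance matrix must be square over ids")
        if not np.allclose(self.dist, self.dist.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(self.dist < 0) or np.any(np.diag(self.dist) != 0):
            raise ValueError("distances must be >= 0 with zero diagonal")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.dist, index=self.ids, columns=self.ids)

    def to_phylip(self) -> str:
        """Phylip square-matrix format (interoperability export)."""
        lines = [f"{len(self.ids):5d}"]
        for i, name in enumerate(self.ids):
            row = " ".join(f"{v:.6f}" for v in self.dist[i])
            lines.append(f"{name[:10]:<10s} {row}")
        return "\n".join(lines) + "\n"


def bsr_to_distance(score: ScoreMatrix) -> tuple[BsrMatrix, DistanceMatrix]:
    """Form BSR and the symmetrised 1−BSR distance matrix.

    The BSR is asymmetric; UPGMA needs a symmetric input, so the distance is
    ``1 - (bsr[q,s] + bsr[s,q]) / 2``, clamped to [0, 1] with an exact zero
    diagonal.
    """
    bsr = score.bits / score.self_bits[:, None]
    np.fill_diagonal(bsr, 1.0)
    sym = (bsr + bsr.T) / 2.0
    dist = np.clip(1.0 - sym, 0.0, 1.0)
    np.fill_diagonal(dist, 0.0)
    return BsrMatrix(list(score.ids), bsr), DistanceMatrix(list(score.ids), dist)


def build_bsr(
    records: Sequence[ProteinSequence],
    params: AlignmentParams = DEFAULT_PARAMS,
) -> tuple[ScoreMatrix, BsrMatrix, DistanceMatrix]:
    """All-vs-all alignment → bit scores → BSR → 1−BSR distances.

    Pairs with no positive-scoring local alignment receive bit score 0
    before ratio formation, so "no similarity" maps to distance ≈ 1.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    ids = _check_ids([r.id for r in records])
    n = len(records)
    aligner = params.aligner()  # built once; matrix loading dominates otherwise
    raw = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i, n):
            score = max(0, int(round(aligner.score(records[i].seq, records[j].seq))))
            raw[i, j] = raw[j, i] = score
    no_hit = raw == 0
    bits = np.where(no_hit, 0.0, (params.lambda_ * raw - math.log(params.k_)) / math.log(2))
    score = ScoreMatrix(ids, bits, no_hit=no_hit)
    bsr, dist = bsr_to_distance(score)
    return score, bsr, dist


#: blastp tabular outfmt 6/10 default field order; bitscore is column 12.
BLAST_FIELDS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


def ingest_score_csv(
    path: str | Path,
    dialect: str = "auto",
) -> ScoreMatrix:
    """Ingest an all-vs-all blastp tabular file (outfmt 6 or 10).

    ``dialect`` is ``"tab"`` (outfmt 6), ``"comma"`` (outfmt 10) or
    ``"auto"``.  The best (maximum) bit score is kept per ordered
    (query, subject) pair; missing pairs are filled with 0 bits and flagged;
    every id must have a self-hit.
    """
    path = Path(path)
    best: dict[tuple[str, str], float] = {}
    ids: list[str] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        sample = fh.read(8192)
        fh.seek(0)
        if dialect == "auto":
            delim = "\t" if "\t" in sample.splitlines()[0] else ","
        elif dialect == "tab":
            delim = "\t"
        elif dialect == "comma":
            delim = ","
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
        reader = csv.reader(fh, delimiter=delim)
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 fields")
            q, s = row[0].strip(), row[1].strip()
            # full blastp rows carry bitscore in field 12; bare 3-field rows
            # carry it in field 3
            raw_bits = row[11] if len(row) >= 12 else row[2]
            try:
                value = float(raw_bits)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: unparseable bit score {raw_bits!r}"
                ) from exc
            for name in (q, s):
                if name not in seen:
                    seen.add(name)
                    ids.append(name)
            key = (q, s)
            if key not in best or value > best[key]:
                best[key] = value
    if not ids:
        raise ValueError(f"{path}: no rows parsed")
    missing_self = sorted(i for i in ids if (i, i) not in best)
    if missing_self:
        raise ValueError(f"{path}: ids without a self-hit: {missing_self}")
    n = len(ids)
    bits = np.zeros((n, n))
    no_hit = np.ones((n, n), dtype=bool)
    index = {name: i for i, name in enumerate(ids)}
    for (q, s), value in best.items():
        bits[index[q], index[s]] = value
        no_hit[index[q], index[s]] = False
    return ScoreMatrix(ids, bits, no_hit=no_hit)


def write_matrix_tsv(
    matrix: ScoreMatrix | BsrMatrix | DistanceMatrix,
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    """Write a matrix as TSV with an id header row/column."""
    df = matrix.to_dataframe()
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index_label="id")
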