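"""The four protein-protein similarity networks: Seqs, Go, Pfam, String.

Each builder returns a :class:`SimilarityMatrix` — a symmetric nonnegative
protein-by-protein matrix with entries in [0, 1] and unit diagonal, carrying
an ordered protein id index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .data_io import ProteinRecord, ScoredEdgeList

SOURCE_TAGS = ("Seqs", "Go", "Pfam", "String", "Binary", "Fused")

_SYM_TOL = 1e-9


@dataclass
class ScoringConfig:
    """Local-alignment scoring: substitution matrix and affine gap penalties."""

    substitution_matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load(self.substitution_matrix)
        aligner.open_gap_score = -abs(self.gap_open)
        aligner.extend_gap_score = -abs(self.gap_extend)
        return aligner


@dataclass
class SimilarityMatrix:
    """Symmetric similarity matrix over an ordered protein index."""

    index: tuple[str, ...]
    values: np.ndarray
    source_tag: str = "Fused"

    def __post_init__(self) -> None:
        self.index = tuple(self.index)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.index)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} does not match index length {n}")
        if self.source_tag not in SOURCE_TAGS:
            raise ValueError(f"unknown source_tag {self.source_tag!r}")

    def validate(self) -> "SimilarityMatrix":
        """Assert the type invariants: symmetry, range [0,1], unit diagonal."""
        v = self.values
        if not np.allclose(v, v.T, atol=_SYM_TOL):
            raise ValueError("matrix is not symmetric")
        if v.min() < -_SYM_TOL or v.max() > 1 + _SYM_TOL:
            raise ValueError("entries outside [0, 1]")
        if not np.allclose(np.diag(v), 1.0, atol=_SYM_TOL):
            raise ValueError("diagonal is not 1")
        return self

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=list(self.index), columns=list(self.index)).to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, path: str | Path, source_tag: str = "Fused") -> "SimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(index=tuple(str(c) for c in df.columns), values=df.to_numpy(), source_tag=source_tag)


def smith_waterman_score(
    seq_a: str, seq_b: str, scoring: ScoringConfig | None = None
) -> float:
    """Best local-alignment score of two protein sequences.

    Affine-gap Smith-Waterman under the configured substitution matrix; the
    score floors at zero by the local-alignment convention.
    """
    scoring = scoring or ScoringConfig()
    if not seq_a or not seq_b:
        raise ValueError("sequences must be nonempty")
    aligner = scoring.make_aligner()
    alphabet = set(str(aligner.substitution_matrix.alphabet))
    for seq in (seq_a, seq_b):
        for ch in seq.upper():
            if ch not in alphabet:
                raise ValueError(f"non-amino-acid character {ch!r} in sequence")
    return float(aligner.score(seq_a.upper(), seq_b.upper()))


def sequence_similarity(
    records: Iterable[ProteinRecord],
    index: Sequence[str],
    scoring: ScoringConfig | None = None,
) -> SimilarityMatrix:
    """Normalized Smith-Waterman similarity, nsw(i,j) = sw(i,j)/sqrt(sw(i,i) sw(j,j)).

    The matrix is symmetrized as (nsw(i,j)+nsw(j,i))/2 — a no-op for symmetric
    substitution matrices, kept for fidelity to the definition.  Proteins
    without sequences get zero off-diagonal entries; the diagonal is 1.
    """
    scoring = scoring or ScoringConfig()
    seqs = {r.id: r.sequence for r in records if r.sequence}
    n = len(index)
    aligner = scoring.make_aligner()
    present = [i for i, pid in enumerate(index) if pid in seqs]
    self_scores = {}
    for i in present:
        s = float(aligner.score(seqs[index[i]].upper(), seqs[index[i]].upper()))
        if s <= 0:
            raise ValueError(f"degenerate self-alignment score for {index[i]}")
        self_scores[i] = s
    values = np.zeros((n, n))
    for ai, i in enumerate(present):
        for j in present[ai + 1 :]:
            sw = float(aligner.score(seqs[index[i]].upper(), seqs[index[j]].upper()))
            nsw = sw / np.sqrt(self_scores[i] * self_scores[j])
            values[i, j] = values[j, i] = nsw
    np.clip(values, 0.0, 1.0, out=values)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(index=tuple(index), values=values, source_tag="Seqs").validate()


def jaccard_similarity(
    set_map: Mapping[str, set], index: Sequence[str], source_tag: str
) -> SimilarityMatrix:
    """Jaccard overlap |t_i ∩ t_j| / |t_i ∪ t_j| of annotation sets.

    Used for both GO term sets and Pfam domain fingerprints.  A pair where
    either set is empty scores 0 off-diagonal; the diagonal is forced to 1.
    """
    if not index:
        raise ValueError("index must be nonempty")
    n = len(index)
    sets = [frozenset(set_map.get(pid, ())) for pid in index]
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            union = len(sets[i] | sets[j])
            if union:
                values[i, j] = values[j, i] = len(sets[i] & sets[j]) / union
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(index=tuple(index), values=values, source_tag=source_tag).validate()


STRING_MAX_SCORE = 999


def string_similarity(edges: ScoredEdgeList, index: Sequence[str]) -> SimilarityMatrix:
    """STRING confidence similarity, score/999 (999 is the maximal confidence).

    Edges are symmetrized; if both directions are listed with different
    scores the larger wins.  Unlisted pairs score 0; the diagonal is 1.
    """
    n = len(index)
    pos = {pid: i for i, pid in enumerate(index)}
    values = np.zeros((n, n))
    for a, b, score in edges.edges:
        if not 0 <= score <= STRING_MAX_SCORE:
            raise ValueError(f"score {score} outside [0, {STRING_MAX_SCORE}]")
        if a in pos and b in pos and a != b:
            i, j = pos[a], pos[b]
            s = score / STRING_MAX_SCORE
            if s > values[i, j]:
                values[i, j] = values[j, i] = s
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(index=tuple(index), values=values, source_tag="String").validate()


def binarize(matrix: SimilarityMatrix, threshold: float | None = None) -> SimilarityMatrix:
    """0/1 edge-existence network: the unweighted-PPI baseline representation.

    Off-diagonal entries become 1 where >= threshold, else 0.  The default
    threshold is the smallest positive off-diagonal value, i.e. any listed
    edge becomes an unweighted edge.
    """
    off = matrix.values[~np.eye(len(matrix.index), dtype=bool)]
    if threshold is None:
        positive = off[off > 0]
        threshold = float(positive.min()) if positive.size else 1.0
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    values = (matrix.values >= threshold).astype(float)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(index=matrix.index, values=values, source_tag="Binary").validate()
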