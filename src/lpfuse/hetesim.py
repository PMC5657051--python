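"""HeteSim relevance scoring on the heterogeneous lncRNA-protein network.

The network has two node types (lncRNA, protein) and two relations: the
binary lncRNA-protein adjacency and the weighted protein-protein similarity.
Scores follow the lncRNA-protein-protein (LPP) relevance path, which splits
at the middle protein type: the relevance of lncRNA l and protein p is the
cosine of two reach-probability distributions over proteins — where l's
interactions lead, and where p's similarity neighbours lie:

    score(l, p) = <A(l,:), B(p,:)> / (||A(l,:)|| ||B(p,:)||)

with A the row-normalized interaction matrix and B the row-normalized
similarity matrix (self-similarity excluded, so a protein's distribution
describes its neighbours).  Scores lie in [0, 1]; a zero reach distribution
on either side scores 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import InteractionTable
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)


@dataclass
class InteractionMatrix:
    """Binary lncRNA (rows) by protein (columns) adjacency."""

    lncrna_index: tuple[str, ...]
    protein_index: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.lncrna_index = tuple(self.lncrna_index)
        self.protein_index = tuple(self.protein_index)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.lncrna_index), len(self.protein_index)):
            raise ValueError("matrix shape does not match indices")
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("interaction matrix entries must be 0 or 1")

    @classmethod
    def from_table(
        cls,
        table: InteractionTable,
        lncrna_index: Sequence[str] | None = None,
        protein_index: Sequence[str] | None = None,
    ) -> "InteractionMatrix":
        lncrna_index = tuple(lncrna_index) if lncrna_index else table.lncrna_index
        protein_index = tuple(protein_index) if protein_index else table.protein_index
        lpos = {l: i for i, l in enumerate(lncrna_index)}
        ppos = {p: i for i, p in enumerate(protein_index)}
        values = np.zeros((len(lncrna_index), len(protein_index)))
        for l, p in table.pairs:
            if l in lpos and p in ppos:
                values[lpos[l], ppos[p]] = 1.0
        return cls(lncrna_index=lncrna_index, protein_index=protein_index, values=values)


@dataclass
class TransitionMatrix:
    """Row-normalized adjacency between two node types; zero rows flagged."""

    source_type: str
    target_type: str
    values: np.ndarray
    zero_rows: tuple[int, ...] = ()


@dataclass
class ScoreTable:
    """lncRNA-by-protein HeteSim relevance scores in [0, 1]."""

    lncrna_index: tuple[str, ...]
    protein_index: tuple[str, ...]
    values: np.ndarray

    def to_tsv(self, path: str | Path) -> None:
        """Write (lncrna_id, protein_id, score) rows sorted by descending score."""
        rows = [
            (l, p, self.values[i, j])
            for i, l in enumerate(self.lncrna_index)
            for j, p in enumerate(self.protein_index)
        ]
        df = pd.DataFrame(rows, columns=["lncrna_id", "protein_id", "score"])
        df.sort_values(
            ["score", "lncrna_id", "protein_id"], ascending=[False, True, True]
        ).to_csv(path, sep="\t", index=False)


def row_normalize(
    adjacency: np.ndarray, source_type: str = "A", target_type: str = "B"
) -> TransitionMatrix:
    """Divide each positive row by its sum; zero rows stay zero and are flagged."""
    adjacency = np.asarray(adjacency, dtype=float)
    if (adjacency < 0).any():
        raise ValueError("adjacency must be nonnegative")
    sums = adjacency.sum(axis=1)
    zero = sums <= 0
    out = np.zeros_like(adjacency)
    out[~zero] = adjacency[~zero] / sums[~zero, None]
    if zero.any():
        logger.warning("%d zero rows in transition matrix", int(zero.sum()))
    return TransitionMatrix(
        source_type=source_type,
        target_type=target_type,
        values=out,
        zero_rows=tuple(np.flatnonzero(zero)),
    )


def reachable_probability(path_matrices: Sequence[TransitionMatrix]) -> np.ndarray:
    """Reach-probability matrix of a relevance path: the ordered product."""
    if not path_matrices:
        raise ValueError("path must contain at least one transition matrix")
    result = path_matrices[0].values
    for tm in path_matrices[1:]:
        if result.shape[1] != tm.values.shape[0]:
            raise ValueError(
                f"dimension mismatch: {result.shape} cannot be chained with {tm.values.shape}"
            )
        result = result @ tm.values
    return result


def _unit_rows(M: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(M, axis=1)
    out = np.zeros_like(M)
    ok = norms > 0
    out[ok] = M[ok] / norms[ok, None]
    return out


def hetesim_lpp(
    lp: InteractionMatrix,
    pp: SimilarityMatrix,
    pp_keep_diagonal: bool = False,
    denominator: str = "cosine",
) -> ScoreTable:
    """Score every lncRNA-protein pair along the LPP path.

    ``denominator="cosine"`` normalizes by the product of Euclidean norms
    (the standard normalized relevance); ``"sqrt"`` uses the square root of
    that product, a literal alternative reading of the normalization.
    """
    if lp.protein_index != pp.index:
        raise ValueError("interaction and similarity protein indices differ")
    if denominator not in ("cosine", "sqrt"):
        raise ValueError(f"unknown denominator {denominator!r}")
    pp_vals = pp.values.copy()
    if not pp_keep_diagonal:
        np.fill_diagonal(pp_vals, 0.0)
    A = row_normalize(lp.values, "lncRNA", "protein").values
    B = row_normalize(pp_vals, "protein", "protein").values
    if denominator == "cosine":
        scores = _unit_rows(A) @ _unit_rows(B).T
    else:
        raw = A @ B.T
        denom = np.sqrt(
            np.outer(np.linalg.norm(A, axis=1), np.linalg.norm(B, axis=1))
        )
        scores = np.divide(raw, denom, out=np.zeros_like(raw), where=denom > 0)
    np.clip(scores, 0.0, 1.0, out=scores)
    return ScoreTable(
        lncrna_index=lp.lncrna_index, protein_index=lp.protein_index, values=scores
    )


def hetesim_recursive(
    o1,
    o2,
    relations: Sequence[dict],
    normalized: bool = True,
) -> float:
    """Slow reference evaluation of path-constrained relevance by recursion.

    ``relations`` is a list of weighted adjacency dicts, one per relation in
    path order: ``relations[r][u][v]`` is the weight of the edge u -> v (the
    last relation is given in its forward orientation; its inverse is taken
    internally for the right half of the path).  Only paths of one or two
    relations are supported — the LPP path and its single-relation prefixes.

    For one relation the raw relation value is returned (interaction
    indicator, or the similarity weight).  For two relations the relevance is
    accumulated over o1's out-neighbours and o2's in-neighbours with
    transition probabilities proportional to edge weights; with uniform 0/1
    weights this reduces to the 1/(|O||I|) neighbour-pair average.  With
    ``normalized`` the score is divided by the product of the Euclidean
    norms of the two reach distributions (cosine normalization), matching
    :func:`hetesim_lpp`.
    """
    if len(relations) == 0:
        return 1.0 if o1 == o2 else 0.0
    if len(relations) == 1:
        return float(relations[0].get(o1, {}).get(o2, 0.0))
    if len(relations) != 2:
        raise ValueError("only paths of at most two relations are supported")

    def out_distribution(rel: dict, node) -> dict:
        nbrs = rel.get(node, {})
        if node not in rel and not nbrs:
            raise KeyError(f"unknown object {node!r}")
        total = sum(nbrs.values())
        if total <= 0:
            return {}
        return {v: w / total for v, w in nbrs.items() if w > 0}

    left = out_distribution(relations[0], o1)
    # in-neighbours of o2 under the last relation == out-neighbours under its inverse
    inverse: dict = {}
    for u, nbrs in relations[1].items():
        for v, w in nbrs.items():
            inverse.setdefault(v, {})[u] = w
    if o2 not in inverse and o2 not in relations[1]:
        raise KeyError(f"unknown object {o2!r}")
    right = out_distribution(inverse, o2) if o2 in inverse else {}
    score = 0.0
    for mid, wl in left.items():
        score += wl * right.get(mid, 0.0)
    if normalized:
        norm_l = np.sqrt(sum(w * w for w in left.values()))
        norm_r = np.sqrt(sum(w * w for w in right.values()))
        if norm_l <= 0 or norm_r <= 0:
            return 0.0
        score /= norm_l * norm_r
    return float(score)
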