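"""Similarity network fusion (SNF) over m protein similarity matrices.

Each input network W is turned into two kernels: a row-stochastic full
kernel P with self-weight 1/2,

    P(i,j) = W(i,j) / (2 * sum_{k != i} W(i,k))   for j != i,
    P(i,i) = 1/2,

and a sparse local kernel S restricted to each node's k nearest neighbours,

    S(i,j) = W(i,j) / sum_{k in N_i} W(i,k)       for j in N_i, else 0.

The fusion iteration diffuses each full kernel through its own kNN graph
against the average of the other networks,

    P_t^(i) = S^(i) @ mean_{k != i}(P_{t-1}^(k)) @ S^(i).T,

renormalizing with the full-kernel map after every sweep so each row sums
to one and the diagonal dominates.  The fused network is the average of the
m diffused kernels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)


def default_k(n: int) -> int:
    """Default neighbourhood size: max(3, n/10), capped at n-1."""
    return min(max(3, round(n / 10)), n - 1)


def full_kernel(W: SimilarityMatrix | np.ndarray) -> np.ndarray:
    """Row-stochastic normalization with self-weight 1/2.

    Rows with no off-diagonal mass (isolated proteins) fall back to
    P(i,i)=1, off-diagonal 0, with a warning.
    """
    values = W.values if isinstance(W, SimilarityMatrix) else np.asarray(W, dtype=float)
    n = values.shape[0]
    off = values.copy()
    np.fill_diagonal(off, 0.0)
    row_sums = off.sum(axis=1)
    P = np.zeros_like(values)
    isolated = row_sums <= 0
    ok = ~isolated
    P[ok] = off[ok] / (2.0 * row_sums[ok, None])
    np.fill_diagonal(P, 0.5)
    if isolated.any():
        logger.warning("%d isolated rows in full_kernel; set to identity rows", isolated.sum())
        for i in np.flatnonzero(isolated):
            P[i] = 0.0
            P[i, i] = 1.0
    return P


def local_kernel(W: SimilarityMatrix | np.ndarray, k: int) -> np.ndarray:
    """kNN-restricted row-normalized affinity; ties at rank k break to lower index."""
    values = W.values if isinstance(W, SimilarityMatrix) else np.asarray(W, dtype=float)
    n = values.shape[0]
    if not 1 <= k <= n - 1:
        raise ValueError(f"k={k} out of range [1, {n - 1}]")
    S = np.zeros_like(values)
    for i in range(n):
        row = values[i].copy()
        row[i] = -np.inf
        # stable sort on (-similarity, index): deterministic tie-break
        order = np.lexsort((np.arange(n), -row))
        neighbours = order[:k]
        mass = values[i, neighbours].sum()
        if mass > 0:
            S[i, neighbours] = values[i, neighbours] / mass
    return S


@dataclass
class FusionState:
    """Kernels and iteration counter for SNF over m networks."""

    full_kernels: list[np.ndarray]
    local_kernels: list[np.ndarray]
    index: tuple[str, ...]
    k_neighbors: int
    iteration: int = 0

    @classmethod
    def from_matrices(
        cls, matrices: list[SimilarityMatrix], k: int | None = None
    ) -> "FusionState":
        if len(matrices) < 2:
            raise ValueError("fusion needs at least two networks")
        index = matrices[0].index
        for m in matrices[1:]:
            if m.index != index:
                raise ValueError("all similarity matrices must share one protein index")
        n = len(index)
        k = default_k(n) if k is None else k
        return cls(
            full_kernels=[full_kernel(m) for m in matrices],
            local_kernels=[local_kernel(m, k) for m in matrices],
            index=index,
            k_neighbors=k,
        )


def _renormalize(P: np.ndarray) -> np.ndarray:
    """Re-apply the full-kernel map: off-diagonal rows sum to 1/2, diagonal 1/2."""
    return full_kernel(P)


def snf_iterate(
    state: FusionState, t_max: int = 20, convergence_tol: float | None = 1e-6
) -> FusionState:
    """Run up to ``t_max`` diffusion sweeps, renormalizing after each.

    The local kernels S are never updated.  When ``convergence_tol`` is set,
    iteration stops early once the mean max-entry change across networks
    falls below it.
    """
    m = len(state.full_kernels)
    if m < 2:
        raise ValueError("fusion undefined for fewer than two networks")
    P = [p.copy() for p in state.full_kernels]
    S = state.local_kernels
    total = sum(P)
    t_done = state.iteration
    for _ in range(t_max):
        new_P = []
        for i in range(m):
            avg_others = (total - P[i]) / (m - 1)
            new_P.append(_renormalize(S[i] @ avg_others @ S[i].T))
        delta = np.mean([np.abs(a - b).max() for a, b in zip(new_P, P)])
        P = new_P
        total = sum(P)
        t_done += 1
        if convergence_tol is not None and delta < convergence_tol:
            break
    return FusionState(
        full_kernels=P,
        local_kernels=S,
        index=state.index,
        k_neighbors=state.k_neighbors,
        iteration=t_done,
    )


def fuse(state: FusionState, as_similarity: bool = True):
    """Average the diffused kernels into the fused network.

    With ``as_similarity`` the average is symmetrized as (P+P')/2, the
    off-diagonal rescaled into [0,1] by its maximum, and the diagonal set
    to 1, yielding a valid :class:`SimilarityMatrix`; otherwise the raw
    averaged kernel array is returned.
    """
    avg = sum(state.full_kernels) / len(state.full_kernels)
    if not as_similarity:
        return avg
    sym = (avg + avg.T) / 2.0
    np.fill_diagonal(sym, 0.0)
    top = sym.max()
    if top > 0:
        sym = sym / top
    np.fill_diagonal(sym, 1.0)
    return SimilarityMatrix(index=state.index, values=sym, source_tag="Fused").validate()


def snf(
    matrices: list[SimilarityMatrix],
    k: int | None = None,
    t_max: int = 20,
    convergence_tol: float | None = 1e-6,
) -> SimilarityMatrix:
    """Convenience wrapper: build the fusion state, iterate, and fuse."""
    state = FusionState.from_matrices(matrices, k=k)
    state = snf_iterate(state, t_max=t_max, convergence_tol=convergence_tol)
    return fuse(state)
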