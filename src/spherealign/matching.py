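"""Unsupervised correspondence and orthogonal alignment between two clouds.

Given two sets of representative latent points (one per dataset), a
correspondence is found without labels by kernelized sorting: the
permutation pi maximizing the Hilbert-Schmidt Independence Criterion

    HSIC(pi, Kbar, Lbar) = trace(Kbar pi^T Lbar pi)

between the two double-centered pairwise-distance matrices.  The
maximization is solved by iterated linear assignment from random initial
permutations.  The matched pairs then yield the orthogonal (rotation +
reflection) transfer map by SVD Procrustes.

Permutation orientation (fixed everywhere): the permutation matrix is
``pi[i, perm[i]] = 1``, so ``perm[k]`` is the K-side (dataset A) index
matched to L-side (dataset B) index ``k``; matched Procrustes pairs are
``(A_points[perm[k]], B_points[k])``.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform, pdist

from .data import LatentCloud

__all__ = [
    "CenteredDistanceMatrix",
    "RepresentativeSet",
    "MatchResult",
    "OrthogonalMap",
    "AlignmentUndefinedError",
    "centered_distance_matrix",
    "select_representatives",
    "hsic",
    "normalized_hsic",
    "kernelized_sort",
    "procrustes_orthogonal",
]


class AlignmentUndefinedError(RuntimeError):
    """Raised when the Procrustes problem or HSIC normalization degenerates."""


@dataclass
class CenteredDistanceMatrix:
    """Double-centered pairwise distance matrix Kbar = H D H."""

    values: np.ndarray
    metric: str = "cosine"
    centering: str = "double"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("values must be square")
        self.values = v

    @property
    def size(self) -> int:
        return self.values.shape[0]

    def frobenius_norm(self) -> float:
        return float(np.linalg.norm(self.values))


@dataclass
class RepresentativeSet:
    """Cluster-representative latent points selected by local density."""

    indices: np.ndarray
    points: np.ndarray
    neighbor_counts: np.ndarray
    complete: bool = True  # False when fewer than m_target could be selected

    @property
    def size(self) -> int:
        return len(self.indices)


@dataclass
class MatchResult:
    permutation: np.ndarray
    hsic: float
    normalized_hsic: float
    restarts_run: int
    iterations_per_restart: list = field(default_factory=list)

    def __post_init__(self):
        p = np.asarray(self.permutation, dtype=np.intp)
        if sorted(p.tolist()) != list(range(len(p))):
            raise ValueError("permutation must be a bijection on 0..m-1")
        self.permutation = p


@dataclass
class OrthogonalMap:
    """Orthogonal matrix R transferring source-space latents into the target
    space, column-vector convention: y_target ~= R @ y_source."""

    R: np.ndarray
    source: str = "B"
    target: str = "A"

    def __post_init__(self):
        R = np.asarray(self.R, dtype=np.float64)
        n = R.shape[0]
        if R.ndim != 2 or R.shape[1] != n:
            raise ValueError("R must be square")
        if np.linalg.norm(R.T @ R - np.eye(n)) > 1e-8 * max(1.0, n):
            raise ValueError("R is not orthogonal within tolerance")
        self.R = R

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to row-stored points: returns points @ R.T."""
        return np.asarray(points, dtype=np.float64) @ self.R.T

    def inverse(self) -> "OrthogonalMap":
        return OrthogonalMap(R=self.R.T, source=self.target, target=self.source)

    @property
    def determinant(self) -> float:
        return float(np.linalg.det(self.R))


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------

def _pairwise_distance(points: np.ndarray, metric: str) -> np.ndarray:
    if metric == "cosine":
        G = points @ points.T
        nrm = np.linalg.norm(points, axis=1)
        D = 1.0 - G / np.outer(nrm, nrm)
        np.fill_diagonal(D, 0.0)
        return D
    if metric == "euclidean":
        return squareform(pdist(points, metric="euclidean"))
    raise ValueError(f"unknown metric {metric!r}")


def centered_distance_matrix(cloud, metric: str = "cosine",
                             centering: str = "double") -> CenteredDistanceMatrix:
    """Zero-mean pairwise distance matrix of a point cloud.

    ``centering='double'`` (default) applies H D H with H = I - (1/m) 11^T,
    zeroing every row sum, column sum and the grand sum — the convention of
    the HSIC literature.  ``centering='grand'`` subtracts only the grand
    mean (kept for sensitivity analysis).
    """
    points = cloud.points if isinstance(cloud, LatentCloud) else np.asarray(cloud, float)
    m = points.shape[0]
    if m < 2:
        raise ValueError("need at least 2 points")
    D = _pairwise_distance(points, metric)
    if centering == "double":
        rm = D.mean(axis=1, keepdims=True)
        cm = D.mean(axis=0, keepdims=True)
        C = D - rm - cm + D.mean()
    elif centering == "grand":
        C = D - D.mean()
    else:
        raise ValueError(f"unknown centering {centering!r}")
    return CenteredDistanceMatrix(values=C, metric=metric, centering=centering)


# ---------------------------------------------------------------------------
# representative selection
# ---------------------------------------------------------------------------

def select_representatives(cloud: LatentCloud, neighbor_radius: float = 0.2,
                           separation: float = 0.2, m_target: int = 1600
                           ) -> RepresentativeSet:
    """Greedy density-based selection of cluster representatives.

    Each point's neighbor count is the number of other points within cosine
    distance ``neighbor_radius``.  Candidates are visited in descending
    neighbor count (ties by ascending index) and accepted iff at cosine
    distance >= ``separation`` from every point already selected, stopping
    at ``m_target`` or exhaustion.
    """
    if cloud.n_points == 0:
        raise ValueError("empty cloud")
    if neighbor_radius <= 0 or separation <= 0 or m_target < 1:
        raise ValueError("neighbor_radius, separation must be > 0 and m_target >= 1")
    D = _pairwise_distance(cloud.points, "cosine")
    counts = ((D < neighbor_radius).sum(axis=1) - 1).astype(np.intp)  # exclude self
    order = np.lexsort((np.arange(len(counts)), -counts))
    selected: list[int] = []
    for i in order:
        if all(D[i, j] >= separation for j in selected):
            selected.append(int(i))
            if len(selected) == m_target:
                break
    complete = len(selected) == m_target
    if not complete:
        warnings.warn(
            f"only {len(selected)} of {m_target} representatives satisfy the "
            f"separation constraint", stacklevel=2)
    idx = np.asarray(selected, dtype=np.intp)
    return RepresentativeSet(indices=idx, points=cloud.points[idx],
                             neighbor_counts=counts[idx], complete=complete)


# ---------------------------------------------------------------------------
# HSIC and kernelized sorting
# ---------------------------------------------------------------------------

def _check_perm(perm, m: int) -> np.ndarray:
    p = np.asarray(perm, dtype=np.intp)
    if p.shape != (m,) or sorted(p.tolist()) != list(range(m)):
        raise ValueError("perm must be a bijection on 0..m-1")
    return p


def _values(M) -> np.ndarray:
    return M.values if isinstance(M, CenteredDistanceMatrix) else np.asarray(M, float)


def hsic(perm, K, L) -> float:
    """trace(Kbar pi^T Lbar pi) with pi[i, perm[i]] = 1."""
    Kv, Lv = _values(K), _values(L)
    if Kv.shape != Lv.shape:
        raise ValueError("K and L must have the same size")
    p = _check_perm(perm, Kv.shape[0])
    inv = np.empty_like(p)
    inv[p] = np.arange(len(p))
    # (pi^T L pi)[a, b] = L[inv[a], inv[b]]
    Lp = Lv[np.ix_(inv, inv)]
    return float(np.einsum("ij,ji->", Kv, Lp))


def normalized_hsic(perm, K, L) -> float:
    """HSIC divided by the product of Frobenius norms; in [-1, 1]."""
    Kv, Lv = _values(K), _values(L)
    nk, nl = np.linalg.norm(Kv), np.linalg.norm(Lv)
    if nk == 0 or nl == 0:
        raise AlignmentUndefinedError("zero-norm centered matrix")
    return hsic(perm, K, L) / (nk * nl)


def _sort_once(Kv: np.ndarray, Lv: np.ndarray, perm0: np.ndarray,
               max_iter: int) -> tuple[np.ndarray, float, int]:
    """Iterated linear assignment from one initial permutation.

    The update linearizes the quadratic objective around the current
    iterate; because centered distance matrices are indefinite the true
    objective need not increase at every step, so the best permutation
    visited (including the start) is tracked and returned.
    """
    perm = perm0
    best_perm, best_val = perm0, hsic(perm0, Kv, Lv)
    for it in range(max_iter):
        # maximize trace(K pi^T L pi_t) over pi: score[k, a] = sum_l L[k,l] K[perm[l], a]
        C = Lv @ Kv[perm]
        _, new = linear_sum_assignment(C, maximize=True)
        new = new.astype(np.intp)
        val = hsic(new, Kv, Lv)
        if val > best_val:
            best_perm, best_val = new, val
        if np.array_equal(new, perm):
            return best_perm, best_val, it + 1
        perm = new
    return best_perm, best_val, max_iter


def kernelized_sort(K, L, restarts: int = 1000, seed: int = 0,
                    max_iter: int = 100) -> MatchResult:
    """HSIC-maximizing permutation by iterated linear assignment.

    Each restart initializes pi uniformly at random (restart r uses its own
    generator seeded ``seed + r``, so results do not depend on execution
    order), iterates the assignment update to a fixed point or ``max_iter``,
    and the best permutation visited over all restarts by HSIC value is
    returned (ties broken by first occurrence).  When ``restarts`` reaches
    m! the random initializations are replaced by a complete enumeration of
    starting permutations, so for small m the search is exhaustive.
    """
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    Kv, Lv = _values(K), _values(L)
    if Kv.shape != Lv.shape:
        raise ValueError("K and L must have the same size")
    m = Kv.shape[0]
    best_perm, best_val = None, -np.inf
    iters: list[int] = []
    n_all = math.factorial(m) if m <= 10 else None
    if n_all is not None and restarts >= n_all:
        starts = (np.asarray(p, dtype=np.intp)
                  for p in itertools.permutations(range(m)))
        restarts_run = n_all
    else:
        def _random_starts():
            for r in range(restarts):
                yield np.random.default_rng(seed + r).permutation(m).astype(np.intp)
        starts = _random_starts()
        restarts_run = restarts
    for perm0 in starts:
        perm, val, n_it = _sort_once(Kv, Lv, perm0, max_iter)
        iters.append(n_it)
        if val > best_val:
            best_perm, best_val = perm, val
    return MatchResult(permutation=best_perm, hsic=best_val,
                       normalized_hsic=normalized_hsic(best_perm, Kv, Lv),
                       restarts_run=restarts_run, iterations_per_restart=iters)


# ---------------------------------------------------------------------------
# orthogonal Procrustes
# ---------------------------------------------------------------------------

def procrustes_orthogonal(P: np.ndarray, Q: np.ndarray,
                          source: str = "B", target: str = "A") -> OrthogonalMap:
    """Best orthogonal map R with y_A ~= R y_B from matched rows of P and Q.

    P holds target-space (A) points, Q source-space (B) points, rows already
    matched.  From the SVD Q^T P = U S V^T the maximizer of
    sum_i p_i . (R q_i) over orthogonal R is R = V U^T (column-vector
    convention; reflections permitted).
    """
    P = np.asarray(P, dtype=np.float64)
    Q = np.asarray(Q, dtype=np.float64)
    if P.shape != Q.shape:
        raise ValueError("P and Q must have the same shape")
    m, n = P.shape
    if m < n:
        warnings.warn(f"only {m} matched pairs for a {n}-dimensional map; "
                      "the solution is underdetermined", stacklevel=2)
    M = Q.T @ P
    if not np.any(M):
        raise AlignmentUndefinedError("Q^T P is zero; alignment undefined")
    U, _, Vt = np.linalg.svd(M)
    R = Vt.T @ U.T
    return OrthogonalMap(R=R, source=source, target=target)
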