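"""Quantitative evaluation of a representation transfer.

The central statistic is the alignment score: the mean cosine similarity
between one dataset's test latents y_i and the orthogonally transferred
latents R yhat_i of the other, over samples whose correspondence is known
(the correspondence is used for evaluation only, never for training).
Because R is orthogonal the score is identical whether computed in either
latent space.  The supervised upper bound replaces the unsupervised R with
the Procrustes optimum computed from the full labeled test correspondence.

Also provided: the per-sample noise-robustness distribution
d_i = 1 - cos(E(x_i), E(x_i + eps)), k-nearest-neighbor category
discrimination in latent space, and representational dissimilarity matrices
(RDMs) with their correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ActivityDataset, LatentCloud
from .embedding import AugmentationConfig, HypersphereEncoder, augment
from .matching import OrthogonalMap, procrustes_orthogonal, _pairwise_distance

__all__ = [
    "EvalReport",
    "UndefinedCorrelationError",
    "alignment_score",
    "upper_bound_map",
    "noise_robustness",
    "knn_category_discrimination",
    "rdm",
    "rdm_correlation",
]


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation is requested of constant values."""


@dataclass
class EvalReport:
    alignment_score: float
    upper_bound_score: float
    normalized_hsic: float | None = None
    knn_accuracy: float | None = None
    rdm_correlation: float | None = None
    per_sample_similarities: np.ndarray | None = None

    def to_dict(self) -> dict:
        out = {
            "alignment_score": self.alignment_score,
            "upper_bound_score": self.upper_bound_score,
        }
        for k in ("normalized_hsic", "knn_accuracy", "rdm_correlation"):
            v = getattr(self, k)
            if v is not None:
                out[k] = float(v)
        return out


def _points(x) -> np.ndarray:
    return x.points if isinstance(x, LatentCloud) else np.asarray(x, dtype=np.float64)


def alignment_score(latents_a, latents_b, omap: OrthogonalMap
                    ) -> tuple[float, np.ndarray]:
    """Mean and per-sample cosine similarity cos(y_i, R yhat_i).

    Rows of the two clouds must be in corresponding order.  Computing in
    A-space with R or in B-space with R^T gives identical values.
    """
    A, B = _points(latents_a), _points(latents_b)
    if A.shape != B.shape:
        raise ValueError("latent clouds must have the same shape")
    Bt = omap.apply(B)
    num = np.sum(A * Bt, axis=1)
    den = np.linalg.norm(A, axis=1) * np.linalg.norm(Bt, axis=1)
    sims = num / den
    return float(sims.mean()), sims


def upper_bound_map(latents_a, latents_b) -> tuple[OrthogonalMap, float]:
    """Procrustes map from the full labeled test correspondence and its
    alignment score — the supervised upper bound of the transfer task."""
    A, B = _points(latents_a), _points(latents_b)
    omap = procrustes_orthogonal(A, B)
    score, _ = alignment_score(A, B, omap)
    return omap, score


def noise_robustness(encoder: HypersphereEncoder, test: ActivityDataset,
                     gain: float, reps: int = 50, seed: int = 0) -> np.ndarray:
    """Per-sample, per-repetition cosine distance under input perturbation.

    d_i = 1 - cos(E(x_i), E(x_i + eps)) with eps per-dimension Gaussian of
    SD ``gain * feature_sd``; ``reps`` independent noise patterns per sample
    (default 50).  Small values mean the embedding is robust to input noise.
    """
    if gain < 0:
        raise ValueError("gain must be >= 0")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    cfg = AugmentationConfig(noise_gain=gain, rng_seed=seed)
    Y = encoder.transform(test.samples)
    out = np.empty((test.n_samples, reps))
    for r in range(reps):
        Xn = augment(test.samples, test, cfg, rng=rng)
        Yn = encoder.transform(Xn)
        out[:, r] = 1.0 - np.sum(Y * Yn, axis=1)
    return out


def knn_category_discrimination(train: LatentCloud, train_labels, test: LatentCloud,
                                k: int = 20, test_labels=None
                                ) -> tuple[float | None, list]:
    """Modal-label k-NN classification in latent space by cosine distance.

    Prediction for each test point is the modal label among its k nearest
    train points (default k=20).  Distance ties are broken by ascending
    train index (stable sort); modal ties by the label of the nearest member
    among the tied labels.  Returns ``(accuracy, predictions)``; accuracy is
    None when ``test_labels`` is not supplied.
    """
    labels = list(train_labels)
    if train.n_points == 0:
        raise ValueError("empty train set")
    if len(labels) != train.n_points:
        raise ValueError("train_labels length mismatch")
    if not (1 <= k <= train.n_points):
        raise ValueError("require 1 <= k <= train size")
    D = 1.0 - _points(test) @ _points(train).T
    preds = []
    for row in D:
        nn = np.argsort(row, kind="stable")[:k]
        counts: dict = {}
        for j in nn:
            counts[labels[j]] = counts.get(labels[j], 0) + 1
        top = max(counts.values())
        tied = {lab for lab, c in counts.items() if c == top}
        if len(tied) == 1:
            preds.append(next(iter(tied)))
        else:
            preds.append(next(labels[j] for j in nn if labels[j] in tied))
    acc = None
    if test_labels is not None:
        truth = list(test_labels)
        if len(truth) != len(preds):
            raise ValueError("test_labels length mismatch")
        acc = float(np.mean([p == t for p, t in zip(preds, truth)]))
    return acc, preds


def rdm(data: np.ndarray, metric: str = "euclidean") -> np.ndarray:
    """Representational dissimilarity matrix: symmetric, zero diagonal.

    Euclidean for raw-space responses, cosine for latent-space points.
    """
    X = _points(data)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite input")
    return _pairwise_distance(X, metric)


def rdm_correlation(rdm1: np.ndarray, rdm2: np.ndarray) -> float:
    """Pearson correlation of the strictly-upper-triangle entries."""
    A = np.asarray(rdm1, float)
    B = np.asarray(rdm2, float)
    if A.shape != B.shape:
        raise ValueError("RDMs must have the same shape")
    iu = np.triu_indices(A.shape[0], k=1)
    a, b = A[iu], B[iu]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedCorrelationError("constant upper triangle")
    return float(np.corrcoef(a, b)[0, 1])
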