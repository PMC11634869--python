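"""Distribution-matching fine-tuning and the end-to-end transfer pipeline.

After the orthogonal map R (source B -> target A) has been estimated from
the unsupervised match, the source encoder is fine-tuned so that the
distribution of its rotated latents matches the target latent distribution,
minimizing the squared maximum mean discrepancy (MMD) with a Gaussian RBF
kernel.  The target encoder and R stay frozen; batch-norm statistics of the
tuned encoder are also frozen so that fine-tuning only moves the affine
weights.  Because the RBF kernel depends only on pairwise distances,
MMD is invariant under a common rotation of both samples, so minimizing
MMD(R E_B(x), Y_A) refines rather than competes with the step-B alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

from .data import ActivityDataset, LatentCloud
from .embedding import (HypersphereEncoder, TrainingDivergedError, _backward,
                        _forward)
from .matching import OrthogonalMap

__all__ = ["MMDConfig", "TransferPipeline", "DegenerateBandwidthError",
           "mmd_squared", "fine_tune", "transfer"]


class DegenerateBandwidthError(ValueError):
    """Raised when the median-heuristic bandwidth resolves to zero."""


@dataclass
class MMDConfig:
    kernel: str = "gaussian_rbf"
    bandwidth: float | str = "median_heuristic"
    estimator: str = "biased"
    epochs: int = 200
    batch_size: int = 512
    learning_rate: float = 0.001

    def __post_init__(self):
        if self.kernel != "gaussian_rbf":
            raise ValueError("only the gaussian_rbf kernel is supported")
        if self.estimator not in ("biased", "unbiased"):
            raise ValueError("estimator must be 'biased' or 'unbiased'")
        if not isinstance(self.bandwidth, str) and self.bandwidth <= 0:
            raise ValueError("bandwidth must be > 0")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "kernel", "bandwidth", "estimator", "epochs", "batch_size",
            "learning_rate")}


@dataclass
class TransferPipeline:
    """Complete transfer: y_A ~= R E_B(x_B), with E_A kept for evaluation."""

    encoder_a: HypersphereEncoder
    encoder_b: HypersphereEncoder
    map: OrthogonalMap
    provenance: dict = field(default_factory=dict)
    finetune_log: list = field(default_factory=list)


def _resolve_bandwidth(X: np.ndarray, Y: np.ndarray, cfg: MMDConfig) -> float:
    if not isinstance(cfg.bandwidth, str):
        return float(cfg.bandwidth)
    if cfg.bandwidth != "median_heuristic":
        raise ValueError(f"unknown bandwidth rule {cfg.bandwidth!r}")
    pooled = np.vstack([X, Y])
    med = float(np.median(pdist(pooled)))
    if med == 0.0:
        raise DegenerateBandwidthError("all pooled points identical")
    return med


def _rbf(A: np.ndarray, B: np.ndarray, sigma: float) -> np.ndarray:
    d2 = (np.sum(A * A, axis=1)[:, None] + np.sum(B * B, axis=1)[None, :]
          - 2.0 * A @ B.T)
    return np.exp(-np.maximum(d2, 0.0) / (2.0 * sigma * sigma))


def mmd_squared(X: np.ndarray, Y: np.ndarray, cfg: MMDConfig | None = None
                ) -> float:
    """Kernel two-sample MMD^2 with Gaussian RBF kernel.

    The biased (V-statistic) estimator is >= 0 always; the unbiased
    (U-statistic) estimator may be negative, bounded below by
    -2/min(p,q) times the maximum kernel value (here 1).
    """
    cfg = cfg or MMDConfig()
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    p, q = X.shape[0], Y.shape[0]
    if cfg.estimator == "unbiased" and (p < 2 or q < 2):
        raise ValueError("unbiased estimator needs p, q >= 2")
    sigma = _resolve_bandwidth(X, Y, cfg)
    Kxx, Kyy, Kxy = _rbf(X, X, sigma), _rbf(Y, Y, sigma), _rbf(X, Y, sigma)
    if cfg.estimator == "biased":
        return float(Kxx.mean() + Kyy.mean() - 2.0 * Kxy.mean())
    sx = (Kxx.sum() - np.trace(Kxx)) / (p * (p - 1))
    sy = (Kyy.sum() - np.trace(Kyy)) / (q * (q - 1))
    return float(sx + sy - 2.0 * Kxy.mean())


def _mmd_grad_x(X: np.ndarray, Y: np.ndarray, sigma: float) -> tuple[float, np.ndarray]:
    """Biased MMD^2 and its gradient w.r.t. the rows of X (Y fixed)."""
    p, q = X.shape[0], Y.shape[0]
    Kxx, Kyy, Kxy = _rbf(X, X, sigma), _rbf(Y, Y, sigma), _rbf(X, Y, sigma)
    val = float(Kxx.mean() + Kyy.mean() - 2.0 * Kxy.mean())
    inv_s2 = 1.0 / (sigma * sigma)
    # d/dx_i of (1/p^2) sum Kxx: (2/p^2) sum_j k(x_i,x_j)(x_j-x_i)/sigma^2
    g_xx = (Kxx @ X - Kxx.sum(axis=1)[:, None] * X) * (2.0 * inv_s2 / (p * p))
    g_xy = (Kxy @ Y - Kxy.sum(axis=1)[:, None] * X) * (-2.0 * inv_s2 / (p * q))
    return val, g_xx + g_xy


def transfer(pipeline: TransferPipeline, x_b: np.ndarray,
             sample_ids=None) -> LatentCloud:
    """Embed source-space activity and rotate it into the target space."""
    Y = pipeline.encoder_b.transform(np.asarray(x_b, dtype=np.float64))
    return LatentCloud(points=pipeline.map.apply(Y), sample_ids=sample_ids,
                       encoder_id=pipeline.encoder_b.encoder_id + "->"
                       + pipeline.encoder_a.encoder_id)


def fine_tune(pipeline: TransferPipeline, data_b: ActivityDataset,
              latents_a: LatentCloud, cfg: MMDConfig, seed: int = 0
              ) -> TransferPipeline:
    """Fine-tune the source encoder by SGD on the (biased) MMD^2 between its
    rotated latents and the fixed target latents.

    Only E_B's affine weights move; E_A, R, and E_B's batch-norm statistics
    are frozen.  ``cfg.epochs = 0`` returns the pipeline unchanged.
    """
    if cfg.epochs == 0:
        return pipeline
    rng = np.random.default_rng(seed)
    enc = pipeline.encoder_b.copy()
    w = enc.weights
    Xb = data_b.samples
    Ya = latents_a.points
    R = pipeline.map.R
    n_b, n_a = Xb.shape[0], Ya.shape[0]
    bs = min(cfg.batch_size, n_b, n_a)
    log: list[tuple[int, float]] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n_b)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n_b, bs):
            ids = order[start:start + bs]
            if len(ids) < 2:
                continue
            xb = Xb[ids]
            ya = Ya[rng.choice(n_a, size=len(ids), replace=False)]
            F, cache = _forward(w, xb, train=False)  # frozen BN statistics
            Frot = F @ R.T
            sigma = _resolve_bandwidth(Frot, ya, cfg)
            loss, gX = _mmd_grad_x(Frot, ya, sigma)
            if not math.isfinite(loss):
                raise TrainingDivergedError(f"non-finite MMD at epoch {epoch}")
            grads = _backward(w, cache, gX @ R, train_batch=False)
            for k in ("W1", "b1", "gamma", "beta", "W2", "b2"):
                w[k] -= cfg.learning_rate * grads[k]
            epoch_loss += loss
            n_batches += 1
        log.append((epoch, epoch_loss / max(n_batches, 1)))
    return TransferPipeline(encoder_a=pipeline.encoder_a, encoder_b=enc,
                            map=pipeline.map,
                            provenance={**pipeline.provenance,
                                        "finetune": cfg.to_dict(),
                                        "finetune_seed": seed},
                            finetune_log=log)
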