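"""Hypersphere embedding by contrastive instance discrimination.

Each dataset gets its own two-layer encoder

    x  ->  FC -> batch-norm -> ReLU  ->  FC -> L2-normalization  ->  y,

mapping D-dimensional activity vectors to unit vectors on S^(n-1).  Training
follows the memory-bank instance-discrimination rule: every training sample
is its own class, the positive for sample i is a Gaussian-noise-augmented
copy of x_i, and negatives are other samples' bank entries.  The
non-parametric softmax loss for one sample is

    -log  exp(f_i . v_i / tau) / ( exp(f_i . v_i / tau)
                                   + sum_{j in Neg_i} exp(f_i . v_j / tau) )

where f_i is the embedded augmented sample, v_i its memory-bank entry, tau a
temperature controlling repulsion, and Neg_i a uniform sample of other bank
indices.  The bank is updated each step as v_i <- normalize(lam v_i +
(1-lam) f_i).

Hyperparameters (tau, noise gain k_sigma) are selected by a grid search that
keeps only cells whose embedded training set is numerically full-rank and,
among those, maximizes the skewness of the pairwise cosine-similarity
distribution — skewed (clustered) embeddings expose the representative
points that later stages match across datasets.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import ActivityDataset, LatentCloud

__all__ = [
    "AugmentationConfig",
    "EncoderConfig",
    "HypersphereEncoder",
    "TrainingDivergedError",
    "UndefinedSkewnessError",
    "NoValidHyperparametersError",
    "intermediate_dim",
    "augment",
    "instance_loss",
    "train_encoder",
    "embed",
    "pairwise_cosine_skewness",
    "is_linearly_independent",
    "grid_search_hyperparams",
]

_BN_EPS = 1e-5
_BN_RUNNING_MOMENTUM = 0.9


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


class UndefinedSkewnessError(ValueError):
    """Raised when all pairwise similarities are identical."""


class NoValidHyperparametersError(RuntimeError):
    """Raised when every grid cell fails the linear-independence criterion."""


def intermediate_dim(input_dim: int, latent_dim: int) -> int:
    """Width of the hidden layer: logarithmic spacing between input and output.

    Returns ``round(sqrt(input_dim * latent_dim))``, i.e. the geometric mean
    of the two widths; half-integers round to the nearest even integer
    (banker's rounding, Python's built-in ``round``).
    """
    if input_dim <= 0 or latent_dim <= 0:
        raise ValueError("dimensions must be positive")
    if input_dim < latent_dim:
        raise ValueError("input_dim must be >= latent_dim")
    return round(math.sqrt(input_dim * latent_dim))


@dataclass
class AugmentationConfig:
    """Gaussian-noise augmentation: per-dimension SD = noise_gain * sigma_j."""

    noise_gain: float = 1.5
    rng_seed: int = 0

    def __post_init__(self):
        if self.noise_gain < 0:
            raise ValueError("noise_gain must be >= 0")


@dataclass
class EncoderConfig:
    input_dim: int = 0
    intermediate_dim: int = 0
    latent_dim: int = 32
    temperature: float = 0.5
    n_negatives: int = 4096
    batch_size: int = 512
    epochs: int = 5000
    learning_rate: float = 0.01
    bank_momentum: float = 0.5

    def __post_init__(self):
        if self.input_dim and not self.intermediate_dim:
            self.intermediate_dim = intermediate_dim(self.input_dim, self.latent_dim)
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if not (0 <= self.bank_momentum < 1):
            raise ValueError("bank_momentum must be in [0, 1)")
        if self.input_dim:
            if not (self.input_dim >= self.intermediate_dim >= self.latent_dim):
                raise ValueError("require input_dim >= intermediate_dim >= latent_dim")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "input_dim", "intermediate_dim", "latent_dim", "temperature",
            "n_negatives", "batch_size", "epochs", "learning_rate", "bank_momentum")}


def augment(x: np.ndarray, dataset: ActivityDataset, cfg: AugmentationConfig,
            rng: np.random.Generator | None = None) -> np.ndarray:
    """Add per-dimension Gaussian noise with SD ``noise_gain * feature_sd``.

    ``rng`` may be passed to draw fresh noise across repeated calls; when
    omitted a generator is created from ``cfg.rng_seed``.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] != dataset.n_features:
        raise ValueError(
            f"input has {x.shape[-1]} features, dataset has {dataset.n_features}")
    if cfg.noise_gain == 0:
        return x.copy()
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    sd = cfg.noise_gain * dataset.feature_sd
    return x + rng.standard_normal(x.shape) * sd


# ---------------------------------------------------------------------------
# network forward / backward
# ---------------------------------------------------------------------------

def _init_weights(cfg: EncoderConfig, rng: np.random.Generator) -> dict:
    d, h, n = cfg.input_dim, cfg.intermediate_dim, cfg.latent_dim
    return {
        "W1": rng.standard_normal((d, h)) * math.sqrt(2.0 / d),
        "b1": np.zeros(h),
        "gamma": np.ones(h),
        "beta": np.zeros(h),
        "W2": rng.standard_normal((h, n)) * math.sqrt(1.0 / h),
        "b2": np.zeros(n),
        "bn_mean": np.zeros(h),
        "bn_var": np.ones(h),
    }


def _forward(w: dict, X: np.ndarray, train: bool):
    """Forward pass; returns (Y, cache). Train mode uses batch statistics and
    updates the running batch-norm statistics in place."""
    Z1 = X @ w["W1"] + w["b1"]
    if train:
        mu = Z1.mean(axis=0)
        var = Z1.var(axis=0)
        m = _BN_RUNNING_MOMENTUM
        w["bn_mean"] = m * w["bn_mean"] + (1 - m) * mu
        w["bn_var"] = m * w["bn_var"] + (1 - m) * var
    else:
        mu, var = w["bn_mean"], w["bn_var"]
    inv_std = 1.0 / np.sqrt(var + _BN_EPS)
    Xhat = (Z1 - mu) * inv_std
    A = w["gamma"] * Xhat + w["beta"]
    H = np.maximum(A, 0.0)
    Z2 = H @ w["W2"] + w["b2"]
    r = np.linalg.norm(Z2, axis=1, keepdims=True)
    r = np.maximum(r, 1e-12)
    Y = Z2 / r
    cache = (X, Xhat, inv_std, A, H, Y, r)
    return Y, cache


def _backward(w: dict, cache, dY: np.ndarray, train_batch: bool = True) -> dict:
    X, Xhat, inv_std, A, H, Y, r = cache
    B = X.shape[0]
    # L2-normalization: dZ2 = (dY - Y <dY, Y>) / r
    dZ2 = (dY - Y * np.sum(dY * Y, axis=1, keepdims=True)) / r
    grads = {"W2": H.T @ dZ2, "b2": dZ2.sum(axis=0)}
    dH = dZ2 @ w["W2"].T
    dA = dH * (A > 0)
    grads["gamma"] = np.sum(dA * Xhat, axis=0)
    grads["beta"] = dA.sum(axis=0)
    dXhat = dA * w["gamma"]
    if train_batch:
        # batch statistics participate in the forward pass
        dZ1 = (inv_std / B) * (
            B * dXhat - dXhat.sum(axis=0) - Xhat * np.sum(dXhat * Xhat, axis=0))
    else:
        dZ1 = dXhat * inv_std
    grads["W1"] = X.T @ dZ1
    grads["b1"] = dZ1.sum(axis=0)
    return grads


# ---------------------------------------------------------------------------
# instance-discrimination loss
# ---------------------------------------------------------------------------

def _sample_negatives(instance_ids: np.ndarray, n_bank: int, n_negatives: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Uniform negatives without replacement, excluding each row's own id."""
    n_neg = min(n_negatives, n_bank - 1)
    out = np.empty((len(instance_ids), n_neg), dtype=np.intp)
    for row, i in enumerate(instance_ids):
        draw = rng.choice(n_bank - 1, size=n_neg, replace=False)
        draw[draw >= i] += 1  # skip self
        out[row] = draw
    return out


def _loss_and_grad(embedded: np.ndarray, instance_ids: np.ndarray,
                   bank: np.ndarray, temperature: float, n_negatives: int,
                   rng: np.random.Generator):
    """Mean instance loss over the batch and its gradient w.r.t. ``embedded``."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    B, n = embedded.shape
    n_bank = bank.shape[0]
    ids = np.asarray(instance_ids, dtype=np.intp)
    if np.any(ids < 0) or np.any(ids >= n_bank):
        raise ValueError("instance_ids out of bank range")
    n_neg = min(n_negatives, n_bank - 1)
    # candidate set per row: own bank entry first, then sampled negatives
    if n_neg == 0:
        cand = ids[:, None]
    elif n_neg == n_bank - 1:
        # all other instances serve as negatives: deterministic candidate set
        others = np.empty((B, n_neg), dtype=np.intp)
        base = np.arange(n_bank - 1)
        for row, i in enumerate(ids):
            o = base.copy()
            o[o >= i] += 1
            others[row] = o
        cand = np.concatenate([ids[:, None], others], axis=1)
    else:
        negs = _sample_negatives(ids, n_bank, n_negatives, rng)
        cand = np.concatenate([ids[:, None], negs], axis=1)
    V = bank[cand]                                    # B x C x n
    logits = np.einsum("bn,bcn->bc", embedded, V) / temperature
    logits -= logits.max(axis=1, keepdims=True)
    expl = np.exp(logits)
    P = expl / expl.sum(axis=1, keepdims=True)
    loss = float(np.mean(-np.log(np.maximum(P[:, 0], 1e-300))))
    coef = P.copy()
    coef[:, 0] -= 1.0
    dE = np.einsum("bc,bcn->bn", coef, V) / (temperature * B)
    return loss, dE


def instance_loss(embedded: np.ndarray, instance_ids, bank: np.ndarray,
                  temperature: float, n_negatives: int,
                  rng: np.random.Generator | None = None) -> float:
    """Mean memory-bank instance-discrimination loss over a batch.

    Negatives are drawn uniformly without replacement from bank indices
    excluding each row's own instance (capped at bank size minus one).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    loss, _ = _loss_and_grad(np.asarray(embedded, dtype=np.float64),
                             instance_ids, np.asarray(bank, dtype=np.float64),
                             temperature, n_negatives, rng)
    return loss


# ---------------------------------------------------------------------------
# encoder object and training loop
# ---------------------------------------------------------------------------

@dataclass
class HypersphereEncoder:
    """Trained two-layer encoder mapping activity vectors onto S^(n-1)."""

    weights: dict
    config: EncoderConfig
    training_log: list = field(default_factory=list)
    augmentation: AugmentationConfig | None = None
    encoder_id: str = ""

    def __post_init__(self):
        if not self.encoder_id:
            key = repr(sorted(self.config.to_dict().items())).encode()
            self.encoder_id = "enc-" + hashlib.sha1(key).hexdigest()[:10]

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Inference-mode forward pass (frozen batch-norm statistics)."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.config.input_dim:
            raise ValueError(
                f"input has {X.shape[1]} features, encoder expects {self.config.input_dim}")
        if X.shape[0] == 0:
            return np.empty((0, self.config.latent_dim))
        Y, _ = _forward(self.weights, X, train=False)
        return Y

    def copy(self) -> "HypersphereEncoder":
        return HypersphereEncoder(
            weights={k: v.copy() for k, v in self.weights.items()},
            config=self.config,
            training_log=list(self.training_log),
            augmentation=self.augmentation,
            encoder_id=self.encoder_id,
        )

    def weight_checksum(self) -> str:
        h = hashlib.sha256()
        for k in sorted(self.weights):
            h.update(k.encode())
            h.update(np.ascontiguousarray(self.weights[k]).tobytes())
        return h.hexdigest()


def train_encoder(dataset: ActivityDataset, cfg: EncoderConfig,
                  aug: AugmentationConfig, seed: int = 0,
                  log_every: int = 1) -> HypersphereEncoder:
    """Train an encoder by instance discrimination with SGD.

    Deterministic given ``seed`` (weight init, batch order, negative
    sampling, augmentation noise all derive from it).  The memory bank is
    updated after every step from the augmented embeddings,
    ``v_i <- normalize(lam v_i + (1-lam) f_i)``.
    """
    if cfg.epochs < 1:
        raise ValueError("epochs must be >= 1")
    if cfg.input_dim == 0:
        cfg = EncoderConfig(**{**cfg.to_dict(), "input_dim": dataset.n_features,
                               "intermediate_dim": 0})
    if cfg.input_dim != dataset.n_features:
        raise ValueError("cfg.input_dim does not match dataset")
    rng = np.random.default_rng(seed)
    N = dataset.n_samples
    X = dataset.samples
    w = _init_weights(cfg, rng)
    bank = rng.standard_normal((N, cfg.latent_dim))
    bank /= np.linalg.norm(bank, axis=1, keepdims=True)
    lam = cfg.bank_momentum
    lr = cfg.learning_rate
    noise_sd = aug.noise_gain * dataset.feature_sd
    log: list[tuple[int, float]] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(N)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, N, cfg.batch_size):
            ids = order[start:start + cfg.batch_size]
            xb = X[ids]
            if aug.noise_gain > 0:
                xb = xb + rng.standard_normal(xb.shape) * noise_sd
            F, cache = _forward(w, xb, train=True)
            loss, dF = _loss_and_grad(F, ids, bank, cfg.temperature,
                                      cfg.n_negatives, rng)
            if not math.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}")
            grads = _backward(w, cache, dF)
            for k in ("W1", "b1", "gamma", "beta", "W2", "b2"):
                w[k] -= lr * grads[k]
            upd = lam * bank[ids] + (1 - lam) * F
            bank[ids] = upd / np.linalg.norm(upd, axis=1, keepdims=True)
            epoch_loss += loss
            n_batches += 1
        if epoch % log_every == 0 or epoch == cfg.epochs - 1:
            log.append((epoch, epoch_loss / n_batches))
    return HypersphereEncoder(weights=w, config=cfg, training_log=log,
                              augmentation=aug)


def embed(encoder: HypersphereEncoder, data: np.ndarray,
          sample_ids=None) -> LatentCloud:
    """Batch inference-mode embedding; row order preserved, no augmentation."""
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2:
        raise ValueError("data must be 2-D (samples x features)")
    Y = encoder.transform(data) if data.shape[0] else np.empty(
        (0, encoder.config.latent_dim))
    return LatentCloud(points=Y, sample_ids=sample_ids,
                       encoder_id=encoder.encoder_id)


# ---------------------------------------------------------------------------
# hyperparameter selection criteria
# ---------------------------------------------------------------------------

def _upper_triangle_cosines(points: np.ndarray) -> np.ndarray:
    G = np.clip(points @ points.T, -1.0, 1.0)
    iu = np.triu_indices(points.shape[0], k=1)
    return G[iu]


def pairwise_cosine_skewness(cloud: LatentCloud) -> float:
    """Fisher-Pearson sample skewness of all pairwise cosine similarities."""
    if cloud.n_points < 3:
        raise ValueError("need at least 3 points")
    sims = _upper_triangle_cosines(cloud.points)
    if np.ptp(sims) == 0:
        raise UndefinedSkewnessError("all pairwise similarities identical")
    return float(stats.skew(sims, bias=True))


def is_linearly_independent(cloud: LatentCloud) -> bool:
    """Numerical full-column-rank test of the N x n latent matrix.

    True iff the smallest singular value exceeds
    ``max(N, n) * eps * largest singular value`` (the standard numerical
    rank rule used by numpy.linalg.matrix_rank).
    """
    N, n = cloud.points.shape
    if N < n:
        raise ValueError(f"cannot span {n} dimensions with {N} points")
    s = np.linalg.svd(cloud.points, compute_uv=False)
    tol = max(N, n) * np.finfo(np.float64).eps * s[0]
    return bool(s[-1] > tol)


def grid_search_hyperparams(dataset: ActivityDataset, tau_grid, gain_grid,
                            cfg_base: EncoderConfig, seed: int = 0
                            ) -> tuple[float, float, pd.DataFrame]:
    """Grid search over (tau, k_sigma).

    Cells whose embedded training set fails the linear-independence
    criterion are discarded; among survivors the cell maximizing pairwise
    cosine skewness wins.  ``cfg_base.epochs`` may be reduced for a cheaper
    proxy training of the grid cells.
    """
    if not len(tau_grid) or not len(gain_grid):
        raise ValueError("grids must be non-empty")
    rows = []
    best = None
    for tau in tau_grid:
        for gain in gain_grid:
            cfg = EncoderConfig(**{**cfg_base.to_dict(), "temperature": float(tau)})
            aug = AugmentationConfig(noise_gain=float(gain), rng_seed=seed)
            enc = train_encoder(dataset, cfg, aug, seed=seed)
            cloud = embed(enc, dataset.samples, sample_ids=dataset.sample_ids)
            try:
                indep = is_linearly_independent(cloud)
            except ValueError:
                indep = False
            try:
                skew = pairwise_cosine_skewness(cloud)
            except UndefinedSkewnessError:
                skew = float("nan")
            rows.append({"tau": float(tau), "noise_gain": float(gain),
                         "skewness": skew, "independent": indep})
            if indep and math.isfinite(skew):
                if best is None or skew > best[2]:
                    best = (float(tau), float(gain), skew)
    table = pd.DataFrame(rows)
    if best is None:
        raise NoValidHyperparametersError(
            "every grid cell failed the linear-independence criterion")
    return best[0], best[1], table
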