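"""Core data containers shared across the pipeline.

An :class:`ActivityDataset` holds one participant's raw activity matrix
(samples x features) together with per-feature scale statistics used by the
Gaussian-noise augmentation.  A :class:`LatentCloud` holds the unit-norm
latent vectors produced by an encoder, i.e. points on the hypersphere
S^(n-1), plus provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["ActivityDataset", "LatentCloud", "UNIT_NORM_ATOL"]

#: tolerance on | ||y||_2 - 1 | for points that claim to be on the sphere
UNIT_NORM_ATOL = 1e-6


def _as_float64_matrix(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-D (samples x features), got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")
    return arr


@dataclass
class ActivityDataset:
    """Raw activity vectors for one participant / recording.

    Parameters
    ----------
    samples
        N x D matrix of activity vectors (arbitrary units).
    sample_ids
        Length-N identifiers; generated as ``s000000..`` when omitted.
    feature_sd
        Per-column sample standard deviation (ddof=1) of ``samples``.
        Recomputed when omitted; validated against the matrix otherwise.
    """

    samples: np.ndarray
    sample_ids: list = field(default=None)  # type: ignore[assignment]
    feature_sd: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.samples = _as_float64_matrix(self.samples, "samples")
        n, d = self.samples.shape
        if n < 2 or d < 1:
            raise ValueError(f"need N >= 2 samples and D >= 1 features, got N={n}, D={d}")
        if self.sample_ids is None:
            self.sample_ids = [f"s{i:06d}" for i in range(n)]
        else:
            self.sample_ids = list(self.sample_ids)
            if len(self.sample_ids) != n:
                raise ValueError("sample_ids length does not match number of rows")
        sd = self.samples.std(axis=0, ddof=1)
        if self.feature_sd is None:
            self.feature_sd = sd
        else:
            self.feature_sd = np.asarray(self.feature_sd, dtype=np.float64)
            if self.feature_sd.shape != (d,):
                raise ValueError("feature_sd must have one entry per feature")
            scale = np.maximum(np.abs(sd), 1.0)
            if not np.all(np.abs(self.feature_sd - sd) <= 1e-9 * scale):
                raise ValueError("feature_sd inconsistent with samples (tolerance 1e-9 relative)")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_features(self) -> int:
        return self.samples.shape[1]


@dataclass
class LatentCloud:
    """Unit vectors on the hypersphere plus provenance."""

    points: np.ndarray
    sample_ids: list = field(default=None)  # type: ignore[assignment]
    encoder_id: str = ""

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2:
            raise ValueError(f"points must be 2-D, got shape {pts.shape}")
        if pts.shape[0] > 0:
            norms = np.linalg.norm(pts, axis=1)
            if not np.all(np.isfinite(pts)) or np.any(np.abs(norms - 1.0) > UNIT_NORM_ATOL):
                raise ValueError("latent points must be unit-norm within 1e-6")
        self.points = pts
        if self.sample_ids is None:
            self.sample_ids = [f"s{i:06d}" for i in range(pts.shape[0])]
        else:
            self.sample_ids = list(self.sample_ids)
            if len(self.sample_ids) != pts.shape[0]:
                raise ValueError("sample_ids length does not match number of points")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def latent_dim(self) -> int:
        return self.points.shape[1]

    def subset(self, indices: Sequence[int]) -> "LatentCloud":
        idx = np.asarray(indices, dtype=int)
        return LatentCloud(
            points=self.points[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            encoder_id=self.encoder_id,
        )
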