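"""Paired synthetic datasets with a shared latent similarity structure.

Two "participants" observe the same underlying clustered point cloud on a
latent hypersphere through different fixed random nonlinear maps with
additive Gaussian measurement noise.  Ground-truth correspondence and
cluster labels are retained for evaluation only, emulating two
independently recorded activity datasets (e.g. two networks' layer outputs,
or two subjects' response patterns) that share representational geometry
without sharing a coordinate system.

``shared_fraction < 1`` replaces part of one side's latent structure with
draws from an independent cloud, emulating dataset pairs whose common
structure is weak or absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ActivityDataset

__all__ = ["SyntheticSpec", "SyntheticPair", "generate_shared_latents",
           "generate_observation", "generate_pair", "split_pair"]


@dataclass
class SyntheticSpec:
    """Generator parameters.

    Defaults emulate the scale of the real use case at reduced sample count:
    ten categories, 1,024-dimensional observations, 32-dimensional latent
    structure, cluster angular spread 0.25 rad, observation noise SD 0.02
    (about 10% of the per-feature signal SD under the random map).
    """

    n_clusters: int = 10
    per_cluster: int = 40
    latent_dim: int = 32
    cluster_spread: float = 0.25
    obs_dims: tuple = (1024, 1024)
    obs_noise: float = 0.02
    nonlinearity: str = "relu"
    shared_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.per_cluster < 2:
            raise ValueError("per_cluster must be >= 2")
        if self.cluster_spread <= 0:
            raise ValueError("cluster_spread must be > 0")
        if self.obs_noise < 0:
            raise ValueError("obs_noise must be >= 0")
        if not (0 <= self.shared_fraction <= 1):
            raise ValueError("shared_fraction must be in [0, 1]")
        if min(self.obs_dims) < self.latent_dim:
            raise ValueError("obs_dims must be >= latent_dim")
        if self.nonlinearity not in ("relu", "tanh", "none"):
            raise ValueError("nonlinearity must be relu, tanh or none")

    @property
    def n_samples(self) -> int:
        return self.n_clusters * self.per_cluster


@dataclass
class SyntheticPair:
    data_a: ActivityDataset
    data_b: ActivityDataset
    correspondence: np.ndarray  # row i of data_a corresponds to row correspondence[i] of data_b
    labels: np.ndarray          # cluster index per data_a row
    truth_latents: np.ndarray   # latent point per data_a row
    spec: SyntheticSpec = None  # type: ignore[assignment]

    def __post_init__(self):
        c = np.asarray(self.correspondence, dtype=np.intp)
        if sorted(c.tolist()) != list(range(len(c))):
            raise ValueError("correspondence must be a bijection")
        self.correspondence = c
        self.labels = np.asarray(self.labels)

    @property
    def labels_b(self) -> np.ndarray:
        """Cluster label per data_b row (via the correspondence)."""
        lab = np.empty(len(self.labels), dtype=self.labels.dtype)
        lab[self.correspondence] = self.labels
        return lab


def _unit_rows(X: np.ndarray) -> np.ndarray:
    return X / np.linalg.norm(X, axis=1, keepdims=True)


def generate_shared_latents(spec: SyntheticSpec, seed: int | None = None
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Clustered unit vectors: uniform cluster centers on the sphere, members
    perturbed by isotropic Gaussian and renormalized.

    The per-dimension noise SD is ``cluster_spread / sqrt(latent_dim)`` so
    that the expected angular deviation of a member from its center is about
    ``cluster_spread`` radians regardless of the latent dimensionality.
    Returns (points, cluster labels)."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    centers = _unit_rows(rng.standard_normal((spec.n_clusters, spec.latent_dim)))
    members = np.repeat(centers, spec.per_cluster, axis=0)
    sd = spec.cluster_spread / np.sqrt(spec.latent_dim)
    members = members + rng.standard_normal(members.shape) * sd
    labels = np.repeat(np.arange(spec.n_clusters), spec.per_cluster)
    return _unit_rows(members), labels


def generate_observation(latents: np.ndarray, obs_dim: int, nonlinearity: str,
                         obs_noise: float, map_seed: int,
                         noise_seed: int | None = None) -> ActivityDataset:
    """Observe latents through a fixed random map plus measurement noise.

    The linear map (entries ~ Normal(0, 1/latent_dim)) and hence the
    "participant" is fixed by ``map_seed``; the additive noise is fresh per
    sample from ``noise_seed`` (defaults to ``map_seed + 1``).
    """
    latents = np.asarray(latents, dtype=np.float64)
    n, d = latents.shape
    if obs_dim < d:
        raise ValueError("obs_dim must be >= latent_dim")
    map_rng = np.random.default_rng(map_seed)
    W = map_rng.standard_normal((d, obs_dim)) / np.sqrt(d)
    Z = latents @ W
    if nonlinearity == "relu":
        Z = np.maximum(Z, 0.0)
    elif nonlinearity == "tanh":
        Z = np.tanh(Z)
    elif nonlinearity != "none":
        raise ValueError(f"unknown nonlinearity {nonlinearity!r}")
    if obs_noise > 0:
        noise_rng = np.random.default_rng(
            map_seed + 1 if noise_seed is None else noise_seed)
        Z = Z + noise_rng.standard_normal(Z.shape) * obs_noise
    return ActivityDataset(samples=Z)


def generate_pair(spec: SyntheticSpec) -> SyntheticPair:
    """Generate a correspondence-shuffled pair of observation datasets.

    Both sides observe the same latent cloud; with ``shared_fraction`` s,
    a fraction 1-s of side B's rows instead observe an independently drawn
    clustered cloud, so only the remaining structure is common.  B's row
    order is randomly permuted; the bijection is recorded for evaluation.
    """
    ss = np.random.SeedSequence([spec.seed, 0xA11CE])
    s_lat, s_mix, s_perm, s_map_a, s_map_b, s_noise_a, s_noise_b = [
        int(x) for x in ss.generate_state(7) >> np.uint32(1)]
    latents, labels = generate_shared_latents(spec, seed=s_lat)
    n = latents.shape[0]
    latents_b = latents.copy()
    if spec.shared_fraction < 1.0:
        # structureless independent draws: uniform on the sphere, so the
        # replaced part carries no similarity structure at all
        rng = np.random.default_rng(s_mix)
        n_replace = int(round((1.0 - spec.shared_fraction) * n))
        idx = rng.choice(n, size=n_replace, replace=False)
        latents_b[idx] = _unit_rows(
            rng.standard_normal((n_replace, spec.latent_dim)))
    data_a = generate_observation(latents, spec.obs_dims[0], spec.nonlinearity,
                                  spec.obs_noise, map_seed=s_map_a,
                                  noise_seed=s_noise_a)
    perm = np.random.default_rng(s_perm).permutation(n)
    data_b_full = generate_observation(latents_b, spec.obs_dims[1],
                                       spec.nonlinearity, spec.obs_noise,
                                       map_seed=s_map_b, noise_seed=s_noise_b)
    # shuffle B's rows; correspondence[i] = B-row holding A-row i's twin
    inv = np.empty(n, dtype=np.intp)
    inv[perm] = np.arange(n)
    data_b = ActivityDataset(samples=data_b_full.samples[perm],
                             sample_ids=[f"b{j:06d}" for j in range(n)])
    data_a = ActivityDataset(samples=data_a.samples,
                             sample_ids=[f"a{i:06d}" for i in range(n)])
    return SyntheticPair(data_a=data_a, data_b=data_b, correspondence=inv,
                         labels=labels, truth_latents=latents, spec=spec)


def split_pair(pair: SyntheticPair, test_fraction: float = 0.25,
               seed: int = 0) -> tuple[SyntheticPair, SyntheticPair]:
    """Split a pair into train/test sub-pairs, consistently on both sides."""
    if not (0 < test_fraction < 1):
        raise ValueError("test_fraction must be in (0, 1)")
    n = pair.data_a.n_samples
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_test = max(2, int(round(test_fraction * n)))
    test_a = np.sort(order[:n_test])
    train_a = np.sort(order[n_test:])

    def _sub(rows_a: np.ndarray) -> SyntheticPair:
        rows_b = pair.correspondence[rows_a]
        sub_b_rows = np.sort(rows_b)
        corr = np.array([np.searchsorted(sub_b_rows, j) for j in rows_b],
                        dtype=np.intp)
        da = ActivityDataset(samples=pair.data_a.samples[rows_a],
                             sample_ids=[pair.data_a.sample_ids[i] for i in rows_a])
        db = ActivityDataset(samples=pair.data_b.samples[sub_b_rows],
                             sample_ids=[pair.data_b.sample_ids[j] for j in sub_b_rows])
        return SyntheticPair(data_a=da, data_b=db, correspondence=corr,
                             labels=pair.labels[rows_a],
                             truth_latents=pair.truth_latents[rows_a],
                             spec=pair.spec)

    return _sub(train_a), _sub(test_a)
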