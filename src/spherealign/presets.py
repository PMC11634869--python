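"""Shipped default configurations.

``ann_*`` presets carry the settings used for network-activity datasets
(4,096/2,048/1,024-dimensional inputs); ``human_*`` presets the settings
for 4,200-dimensional response-pattern datasets.  ``desk_*`` presets are
the package's reduced-size study configuration used by the test suite and
the reproduction script: same architecture and training rule, smaller
matrices and fewer epochs so a full two-encoder pipeline runs in seconds
on one CPU.
"""

from __future__ import annotations

from .config import MatchingConfig
from .embedding import AugmentationConfig, EncoderConfig
from .synthetic import SyntheticSpec
from .transfer import MMDConfig

__all__ = [
    "ANN_HYPERPARAMS", "ann_encoder_config", "ann_matching_config",
    "human_encoder_config", "human_matching_config",
    "desk_spec", "desk_encoder_config", "desk_augmentation",
    "desk_matching_config", "desk_mmd_config",
]

#: (tau, k_sigma) selected by grid search per input dimensionality
ANN_HYPERPARAMS = {4096: (0.8, 1.5), 2048: (0.5, 1.5), 1024: (0.8, 0.75)}


def ann_encoder_config(input_dim: int) -> EncoderConfig:
    tau, _ = ANN_HYPERPARAMS.get(input_dim, (0.8, 1.5))
    return EncoderConfig(input_dim=input_dim, latent_dim=32, temperature=tau,
                         n_negatives=4096, batch_size=512, epochs=5000,
                         learning_rate=0.01)


def ann_augmentation(input_dim: int, rng_seed: int = 0) -> AugmentationConfig:
    _, gain = ANN_HYPERPARAMS.get(input_dim, (0.8, 1.5))
    return AugmentationConfig(noise_gain=gain, rng_seed=rng_seed)


def ann_matching_config() -> MatchingConfig:
    return MatchingConfig(m_target=1600, neighbor_radius=0.2, separation=0.2,
                          restarts=26000)


def human_encoder_config(temperature: float = 0.5) -> EncoderConfig:
    # grid-searched tau in [0.4, 0.6] and k_sigma in [1.5, 2.5] per participant
    return EncoderConfig(input_dim=4200, latent_dim=32, temperature=temperature,
                         n_negatives=4096, batch_size=512, epochs=5000,
                         learning_rate=0.01)


def human_matching_config() -> MatchingConfig:
    return MatchingConfig(m_target=1600, neighbor_radius=0.1, separation=0.1,
                          restarts=1000)


# ---------------------------------------------------------------------------
# desk-scale study configuration (tests and reproduction script)
# ---------------------------------------------------------------------------

def desk_spec(seed: int = 0, shared_fraction: float = 1.0) -> SyntheticSpec:
    """Reduced synthetic pair: 8 clusters x 30 samples on a 6-d latent
    sphere (angular spread 0.35 rad), observed through 192- and
    160-dimensional random relu maps with noise SD 0.02."""
    return SyntheticSpec(n_clusters=8, per_cluster=30, latent_dim=6,
                         cluster_spread=0.35, obs_dims=(192, 160),
                         obs_noise=0.02, nonlinearity="relu",
                         shared_fraction=shared_fraction, seed=seed)


def desk_encoder_config(input_dim: int, epochs: int = 300) -> EncoderConfig:
    """Embeds onto a 16-d sphere; 300 full-batch epochs keep the embedding
    faithful to the input geometry (longer training drifts toward a uniform,
    symmetry-prone arrangement that degrades unsupervised matching)."""
    return EncoderConfig(input_dim=input_dim, latent_dim=16, temperature=0.35,
                         n_negatives=4096, batch_size=512, epochs=epochs,
                         learning_rate=0.01)


def desk_augmentation(rng_seed: int = 0, noise_gain: float = 1.5
                      ) -> AugmentationConfig:
    return AugmentationConfig(noise_gain=noise_gain, rng_seed=rng_seed)


def desk_matching_config(restarts: int = 2000) -> MatchingConfig:
    """At desk sample counts every training point serves as a representative
    (separation 0.001), and the centered distance matrices use Euclidean
    latent distances."""
    return MatchingConfig(m_target=256, neighbor_radius=0.2, separation=0.001,
                          restarts=restarts, metric="euclidean")


def desk_mmd_config(epochs: int = 100) -> MMDConfig:
    return MMDConfig(epochs=epochs, batch_size=512, learning_rate=0.01)
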