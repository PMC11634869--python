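import math

import numpy as np
import pytest

from spherealign.data import ActivityDataset, LatentCloud
from spherealign.embedding import (AugmentationConfig, EncoderConfig,
                                   NoValidHyperparametersError,
                                   UndefinedSkewnessError, augment, embed,
                                   grid_search_hyperparams, instance_loss,
                                   intermediate_dim, is_linearly_independent,
                                   pairwise_cosine_skewness, train_encoder,
                                   _backward, _forward, _init_weights)


class TestIntermediateDim:
    @pytest.mark.parametrize("d, n, expected", [
        (4096, 32, 362),   # printed encoder widths for the network datasets
        (2048, 32, 256),
        (1024, 32, 181),
        (4200, 32, 367),   # human response-pattern dataset
        (32, 32, 32),      # geometric mean of equal widths
    ])
    def test_logarithmic_spacing(self, d, n, expected):
        assert intermediate_dim(d, n) == expected

    def test_invalid_dims_rejected(self):
        with pytest.raises(ValueError):
            intermediate_dim(0, 32)
        with pytest.raises(ValueError):
            intermediate_dim(16, 32)


class TestAugment:
    def test_zero_gain_is_identity(self, small_dataset):
        x = small_dataset.samples[0]
        out = augment(x, small_dataset, AugmentationConfig(noise_gain=0.0))
        assert np.array_equal(out, x)

    def test_zero_feature_sd_is_identity(self):
        X = np.tile([1.0, 2.0, 3.0], (5, 1))
        X[0, 0] = 1.0  # constant columns -> sd 0
        ds = ActivityDataset(samples=X)
        out = augment(X[1], ds, AugmentationConfig(noise_gain=1.5),
                      rng=np.random.default_rng(0))
        assert np.array_equal(out, X[1])

    def test_noise_scale_and_unbiasedness(self, small_dataset):
        # Monte-Carlo: empirical SD of the perturbation must match
        # noise_gain * feature_sd, and its mean must be 0 within 4 SE.
        gain = 1.5
        cfg = AugmentationConfig(noise_gain=gain)
        r = np.random.default_rng(7)
        x = small_dataset.samples[0]
        n_draws = 100_000
        draws = np.stack([augment(x, small_dataset, cfg, rng=r) - x
                          for _ in range(200)])
        # vectorized bulk draws for the rest
        sd = gain * small_dataset.feature_sd
        eps = r.standard_normal((n_draws, x.size)) * sd
        eps[:200] = draws
        emp_sd = eps.std(axis=0)
        assert np.all(np.abs(emp_sd - sd) <= 0.03 * sd)
        se = sd / math.sqrt(n_draws)
        assert np.all(np.abs(eps.mean(axis=0)) <= 4 * se)

    def test_dimension_mismatch(self, small_dataset):
        with pytest.raises(ValueError, match="features"):
            augment(np.zeros(3), small_dataset, AugmentationConfig())


class TestInstanceLoss:
    def test_single_candidate_gives_zero(self):
        # bank of size 1: softmax over one candidate, -log(1) = 0
        f = np.array([[1.0, 0.0]])
        assert instance_loss(f, [0], f.copy(), temperature=1.0,
                             n_negatives=4096) == pytest.approx(0.0)

    def test_two_by_two_hand_value(self):
        # B=2, n=2, tau=1, all other instances as negatives; the loss is
        # recomputed here with explicit scalars
        e1, e2 = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        bank = np.stack([e1, (e1 + e2) / np.sqrt(2)])
        emb = np.stack([e1, e2])
        tau = 1.0
        expected = 0.0
        for i in range(2):
            pos = math.exp(emb[i] @ bank[i] / tau)
            neg = math.exp(emb[i] @ bank[1 - i] / tau)
            expected += -math.log(pos / (pos + neg))
        expected /= 2
        got = instance_loss(emb, [0, 1], bank, temperature=tau, n_negatives=1)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_temperature_must_be_positive(self):
        f = np.array([[1.0, 0.0]])
        with pytest.raises(ValueError):
            instance_loss(f, [0], f, temperature=0.0, n_negatives=1)

    def test_loss_nonnegative_random(self, rng):
        emb = rng.standard_normal((8, 4))
        emb /= np.linalg.norm(emb, axis=1, keepdims=True)
        bank = rng.standard_normal((20, 4))
        bank /= np.linalg.norm(bank, axis=1, keepdims=True)
        loss = instance_loss(emb, list(range(8)), bank, 0.5, 10, rng)
        assert loss >= 0


def test_backprop_matches_finite_differences():
    """Analytic gradients of the full encoder + loss agree with central
    finite differences in both batch-stat and frozen-stat modes."""
    rng = np.random.default_rng(0)
    cfg = EncoderConfig(input_dim=7, intermediate_dim=5, latent_dim=3)
    w = _init_weights(cfg, rng)
    X = rng.standard_normal((6, 7))
    bank = rng.standard_normal((10, 3))
    bank /= np.linalg.norm(bank, axis=1, keepdims=True)
    ids = np.array([0, 3, 5, 7, 8, 9])

    def loss_of(wd, train):
        Y, _ = _forward({k: v.copy() for k, v in wd.items()}, X, train=train)
        return instance_loss(Y, ids, bank, 0.7, 9)

    for train in (True, False):
        Y, cache = _forward({k: v.copy() for k, v in w.items()}, X, train=train)
        from spherealign.embedding import _loss_and_grad
        _, dY = _loss_and_grad(Y, ids, bank, 0.7, 9, np.random.default_rng(0))
        grads = _backward(w, cache, dY, train_batch=train)
        eps = 1e-6
        for k in ("W1", "gamma", "W2", "b2"):
            flat = w[k].reshape(-1)
            for idx in (0, flat.size // 2, flat.size - 1):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = loss_of(w, train)
                flat[idx] = orig - eps
                lm = loss_of(w, train)
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert grads[k].reshape(-1)[idx] == pytest.approx(num, abs=1e-7)


class TestTrainEncoder:
    def test_outputs_unit_norm_and_deterministic(self, small_dataset):
        cfg = EncoderConfig(input_dim=12, latent_dim=4, temperature=0.5,
                            epochs=20, batch_size=16)
        aug = AugmentationConfig(noise_gain=0.5)
        enc1 = train_encoder(small_dataset, cfg, aug, seed=3)
        enc2 = train_encoder(small_dataset, cfg, aug, seed=3)
        r = np.random.default_rng(0)
        X = r.standard_normal((100, 12))
        Y = enc1.transform(X)
        assert np.allclose(np.linalg.norm(Y, axis=1), 1.0, atol=1e-6)
        assert np.array_equal(Y, enc2.transform(X))

    def test_identical_inputs_identical_latents(self, small_dataset):
        cfg = EncoderConfig(input_dim=12, latent_dim=4, epochs=5)
        enc = train_encoder(small_dataset, cfg, AugmentationConfig(0.5), seed=0)
        X = np.tile(small_dataset.samples[0], (2, 1))
        Y = enc.transform(X)
        assert np.array_equal(Y[0], Y[1])

    def test_loss_decreases_over_first_epochs(self, desk_pair):
        # median over 5 seeds of (mean loss epoch 0) - (mean loss epoch 9)
        _, _, train, _ = desk_pair
        drops = []
        for seed in range(5):
            cfg = EncoderConfig(input_dim=train.data_a.n_features,
                                latent_dim=16, temperature=0.35, epochs=10)
            enc = train_encoder(train.data_a, cfg, AugmentationConfig(1.5),
                                seed=seed)
            log = dict(enc.training_log)
            drops.append(log[0] - log[9])
        assert np.median(drops) > 0

    def test_cluster_structure_preserved(self, desk_pair, desk_encoders):
        # within-cluster cosine similarity of latents exceeds between-cluster
        _, _, train, _ = desk_pair
        enc_a, _ = desk_encoders
        cloud = embed(enc_a, train.data_a.samples)
        lab = train.labels
        G = cloud.points @ cloud.points.T
        same = lab[:, None] == lab[None, :]
        iu = np.triu_indices(len(lab), k=1)
        within = G[iu][same[iu]].mean()
        between = G[iu][~same[iu]].mean()
        assert within > between

    def test_epochs_must_be_positive(self, small_dataset):
        cfg = EncoderConfig(input_dim=12, latent_dim=4, epochs=0)
        with pytest.raises(ValueError):
            train_encoder(small_dataset, cfg, AugmentationConfig(0.5))


class TestEmbed:
    def test_embedding_is_reproducible_and_order_preserving(self, small_dataset):
        cfg = EncoderConfig(input_dim=12, latent_dim=4, epochs=5)
        enc = train_encoder(small_dataset, cfg, AugmentationConfig(0.5), seed=0)
        c1 = embed(enc, small_dataset.samples)
        c2 = embed(enc, small_dataset.samples)
        assert np.array_equal(c1.points, c2.points)
        # row order: embedding rows individually matches the batch result
        single = enc.transform(small_dataset.samples[7])
        assert np.allclose(c1.points[7], single[0])

    def test_empty_input_gives_empty_cloud(self, small_dataset):
        cfg = EncoderConfig(input_dim=12, latent_dim=4, epochs=2)
        enc = train_encoder(small_dataset, cfg, AugmentationConfig(0.0), seed=0)
        cloud = embed(enc, np.empty((0, 12)))
        assert cloud.n_points == 0

    def test_dimension_mismatch(self, small_dataset):
        cfg = EncoderConfig(input_dim=12, latent_dim=4, epochs=2)
        enc = train_encoder(small_dataset, cfg, AugmentationConfig(0.0), seed=0)
        with pytest.raises(ValueError):
            embed(enc, np.zeros((3, 5)))


class TestSkewness:
    def test_two_antipodal_pairs_hand_value(self):
        # points {p, p, -p, -p}: similarity multiset {1, 1, -1, -1, -1, -1}
        p = np.array([1.0, 0.0])
        cloud = LatentCloud(points=np.stack([p, p, -p, -p]))
        vals = np.array([1.0, -1, -1, 1, -1, -1])
        mu = vals.mean()
        m2 = ((vals - mu) ** 2).mean()
        m3 = ((vals - mu) ** 3).mean()
        assert pairwise_cosine_skewness(cloud) == pytest.approx(
            m3 / m2 ** 1.5, rel=1e-12)

    def test_right_angle_configuration_hand_value(self):
        # four points at 90-degree spacing: sims {0, -1, 0, 0, 0, -1}
        th = np.array([0.0, np.pi / 2])
        pts = np.column_stack([np.cos(th), np.sin(th)])
        cloud = LatentCloud(points=np.vstack([pts, -pts]))
        vals = np.array([0.0, -1, 0, 0, 0, -1])
        mu = vals.mean()
        g1 = (((vals - mu) ** 3).mean()) / (((vals - mu) ** 2).mean()) ** 1.5
        assert pairwise_cosine_skewness(cloud) == pytest.approx(g1, abs=1e-12)

    def test_matches_brute_force_on_random_cloud(self, rng):
        pts = rng.standard_normal((100, 6))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        cloud = LatentCloud(points=pts)
        sims = []
        for i in range(100):
            for j in range(i + 1, 100):
                sims.append(float(pts[i] @ pts[j]))
        sims = np.array(sims)
        mu = sims.mean()
        g1 = (((sims - mu) ** 3).mean()) / (((sims - mu) ** 2).mean()) ** 1.5
        assert pairwise_cosine_skewness(cloud) == pytest.approx(g1, rel=1e-10)

    def test_degenerate_cases(self):
        p = np.array([1.0, 0.0])
        with pytest.raises(ValueError):
            pairwise_cosine_skewness(LatentCloud(points=p[None]))
        with pytest.raises(UndefinedSkewnessError):
            pairwise_cosine_skewness(LatentCloud(points=np.tile(p, (5, 1))))


class TestLinearIndependence:
    def test_great_circle_is_rank_deficient(self):
        th = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        pts = np.zeros((40, 32))
        pts[:, 0], pts[:, 1] = np.cos(th), np.sin(th)
        assert is_linearly_independent(LatentCloud(points=pts)) is False

    def test_random_cloud_is_full_rank(self):
        cloud_pts = np.random.default_rng(0).standard_normal((42, 32))
        cloud_pts /= np.linalg.norm(cloud_pts, axis=1, keepdims=True)
        assert is_linearly_independent(LatentCloud(points=cloud_pts)) is True

    def test_duplicate_points_do_not_matter(self, rng):
        pts = rng.standard_normal((10, 4))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts[1] = pts[0]  # independence is of dimensions, not samples
        assert is_linearly_independent(LatentCloud(points=pts)) is True

    def test_too_few_points_error(self, rng):
        pts = rng.standard_normal((3, 8))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        with pytest.raises(ValueError):
            is_linearly_independent(LatentCloud(points=pts))


class TestGridSearch:
    def test_single_passing_cell_returned(self, small_dataset):
        cfg = EncoderConfig(input_dim=12, latent_dim=4, epochs=10)
        tau, gain, table = grid_search_hyperparams(
            small_dataset, [0.5], [1.0], cfg, seed=0)
        assert (tau, gain) == (0.5, 1.0)
        assert len(table) == 1 and bool(table["independent"][0])

    def test_best_skewness_among_survivors(self, small_dataset):
        cfg = EncoderConfig(input_dim=12, latent_dim=4, epochs=10)
        tau, gain, table = grid_search_hyperparams(
            small_dataset, [0.3, 0.8], [0.5], cfg, seed=0)
        ok = table[table["independent"]]
        best = ok.loc[ok["skewness"].idxmax()]
        assert (tau, gain) == (best["tau"], best["noise_gain"])

    def test_all_cells_failing_raises(self, rng):
        # more latent dimensions than samples: rank deficiency is guaranteed
        ds = ActivityDataset(samples=rng.standard_normal((6, 16)))
        cfg = EncoderConfig(input_dim=16, intermediate_dim=16, latent_dim=8,
                            epochs=2)
        with pytest.raises(NoValidHyperparametersError):
            grid_search_hyperparams(ds, [0.5], [1.0], cfg, seed=0)

    def test_empty_grid_rejected(self, small_dataset):
        cfg = EncoderConfig(input_dim=12, latent_dim=4, epochs=2)
        with pytest.raises(ValueError):
            grid_search_hyperparams(small_dataset, [], [1.0], cfg)
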