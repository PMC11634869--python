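"""End-to-end orchestration of the three computational steps.

Step A: train one contrastive encoder per dataset (optionally after a
(tau, k_sigma) grid search) and embed each dataset on its hypersphere.
Step B: select cluster representatives, match them across datasets by
HSIC-maximizing kernelized sorting, and estimate the orthogonal transfer
map by Procrustes.  Step C: fine-tune the source encoder with MMD loss.

Every stage's derived seed and parameters go into the report; with an
output directory set, the config snapshot, report JSON, matching artifacts
and encoder checkpoints are written there.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np

from .config import RunConfig
from .data import ActivityDataset
from .embedding import (EncoderConfig, embed, grid_search_hyperparams,
                        train_encoder)
from .evaluation import alignment_score, upper_bound_map
from .matching import (centered_distance_matrix, kernelized_sort,
                       procrustes_orthogonal, select_representatives)
from .transfer import TransferPipeline, fine_tune, transfer

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """Wraps a stage failure with the stage name attached."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


def _evaluate(pipe: TransferPipeline, test_a, test_b, corr, labels):
    ya = embed(pipe.encoder_a, test_a.samples)
    yb = embed(pipe.encoder_b, test_b.samples)
    yb_matched = yb.points[np.asarray(corr, dtype=np.intp)]
    score, sims = alignment_score(ya.points, yb_matched, pipe.map)
    _, ub = upper_bound_map(ya.points, yb_matched)
    out = {"alignment_score": score, "upper_bound_score": ub}
    if labels is not None:
        from .evaluation import knn_category_discrimination
        transferred = transfer(pipe, test_b.samples)
        acc, _ = knn_category_discrimination(
            ya, list(labels), transferred.subset(np.asarray(corr, dtype=np.intp)),
            k=min(20, ya.n_points), test_labels=list(labels))
        out["knn_transfer_accuracy"] = acc
    return out, sims


def run_pipeline(data_a: ActivityDataset, data_b: ActivityDataset,
                 config: RunConfig, test_a: ActivityDataset | None = None,
                 test_b: ActivityDataset | None = None,
                 test_correspondence=None, test_labels=None
                 ) -> tuple[TransferPipeline, dict]:
    """Run steps A-C on two unlabeled datasets.

    ``test_*`` arguments are evaluation-only: held-out samples with a known
    correspondence used to compute alignment scores and the supervised
    upper bound; they never influence training or matching.
    """
    seed = config.seed
    report: dict = {"seed": seed, "stages": {}, "config": config.to_dict()}
    t0 = time.time()

    def stage(name):
        report["stages"][name] = {"t_start": round(time.time() - t0, 3)}
        return report["stages"][name]

    # --- step A: encoders ---------------------------------------------------
    encoders = []
    for side, data, enc_cfg, aug in (("a", data_a, config.encoder_a, config.augment_a),
                                     ("b", data_b, config.encoder_b, config.augment_b)):
        s = stage(f"train_encoder_{side}")
        enc_seed = seed + (1 if side == "a" else 2)
        try:
            if enc_cfg.input_dim == 0:
                enc_cfg = EncoderConfig(**{**enc_cfg.to_dict(),
                                           "input_dim": data.n_features,
                                           "intermediate_dim": 0})
            if config.grid_tau and config.grid_gain:
                tau, gain, table = grid_search_hyperparams(
                    data, config.grid_tau, config.grid_gain, enc_cfg,
                    seed=enc_seed)
                enc_cfg = EncoderConfig(**{**enc_cfg.to_dict(), "temperature": tau})
                aug = type(aug)(noise_gain=gain, rng_seed=aug.rng_seed)
                s["grid_search"] = table.to_dict(orient="records")
            enc = train_encoder(data, enc_cfg, aug, seed=enc_seed,
                                log_every=max(1, enc_cfg.epochs // 20))
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"train_encoder_{side}", e) from e
        s.update(seed=enc_seed, temperature=enc_cfg.temperature,
                 noise_gain=aug.noise_gain, final_loss=enc.training_log[-1][1])
        encoders.append(enc)
    enc_a, enc_b = encoders

    # --- step B: match and align -------------------------------------------
    s = stage("match")
    try:
        cloud_a = embed(enc_a, data_a.samples, sample_ids=data_a.sample_ids)
        cloud_b = embed(enc_b, data_b.samples, sample_ids=data_b.sample_ids)
        mc = config.matching
        reps_a = select_representatives(cloud_a, mc.neighbor_radius,
                                        mc.separation, mc.m_target)
        reps_b = select_representatives(cloud_b, mc.neighbor_radius,
                                        mc.separation, mc.m_target)
        m = min(reps_a.size, reps_b.size)
        pa, pb = reps_a.points[:m], reps_b.points[:m]
        K = centered_distance_matrix(pa, metric=mc.metric, centering=mc.centering)
        L = centered_distance_matrix(pb, metric=mc.metric, centering=mc.centering)
        match = kernelized_sort(K, L, restarts=mc.restarts, seed=seed + 3,
                                max_iter=mc.max_iter)
        # perm[k] is the A-index matched to B-index k
        omap = procrustes_orthogonal(pa[match.permutation], pb,
                                     source=enc_b.encoder_id,
                                     target=enc_a.encoder_id)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("match", e) from e
    s.update(m=m, hsic=match.hsic, normalized_hsic=match.normalized_hsic,
             restarts=mc.restarts, seed=seed + 3)
    report["hsic"] = match.hsic
    report["normalized_hsic"] = match.normalized_hsic

    pipe = TransferPipeline(
        encoder_a=enc_a, encoder_b=enc_b, map=omap,
        provenance={"seed": seed, "match_seed": seed + 3,
                    "m": int(m), "restarts": mc.restarts})

    have_test = test_a is not None and test_b is not None \
        and test_correspondence is not None
    if have_test:
        ev, _ = _evaluate(pipe, test_a, test_b, test_correspondence, test_labels)
        report["evaluation_before_finetune"] = ev

    # --- step C: fine-tune ---------------------------------------------------
    if config.finetune and config.mmd.epochs > 0:
        s = stage("finetune")
        try:
            pipe = fine_tune(pipe, data_b, cloud_a, config.mmd, seed=seed + 4)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("finetune", e) from e
        s.update(seed=seed + 4, epochs=config.mmd.epochs,
                 final_mmd=pipe.finetune_log[-1][1])
    else:
        report["stages"]["finetune"] = {"skipped": True}

    if have_test:
        ev, sims = _evaluate(pipe, test_a, test_b, test_correspondence,
                             test_labels)
        report["evaluation"] = ev
        report["per_sample_similarities"] = sims.tolist()

    report["elapsed_s"] = round(time.time() - t0, 3)
    if config.out_dir:
        _write_artifacts(Path(config.out_dir), config, report, pipe, match)
    return pipe, report


def _write_artifacts(out: Path, config: RunConfig, report: dict,
                     pipe: TransferPipeline, match) -> None:
    from . import io as sio
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(config.to_yaml())
    slim = {k: v for k, v in report.items() if k != "per_sample_similarities"}
    (out / "report.json").write_text(json.dumps(slim, indent=2, default=float))
    sio.save_match(out / "match.h5", match, pipe.map)
    sio.save_encoder(out / "encoder_a.h5", pipe.encoder_a)
    sio.save_encoder(out / "encoder_b.h5", pipe.encoder_b)
    with open(out / "log.txt", "a") as fh:
        fh.write(f"{time.strftime('%Y-%m-%dT%H:%M:%S')} run seed={config.seed} "
                 f"hsic={report['hsic']:.6g} nhsic={report['normalized_hsic']:.4f} "
                 f"elapsed={report['elapsed_s']}s\n")
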