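"""Readers and writers for matrices, encoder checkpoints and match artifacts.

Matrices travel as CSV/TSV (rows = samples, optional header row, optional
first column of sample ids) or HDF5 (dataset ``samples`` with attribute
``sample_ids``).  Encoders and matches are HDF5 groups with named weight
arrays and provenance attributes.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .embedding import AugmentationConfig, EncoderConfig, HypersphereEncoder
from .matching import MatchResult, OrthogonalMap

__all__ = ["MatrixFormatError", "load_matrix", "save_matrix",
           "save_encoder", "load_encoder", "save_match", "load_match"]


class MatrixFormatError(ValueError):
    """Raised on malformed matrix files, naming the offending line."""


def _is_hdf5(path: Path, format_hint: str | None) -> bool:
    if format_hint:
        return format_hint.lower() in ("h5", "hdf5")
    return path.suffix.lower() in (".h5", ".hdf5")


def _looks_numeric(tokens: list[str]) -> bool:
    try:
        [float(t) for t in tokens]
        return True
    except ValueError:
        return False


def load_matrix(path, format_hint: str | None = None,
                nan_policy: str = "reject") -> tuple[np.ndarray, list]:
    """Load a samples x features matrix plus sample ids.

    CSV/TSV header rows and a leading id column are auto-detected (a header
    is assumed when the first row is not fully numeric; an id column when
    the first field of data rows is not numeric).  Ragged rows raise
    :class:`MatrixFormatError` naming the line.  NaNs are rejected unless
    ``nan_policy='impute_mean'``, which fills column means.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_hdf5(path, format_hint):
        with h5py.File(path, "r") as fh:
            X = np.asarray(fh["samples"], dtype=np.float64)
            ids = fh["samples"].attrs.get("sample_ids")
            ids = [s.decode() if isinstance(s, bytes) else str(s) for s in ids] \
                if ids is not None else [f"s{i:06d}" for i in range(X.shape[0])]
    else:
        sep = "\t" if (format_hint == "tsv" or path.suffix.lower() in
                       (".tsv", ".tab")) else ","
        lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
        if not lines:
            raise MatrixFormatError(f"{path}: empty file")
        rows = [ln.split(sep) for ln in lines]
        widths = {len(r) for r in rows}
        if len(widths) != 1:
            bad = next(i for i, r in enumerate(rows) if len(r) != len(rows[0]))
            raise MatrixFormatError(f"{path}: ragged row at line {bad + 1}")
        has_header = not _looks_numeric(rows[0][1:] if len(rows[0]) > 1 else rows[0])
        data_rows = rows[1:] if has_header else rows
        if not data_rows:
            raise MatrixFormatError(f"{path}: no data rows")
        has_ids = not _looks_numeric(data_rows[0][:1])
        ids = [r[0] for r in data_rows] if has_ids else \
            [f"s{i:06d}" for i in range(len(data_rows))]
        body = [r[1:] if has_ids else r for r in data_rows]
        try:
            X = np.array([[float(v) for v in r] for r in body], dtype=np.float64)
        except ValueError as e:
            raise MatrixFormatError(f"{path}: non-numeric value ({e})") from e
    if np.isnan(X).any():
        if nan_policy == "impute_mean":
            means = np.nanmean(X, axis=0)
            idx = np.where(np.isnan(X))
            X[idx] = means[idx[1]]
        else:
            raise MatrixFormatError(f"{path}: contains NaN (nan_policy='reject')")
    if not np.all(np.isfinite(X)):
        raise MatrixFormatError(f"{path}: contains non-finite values")
    return X, ids


def save_matrix(path, X: np.ndarray, sample_ids=None,
                format_hint: str | None = None) -> None:
    path = Path(path)
    X = np.asarray(X, dtype=np.float64)
    ids = list(sample_ids) if sample_ids is not None else \
        [f"s{i:06d}" for i in range(X.shape[0])]
    if _is_hdf5(path, format_hint):
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("samples", data=X)
            ds.attrs["sample_ids"] = [str(s) for s in ids]
    else:
        sep = "\t" if (format_hint == "tsv" or path.suffix.lower() == ".tsv") else ","
        df = pd.DataFrame(X, index=ids)
        df.to_csv(path, sep=sep, header=False, float_format="%.17g")


def save_encoder(path, encoder: HypersphereEncoder) -> None:
    with h5py.File(path, "w") as fh:
        g = fh.create_group("encoder")
        for k, v in encoder.weights.items():
            g.create_dataset(k, data=np.asarray(v, dtype=np.float64))
        for k, v in encoder.config.to_dict().items():
            g.attrs[k] = v
        g.attrs["encoder_id"] = encoder.encoder_id
        if encoder.augmentation is not None:
            g.attrs["noise_gain"] = encoder.augmentation.noise_gain
            g.attrs["rng_seed"] = encoder.augmentation.rng_seed
        if encoder.training_log:
            g.create_dataset("training_log",
                             data=np.asarray(encoder.training_log, dtype=np.float64))


def load_encoder(path) -> HypersphereEncoder:
    with h5py.File(path, "r") as fh:
        g = fh["encoder"]
        weights = {k: np.asarray(g[k], dtype=np.float64)
                   for k in g if k != "training_log"}
        cfg = EncoderConfig(**{k: (int(g.attrs[k]) if k in (
            "input_dim", "intermediate_dim", "latent_dim", "n_negatives",
            "batch_size", "epochs") else float(g.attrs[k]))
            for k in EncoderConfig().to_dict()})
        aug = None
        if "noise_gain" in g.attrs:
            aug = AugmentationConfig(noise_gain=float(g.attrs["noise_gain"]),
                                     rng_seed=int(g.attrs["rng_seed"]))
        log = [(int(e), float(l)) for e, l in g["training_log"][()]] \
            if "training_log" in g else []
        return HypersphereEncoder(weights=weights, config=cfg,
                                  training_log=log, augmentation=aug,
                                  encoder_id=str(g.attrs["encoder_id"]))


def save_match(path, match: MatchResult, omap: OrthogonalMap,
               extra_attrs: dict | None = None) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("permutation", data=match.permutation.astype(np.int64))
        fh.create_dataset("R", data=omap.R.astype(np.float64))
        fh.attrs.update({"hsic": match.hsic,
                         "normalized_hsic": match.normalized_hsic,
                         "restarts_run": match.restarts_run,
                         "source": omap.source, "target": omap.target})
        if extra_attrs:
            fh.attrs.update(extra_attrs)


def load_match(path) -> tuple[MatchResult, OrthogonalMap]:
    with h5py.File(path, "r") as fh:
        match = MatchResult(
            permutation=np.asarray(fh["permutation"], dtype=np.intp),
            hsic=float(fh.attrs["hsic"]),
            normalized_hsic=float(fh.attrs["normalized_hsic"]),
            restarts_run=int(fh.attrs["restarts_run"]))
        omap = OrthogonalMap(R=np.asarray(fh["R"], dtype=np.float64),
                             source=str(fh.attrs["source"]),
                             target=str(fh.attrs["target"]))
    return match, omap
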