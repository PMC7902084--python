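"""HDF5 persistence for snapshot stacks, models and predictions.

Snapshot stacks use a minimal CXI-style layout: datasets ``frames``
(n x rows x cols), ``labels``, ``qmap`` and ``mask``, with the scalar
geometry stored as attributes and per-frame provenance under ``meta/``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Union

import h5py
import numpy as np
import yaml

from .gml import Prediction
from .manifold import KernelParams, Manifold
from .simulate import QGrid, SnapshotSet, make_qgrid

PathLike = Union[str, Path]


def _pixel_geometry(qmap: np.ndarray, mask: np.ndarray, attrs) -> QGrid:
    n_rows, n_cols = qmap.shape
    ref = make_qgrid(
        n_rows, n_cols, float(attrs["q_corner"]), 0, float(attrs["particle_diameter"])
    )
    return QGrid(
        n_rows=n_rows,
        n_cols=n_cols,
        q=qmap,
        theta=ref.theta,
        q_corner=float(attrs["q_corner"]),
        gap_mask=mask.astype(bool),
        shannon_side=float(attrs["shannon_side"]),
    )


def save_snapshots(path: PathLike, sset: SnapshotSet, config_yaml: Optional[str] = None):
    g = sset.geometry
    with h5py.File(path, "w") as h5:
        h5.create_dataset(
            "frames", data=sset.frames.reshape(sset.n, g.n_rows, g.n_cols)
        )
        if sset.labels is not None:
            h5.create_dataset("labels", data=np.asarray(sset.labels, dtype=np.uint8))
        h5.create_dataset("qmap", data=g.q)
        h5.create_dataset("mask", data=g.gap_mask.astype(np.uint8))
        h5.attrs["q_corner"] = g.q_corner
        h5.attrs["shannon_side"] = g.shannon_side
        h5.attrs["particle_diameter"] = 0.5 / g.shannon_side
        if config_yaml is not None:
            h5.attrs["config"] = config_yaml
        meta = h5.create_group("meta")
        for key, val in sset.meta.items():
            if np.ndim(val) >= 1:
                meta.create_dataset(key, data=np.asarray(val))
            else:
                meta.attrs[key] = val


def load_snapshots(path: PathLike) -> SnapshotSet:
    with h5py.File(path, "r") as h5:
        frames = h5["frames"][...]
        labels = h5["labels"][...] if "labels" in h5 else None
        geometry = _pixel_geometry(h5["qmap"][...], h5["mask"][...], h5.attrs)
        meta = {}
        if "meta" in h5:
            for key in h5["meta"]:
                meta[key] = h5["meta"][key][...]
            meta.update(dict(h5["meta"].attrs))
    n = frames.shape[0]
    return SnapshotSet(
        frames=frames.reshape(n, -1), labels=labels, geometry=geometry, meta=meta
    )


def save_features(
    path: PathLike,
    X: np.ndarray,
    indices: np.ndarray,
    shape: tuple[int, int],
    labels: Optional[np.ndarray] = None,
):
    with h5py.File(path, "w") as h5:
        h5.create_dataset("X", data=X)
        h5.create_dataset("indices", data=np.asarray(indices))
        h5.attrs["grid_shape"] = shape
        if labels is not None:
            h5.create_dataset("labels", data=np.asarray(labels, dtype=np.uint8))


def load_features(path: PathLike):
    with h5py.File(path, "r") as h5:
        X = h5["X"][...]
        indices = h5["indices"][...]
        shape = tuple(int(v) for v in h5.attrs["grid_shape"])
        labels = h5["labels"][...] if "labels" in h5 else None
    return X, indices, shape, labels


def array_hash(X: np.ndarray) -> str:
    """Content hash of an array (dtype/shape-sensitive)."""
    h = hashlib.sha256()
    h.update(str(X.dtype).encode())
    h.update(str(X.shape).encode())
    h.update(np.ascontiguousarray(X).tobytes())
    return h.hexdigest()


def save_manifold(path: PathLike, manifold: Manifold):
    with h5py.File(path, "w") as h5:
        h5.create_dataset("X_train", data=manifold.X_train)
        h5.create_dataset("psi", data=manifold.psi)
        h5.create_dataset("eigenvalues", data=manifold.eigenvalues)
        h5.create_dataset("degrees", data=manifold.degrees)
        p = manifold.params
        h5.attrs.update(
            {
                "nN": p.nN,
                "sigma_mult": p.sigma_mult,
                "k": p.k,
                "sigmaF": p.sigmaF,
                "x_train_hash": array_hash(manifold.X_train),
            }
        )


def load_manifold(path: PathLike) -> Manifold:
    with h5py.File(path, "r") as h5:
        params = KernelParams(
            nN=int(h5.attrs["nN"]),
            sigma_mult=float(h5.attrs["sigma_mult"]),
            k=int(h5.attrs["k"]),
            sigmaF=float(h5.attrs["sigmaF"]),
        )
        return Manifold(
            X_train=h5["X_train"][...],
            psi=h5["psi"][...],
            eigenvalues=h5["eigenvalues"][...],
            degrees=h5["degrees"][...],
            params=params,
        )


def save_prediction(path: PathLike, pred: Prediction):
    with h5py.File(path, "w") as h5:
        h5.create_dataset("f_tilde", data=pred.f_tilde)
        h5.create_dataset("d", data=pred.d)
        h5.create_dataset("rank", data=pred.rank)
        if pred.unreliable is not None:
            h5.create_dataset("unreliable", data=pred.unreliable.astype(np.uint8))


def load_prediction(path: PathLike) -> Prediction:
    with h5py.File(path, "r") as h5:
        f_tilde = h5["f_tilde"][...]
        unreliable = (
            h5["unreliable"][...].astype(bool) if "unreliable" in h5 else None
        )
    return Prediction(f_tilde=f_tilde, unreliable=unreliable)


def write_json(path: PathLike, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def config_hash(config_dict: dict) -> str:
    """Stable short hash of a (nested, JSON-serializable) configuration."""
    canonical = json.dumps(config_dict, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def dump_yaml(path: PathLike, obj) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def load_yaml(path: PathLike):
    return yaml.safe_load(Path(path).read_text())
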