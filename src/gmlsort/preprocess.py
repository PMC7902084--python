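"""Feature extraction from detector frames.

Snapshots are compared within an annular q-band (default 0.03-0.08
nm^-1): the band excludes the nearly isotropic low-q core and the
signal-starved detector corners.  This module builds annulus masks,
computes photon statistics per Shannon pixel, filters photon-count
outliers, and vectorizes masked (optionally binned, optionally
unit-mean normalized) frames into the matrix on which all distances
are computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DataError
from .simulate import QGrid, SnapshotSet

__all__ = [
    "FeatureSpec",
    "PixelMap",
    "annulus_mask",
    "nphsh_of",
    "remove_outliers",
    "vectorize",
]


@dataclass
class FeatureSpec:
    """How frames become feature vectors.

    Annulus bounds are half-open [q_lo, q_hi) so adjacent bands are
    disjoint.  ``normalize='unit-mean'`` scales each frame to mean 1
    within the annulus, making distances insensitive to the per-shot
    intensity factor; ``'none'`` keeps raw counts.  ``bin_factor`` > 1
    sums square pixel blocks before vectorization (coarse, Shannon-scale
    features for speed or photon aggregation).
    """

    q_lo: float = 0.03
    q_hi: float = 0.08
    normalize: str = "unit-mean"
    bin_factor: int = 1

    def __post_init__(self):
        if not (0 <= self.q_lo < self.q_hi):
            raise ConfigError("require 0 <= q_lo < q_hi")
        if self.normalize not in ("unit-mean", "none"):
            raise ConfigError("normalize must be 'unit-mean' or 'none'")
        if self.bin_factor < 1:
            raise ConfigError("bin_factor must be >= 1")


@dataclass
class PixelMap:
    """Mapping from feature-vector entries back to (possibly binned) pixels."""

    shape: tuple[int, int]
    indices: np.ndarray  # flat indices into the (binned) grid
    bin_factor: int = 1

    def to_frame(self, values: np.ndarray) -> np.ndarray:
        """Scatter a feature vector back onto a 2-D grid for display."""
        out = np.zeros(self.shape[0] * self.shape[1], dtype=float)
        out[self.indices] = values
        return out.reshape(self.shape)


def annulus_mask(qgrid: QGrid, q_lo: float, q_hi: float) -> np.ndarray:
    """Boolean mask of usable pixels with q in [q_lo, q_hi).

    Half-open bounds keep adjacent annuli disjoint.  Gap pixels are
    always excluded.
    """
    if not (0 <= q_lo < q_hi):
        raise ConfigError("require 0 <= q_lo < q_hi")
    if q_lo > qgrid.q_corner:
        raise ConfigError("q_lo exceeds the detector corner q")
    mask = (qgrid.q >= q_lo) & (qgrid.q < q_hi) & qgrid.gap_mask
    if not mask.any():
        raise DataError(f"annulus [{q_lo}, {q_hi}) contains no usable pixels")
    return mask


def _shannon_count(qgrid: QGrid, mask: np.ndarray) -> float:
    # q-area covered by the usable pixels, in Shannon-pixel units
    return mask.sum() * (qgrid.dq / qgrid.shannon_side) ** 2


def nphsh_of(
    frame: np.ndarray, qgrid: QGrid, q_lo: float = 0.06, q_hi: float = 0.08
) -> float:
    """Average photon count per Shannon pixel within an annulus.

    The Shannon pixel is a square of side 1/(2D) in q for particle
    diameter D; the annulus holds (usable q-area)/(Shannon side)^2 of
    them.  This is the oversampling-independent signal-level statistic
    used throughout the simulator and the noise scans.
    """
    mask = annulus_mask(qgrid, q_lo, q_hi)
    frame2d = np.asarray(frame).reshape(qgrid.shape)
    return float(frame2d[mask].sum() / _shannon_count(qgrid, mask))


def remove_outliers(
    sset: SnapshotSet,
    upper_quantile: float = 0.995,
    q_lo: float = 0.03,
    q_hi: float = 0.08,
) -> SnapshotSet:
    """Drop frames whose annulus photon total exceeds an upper quantile.

    Emulates the customary removal of abnormally bright frames (droplet
    hits, detector artifacts) before embedding.  Frames strictly above
    the ``upper_quantile`` quantile of the per-frame annulus totals are
    removed; the dropped indices are recorded in
    ``meta['dropped_indices']``.
    """
    if not (0 < upper_quantile <= 1):
        raise ConfigError("upper_quantile must be in (0, 1]")
    mask = annulus_mask(sset.geometry, q_lo, q_hi).ravel()
    totals = sset.frames[:, mask].sum(axis=1)
    threshold = np.quantile(totals, upper_quantile)
    keep = totals <= threshold
    dropped = np.flatnonzero(~keep)
    meta = dict(sset.meta)
    for key in ("K", "alpha", "w"):
        if key in meta and np.ndim(meta[key]) == 1 and len(meta[key]) == sset.n:
            meta[key] = np.asarray(meta[key])[keep]
    meta["dropped_indices"] = dropped
    return SnapshotSet(
        frames=sset.frames[keep],
        labels=None if sset.labels is None else sset.labels[keep],
        geometry=sset.geometry,
        meta=meta,
    )


def _bin_blocks(arr: np.ndarray, f: int, how: str) -> np.ndarray:
    """Reduce f x f pixel blocks of the trailing two axes."""
    *lead, R, C = arr.shape
    Rb, Cb = R // f, C // f
    view = arr[..., : Rb * f, : Cb * f].reshape(*lead, Rb, f, Cb, f)
    if how == "sum":
        return view.sum(axis=(-3, -1))
    if how == "mean":
        return view.mean(axis=(-3, -1))
    if how == "all":
        return view.all(axis=(-3, -1))
    raise ValueError(how)


def vectorize(
    sset: SnapshotSet, spec: FeatureSpec = FeatureSpec()
) -> tuple[np.ndarray, PixelMap]:
    """Snapshots -> (n x p) feature matrix restricted to the annulus.

    With binning, photon counts are block-summed, the q map is
    block-averaged, and a binned pixel is usable only if its whole block
    is.  Unit-mean normalization divides each row by its annulus mean
    (rows with zero total are left untouched).  Returns the matrix and a
    :class:`PixelMap` for scattering vectors back onto the detector.
    """
    qgrid = sset.geometry
    f = spec.bin_factor
    frames = sset.frames.reshape(sset.n, qgrid.n_rows, qgrid.n_cols)
    q = qgrid.q
    usable = qgrid.gap_mask
    if f > 1:
        frames = _bin_blocks(frames, f, "sum")
        q = _bin_blocks(q, f, "mean")
        usable = _bin_blocks(usable, f, "all")
    mask = (q >= spec.q_lo) & (q < spec.q_hi) & usable
    if not mask.any():
        raise DataError("feature annulus is empty after binning/masking")
    flat_idx = np.flatnonzero(mask.ravel())
    X = frames.reshape(sset.n, -1)[:, flat_idx].astype(np.float32)
    if spec.normalize == "unit-mean":
        means = X.mean(axis=1)
        nz = means > 0
        X[nz] /= means[nz, None]
    return X, PixelMap(shape=mask.shape, indices=flat_idx, bin_factor=f)
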