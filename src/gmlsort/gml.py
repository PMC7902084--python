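"""Label projection and out-of-sample prediction (the classifier core).

The binary training labels f (1 = single particle) are projected onto
the embedding basis to give the transform vector C = Psi^T f, using the
orthonormality Psi^T Psi = I.  Test snapshots are carried into the same
embedding by the Nystrom extension: each test point receives kernel
weights against its nearest training points, which are normalized
consistently with the training operator and combined with the training
eigenvectors, each coordinate rescaled by its eigenvalue.  The
prediction f~ = Psi~ C then lands near 1 for single particles and near
0 for everything else; ranking by the deviation d = |f~ - 1| drives
subset selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .errors import ConfigError, DataError
from .manifold import Manifold

__all__ = [
    "TransformVector",
    "Prediction",
    "fit_transform_vector",
    "nystrom_extend",
    "predict",
    "select_top",
    "select_window",
    "truncated_predict",
]

_EIGENVALUE_FLOOR = 1e-12


@dataclass
class TransformVector:
    """Coefficients of the training labels in the embedding basis."""

    C: np.ndarray
    order: np.ndarray  # permutation sorting |C| descending (stable)


@dataclass
class Prediction:
    """Per-snapshot scores f~, deviations d = |f~ - 1| and the d-ranking.

    ``rank`` is a stable ascending-d permutation (ties broken by
    original index); ``unreliable`` flags test points whose extension
    kernel weights all underflowed.
    """

    f_tilde: np.ndarray
    d: np.ndarray = field(init=False)
    rank: np.ndarray = field(init=False)
    unreliable: Optional[np.ndarray] = None

    def __post_init__(self):
        self.f_tilde = np.asarray(self.f_tilde, dtype=float)
        self.d = np.abs(self.f_tilde - 1.0)
        self.rank = np.argsort(self.d, kind="stable")

    @property
    def m(self) -> int:
        return len(self.f_tilde)


def _psi_of(manifold_or_psi: Union[Manifold, np.ndarray]) -> np.ndarray:
    return getattr(manifold_or_psi, "psi", manifold_or_psi)


def fit_transform_vector(
    manifold: Union[Manifold, np.ndarray], f: np.ndarray
) -> TransformVector:
    """C = Psi^T f, with the |C|-descending ordering attached.

    ``f`` must be a binary ground-truth vector matching the embedding
    rows.  Because Psi has orthonormal columns, C is also the
    least-squares solution of Psi C ~ f.
    """
    psi = _psi_of(manifold)
    f = np.asarray(f)
    if len(f) != psi.shape[0]:
        raise DataError(f"label length {len(f)} != embedding rows {psi.shape[0]}")
    if not np.isin(f, (0, 1)).all():
        raise DataError("ground-truth vector must be binary (0/1)")
    C = psi.T @ f.astype(float)
    order = np.argsort(-np.abs(C), kind="stable")
    return TransformVector(C=C, order=order)


def nystrom_extend(
    manifold: Manifold,
    X_test: np.ndarray,
    n_neighbors: Optional[int] = None,
    dense: bool = False,
    chunk_size: int = 2048,
    return_flags: bool = False,
):
    """Project test points into the training embedding (m x k matrix).

    For a test point x with kernel weights w_j = exp(-|x - x_j|^2 /
    (2 sigmaN^2)) over its ``n_neighbors`` nearest training points
    (default: the training nN; ``dense=True`` uses all training
    points), the extended coordinates are

        psi~_k(x) = (1/lambda_k) * sum_j w_j / (sqrt(sum w) sqrt(deg_j)) psi_jk,

    which reproduces the training rows exactly on a fully dense graph.
    Coordinates belonging to eigenvalues below 1e-12 in magnitude are
    zeroed with a warning instead of amplified; test points whose
    weights all underflow are flagged unreliable (row of zeros).
    """
    X_test = np.asarray(X_test)
    k = manifold.k
    if X_test.ndim != 2 or X_test.shape[1] != manifold.X_train.shape[1]:
        if X_test.shape[0] == 0:
            return (np.zeros((0, k)), np.zeros(0, bool)) if return_flags else np.zeros((0, k))
        raise DataError(
            f"test feature dimension {X_test.shape[1:]} does not match "
            f"training dimension {manifold.X_train.shape[1]}"
        )
    m = len(X_test)
    if m == 0:
        return (np.zeros((0, k)), np.zeros(0, bool)) if return_flags else np.zeros((0, k))

    lam = manifold.eigenvalues
    usable = np.abs(lam) >= _EIGENVALUE_FLOOR
    if not usable.all():
        warnings.warn(
            f"{(~usable).sum()} eigenvalue(s) below {_EIGENVALUE_FLOOR}; "
            "their extended coordinates are set to zero",
            stacklevel=2,
        )
    inv_lam = np.where(usable, 1.0 / np.where(usable, lam, 1.0), 0.0)
    sqrt_deg = np.sqrt(manifold.degrees)
    two_sigma2 = 2.0 * manifold.sigmaN**2

    psi_tilde = np.empty((m, k))
    flags = np.zeros(m, dtype=bool)

    if dense:
        for start in range(0, m, chunk_size):
            sl = slice(start, min(start + chunk_size, m))
            diff = X_test[sl].astype(np.float64)
            d2 = (
                (diff**2).sum(1)[:, None]
                - 2.0 * diff @ manifold.X_train.T.astype(np.float64)
                + (manifold.X_train.astype(np.float64) ** 2).sum(1)[None, :]
            )
            w = np.exp(-np.clip(d2, 0.0, None) / two_sigma2)
            total = w.sum(1)
            bad = total <= 0
            flags[sl] = bad
            total[bad] = 1.0
            a = w / (np.sqrt(total)[:, None] * sqrt_deg[None, :])
            a[bad] = 0.0
            psi_tilde[sl] = (a @ manifold.psi) * inv_lam[None, :]
    else:
        nN = n_neighbors if n_neighbors is not None else manifold.params.nN
        nN = min(nN, manifold.n)
        nn = NearestNeighbors(n_neighbors=nN, algorithm="brute").fit(manifold.X_train)
        for start in range(0, m, chunk_size):
            sl = slice(start, min(start + chunk_size, m))
            dist, idx = nn.kneighbors(X_test[sl])
            w = np.exp(-(dist.astype(np.float64) ** 2) / two_sigma2)
            total = w.sum(1)
            bad = total <= 0
            flags[sl] = bad
            total[bad] = 1.0
            a = w / (np.sqrt(total)[:, None] * sqrt_deg[idx])
            a[bad] = 0.0
            rows = np.einsum("tj,tjk->tk", a, manifold.psi[idx])
            psi_tilde[sl] = rows * inv_lam[None, :]

    if flags.any():
        warnings.warn(
            f"{flags.sum()} test point(s) had fully-underflowed extension "
            "weights; their predictions are unreliable",
            stacklevel=2,
        )
    return (psi_tilde, flags) if return_flags else psi_tilde


def predict(
    psi_tilde: np.ndarray,
    C: Union[TransformVector, np.ndarray],
    unreliable: Optional[np.ndarray] = None,
) -> Prediction:
    """f~ = Psi~ C with deviation d = |f~ - 1| and the stable d-ranking."""
    psi_tilde = np.asarray(psi_tilde)
    Cvec = C.C if isinstance(C, TransformVector) else np.asarray(C, dtype=float)
    if psi_tilde.shape[1] != len(Cvec):
        raise DataError(
            f"embedding has {psi_tilde.shape[1]} columns but C has {len(Cvec)}"
        )
    return Prediction(f_tilde=psi_tilde @ Cvec, unreliable=unreliable)


def select_top(prediction: Prediction, tau: int) -> np.ndarray:
    """Indices of the tau snapshots closest to the ideal single score.

    Selections are nested: select_top(tau) is a prefix of
    select_top(tau + 1).
    """
    if not (1 <= tau <= prediction.m):
        raise ConfigError(f"tau must be in [1, {prediction.m}], got {tau}")
    return prediction.rank[:tau]


def select_window(prediction: Prediction, lo: float, hi: float) -> np.ndarray:
    """Indices with lo <= f~ <= hi (e.g. the [0.8, 1.2] single-particle band)."""
    if not lo < hi:
        raise ConfigError("window requires lo < hi")
    f = prediction.f_tilde
    return np.flatnonzero((f >= lo) & (f <= hi))


def truncated_predict(
    psi: Union[Manifold, np.ndarray],
    tv: TransformVector,
    k_used: int,
    order: str = "natural",
) -> Prediction:
    """Prediction from the leading k_used eigenvector/coefficient pairs.

    ``order='natural'`` takes the first k_used eigenvalue-ordered
    columns; ``order='sorted'`` takes the k_used largest-|C| pairs.
    Used to study how many embedding coordinates actually carry the
    single/non-single separation.
    """
    psi = _psi_of(psi)
    if not (1 <= k_used <= psi.shape[1]):
        raise ConfigError(f"k_used must be in [1, {psi.shape[1]}]")
    if order == "natural":
        cols = np.arange(k_used)
    elif order == "sorted":
        cols = tv.order[:k_used]
    else:
        raise ConfigError("order must be 'natural' or 'sorted'")
    return Prediction(f_tilde=psi[:, cols] @ tv.C[cols])
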