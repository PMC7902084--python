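"""Diffusion-map embedding of the training feature matrix.

A sparse symmetrized k-nearest-neighbor graph carries a Gaussian kernel
W_ij = exp(-d_ij^2 / (2 sigmaN^2)); the symmetrically normalized
operator S = D^{-1/2} W D^{-1/2} is eigendecomposed and the top-k
orthonormal eigenvectors form the embedding matrix Psi (one row per
training snapshot).  The kernel width is expressed as a multiple of an
automatically selected length scale sigmaF, found from the linear
region of the log-log kernel-sum curve (the standard bandwidth-selection
procedure for diffusion maps).

Symmetric normalization is used (rather than the row-stochastic form)
so that the eigenvectors are orthonormal in the ordinary inner product:
Psi^T Psi = I, the identity on which the label-projection step relies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import eigsh
from sklearn.neighbors import NearestNeighbors

from .errors import ConfigError, DataError, NumericalError

__all__ = [
    "KernelParams",
    "KnnGraph",
    "Manifold",
    "knn_distances",
    "ferguson_sigma",
    "diffusion_map",
    "bimodality_score",
    "parameter_scan",
]


@dataclass
class KernelParams:
    """Diffusion-map kernel parameters.

    ``nN`` nearest neighbors per point; ``sigma_mult`` multiplies the
    automatically selected length scale sigmaF to give the kernel width
    sigmaN = sigma_mult * sigmaF; ``k`` is the embedding dimension
    (leading, quasi-constant eigenvector included).  The defaults
    (k=201, nN=30, sigma_mult=10) are the reference operating point for
    snapshot classification.
    """

    nN: int = 30
    sigma_mult: float = 10.0
    k: int = 201
    sigmaF: Optional[float] = None

    def __post_init__(self):
        if self.nN < 2:
            raise ConfigError("nN must be >= 2")
        if self.sigma_mult <= 0:
            raise ConfigError("sigma_mult must be positive")
        if self.k < 1:
            raise ConfigError("k must be >= 1")


@dataclass
class KnnGraph:
    """Symmetrized kNN graph as a unique undirected edge list (rows < cols)."""

    n: int
    rows: np.ndarray
    cols: np.ndarray
    dists: np.ndarray


def knn_distances(X: np.ndarray, nN: int) -> KnnGraph:
    """Euclidean kNN graph, symmetrized by union of neighbor lists.

    An edge is kept if either endpoint lists the other among its nN
    nearest; zero distances (duplicate points) are legitimate edges.
    Ties are resolved by index order, for reproducibility.
    """
    X = np.asarray(X)
    n = len(X)
    if n <= nN:
        raise DataError(f"need more than nN={nN} points, got {n}")
    nbrs = NearestNeighbors(n_neighbors=min(nN + 1, n), algorithm="brute").fit(X)
    dist, idx = nbrs.kneighbors(X)
    src = np.repeat(np.arange(n), idx.shape[1])
    dst = idx.ravel().astype(np.int64)
    d = dist.ravel().astype(np.float64)
    nonself = src != dst
    src, dst, d = src[nonself], dst[nonself], d[nonself]
    lo = np.minimum(src, dst)
    hi = np.maximum(src, dst)
    key = lo * n + hi
    uniq, first = np.unique(key, return_index=True)
    return KnnGraph(n=n, rows=(uniq // n), cols=(uniq % n), dists=d[first])


def ferguson_sigma(
    graph: KnnGraph, n_grid: int = 64, slope_fraction: float = 0.5
) -> float:
    """Automatic kernel length scale from the log-log kernel-sum curve.

    Evaluates L(sigma) = n + 2 * sum_edges exp(-d^2/(2 sigma^2)) over a
    logarithmic sigma grid (the n self-terms give the small-sigma
    plateau, the edge count the large-sigma plateau), locates the
    steepest linear region of log L vs log sigma, and returns the
    geometric midpoint of that region.  Falls back to the median edge
    distance when no rising region is detected.
    """
    d = np.asarray(graph.dists, dtype=float)
    pos = d[d > 0]
    if pos.size == 0:
        raise NumericalError("all neighbor distances are zero; no length scale")
    grid = np.geomspace(pos.min() / 10.0, d.max() * 10.0, n_grid)
    logL = np.empty(n_grid)
    for i, s in enumerate(grid):
        logL[i] = np.log(graph.n + 2.0 * np.exp(-(d**2) / (2.0 * s**2)).sum())
    slope = np.gradient(logL, np.log(grid))
    imax = int(np.argmax(slope))
    smax = slope[imax]
    if not np.isfinite(smax) or smax <= 0:
        return float(np.median(d))
    threshold = slope_fraction * smax
    i0 = imax
    while i0 > 0 and slope[i0 - 1] >= threshold:
        i0 -= 1
    i1 = imax
    while i1 < n_grid - 1 and slope[i1 + 1] >= threshold:
        i1 += 1
    return float(np.sqrt(grid[i0] * grid[i1]))


@dataclass
class Manifold:
    """Trained diffusion-map embedding.

    ``psi`` is the n x k matrix of orthonormal eigenvectors of the
    normalized kernel operator (columns sorted by descending
    eigenvalue, sign fixed so each column's largest-magnitude entry is
    positive); ``degrees`` are the kernel row sums, needed by the
    out-of-sample extension; ``X_train`` is retained for neighbor
    queries against new data.
    """

    X_train: np.ndarray
    psi: np.ndarray
    eigenvalues: np.ndarray
    degrees: np.ndarray
    params: KernelParams

    @property
    def n(self) -> int:
        return self.psi.shape[0]

    @property
    def k(self) -> int:
        return self.psi.shape[1]

    @property
    def sigmaN(self) -> float:
        return self.params.sigma_mult * self.params.sigmaF


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    j = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[j, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    return vecs * signs


def diffusion_map(X: np.ndarray, params: KernelParams = KernelParams()) -> Manifold:
    """Embed a feature matrix into the top-k diffusion-map eigenvectors.

    Builds the Gaussian kernel on the symmetrized kNN graph (diagonal
    1), normalizes symmetrically, and extracts the k leading
    eigenpairs with a sparse Lanczos solver (dense fallback when k is
    close to n).  A disconnected graph triggers a warning but the
    computation proceeds.  Deterministic for a fixed input.
    """
    X = np.asarray(X)
    n = len(X)
    if params.k > n - 1:
        raise ConfigError(f"embedding dimension k={params.k} needs n >= k+1 (n={n})")
    graph = knn_distances(X, params.nN)
    sigmaF = params.sigmaF if params.sigmaF is not None else ferguson_sigma(graph)
    resolved = replace(params, sigmaF=float(sigmaF))
    sigmaN = resolved.sigma_mult * resolved.sigmaF

    w = np.exp(-(graph.dists**2) / (2.0 * sigmaN**2))
    diag = np.arange(n)
    W = sp.coo_matrix(
        (
            np.concatenate([w, w, np.ones(n)]),
            (
                np.concatenate([graph.rows, graph.cols, diag]),
                np.concatenate([graph.cols, graph.rows, diag]),
            ),
        ),
        shape=(n, n),
    ).tocsr()

    ncomp, _ = connected_components(W, directed=False)
    if ncomp > 1:
        warnings.warn(
            f"kNN kernel graph has {ncomp} connected components; "
            "embedding proceeds but eigenvectors factor per component",
            stacklevel=2,
        )

    degrees = np.asarray(W.sum(axis=1)).ravel()
    inv_sqrt_deg = 1.0 / np.sqrt(degrees)
    S = sp.diags(inv_sqrt_deg) @ W @ sp.diags(inv_sqrt_deg)

    try:
        if params.k >= n - 1:
            vals, vecs = np.linalg.eigh(S.toarray())
            vals, vecs = vals[-params.k :], vecs[:, -params.k :]
        else:
            v0 = np.full(n, 1.0 / np.sqrt(n))
            vals, vecs = eigsh(S.tocsc(), k=params.k, which="LA", v0=v0)
    except Exception as exc:  # pragma: no cover - solver failure path
        raise NumericalError(f"eigendecomposition failed: {exc}") from exc

    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], _fix_signs(vecs[:, order])
    return Manifold(
        X_train=X, psi=vecs, eigenvalues=vals, degrees=degrees, params=resolved
    )


def bimodality_score(f_tilde: np.ndarray, labels: np.ndarray) -> float:
    """Two-class separation of the prediction scores (d-prime).

    |mean(f~ | single) - mean(f~ | non-single)| over the root of the
    summed within-class variances.  Large values mean a sharply bimodal
    score distribution.
    """
    f_tilde = np.asarray(f_tilde, dtype=float)
    labels = np.asarray(labels).astype(bool)
    a, b = f_tilde[labels], f_tilde[~labels]
    if a.size == 0 or b.size == 0:
        raise DataError("both classes must be present")
    spread = np.sqrt(a.var() + b.var())
    return float(abs(a.mean() - b.mean()) / max(spread, 1e-12))


def parameter_scan(
    X: np.ndarray,
    f: np.ndarray,
    grid: Iterable[tuple[int, int, float]],
    criterion: str = "max-purity",
    eval_fraction: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Score (k, nN, sigma_mult) combinations by self-prediction quality.

    For each combination the training set predicts itself (f~ = Psi
    Psi^T f truncated to k columns) and the score is either the maximum
    purity over the tau sweep on a held-out random split
    (``'max-purity'``), or the bimodality (d-prime) of the f~
    distribution (``'bimodality'``).  Embeddings are shared across k
    values with common (nN, sigma_mult).  Returns a DataFrame sorted by
    descending score.
    """
    from .metrics import evaluate, max_purity_point

    if criterion not in ("max-purity", "bimodality"):
        raise ConfigError("criterion must be 'max-purity' or 'bimodality'")
    grid = list(grid)
    if not grid:
        raise ConfigError("empty parameter grid")
    f = np.asarray(f, dtype=float)
    n = len(f)
    rng = np.random.default_rng(seed)
    held = np.sort(rng.permutation(n)[: max(2, int(round(eval_fraction * n)))])

    by_pair: dict[tuple[int, float], list[int]] = {}
    for k, nN, sm in grid:
        by_pair.setdefault((int(nN), float(sm)), []).append(int(k))

    rows = []
    for (nN, sm), ks in by_pair.items():
        mani = diffusion_map(X, KernelParams(nN=nN, sigma_mult=sm, k=max(ks)))
        for k in ks:
            psi_k = mani.psi[:, :k]
            f_tilde = psi_k @ (psi_k.T @ f)
            if criterion == "bimodality":
                score = bimodality_score(f_tilde, f)
            else:
                d = np.abs(f_tilde[held] - 1.0)
                ranking = np.argsort(d, kind="stable")
                report = evaluate(ranking, f[held].astype(int))
                score = max_purity_point(report).chi
            rows.append(
                {
                    "k": k,
                    "nN": nN,
                    "sigma_mult": sm,
                    "sigmaF": mani.params.sigmaF,
                    "score": score,
                }
            )
    df = pd.DataFrame(rows).sort_values("score", ascending=False, kind="stable")
    return df.reset_index(drop=True)
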