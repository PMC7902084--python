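"""Synthetic XFEL snapshot simulator.

Generates labeled stacks of single- and multiple-particle diffraction
snapshots with the statistical structure of a single-particle imaging
(SPI) run:

* a parametric spherical-particle intensity model (uniform-sphere form
  factor, ~70 nm virus-sized particles, with size jitter and a random
  low-order angular modulation standing in for orientation variability),
* a Poisson particle-count law conditioned on at least one particle per
  hit (label 1 = exactly one particle),
* scaling of every pattern to a target average photon count per Shannon
  pixel (``nphsh``) in an outer q-annulus,
* a flat background at ``b`` times the sample signal, a per-shot
  intensity factor ``w``, per-pixel Poisson photon sampling, and a
  horizontal detector-panel gap.

Momentum transfer uses the crystallographic convention q = 1/d, so a
detector-corner value q = 0.11 nm^-1 corresponds to 9.0 nm resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ConfigError, DataError

__all__ = [
    "QGrid",
    "SimulationConfig",
    "SnapshotSet",
    "make_qgrid",
    "single_particle_intensity",
    "multiple_particle_intensity",
    "sample_particle_count",
    "compute_alpha",
    "add_background",
    "generate_dataset",
]

# First zero of the uniform-sphere form factor amplitude
# 3(sin x - x cos x)/x^3 occurs at x = 2*pi*q*R ~ 4.4934.
_SPHERE_FIRST_ZERO_X = 4.493409457909064

# Fixed angular shape signature of the model particle: harmonic order,
# amplitude-modulation depth, and phase relative to the particle frame.
# Every single particle shows this same signature at a random in-plane
# rotation; the depths sum to < 1 so the amplitude (and hence the
# squared intensity) stays positive.
_ANGULAR_SIGNATURE = ((2, 0.30, 0.0), (3, 0.25, 1.1), (5, 0.20, 2.4))


@dataclass
class QGrid:
    """Detector pixel grid mapped to momentum-transfer magnitudes.

    Attributes
    ----------
    n_rows, n_cols : int
        Detector dimensions in pixels.
    q : ndarray of shape (n_rows, n_cols)
        q-magnitude of each pixel in nm^-1, radially monotone from the
        pattern center and equal to ``q_corner`` at the corners.
    theta : ndarray of shape (n_rows, n_cols)
        Azimuthal angle of each pixel about the pattern center (rad).
    q_corner : float
        q at the detector corner (nm^-1).
    gap_mask : ndarray of bool
        True where the pixel is usable; False inside the panel gap.
    shannon_side : float
        Side length of a Shannon pixel in q, 1/(2 D) for particle
        diameter D (nm^-1).
    """

    n_rows: int
    n_cols: int
    q: np.ndarray
    theta: np.ndarray
    q_corner: float
    gap_mask: np.ndarray
    shannon_side: float

    @property
    def dq(self) -> float:
        """q increment of one detector pixel (nm^-1)."""
        cy = (self.n_rows - 1) / 2.0
        cx = (self.n_cols - 1) / 2.0
        return self.q_corner / float(np.hypot(cy, cx))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)


def make_qgrid(
    n_rows: int = 128,
    n_cols: int = 128,
    q_corner: float = 0.11,
    gap_rows: int = 4,
    particle_diameter: float = 70.0,
) -> QGrid:
    """Build the detector geometry: per-pixel q map, panel gap, Shannon scale.

    The pattern center sits between the four central pixels; q grows
    linearly with pixel radius and reaches ``q_corner`` exactly at the
    corner pixels.  ``gap_rows`` contiguous central rows are masked out
    to emulate the gap between two detector panels.
    """
    if n_rows < 16 or n_cols < 16:
        raise ConfigError("detector must be at least 16x16 pixels")
    if q_corner <= 0:
        raise ConfigError("q_corner must be positive")
    if gap_rows < 0 or gap_rows >= n_rows:
        raise ConfigError("gap_rows must be in [0, n_rows)")
    if particle_diameter <= 0:
        raise ConfigError("particle_diameter must be positive")

    cy = (n_rows - 1) / 2.0
    cx = (n_cols - 1) / 2.0
    yy = np.arange(n_rows)[:, None] - cy
    xx = np.arange(n_cols)[None, :] - cx
    r = np.hypot(yy, xx)
    q = q_corner * r / float(np.hypot(cy, cx))
    theta = np.arctan2(yy, xx + np.zeros_like(yy))

    gap_mask = np.ones((n_rows, n_cols), dtype=bool)
    if gap_rows:
        start = n_rows // 2 - gap_rows // 2
        gap_mask[start : start + gap_rows, :] = False

    shannon_side = 1.0 / (2.0 * particle_diameter)
    return QGrid(n_rows, n_cols, q, theta, q_corner, gap_mask, shannon_side)


def _sphere_amplitude(x: np.ndarray) -> np.ndarray:
    """Uniform-sphere form factor amplitude 3(sin x - x cos x)/x^3, F(0)=1."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    nz = np.abs(x) > 1e-8
    xn = x[nz]
    out[nz] = 3.0 * (np.sin(xn) - xn * np.cos(xn)) / xn**3
    return out


def single_particle_intensity(
    qgrid: QGrid,
    rng: np.random.Generator,
    size_jitter: float = 0.05,
    radius: Optional[float] = None,
    modulation: bool = True,
) -> np.ndarray:
    """Noise-free scattered intensity of one particle on the detector.

    The radial structure is the squared uniform-sphere form factor at a
    jittered radius ``R (1 + eps)``, ``eps ~ U(-size_jitter, size_jitter)``.
    With ``modulation=True`` the particle additionally carries a fixed
    low-order angular signature (a faceted, not perfectly spherical
    shape) observed at a random in-plane orientation: cosine harmonics
    of fixed order, depth and relative phase modulate the scattered
    *amplitude* and enter the intensity squared, giving the order-unity
    azimuthal speckle contrast of real faceted particles.  The
    modulation is rotated by a random angle and attenuated toward low
    q, where real patterns are nearly isotropic.  Per-particle
    randomness is therefore low-dimensional (size and orientation), as
    for a rigid particle in an imaging experiment.  The result is
    nonnegative everywhere and deterministic given the generator state.
    """
    if radius is None:
        radius = 0.5 / (2.0 * qgrid.shannon_side)  # recover D/2 from 1/(2D)
    eps = rng.uniform(-size_jitter, size_jitter) if size_jitter > 0 else 0.0
    R = radius * (1.0 + eps)
    x = 2.0 * np.pi * qgrid.q * R
    intensity = _sphere_amplitude(x) ** 2
    if modulation:
        # low-q isotropy ramp: full modulation depth only beyond the
        # first form-factor minimum
        q_ramp = _SPHERE_FIRST_ZERO_X / (2.0 * np.pi * radius)
        ramp = np.clip(qgrid.q / q_ramp, 0.0, 1.0)
        rotation = rng.uniform(0.0, 2.0 * np.pi)
        amp_mod = np.ones_like(intensity)
        for order, depth, phase0 in _ANGULAR_SIGNATURE:
            amp_mod += depth * ramp * np.cos(order * (qgrid.theta - rotation) + phase0)
        intensity *= amp_mod**2
    return intensity


def multiple_particle_intensity(
    qgrid: QGrid,
    K: int,
    rng: np.random.Generator,
    size_jitter: float = 0.05,
    modulation: bool = True,
) -> np.ndarray:
    """Incoherent sum of K independent single-particle intensities (K >= 2)."""
    if K < 2:
        raise DataError(f"multiple-particle frame requires K >= 2, got {K}")
    total = np.zeros(qgrid.shape)
    for _ in range(K):
        total += single_particle_intensity(
            qgrid, rng, size_jitter=size_jitter, modulation=modulation
        )
    return total


def sample_particle_count(lambda_count: float, rng: np.random.Generator) -> int:
    """Draw a particle count from Poisson(lambda) conditioned on K >= 1."""
    if lambda_count <= 0:
        raise ConfigError("lambda_count must be positive")
    while True:
        k = int(rng.poisson(lambda_count))
        if k >= 1:
            return k


def compute_alpha(
    intensity: np.ndarray,
    qgrid: QGrid,
    outer_disk: tuple[float, float] = (0.06, 0.08),
    nphsh_target: float = 1.0,
) -> float:
    """Scaling factor bringing a pattern to the target photons/Shannon pixel.

    alpha is chosen so that ``alpha * intensity`` carries an average of
    ``nphsh_target`` expected photons per Shannon pixel within the outer
    annulus ``outer_disk``.
    """
    from .preprocess import nphsh_of

    current = nphsh_of(intensity, qgrid, *outer_disk)
    if current <= 0:
        raise DataError("no signal in the outer disk; cannot scale")
    return nphsh_target / current


def add_background(
    intensity: np.ndarray,
    qgrid: QGrid,
    b: float,
    nphsh_target: float,
    outer_disk: tuple[float, float] = (0.06, 0.08),
) -> np.ndarray:
    """Add a flat background whose outer-disk nphsh equals ``b * nphsh_target``.

    Models nearly q-independent scattering (e.g. from carrier gas) as a
    spatially constant per-pixel level.  ``b = 0`` returns the input
    unchanged.
    """
    from .preprocess import nphsh_of

    if b < 0:
        raise ConfigError("background factor b must be nonnegative")
    if b == 0:
        return intensity
    unit = nphsh_of(np.ones(qgrid.shape), qgrid, *outer_disk)
    level = b * nphsh_target / unit
    return intensity + level


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset.

    ``nphsh_target`` is the average photon count per Shannon pixel in
    the outer disk (the experiment's signal-level scale; typical values
    0.001-1), ``b`` the background-to-sample ratio (0, 1, 10, 100),
    ``w_range`` the shot-to-shot intensity factor interval, and
    ``lambda_count`` the mean of the Poisson particle-count law before
    conditioning on a hit.  ``noise_free=True`` suppresses the shot
    factor, background and Poisson sampling, yielding ideal patterns.
    """

    nphsh_target: float = 1.0
    b: float = 0.0
    w_range: tuple[float, float] = (0.2, 1.8)
    lambda_count: float = 1.0
    particle_diameter: float = 70.0
    size_jitter: float = 0.05
    n_train: int = 8000
    n_test: int = 10000
    seed: int = 0
    outer_disk: tuple[float, float] = (0.06, 0.08)
    noise_free: bool = False
    # geometry
    n_rows: int = 128
    n_cols: int = 128
    q_corner: float = 0.11
    gap_rows: int = 4
    # model details
    modulation: bool = True
    w_scales_background: bool = False

    def __post_init__(self):
        if not self.noise_free and self.nphsh_target <= 0:
            raise ConfigError("nphsh_target must be positive")
        if self.b < 0:
            raise ConfigError("b must be nonnegative")
        lo, hi = self.w_range
        if not (0 < lo <= hi):
            raise ConfigError("w_range must satisfy 0 < low <= high")
        if self.lambda_count <= 0:
            raise ConfigError("lambda_count must be positive")

    def qgrid(self) -> QGrid:
        return make_qgrid(
            self.n_rows,
            self.n_cols,
            self.q_corner,
            self.gap_rows,
            self.particle_diameter,
        )


@dataclass
class SnapshotSet:
    """A stack of flattened snapshots with labels, geometry, and provenance.

    ``frames`` holds nonnegative photon counts (or noise-free
    intensities) with one row per snapshot; ``labels`` is 1 for single
    particles, 0 otherwise; ``meta`` carries per-frame particle count
    ``K``, applied scaling ``alpha`` and shot factor ``w``.
    """

    frames: np.ndarray
    labels: Optional[np.ndarray]
    geometry: QGrid
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.labels is not None and len(self.labels) != len(self.frames):
            raise DataError("labels length must match number of frames")

    @property
    def n(self) -> int:
        return len(self.frames)

    def frame(self, i: int) -> np.ndarray:
        """Snapshot i reshaped to the 2-D detector layout."""
        return self.frames[i].reshape(self.geometry.shape)


def generate_dataset(
    config: SimulationConfig,
    n: Optional[int] = None,
    seed: Optional[int] = None,
    noise_free: Optional[bool] = None,
) -> SnapshotSet:
    """Generate a labeled snapshot set under the configured conditions.

    Per frame: draw the particle count K from the conditional Poisson
    law; build the single (K=1) or multiple (K>=2) particle intensity;
    scale with alpha to the target nphsh; multiply the sample term by a
    shot factor w ~ U(w_range); add the flat background; Poisson-sample
    each pixel; zero the gap pixels.  ``noise_free`` skips w, background
    and Poisson sampling.  Fully reproducible from the seed.

    ``n``, ``seed`` and ``noise_free`` override the corresponding config
    fields (``n`` defaults to ``config.n_train``), so one config can
    produce matched training and test sets.
    """
    if n is None:
        n = config.n_train
    if seed is None:
        seed = config.seed
    nf = config.noise_free if noise_free is None else noise_free

    qgrid = config.qgrid()
    rng = np.random.default_rng(seed)
    npix = qgrid.n_rows * qgrid.n_cols
    gap_flat = ~qgrid.gap_mask.ravel()

    from .preprocess import nphsh_of

    bg_level = 0.0
    if config.b > 0 and not nf:
        unit = nphsh_of(np.ones(qgrid.shape), qgrid, *config.outer_disk)
        bg_level = config.b * config.nphsh_target / unit

    frames = np.empty((n, npix), dtype=np.float32)
    counts = np.empty(n, dtype=np.int64)
    alphas = np.empty(n, dtype=np.float64)
    ws = np.ones(n, dtype=np.float64)

    for i in range(n):
        K = sample_particle_count(config.lambda_count, rng)
        if K == 1:
            intensity = single_particle_intensity(
                qgrid, rng, config.size_jitter, modulation=config.modulation
            )
        else:
            intensity = multiple_particle_intensity(
                qgrid, K, rng, config.size_jitter, modulation=config.modulation
            )
        alpha = compute_alpha(intensity, qgrid, config.outer_disk, config.nphsh_target)
        intensity = intensity * alpha
        if nf:
            frame = intensity
        else:
            w = rng.uniform(*config.w_range)
            ws[i] = w
            frame = w * intensity
            if bg_level > 0:
                frame = frame + (w * bg_level if config.w_scales_background else bg_level)
            frame = rng.poisson(frame).astype(np.float64)
        flat = frame.ravel().astype(np.float32)
        flat[gap_flat] = 0.0
        frames[i] = flat
        counts[i] = K
        alphas[i] = alpha

    labels = (counts == 1).astype(np.uint8)
    meta = {"K": counts, "alpha": alphas, "w": ws, "seed": seed}
    return SnapshotSet(frames=frames, labels=labels, geometry=qgrid, meta=meta)
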