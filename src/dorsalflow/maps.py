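"""Pinwheel-structured preference maps and Gabor receptive fields.

Orientation (V1) and direction (MT) preference maps are generated by
superposing ``n_waves`` complex plane waves with a common wavenumber
``2*pi/lambda_map`` and random propagation angles and phases.  The argument of
the resulting complex field, mapped onto the layer's angular period, yields a
quasi-periodic map organized around pinwheel singularities.  A second,
independent realization provides the receptive-field phase map.

Receptive fields are Gabor functions: an oriented Gaussian envelope times a
cosine carrier whose modulation axis is perpendicular to the preferred (bar)
orientation.  Lateral connectivity in V1/MT is derived from normalized inner
products between pairs of Gabor fields (:func:`gabor_correlation`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "OrientationMap",
    "GaborRF",
    "generate_map",
    "gabor",
    "gabor_correlation",
    "gabor_field_matrix",
]


@dataclass
class OrientationMap:
    """Per-grid-cell preferred angle and RF phase with pinwheel structure.

    ``theta`` lies in [0, period): period pi for orientation maps (V1),
    2*pi for direction maps (MT).  ``phase`` lies in [0, 2*pi).  Both are
    (rows, cols) arrays over the layer grid.
    """

    theta: np.ndarray
    phase: np.ndarray
    lambda_map: float
    seed: int
    period: float

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if self.theta.shape != self.phase.shape or self.theta.ndim != 2:
            raise ValueError("theta and phase must be equal-shape 2-D arrays")
        if np.any(self.theta < 0) or np.any(self.theta >= self.period + 1e-12):
            raise ValueError("theta outside [0, period)")

    @property
    def dims(self) -> tuple[int, int]:
        return self.theta.shape

    def theta_flat(self) -> np.ndarray:
        """Preferences as a flat vector (row-major, matching grid indexing)."""
        return self.theta.ravel()

    def phase_flat(self) -> np.ndarray:
        return self.phase.ravel()

    def save_text(self, path_prefix: str | Path) -> None:
        """Save theta/phase as delimited text grids plus a metadata sidecar."""
        prefix = Path(path_prefix)
        np.savetxt(f"{prefix}_theta.txt", self.theta, fmt="%.6f")
        np.savetxt(f"{prefix}_phase.txt", self.phase, fmt="%.6f")
        with open(f"{prefix}_meta.txt", "w") as fh:
            fh.write(f"lambda_map: {self.lambda_map}\n")
            fh.write(f"seed: {self.seed}\n")
            fh.write(f"period: {self.period}\n")


def _complex_wave_field(
    shape: tuple[int, int],
    lambda_map: float,
    n_waves: int,
    rng: np.random.Generator,
    mirror_offset: float | None = None,
) -> np.ndarray:
    """Superpose random plane waves on the centered grid.

    With ``mirror_offset`` set, every wave (kx, ky, phi) is paired with the
    partner (kx, -ky, mirror_offset - phi), which makes the summed field S
    satisfy ``S(-x, y) = exp(i*mirror_offset) * conj(S(x, y))`` — i.e. the
    derived angle map is even-symmetric about the vertical midline.
    """
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
    xx -= (cols - 1) / 2.0
    yy -= (rows - 1) / 2.0
    k = 2.0 * math.pi / lambda_map
    n_draw = n_waves if mirror_offset is None else (n_waves + 1) // 2
    angles = rng.uniform(0.0, 2.0 * math.pi, n_draw)
    phases = rng.uniform(0.0, 2.0 * math.pi, n_draw)
    z = np.zeros(shape, dtype=complex)
    for a, p in zip(angles, phases):
        kx, ky = k * math.cos(a), k * math.sin(a)
        z += np.exp(1j * (kx * xx + ky * yy + p))
        if mirror_offset is not None:
            # reflection partner: x -> -x maps this wave onto the first one
            z += np.exp(1j * (kx * xx - ky * yy + (mirror_offset - p)))
    return z


def generate_map(
    dims: tuple[int, int] = (20, 20),
    lambda_map: float = 10.0,
    n_waves: int = 30,
    seed: int = 0,
    period: float = math.pi,
    mirror_symmetric: bool = False,
) -> OrientationMap:
    """Generate a pinwheel preference map by plane-wave superposition.

    The preferred angle is ``arg(z) * period / (2*pi) mod period`` of the
    superposed complex field z, so the doubled-angle field ``exp(i*2*theta)``
    (orientation maps) has spatial power concentrated at wavenumber
    ``2*pi/lambda_map``.  The phase map comes from a second independent
    realization.  Identical seed and parameters give a bit-identical map.

    With ``mirror_symmetric`` the realization is constrained to be even about
    the vertical midline of the grid: preferences at (-x, y) are the exact
    reflections (theta -> pi - theta on the angle circle, phase -> -phase) of
    those at (x, y).  A mirror-symmetric preference structure makes the left and right
    halves of downstream template populations statistically identical, which
    removes any built-in bias between the two decision alternatives.
    """
    if lambda_map <= 0:
        raise ValueError("lambda_map must be positive")
    rng = np.random.default_rng(seed)
    theta_offset = (math.pi if period > math.pi else 0.0) if mirror_symmetric else None
    phase_offset = 0.0 if mirror_symmetric else None
    z_theta = _complex_wave_field(dims, lambda_map, n_waves, rng, theta_offset)
    z_phase = _complex_wave_field(dims, lambda_map, n_waves, rng, phase_offset)
    theta = (np.angle(z_theta) % (2.0 * math.pi)) * (period / (2.0 * math.pi))
    phase = np.angle(z_phase) % (2.0 * math.pi)
    return OrientationMap(theta, phase, lambda_map, seed, period)


@dataclass
class GaborRF:
    """A Gabor receptive field in grid-unit coordinates.

    ``orientation`` is the bar orientation (radians); the cosine carrier of
    spatial frequency ``freq`` (cycles per grid unit) modulates perpendicular
    to it.  ``sigma_x`` elongates the envelope along the bar, ``sigma_y``
    across it.
    """

    center: tuple[float, float]
    orientation: float
    phase: float
    sigma_x: float
    sigma_y: float
    freq: float

    def __post_init__(self) -> None:
        if self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ValueError("sigmas must be positive")
        if self.freq < 0:
            raise ValueError("freq must be non-negative")


def gabor(rf: GaborRF, x, y):
    """Evaluate the Gabor field at position(s) (x, y) in grid units."""
    dx = np.asarray(x, dtype=float) - rf.center[0]
    dy = np.asarray(y, dtype=float) - rf.center[1]
    c, s = math.cos(rf.orientation), math.sin(rf.orientation)
    along = dx * c + dy * s
    across = -dx * s + dy * c
    envelope = np.exp(
        -(along**2 / (2.0 * rf.sigma_x**2) + across**2 / (2.0 * rf.sigma_y**2))
    )
    return envelope * np.cos(2.0 * math.pi * rf.freq * across + rf.phase)


def _common_raster(rfs, step: float):
    cx = [rf.center[0] for rf in rfs]
    cy = [rf.center[1] for rf in rfs]
    reach = 3.0 * max(max(rf.sigma_x, rf.sigma_y) for rf in rfs)
    xs = np.arange(min(cx) - reach, max(cx) + reach + step, step)
    ys = np.arange(min(cy) - reach, max(cy) + reach + step, step)
    return np.meshgrid(xs, ys)


def gabor_correlation(rf_a: GaborRF, rf_b: GaborRF, step: float = 0.2) -> float:
    """Normalized inner product of two Gabor fields on a common raster.

    Symmetric in its arguments, equals 1 for identical RFs, and lies in
    [-1, 1]; decays with center separation, orientation and phase mismatch.
    """
    xx, yy = _common_raster((rf_a, rf_b), step)
    fa = gabor(rf_a, xx, yy).ravel()
    fb = gabor(rf_b, xx, yy).ravel()
    na, nb = np.linalg.norm(fa), np.linalg.norm(fb)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.clip(fa @ fb / (na * nb), -1.0, 1.0))


def gabor_field_matrix(
    rfs, extent: tuple[float, float, float, float], step: float = 0.5
) -> np.ndarray:
    """Evaluate many Gabor RFs on one shared raster; rows are unit-normalized
    flattened fields.  ``extent`` is (x0, x1, y0, y1) in grid units.

    The pairwise products of the returned rows are the gabor correlations on
    that raster; evaluating all cells on one raster makes building the full
    lateral-connection matrix a single matrix product.
    """
    x0, x1, y0, y1 = extent
    xs = np.arange(x0, x1 + step, step)
    ys = np.arange(y0, y1 + step, step)
    xx, yy = np.meshgrid(xs, ys)
    out = np.empty((len(rfs), xx.size))
    for i, rf in enumerate(rfs):
        f = gabor(rf, xx, yy).ravel()
        n = np.linalg.norm(f)
        out[i] = f / n if n > 0 else f
    return out
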