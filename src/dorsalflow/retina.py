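"""Retinal ganglion cell stage: spatiotemporal filtering of luminance frames.

A 20 x 20 grid of RGCs covers the stimulus image.  Each cell applies a
center-surround difference-of-Gaussians (DOG) spatial filter

    w(dx, dy) = a_c exp(-(dx^2+dy^2)/sigma_c^2)/sigma_c^2
              - a_s exp(-(dx^2+dy^2)/sigma_s^2)/sigma_s^2

(distances in grid units) followed by a biphasic temporal kernel formed as the
difference of two Gamma densities.  The ON channel uses the kernel as written;
the OFF channel uses its sign inversion (off-center/on-surround).  The filter
output, scaled by ``gain``, is the continuous current (pA) injected one-to-one
into the corresponding LGN relay cells and interneurons.

The spatial stage is evaluated as a Gaussian convolution on a block-averaged
pixel raster: the printed DOG with its 1/sigma^2 prefactors equals
pi * (a_c N(sigma_c/sqrt(2)) - a_s N(sigma_s/sqrt(2))) with N a normalized
Gaussian, so two `scipy.ndimage` blurs reproduce the pixel sum exactly up to
the block-averaging resolution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from scipy.stats import gamma as gamma_dist

from .stimuli import FrameSequence

__all__ = [
    "RGCParams",
    "CurrentTrace",
    "spatial_dog",
    "temporal_kernel",
    "filter_frames",
    "grid_positions_px",
]

GRID: int = 20  # cells per side of the retinotopic grid


@dataclass
class RGCParams:
    """Parameters of the RGC spatiotemporal filter.

    Spatial widths are in grid units (the 20 x 20 grid spans the image, so one
    grid unit is image_width/20 pixels).  The temporal kernel is
    ``g1 * Gamma(k1, tau1) - g2 * Gamma(k2, tau2)`` (Gamma pdfs of time in ms)
    truncated to ``t_support`` ms, and must be biphasic (exactly one sign
    change on its support).
    """

    a_c: float = 1.0
    a_s: float = 0.9
    sigma_c: float = 0.8
    sigma_s: float = 2.4
    k1: float = 2.0
    k2: float = 2.0
    tau1: float = 24.0
    tau2: float = 48.0
    g1: float = 1.0
    g2: float = 0.7
    t_support: float = 250.0
    gain: float = 10000.0  # pA per unit filter response
    downsample: int = 5  # pixel block size for the spatial stage

    def __post_init__(self) -> None:
        if self.sigma_c <= 0 or self.sigma_s <= 0:
            raise ValueError("sigma_c and sigma_s must be positive")
        if self.sigma_s <= self.sigma_c:
            raise ValueError("surround width sigma_s must exceed center width sigma_c")
        if min(self.tau1, self.tau2) <= 0 or min(self.k1, self.k2) <= 0:
            raise ValueError("Gamma shape and scale parameters must be positive")
        if self.t_support <= 0:
            raise ValueError("t_support must be positive")
        self._check_biphasic()

    def _check_biphasic(self) -> None:
        t = np.linspace(0.0, self.t_support, 2000)
        v = temporal_kernel(self, t)
        signs = np.sign(v[np.abs(v) > 1e-12 * max(np.abs(v).max(), 1e-30)])
        changes = int(np.sum(signs[1:] != signs[:-1])) if signs.size else 0
        if self.g2 != 0 and changes != 1:
            raise ValueError(
                "temporal kernel is not biphasic (expected exactly one sign change); "
                f"found {changes}"
            )


def spatial_dog(params: RGCParams, dx, dy):
    """Difference-of-Gaussians weight at offset (dx, dy) in grid units.

    Includes the 1/sigma^2 prefactors, so the integral of the kernel over the
    plane is pi * (a_c - a_s).
    """
    r2 = np.asarray(dx, dtype=float) ** 2 + np.asarray(dy, dtype=float) ** 2
    return (
        params.a_c * np.exp(-r2 / params.sigma_c**2) / params.sigma_c**2
        - params.a_s * np.exp(-r2 / params.sigma_s**2) / params.sigma_s**2
    )


def temporal_kernel(params: RGCParams, t):
    """Biphasic temporal impulse response at time(s) `t` ms (zero outside
    [0, t_support])."""
    t = np.asarray(t, dtype=float)
    v = params.g1 * gamma_dist.pdf(t, params.k1, scale=params.tau1) - (
        params.g2 * gamma_dist.pdf(t, params.k2, scale=params.tau2)
    )
    return np.where((t >= 0) & (t <= params.t_support), v, 0.0)


@dataclass
class CurrentTrace:
    """Piecewise-constant injected current for one neuron.

    ``current[k]`` holds over ``[times[k], times[k] + dt)`` with the uniform
    simulation step dt implied by the time grid.
    """

    neuron: int
    times: np.ndarray  # ms
    current: np.ndarray  # pA

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.times.shape != self.current.shape:
            raise ValueError("times and current must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.current)):
            raise ValueError("current contains non-finite values")


def grid_positions_px(size_px: tuple[int, int], grid: int = GRID) -> np.ndarray:
    """Pixel-center positions (x, y) of the `grid` x `grid` cells spanning the
    image with equal spacing.  Returned shape (grid*grid, 2), row-major with x
    varying fastest."""
    h, w = size_px
    sx, sy = w / grid, h / grid
    xs = (np.arange(grid) + 0.5) * sx
    ys = (np.arange(grid) + 0.5) * sy
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


def _spatial_responses(frames: FrameSequence, params: RGCParams) -> np.ndarray:
    """DOG response of every grid cell to every frame, shape (n_frames, grid^2).

    The response is the sum over pixels of DOG(offset in grid units) * I(pixel)
    * dA, with dA the pixel area in grid units squared, approximated on a
    block-averaged raster.
    """
    n_frames, h, w = frames.frames.shape
    ds = params.downsample
    if h % ds or w % ds:
        raise ValueError(f"image size {h}x{w} not divisible by downsample={ds}")
    hd, wd = h // ds, w // ds
    # block-average (luminance mean per ds x ds block)
    blocks = frames.frames.reshape(n_frames, hd, ds, wd, ds).mean(axis=(2, 4))

    unit_px = w / GRID  # grid unit in original pixels
    # sigma in block pixels; exponent exp(-r^2/sigma^2) = Gaussian with std sigma/sqrt(2)
    sc = params.sigma_c * unit_px / ds / math.sqrt(2.0)
    ss = params.sigma_s * unit_px / ds / math.sqrt(2.0)
    out = np.empty((n_frames, GRID * GRID), dtype=np.float32)
    # sample the blurred field at the exact grid centers (block coordinates;
    # block b has its center at b + 0.5) with bilinear interpolation, which
    # keeps the sampling exactly mirror-symmetric
    pos = grid_positions_px((h, w)) / ds - 0.5
    coords = np.vstack([pos[:, 1], pos[:, 0]])
    for f in range(n_frames):
        img = blocks[f]
        resp = math.pi * (
            params.a_c * ndimage.gaussian_filter(img, sc, mode="constant")
            - params.a_s * ndimage.gaussian_filter(img, ss, mode="constant")
        )
        out[f] = ndimage.map_coordinates(resp, coords, order=1, mode="nearest")
    return out


def filter_frames(
    frames: FrameSequence,
    params: RGCParams,
    polarity: str = "ON",
    dt: float = 0.1,
) -> np.ndarray:
    """Spatiotemporally filter a frame sequence into injected currents.

    Returns an ``(n_steps, 400)`` float32 array of currents (pA) sampled at
    the simulation step ``dt``; column k is the current of grid cell k.  The
    OFF polarity is the sign inversion of the ON response.  Frames shorter
    than the temporal support produce a warning (the missing history is
    treated as zero luminance).
    """
    if polarity not in ("ON", "OFF"):
        raise ValueError("polarity must be 'ON' or 'OFF'")
    if frames.duration < params.t_support:
        warnings.warn(
            "stimulus shorter than the temporal filter support; "
            "history is zero-padded",
            stacklevel=2,
        )
    spatial = _spatial_responses(frames, params)  # (n_frames, 400)
    n_steps = int(round(frames.duration / dt))
    frame_of_step = np.minimum(
        (np.arange(n_steps) * dt / frames.frame_interval).astype(int),
        frames.n_frames - 1,
    )
    dense = spatial[frame_of_step]  # (n_steps, 400), piecewise-constant
    kt = temporal_kernel(params, np.arange(0.0, params.t_support, dt)) * dt
    filtered = signal.fftconvolve(dense, kt[:, None].astype(np.float32), axes=0)[
        :n_steps
    ]
    sign = 1.0 if polarity == "ON" else -1.0
    return (sign * params.gain * filtered).astype(np.float32)


def traces_from_array(currents: np.ndarray, dt: float) -> list[CurrentTrace]:
    """Wrap an (n_steps, n_cells) current array as per-neuron CurrentTraces."""
    times = np.arange(currents.shape[0]) * dt
    return [CurrentTrace(i, times, currents[:, i]) for i in range(currents.shape[1])]
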