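"""Synthetic visual stimuli: drifting-bar fields and random-dot flow kinematograms.

Two stimulus classes are produced, both as :class:`FrameSequence` luminance
stacks that the retinal stage consumes directly:

* two-region bar fields (:func:`make_bar_stimulus`) — each region contains a
  periodic pattern of dashed bars drifting parallel to the bar orientation;
  used to probe orientation (V1) and motion-direction (MT) selectivity.
* radial dot-flow fields (:func:`make_dot_stimulus`) — a 50-dot kinematogram
  whose expansion center is displaced left or right of the screen center,
  emulating the retinal flow of forward self-motion with a heading offset.

Coordinate conventions: pixel positions are (x, y) with x along columns and y
along rows; angles are measured from the +x axis, counterclockwise positive.
Frame arrays are indexed ``[frame, y, x]``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "PX_PER_DEGREE",
    "DISPLACEMENTS_PX",
    "FrameSequence",
    "DotField",
    "BarRegion",
    "BarStimulusSpec",
    "RegionOverlapError",
    "make_bar_stimulus",
    "fig_style_bar_spec",
    "init_dot_field",
    "step_dots",
    "render_dots",
    "make_dot_stimulus",
]

#: Fixed angular scale of the display: 30 px per degree of visual arc, so the
#: displacement range 20-140 px corresponds to 0.67-4.67 deg.
PX_PER_DEGREE: float = 30.0

#: The seven expansion-center displacement magnitudes (px) used in the heading
#: discrimination experiment.
DISPLACEMENTS_PX: tuple[int, ...] = (20, 40, 60, 80, 100, 120, 140)

#: Default screen geometry and dot kinematics (free parameters of the
#: generator; see docs/methods.md for the rationale).
SCREEN_PX: int = 600
DOT_RADIUS_PX: float = 8.0
DOT_SPEED_PX_S: float = 600.0
DOT_LIFETIME_MS: float = 100.0
FRAME_INTERVAL_MS: float = 100.0 / 3.0
N_DOTS: int = 50
N_RADIAL: int = 36


class RegionOverlapError(ValueError):
    """Raised when two bar-stimulus regions claim the same pixels."""


# ---------------------------------------------------------------------------
# FrameSequence
# ---------------------------------------------------------------------------


@dataclass
class FrameSequence:
    """A time-ordered stack of grayscale luminance frames.

    Attributes
    ----------
    frames:
        ``(n_frames, height_px, width_px)`` float array with values in [0, 1].
    frame_interval:
        Time between successive frames, ms.
    px_per_degree:
        Angular scale of the display.
    metadata:
        Free-form key/value block (condition labels, ground truth, seeds).
    """

    frames: np.ndarray
    frame_interval: float
    px_per_degree: float = PX_PER_DEGREE
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_frames, height, width)")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.px_per_degree <= 0:
            raise ValueError("px_per_degree must be positive")
        lo, hi = float(self.frames.min(initial=0.0)), float(self.frames.max(initial=0.0))
        if lo < -1e-6 or hi > 1.0 + 1e-6:
            raise ValueError(f"luminance values outside [0, 1]: [{lo}, {hi}]")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        """Total stimulus duration, ms."""
        return self.n_frames * self.frame_interval

    @property
    def size_px(self) -> tuple[int, int]:
        """(height, width) in pixels."""
        return self.frames.shape[1], self.frames.shape[2]

    def save_png(self, directory: str | Path, prefix: str = "frame") -> None:
        """Export frames as numbered grayscale PNGs plus a metadata sidecar."""
        from PIL import Image

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(self.frames):
            img = Image.fromarray((frame * 255).astype(np.uint8), mode="L")
            img.save(directory / f"{prefix}_{i:04d}.png")
        with open(directory / f"{prefix}_metadata.txt", "w") as fh:
            fh.write(f"n_frames: {self.n_frames}\n")
            fh.write(f"frame_interval_ms: {self.frame_interval}\n")
            fh.write(f"px_per_degree: {self.px_per_degree}\n")
            for key, value in self.metadata.items():
                fh.write(f"{key}: {value}\n")


# ---------------------------------------------------------------------------
# Bar stimuli
# ---------------------------------------------------------------------------


@dataclass
class BarRegion:
    """One region of a bar stimulus.

    ``polygon`` is an (N, 2) vertex list in pixel coordinates.  ``orientation``
    is the bar orientation in radians; the pattern drifts parallel to the bars
    with signed ``speed`` (px/s): positive speed moves along ``orientation``,
    negative along ``orientation + pi``.  Bars are dashed (finite segments of
    length ``dash_duty * dash_period`` along the bar) so that motion parallel
    to the bar orientation is visible in the luminance signal.
    """

    polygon: np.ndarray
    orientation: float
    spacing: float
    width: float
    speed: float
    dash_period: float | None = None
    dash_duty: float = 0.5

    def __post_init__(self) -> None:
        self.polygon = np.asarray(self.polygon, dtype=float)
        if self.polygon.ndim != 2 or self.polygon.shape[1] != 2 or len(self.polygon) < 3:
            raise ValueError("polygon must be an (N>=3, 2) vertex array")
        if self.spacing <= 0 or self.width <= 0 or self.width > self.spacing:
            raise ValueError("need 0 < width <= spacing")
        if self.dash_period is None:
            self.dash_period = 2.0 * self.spacing

    @property
    def direction(self) -> float:
        """Motion direction in radians, parallel to the bar orientation."""
        d = self.orientation if self.speed >= 0 else self.orientation + math.pi
        return d % (2.0 * math.pi)

    def mask(self, size_px: tuple[int, int]) -> np.ndarray:
        from matplotlib.path import Path as MplPath

        h, w = size_px
        yy, xx = np.mgrid[0:h, 0:w]
        pts = np.column_stack([xx.ravel() + 0.5, yy.ravel() + 0.5])
        inside = MplPath(self.polygon).contains_points(pts)
        return inside.reshape(h, w)


@dataclass
class BarStimulusSpec:
    """A multi-region bar stimulus: disjoint regions, each with its own
    drifting bar pattern, all moving with (typically) equal speed."""

    regions: list[BarRegion]
    duration: float = 600.0

    def __post_init__(self) -> None:
        if not self.regions:
            raise ValueError("at least one region required")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


def _circular_mean(angles: np.ndarray, weights: np.ndarray, period: float) -> float:
    """Weighted circular mean of `angles` with the given period (pi or 2*pi)."""
    wrap = 2.0 * math.pi / period
    s = float(np.sum(weights * np.sin(wrap * angles)))
    c = float(np.sum(weights * np.cos(wrap * angles)))
    return (math.atan2(s, c) / wrap) % period


def make_bar_stimulus(
    spec: BarStimulusSpec,
    size_px: tuple[int, int] = (SCREEN_PX, SCREEN_PX),
    frame_interval: float = FRAME_INTERVAL_MS,
) -> FrameSequence:
    """Render a multi-region drifting-bar stimulus.

    Each region shows a periodic pattern of dashed bright bars on a dark
    background, translating parallel to its bar orientation at the region's
    speed.  Region masks must be pixel-disjoint.

    Metadata records per-region orientation/direction/area and the
    area-weighted circular mean orientation (period pi) and motion direction
    (period 2*pi) of the whole stimulus.
    """
    h, w = size_px
    masks = [r.mask((h, w)) for r in spec.regions]
    claimed = np.zeros((h, w), dtype=np.int32)
    for m in masks:
        claimed += m
    if np.any(claimed > 1):
        raise RegionOverlapError("bar stimulus regions overlap")
    for r in spec.regions:
        if min(h, w) < 2 * r.spacing:
            raise ValueError("size_px must be at least twice the bar spacing")

    n_frames = math.ceil(spec.duration / frame_interval)
    frames = np.zeros((n_frames, h, w), dtype=np.float32)
    yy, xx = np.mgrid[0:h, 0:w]
    xc = xx + 0.5
    yc = yy + 0.5
    for region, mask in zip(spec.regions, masks):
        theta = region.orientation
        along = xc * math.cos(theta) + yc * math.sin(theta)
        across = -xc * math.sin(theta) + yc * math.cos(theta)
        bars = (across % region.spacing) < region.width
        for f in range(n_frames):
            t_s = f * frame_interval / 1000.0
            dash = ((along - region.speed * t_s) % region.dash_period) < (
                region.dash_duty * region.dash_period
            )
            frames[f][mask & bars & dash] = 1.0

    areas = np.array([m.sum() for m in masks], dtype=float)
    orientations = np.array([r.orientation % math.pi for r in spec.regions])
    directions = np.array([r.direction for r in spec.regions])
    metadata = {
        "stimulus": "bars",
        "region_orientation_deg": [round(math.degrees(o), 3) for o in orientations],
        "region_direction_deg": [round(math.degrees(d), 3) for d in directions],
        "region_area_px": [int(a) for a in areas],
        "mean_orientation_deg": math.degrees(
            _circular_mean(orientations, areas, math.pi)
        ),
        "mean_direction_deg": math.degrees(
            _circular_mean(directions, areas, 2.0 * math.pi)
        ),
    }
    return FrameSequence(frames, frame_interval, PX_PER_DEGREE, metadata)


def fig_style_bar_spec(
    size_px: tuple[int, int] = (SCREEN_PX, SCREEN_PX),
    duration: float = 600.0,
    speed: float = 120.0,
) -> BarStimulusSpec:
    """The package's standard two-region orientation/direction test stimulus.

    A narrower left region contains near-horizontal bars (10 deg, slightly
    off-axis so the bars do not alias against the retinotopic grid) drifting
    down-left along their orientation; the wider right region contains
    diagonal bars at 64.9 deg drifting up-right.  The diagonal region border
    and the area split (32.3% / 67.7%) are chosen so that the area-weighted
    circular mean orientation is ~50.8 deg and the mean motion direction is
    ~93.3 deg, the values the decoding stages are expected to recover.  Bar
    spacing matches the model's V1 carrier period; the drift is slow enough
    that the sustained bar structure, not the moving dash edges, dominates
    the retinal response.
    """
    h, w = size_px
    # diagonal region border at ~51 deg (the stimulus mean orientation), as
    # in a two-region display separated by oblique lines; the border chord is
    # placed so the left region holds 32.3% of the area
    run_x = h / math.tan(math.radians(51.0))
    a = 0.3231 * w - run_x / 2.0
    border_lo, border_hi = (a, 0.0), (a + run_x, h)
    left = BarRegion(
        polygon=[(-w, 0), border_lo, border_hi, (-w, h)],
        orientation=math.radians(10.0),
        spacing=100.0,
        width=30.0,
        speed=-speed,
        dash_period=300.0,
        dash_duty=0.6,
    )
    right = BarRegion(
        polygon=[(border_lo[0] + 1.0, 0), (2 * w, 0), (2 * w, h), (border_hi[0] + 1.0, h)],
        orientation=math.radians(64.9),
        spacing=100.0,
        width=30.0,
        speed=speed,
        dash_period=300.0,
        dash_duty=0.6,
    )
    return BarStimulusSpec(regions=[left, right], duration=duration)


# ---------------------------------------------------------------------------
# Dot kinematograms
# ---------------------------------------------------------------------------


@dataclass
class DotField:
    """Mutable state of the random-dot flow kinematogram.

    50 dots total: the first ``n_radial`` (36) move radially away from the
    expansion center (pure expansion field), the remainder (14) move in fixed
    uniformly random directions.  Each dot lives for 100 ms and is then
    re-positioned uniformly at random.
    """

    positions: np.ndarray  # (n, 2) px
    directions: np.ndarray  # (n, 2) unit vectors
    ages: np.ndarray  # (n,) ms in [0, lifetime)
    is_radial: np.ndarray  # (n,) bool
    center: np.ndarray  # (2,) expansion-center px
    speed: float = DOT_SPEED_PX_S  # px/s
    lifetime: float = DOT_LIFETIME_MS  # ms
    size_px: tuple[int, int] = (SCREEN_PX, SCREEN_PX)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.directions = np.asarray(self.directions, dtype=float)
        self.ages = np.asarray(self.ages, dtype=float)
        self.is_radial = np.asarray(self.is_radial, dtype=bool)
        self.center = np.asarray(self.center, dtype=float)
        n = len(self.positions)
        if not (len(self.directions) == len(self.ages) == len(self.is_radial) == n):
            raise ValueError("inconsistent dot-field array lengths")
        if np.any(self.ages < 0) or np.any(self.ages >= self.lifetime):
            raise ValueError("ages must lie in [0, lifetime)")

    @property
    def n_dots(self) -> int:
        return len(self.positions)


def _radial_directions(positions: np.ndarray, center: np.ndarray) -> np.ndarray:
    """Unit vectors pointing away from `center` (pure expansion)."""
    delta = positions - center[None, :]
    norm = np.linalg.norm(delta, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return delta / norm


def init_dot_field(
    displacement_px: float,
    size_px: tuple[int, int] = (SCREEN_PX, SCREEN_PX),
    speed: float = DOT_SPEED_PX_S,
    seed: int | None = None,
    n_dots: int = N_DOTS,
    n_radial: int = N_RADIAL,
    lifetime: float = DOT_LIFETIME_MS,
    rng: np.random.Generator | None = None,
) -> DotField:
    """Create the initial dot field for a given signed center displacement.

    ``displacement_px < 0`` places the expansion center left of the screen
    center, ``> 0`` right.  Dots are placed uniformly over the screen; ages are
    staggered uniformly over [0, lifetime) so that with the default frame
    interval of lifetime/3 about one-third of the dots is renewed per frame.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    h, w = size_px
    center = np.array([w / 2.0 + displacement_px, h / 2.0])
    if not (0 <= center[0] < w):
        raise ValueError(
            f"displacement {displacement_px} px puts the expansion center off-screen"
        )
    positions = rng.uniform(low=(0, 0), high=(w, h), size=(n_dots, 2))
    directions = np.empty((n_dots, 2))
    is_radial = np.zeros(n_dots, dtype=bool)
    is_radial[:n_radial] = True
    directions[:n_radial] = _radial_directions(positions[:n_radial], center)
    angles = rng.uniform(0.0, 2.0 * math.pi, size=n_dots - n_radial)
    directions[n_radial:] = np.column_stack([np.cos(angles), np.sin(angles)])
    ages = rng.uniform(0.0, lifetime, size=n_dots)
    return DotField(
        positions, directions, ages, is_radial, center, speed, lifetime, (h, w)
    )


def step_dots(
    dots: DotField, dt_frame: float, rng: np.random.Generator
) -> DotField:
    """Advance the dot field by one frame of `dt_frame` ms.

    Dots translate along their directions at the field speed, age, and are
    renewed (re-positioned uniformly at random) once their age reaches the
    lifetime; a renewed random-class dot keeps its direction, while a renewed
    or off-screen radial dot has its direction recomputed radially from the
    expansion center so the 36-dot subfield stays a pure expansion field.
    Random-class dots that drift off-screen wrap toroidally.
    """
    if dt_frame < 0:
        raise ValueError("dt_frame must be non-negative")
    if dt_frame == 0:
        return replace(dots)
    h, w = dots.size_px
    positions = dots.positions + dots.directions * (dots.speed * dt_frame / 1000.0)
    directions = dots.directions.copy()
    ages = dots.ages + dt_frame

    renew = ages >= dots.lifetime
    n_renew = int(renew.sum())
    if n_renew:
        positions[renew] = rng.uniform(low=(0, 0), high=(w, h), size=(n_renew, 2))
        ages[renew] = ages[renew] % dots.lifetime

    off = (
        (positions[:, 0] < 0)
        | (positions[:, 0] >= w)
        | (positions[:, 1] < 0)
        | (positions[:, 1] >= h)
    )
    off_radial = off & dots.is_radial
    n_off = int(off_radial.sum())
    if n_off:
        positions[off_radial] = rng.uniform(low=(0, 0), high=(w, h), size=(n_off, 2))
    off_random = off & ~dots.is_radial
    positions[off_random, 0] %= w
    positions[off_random, 1] %= h

    redirect = dots.is_radial & (renew | off_radial)
    directions[redirect] = _radial_directions(positions[redirect], dots.center)
    return DotField(
        positions,
        directions,
        ages,
        dots.is_radial,
        dots.center,
        dots.speed,
        dots.lifetime,
        dots.size_px,
    )


def render_dots(
    trace: Sequence[DotField],
    size_px: tuple[int, int] = (SCREEN_PX, SCREEN_PX),
    dot_radius_px: float = DOT_RADIUS_PX,
    frame_interval: float = FRAME_INTERVAL_MS,
    metadata: dict | None = None,
) -> FrameSequence:
    """Render a sequence of dot fields as anti-aliased bright discs on black."""
    h, w = size_px
    frames = np.zeros((len(trace), h, w), dtype=np.float32)
    r = float(dot_radius_px)
    pad = int(math.ceil(r)) + 1
    for f, dots in enumerate(trace):
        frame = frames[f]
        for x, y in dots.positions:
            x0, y0 = int(math.floor(x)), int(math.floor(y))
            xs = slice(max(x0 - pad, 0), min(x0 + pad + 1, w))
            ys = slice(max(y0 - pad, 0), min(y0 + pad + 1, h))
            if xs.start >= xs.stop or ys.start >= ys.stop:
                continue
            yy, xx = np.mgrid[ys, xs]
            dist = np.hypot(xx + 0.5 - x, yy + 0.5 - y)
            disc = np.clip(r + 0.5 - dist, 0.0, 1.0)
            np.maximum(frame[ys, xs], disc, out=frame[ys, xs])
    meta = dict(metadata or {})
    return FrameSequence(frames, frame_interval, PX_PER_DEGREE, meta)


def make_dot_stimulus(
    displacement_px: float,
    duration: float = 600.0,
    size_px: tuple[int, int] = (SCREEN_PX, SCREEN_PX),
    speed: float = DOT_SPEED_PX_S,
    dot_radius_px: float = DOT_RADIUS_PX,
    frame_interval: float = FRAME_INTERVAL_MS,
    seed: int | None = None,
) -> FrameSequence:
    """Generate a full dot-flow stimulus for one heading condition.

    The expansion center sits at ``screen center + (displacement_px, 0)``;
    negative displacements are leftward headings.  Metadata records the true
    side, displacement (px and degrees), and the seed.
    """
    rng = np.random.default_rng(seed)
    dots = init_dot_field(
        displacement_px, size_px, speed, rng=rng
    )
    n_frames = math.ceil(duration / frame_interval)
    trace = []
    for _ in range(n_frames):
        trace.append(dots)
        dots = step_dots(dots, frame_interval, rng)
    side = "left" if displacement_px < 0 else ("right" if displacement_px > 0 else "center")
    metadata = {
        "stimulus": "dots",
        "displacement_px": float(displacement_px),
        "displacement_deg": float(displacement_px) / PX_PER_DEGREE,
        "side": side,
        "center_px": (size_px[1] / 2.0 + displacement_px, size_px[0] / 2.0),
        "n_dots": trace[0].n_dots,
        "n_radial": int(trace[0].is_radial.sum()),
        "dot_speed_px_s": speed,
        "dot_lifetime_ms": trace[0].lifetime,
        "seed": seed,
    }
    return render_dots(trace, size_px, dot_radius_px, frame_interval, metadata)
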