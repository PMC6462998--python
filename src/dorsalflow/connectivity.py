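"""Synapse-population builders for every projection of the pathway.

All builders are deterministic given the preference maps and parameters, and
return explicit :class:`ConnectionSet` synapse lists (pre id, post id, signed
weight, delay).  Layer geometry lives on a common retinotopic coordinate
system in *grid units*: the 20 x 20 excitatory grids occupy integer-spaced
positions centered on the visual field (x, y in [-9.5, 9.5]); the 10 x 10
inhibitory grids are dispersed among them at twice the spacing.

Weight rules implemented here:

* LGN -> V1: ON (OFF) afferents where the target's Gabor RF is positive
  (negative), weight proportional to |Gabor| above a cutoff; all excitatory.
* V1/MT lateral: excitatory weights from positive Gabor-field correlations;
  inhibitory weights strongest for RF phase differences near 180 deg
  (von-Mises weighting) with a Gaussian spatial envelope.
* V1 -> MT: ``w = k_c * w_cs(dx, dy) * cos(phi)`` for ``0 <= phi <= pi/2``
  and 0 otherwise, where phi is the unsigned angle between the two cells'
  preferences folded to [0, pi) and w_cs is a DOG of the retinotopic offset.
* MT -> MST: expansion/contraction templates — a binary direction gate T
  (the MT cell's preferred direction must point away from / toward the
  template's focal point within a tolerance) times ``exp(-d * r_focal^2)``
  times a Gaussian of the MT-MST offset.
* MST lateral: same-focal pairs excite, different-focal pairs inhibit
  (intra-layer); expansion<->contraction connections are all inhibitory.
* MST -> LIP: each LIP decision unit is excited by expansion cells whose
  focal point matches its decision side and inhibited by every other MST
  cell; the two LIP units inhibit each other.
* V1 -> TRN/IN -> LGN: retinotopically aligned feedback inhibition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .maps import GaborRF, OrientationMap, gabor, gabor_field_matrix

__all__ = [
    "ConnectionSet",
    "MstTemplateSpec",
    "grid_coords",
    "sample_map_at",
    "assign_focal_points",
    "build_lgn_v1",
    "build_v1_lateral",
    "build_v1_mt",
    "mst_template_weight",
    "build_mt_mst",
    "build_mst_lateral",
    "build_mst_lip",
    "build_feedback_inhibition",
]

DEFAULT_DELAY: float = 1.0  # ms, global synaptic delay
FOCAL_XS: tuple[float, float, float] = (-7.0, 0.0, 7.0)
PRUNE_FRAC: float = 1e-3  # drop |w| below this fraction of the projection max


@dataclass
class ConnectionSet:
    """An explicit weighted, delayed synapse list between two layers."""

    pre_layer: str
    post_layer: str
    pre: np.ndarray
    post: np.ndarray
    weight: np.ndarray
    delay: np.ndarray

    def __post_init__(self) -> None:
        self.pre = np.asarray(self.pre, dtype=np.int64)
        self.post = np.asarray(self.post, dtype=np.int64)
        self.weight = np.asarray(self.weight, dtype=float)
        self.delay = np.asarray(self.delay, dtype=float)
        n = len(self.pre)
        if not (len(self.post) == len(self.weight) == n):
            raise ValueError("pre/post/weight lengths differ")
        if self.delay.ndim == 0:
            self.delay = np.full(n, float(self.delay))
        if len(self.delay) != n:
            raise ValueError("delay length mismatch")

    @property
    def n_synapses(self) -> int:
        return len(self.pre)

    def to_dense(self, n_pre: int, n_post: int) -> np.ndarray:
        """Dense (n_post, n_pre) weight matrix (parallel synapses summed)."""
        w = np.zeros((n_post, n_pre))
        np.add.at(w, (self.post, self.pre), self.weight)
        return w

    def save_text(self, path: str | Path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.pre, self.post, self.weight, self.delay]),
            fmt=("%d", "%d", "%.6g", "%.3f"),
            delimiter="\t",
            header=f"{self.pre_layer} -> {self.post_layer}\npre\tpost\tweight\tdelay_ms",
        )


def _from_dense(
    pre_layer: str,
    post_layer: str,
    w: np.ndarray,
    delay: float = DEFAULT_DELAY,
    prune_frac: float = PRUNE_FRAC,
    no_self: bool = False,
) -> ConnectionSet:
    w = np.asarray(w, dtype=float)
    if no_self:
        w = w.copy()
        np.fill_diagonal(w, 0.0)
    wmax = np.abs(w).max() if w.size else 0.0
    post, pre = np.nonzero(np.abs(w) > prune_frac * wmax)
    return ConnectionSet(pre_layer, post_layer, pre, post, w[post, pre], np.full(len(pre), delay))


def grid_coords(n_side: int, spacing: float = 1.0) -> np.ndarray:
    """Centered (n_side^2, 2) grid positions in grid units, row-major
    (x varies fastest).  spacing=2 gives a 10x10 grid dispersed among a 20x20
    one."""
    offset = (n_side - 1) / 2.0
    idx = np.arange(n_side, dtype=float)
    gx, gy = np.meshgrid((idx - offset) * spacing, (idx - offset) * spacing)
    return np.column_stack([gx.ravel(), gy.ravel()])


def sample_map_at(omap: OrientationMap, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(theta, phase) of the map cells nearest to the given grid-unit
    positions (the map grid sits at integer-spaced centered coordinates)."""
    rows, cols = omap.dims
    col = np.clip(np.round(positions[:, 0] + (cols - 1) / 2.0).astype(int), 0, cols - 1)
    row = np.clip(np.round(positions[:, 1] + (rows - 1) / 2.0).astype(int), 0, rows - 1)
    return omap.theta[row, col], omap.phase[row, col]


def _fold_angle_diff(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Unsigned angle between two preferences folded to [0, pi).

    Each preference is first reduced to its orientation axis in [0, pi) (a
    direction and its reversal share an axis), then the unsigned difference
    is taken; the result lies in [0, pi) and is symmetric in its arguments
    and invariant under reversing either direction preference.
    """
    return np.abs((np.asarray(a) % math.pi) - (np.asarray(b) % math.pi))


def _circ_dist(a, b) -> np.ndarray:
    """Absolute circular distance on the full circle, in [0, pi]."""
    d = (np.asarray(a) - np.asarray(b)) % (2.0 * math.pi)
    return np.minimum(d, 2.0 * math.pi - d)


def _dog(r2: np.ndarray, a_c: float, a_s: float, sigma_c: float, sigma_s: float) -> np.ndarray:
    return (
        a_c * np.exp(-r2 / sigma_c**2) / sigma_c**2
        - a_s * np.exp(-r2 / sigma_s**2) / sigma_s**2
    )


# ---------------------------------------------------------------------------
# LGN -> V1
# ---------------------------------------------------------------------------


def make_gabor_rfs(
    positions: np.ndarray,
    theta: np.ndarray,
    phase: np.ndarray,
    sigma_x: float,
    sigma_y: float,
    freq: float,
) -> list[GaborRF]:
    return [
        GaborRF((p[0], p[1]), t, ph, sigma_x, sigma_y, freq)
        for p, t, ph in zip(positions, theta, phase)
    ]


def build_lgn_v1(
    v1_map: OrientationMap,
    v1_positions: np.ndarray,
    lgn_positions: np.ndarray,
    post_layer: str = "V1e",
    gain: float = 1.0,
    cutoff_frac: float = 0.1,
    sigma_x: float = 1.5,
    sigma_y: float = 0.75,
    freq: float = 0.3,
    pull_gain: float = 0.0,
    delay: float = DEFAULT_DELAY,
) -> tuple[ConnectionSet, ConnectionSet]:
    """Feedforward LGN->V1 wiring from the targets' Gabor receptive fields.

    Each V1 cell connects to ON LGN cells at grid positions where its Gabor
    field is positive and to OFF cells where it is negative, with weight
    ``gain * |gabor|`` for values above ``cutoff_frac * max|gabor|``.  Returns
    the (ON, OFF) connection sets; with the default ``pull_gain = 0`` all
    weights are non-negative (excitatory).

    A positive ``pull_gain`` adds the push-pull arrangement of the classic
    feedforward V1 models: each channel also *inhibits* the V1 cell over the
    anti-phase subregions (ON where the Gabor is negative, OFF where it is
    positive) with weight ``-pull_gain * |gabor|``.  The summed ON/OFF drive
    then approximates a signed Gabor filtering of the retinal signal, which
    is what gives simple cells their orientation and phase selectivity.
    """
    theta, phase = sample_map_at(v1_map, v1_positions)
    n_post, n_pre = len(v1_positions), len(lgn_positions)
    w_on = np.zeros((n_post, n_pre))
    w_off = np.zeros((n_post, n_pre))
    for j in range(n_post):
        rf = GaborRF(
            (v1_positions[j, 0], v1_positions[j, 1]),
            theta[j],
            phase[j],
            sigma_x,
            sigma_y,
            freq,
        )
        v = gabor(rf, lgn_positions[:, 0], lgn_positions[:, 1])
        cutoff = cutoff_frac * np.abs(v).max()
        pos_lobe, neg_lobe = v > cutoff, v < -cutoff
        w_on[j, pos_lobe] = gain * v[pos_lobe]
        w_off[j, neg_lobe] = gain * (-v[neg_lobe])
        if pull_gain > 0:
            w_on[j, neg_lobe] = pull_gain * v[neg_lobe]
            w_off[j, pos_lobe] = -pull_gain * v[pos_lobe]
    on = _from_dense("LGN_ON", post_layer, w_on, delay, prune_frac=0.0)
    off = _from_dense("LGN_OFF", post_layer, w_off, delay, prune_frac=0.0)
    return on, off


# ---------------------------------------------------------------------------
# V1 / MT lateral connectivity
# ---------------------------------------------------------------------------


def build_v1_lateral(
    omap: OrientationMap,
    exc_positions: np.ndarray,
    inh_positions: np.ndarray,
    layer_prefix: str = "V1",
    g_exc: float = 1.0,
    g_inh: float = 1.0,
    kappa_phase: float = 2.0,
    sigma_inh: float = 2.0,
    rf_sigma: float = 1.0,
    rf_freq: float = 0.3,
    raster_step: float = 0.5,
    delay: float = DEFAULT_DELAY,
) -> dict[tuple[str, str], ConnectionSet]:
    """Lateral connectivity within a cortical layer (V1 or MT).

    Excitatory cells connect with weight ``g_exc * max(corr, 0)`` where corr
    is the Gabor-field correlation of the pair (circular envelopes,
    ``rf_sigma = sigma_x = sigma_y``).  Inhibitory cells connect with weight
    ``-g_inh * vm(dphase) * exp(-dpos^2 / (2 sigma_inh^2))`` where the
    von-Mises factor ``vm`` peaks at phase differences of 180 deg.  The 4:1
    excitatory/inhibitory population ratio is fixed by the caller's position
    arrays (400 and 100 cells).
    """
    exc_name, inh_name = layer_prefix + "e", layer_prefix + "i"
    pos = np.vstack([exc_positions, inh_positions])
    theta, phase = sample_map_at(omap, pos)
    # direction maps (period 2*pi) fold onto the orientation axis
    rfs = make_gabor_rfs(pos, theta % math.pi, phase, rf_sigma, rf_sigma, rf_freq)
    g = gabor_field_matrix(rfs, extent=(-12, 12, -12, 12), step=raster_step)
    corr = np.clip(g @ g.T, -1.0, 1.0)

    n_e = len(exc_positions)
    n = len(pos)
    w_exc = g_exc * np.maximum(corr, 0.0)  # rows=post? symmetric; slice below

    dphase = phase[None, :] - phase[:, None]
    vm = np.exp(kappa_phase * (np.cos(dphase - math.pi) - 1.0))
    d2 = ((pos[None, :, :] - pos[:, None, :]) ** 2).sum(-1)
    w_inh = -g_inh * vm * np.exp(-d2 / (2.0 * sigma_inh**2))

    out: dict[tuple[str, str], ConnectionSet] = {}
    slices = {exc_name: slice(0, n_e), inh_name: slice(n_e, n)}
    for pre_name, pre_sl in slices.items():
        base = w_exc if pre_name == exc_name else w_inh
        for post_name, post_sl in slices.items():
            w = base[post_sl, pre_sl]
            out[(pre_name, post_name)] = _from_dense(
                pre_name, post_name, w, delay, no_self=(pre_name == post_name)
            )
    return out


# ---------------------------------------------------------------------------
# V1 -> MT
# ---------------------------------------------------------------------------


def build_v1_mt(
    v1_map: OrientationMap,
    mt_map: OrientationMap,
    v1_positions: np.ndarray,
    mt_positions: np.ndarray,
    post_layer: str = "MTe",
    k_c: float = 1.0,
    a_c: float = 1.0,
    a_s: float = 0.5,
    sigma_c: float = 2.0,
    sigma_s: float = 6.0,
    delay: float = DEFAULT_DELAY,
    prune_frac: float = PRUNE_FRAC,
    motion_delay_v: float | None = None,
    motion_delay_base: float = 100.0,
) -> ConnectionSet:
    """Feedforward V1->MT weights: ``k_c * w_cs(offset) * cos(phi)`` gated at
    ``phi = pi/2``, with phi the unsigned angle between the V1 orientation
    preference and the MT direction preference folded to [0, pi), and w_cs
    the printed DOG of the retinotopic offset.

    Delays: with the default ``motion_delay_v = None`` every synapse uses the
    uniform ``delay``.  Given a preferred speed ``motion_delay_v`` (grid
    units per second), delays are instead graded along each MT cell's
    preferred direction d:

        delay_ij = motion_delay_base - ((x_V1 - x_MT) . d) / motion_delay_v

    (clipped to [delay, 2*motion_delay_base]).  A feature moving along d
    then reaches the afferents in the order that makes their volleys arrive
    at the MT cell together, while anti-preferred motion disperses them —
    spatiotemporal coincidence detection that gives MT cells true direction
    selectivity with the weight equation untouched.
    """
    if k_c <= 0:
        raise ValueError("k_c must be positive")
    theta_v1, _ = sample_map_at(v1_map, v1_positions)
    theta_mt, _ = sample_map_at(mt_map, mt_positions)
    dx = mt_positions[:, 0:1] - v1_positions[None, :, 0]
    dy = mt_positions[:, 1:2] - v1_positions[None, :, 1]
    w_cs = _dog(dx**2 + dy**2, a_c, a_s, sigma_c, sigma_s)
    # An MT cell's orientation preference is orthogonal to its preferred
    # direction of motion (direction-selective cells respond to contours
    # crossing their RF), so a direction map value d corresponds to the
    # orientation axis d + pi/2 when compared against V1 orientations.
    ori_mt = theta_mt + math.pi / 2.0 if mt_map.period > math.pi else theta_mt
    phi = _fold_angle_diff(ori_mt[:, None], theta_v1[None, :])
    w = np.where(phi <= math.pi / 2.0, k_c * w_cs * np.cos(phi), 0.0)
    cs = _from_dense("V1e", post_layer, w, delay, prune_frac=prune_frac)
    if motion_delay_v is not None:
        if motion_delay_v <= 0:
            raise ValueError("motion_delay_v must be positive")
        d_mt = theta_mt[cs.post]
        s = (-dx[cs.post, cs.pre]) * np.cos(d_mt) + (-dy[cs.post, cs.pre]) * np.sin(
            d_mt
        )  # projection of (V1 - MT) offset on the preferred direction
        graded = motion_delay_base - s / motion_delay_v * 1000.0
        cs.delay = np.clip(graded, delay, 2.0 * motion_delay_base)
    return cs


# ---------------------------------------------------------------------------
# MT -> MST templates
# ---------------------------------------------------------------------------


@dataclass
class MstTemplateSpec:
    """An expansion/contraction connection template.

    ``focal`` is the template's focal point in MT grid units (y must be 0);
    ``width`` is the template concentration d in the radial factor
    ``exp(-d * r^2)``; ``tolerance`` is the half-width of the direction gate;
    ``sigma_I`` the MST on-center RF width; ``sigma_ts`` the similarity width
    of the lateral rules.
    """

    kind: str
    focal: tuple[float, float] = (0.0, 0.0)
    width: float = 0.005
    tolerance: float = math.pi / 4.0
    sigma_I: float = 6.0
    sigma_ts: float = 3.0

    def __post_init__(self) -> None:
        if self.kind not in ("expansion", "contraction"):
            raise ValueError("kind must be 'expansion' or 'contraction'")
        if self.focal[1] != 0.0:
            raise ValueError("focal points lie on the horizontal meridian (y = 0)")
        if self.width <= 0:
            raise ValueError("width d must be positive")


def mst_template_weight(
    spec: MstTemplateSpec,
    mt_pos: tuple[float, float],
    mt_dir: float,
    mst_pos: tuple[float, float],
) -> float:
    """Weight of one MT cell onto one MST cell under a template.

    ``delta = atan2(y_e - y_MT, x_e - x_MT)`` points from the MT cell toward
    the focal point; the gate passes MT cells whose preferred direction is
    within the tolerance of ``delta`` (contraction) or ``delta + pi``
    (expansion).  An MT cell exactly at the focal point has an undefined
    radial direction and weight 0.
    """
    dxf = spec.focal[0] - mt_pos[0]
    dyf = spec.focal[1] - mt_pos[1]
    r2f = dxf * dxf + dyf * dyf
    if r2f == 0.0:
        return 0.0
    delta = math.atan2(dyf, dxf)
    target = delta if spec.kind == "contraction" else delta + math.pi
    if _circ_dist(mt_dir, target) > spec.tolerance:
        return 0.0
    dxm = mt_pos[0] - mst_pos[0]
    dym = mt_pos[1] - mst_pos[1]
    return float(
        math.exp(-spec.width * r2f)
        * math.exp(-(dxm * dxm + dym * dym) / (2.0 * spec.sigma_I**2))
        / (2.0 * math.pi * spec.sigma_I**2)
    )


def assign_focal_points(
    positions: np.ndarray, focal_xs: tuple[float, ...] = FOCAL_XS
) -> np.ndarray:
    """Assign each MST cell the focal point of its horizontal third of the
    grid (left/center/right), returning the focal x per cell."""
    edges = [-10.0 / 3.0, 10.0 / 3.0]
    out = np.full(len(positions), focal_xs[1], dtype=float)
    out[positions[:, 0] < edges[0]] = focal_xs[0]
    out[positions[:, 0] > edges[1]] = focal_xs[2]
    return out


def build_mt_mst(
    mt_map: OrientationMap,
    mt_positions: np.ndarray,
    mst_positions: np.ndarray,
    focal_x: np.ndarray,
    kind: str,
    post_layer: str,
    gain: float = 1.0,
    width: float = 0.005,
    tolerance: float = math.pi / 4.0,
    sigma_I: float = 6.0,
    normalize: bool = False,
    delay: float = DEFAULT_DELAY,
) -> ConnectionSet:
    """All template-gated MT -> MST synapses for one MST layer (vectorized
    evaluation of :func:`mst_template_weight` over all pairs).

    With ``normalize`` each MST cell's afferent weight vector is rescaled to
    a common total (``gain``), so that the cell's drive measures how well the
    MT activity pattern matches its template rather than how many map cells
    happened to satisfy its direction gate; cells whose gate selects no MT
    cell stay disconnected.
    """
    theta_mt, _ = sample_map_at(mt_map, mt_positions)
    dxf = focal_x[:, None] - mt_positions[None, :, 0]
    dyf = 0.0 - mt_positions[None, :, 1]
    r2f = dxf**2 + dyf**2
    delta = np.arctan2(dyf, dxf)
    target = delta if kind == "contraction" else delta + math.pi
    gate = (_circ_dist(theta_mt[None, :], target) <= tolerance) & (r2f > 0)
    d2 = ((mst_positions[:, None, :] - mt_positions[None, :, :]) ** 2).sum(-1)
    w = (
        gate
        * np.exp(-width * r2f)
        * np.exp(-d2 / (2.0 * sigma_I**2))
        / (2.0 * math.pi * sigma_I**2)
    )
    if normalize:
        totals = w.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        w = w / totals
    return _from_dense("MTe", post_layer, gain * w, delay)


# ---------------------------------------------------------------------------
# MST lateral and MST -> LIP
# ---------------------------------------------------------------------------


def build_mst_lateral(
    mst_positions: np.ndarray,
    focal_e: np.ndarray,
    focal_c: np.ndarray,
    gain: float = 1.0,
    sigma_ts: float = 3.0,
    delay: float = DEFAULT_DELAY,
) -> dict[tuple[str, str], ConnectionSet]:
    """Recurrent connectivity of the two MST layers.

    Intra-layer pairs sharing a focal point get ``+exp(-dpos^2/(2 sigma_ts^2))``,
    pairs with different focal points the negated value.  Inter-layer
    (expansion<->contraction) weights are all inhibitory:
    ``-exp(-dpos^2/(2 sigma_ts^2)) * exp(-dfocal^2/(2 sigma_ts^2))``.
    """
    d2 = ((mst_positions[:, None, :] - mst_positions[None, :, :]) ** 2).sum(-1)
    prox = np.exp(-d2 / (2.0 * sigma_ts**2))
    out: dict[tuple[str, str], ConnectionSet] = {}
    for name, focal in (("MSTe", focal_e), ("MSTc", focal_c)):
        same = focal[:, None] == focal[None, :]
        w = gain * np.where(same.T, prox, -prox)
        out[(name, name)] = _from_dense(name, name, w, delay, no_self=True)
    for pre, post, f_pre, f_post in (
        ("MSTe", "MSTc", focal_e, focal_c),
        ("MSTc", "MSTe", focal_c, focal_e),
    ):
        dfocal2 = (f_post[:, None] - f_pre[None, :]) ** 2
        w = -gain * prox * np.exp(-dfocal2 / (2.0 * sigma_ts**2))
        out[(pre, post)] = _from_dense(pre, post, w, delay)
    return out


def build_mst_lip(
    focal_e: np.ndarray,
    focal_c: np.ndarray,
    g_exc: float = 1.0,
    g_inh: float = 0.3,
    g_mutual: float = 1.0,
    left_x: float = FOCAL_XS[0],
    right_x: float = FOCAL_XS[2],
    delay: float = DEFAULT_DELAY,
) -> dict[tuple[str, str], ConnectionSet]:
    """Decision readout wiring.

    LIP neuron 0 (left) receives ``+g_exc`` from expansion cells with the
    left focal point and ``-g_inh`` from every other MST cell (expansion with
    other focal points and all contraction cells); neuron 1 (right) is the
    mirror image.  The two LIP neurons inhibit each other with ``-g_mutual``.
    """
    out: dict[tuple[str, str], ConnectionSet] = {}
    for name, focal in (("MSTe", focal_e), ("MSTc", focal_c)):
        n = len(focal)
        w = np.full((2, n), -g_inh)
        if name == "MSTe":
            w[0, focal == left_x] = g_exc
            w[1, focal == right_x] = g_exc
        out[(name, "LIP")] = _from_dense(name, "LIP", w, delay, prune_frac=0.0)
    out[("LIP", "LIP")] = ConnectionSet(
        "LIP", "LIP", [0, 1], [1, 0], [-g_mutual, -g_mutual], delay
    )
    return out


# ---------------------------------------------------------------------------
# Thalamic feedback inhibition
# ---------------------------------------------------------------------------


def build_feedback_inhibition(
    v1_positions: np.ndarray,
    lgn_positions: np.ndarray,
    channels: tuple[str, ...] = ("ON", "OFF"),
    g_v1_trn: float = 1.0,
    g_v1_in: float = 1.0,
    g_trn_lgn: float = 1.0,
    g_in_lgn: float = 1.0,
    delay: float = DEFAULT_DELAY,
) -> dict[tuple[str, str], ConnectionSet]:
    """Inhibitory feedback loop V1 -> TRN/IN -> LGN.

    V1 excitatory cells excite the TRN and IN cells at the retinotopically
    matching grid node of each channel; TRN and IN cells inhibit the matching
    LGN relay cell one-to-one.  Zero gains yield empty sets.
    """
    if len(v1_positions) != len(lgn_positions):
        raise ValueError("feedback loop assumes aligned 20x20 grids")
    n = len(v1_positions)
    idx = np.arange(n)
    ones = np.ones(n)
    out: dict[tuple[str, str], ConnectionSet] = {}

    def one_to_one(pre, post, w):
        if w == 0.0:
            return ConnectionSet(pre, post, [], [], [], delay)
        return ConnectionSet(pre, post, idx, idx, w * ones, np.full(n, delay))

    for ch in channels:
        out[("V1e", f"TRN_{ch}")] = one_to_one("V1e", f"TRN_{ch}", g_v1_trn)
        out[("V1e", f"IN_{ch}")] = one_to_one("V1e", f"IN_{ch}", g_v1_in)
        out[(f"TRN_{ch}", f"LGN_{ch}")] = one_to_one(f"TRN_{ch}", f"LGN_{ch}", -g_trn_lgn)
        out[(f"IN_{ch}", f"LGN_{ch}")] = one_to_one(f"IN_{ch}", f"LGN_{ch}", -g_in_lgn)
    return out
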