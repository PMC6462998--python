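"""Full-pathway assembly and the fixed-step spiking simulation engine.

The network instantiates the layer stack of the dorsal-pathway model —
ON/OFF retinal filters feeding LGN relay cells (conductance-based neurons
with AHP), interneurons (IN) and reticular (TRN) cells per channel, V1 and MT
(400 excitatory on a 20 x 20 grid + 100 inhibitory on a dispersed 10 x 10
grid each), two 400-cell MST layers with expansion/contraction templates, and
a 2-neuron LIP decision stage with mutual inhibition — and wires every
projection with the builders in :mod:`dorsalflow.connectivity`.

The engine advances all neurons on a global fixed step (default dt = 0.1 ms)
with exact-exponential sub-threshold updates, a spike ring buffer implementing
the uniform synaptic delay, per-layer current injection from the retina stage,
and optional background Poisson noise to the cortical layers.  Given identical
seeds the simulation is reproducible bit-for-bit.
"""

from __future__ import annotations

import math
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import connectivity as conn
from . import readout as ro
from .maps import OrientationMap, generate_map
from .neurons import (
    LifCondAhpLayer,
    LifCondAhpParams,
    LifExpLayer,
    LifExpParams,
    SpikeData,
)
from .retina import GRID, RGCParams, filter_frames
from .stimuli import FrameSequence

__all__ = [
    "ProjectionGains",
    "NetworkConfig",
    "Network",
    "SimulationResult",
    "assemble",
    "run",
    "run_experiment",
]


class ConfigError(ValueError):
    """A NetworkConfig field violates a structural invariant."""


@dataclass
class ProjectionGains:
    """Free gain/shape parameters of every projection (weights in pA for
    current-based targets, nS for the conductance-based LGN)."""

    lgn_v1: float = 3000.0
    lgn_v1_pull: float = 1.0  # push-pull ratio: anti-phase inhibition / excitation
    lgn_v1_cutoff: float = 0.05
    v1_rf_sigma_x: float = 2.0
    v1_rf_sigma_y: float = 0.75
    v1_rf_freq: float = 0.3
    lat_g_exc: float = 10.0
    lat_g_inh: float = 300.0
    lat_kappa: float = 1.0
    lat_sigma_inh: float = 3.0
    lat_rf_sigma: float = 1.0
    lat_rf_freq: float = 0.3
    v1_mt_k_c: float = 1500.0
    v1_mt_a_c: float = 1.0
    v1_mt_a_s: float = 0.5
    v1_mt_sigma_c: float = 2.0
    v1_mt_sigma_s: float = 6.0
    # direction-graded V1->MT conduction delays (None disables the grading):
    # preferred speed in grid units/s and the mid-range delay in ms
    v1_mt_delay_v: float | None = 20.0
    v1_mt_delay_base: float = 100.0
    mt_mst: float = 12000.0
    mt_mst_normalize: bool = True
    mst_focal_x: float = 7.0
    mst_width: float = 0.005
    mst_tolerance: float = math.pi / 4.0
    mst_sigma_I: float = 6.0
    mst_sigma_ts: float = 3.0
    mst_lat: float = 2.0
    mst_lip_exc: float = 6.0
    mst_lip_inh: float = 0.05
    lip_mutual: float = 80.0
    fb_v1_trn: float = 30.0
    fb_v1_in: float = 30.0
    fb_trn_lgn: float = 1.0
    fb_in_lgn: float = 1.0


@dataclass
class NetworkConfig:
    """Layer sizes, neuron parameters, connectivity gains, and seeds."""

    grid: int = 20
    inh_grid: int = 10
    n_lip: int = 2
    dt: float = 0.1
    delay: float = 1.0
    lambda_map: float = 5.0
    n_waves: int = 80
    v1_map_seed: int = 11
    mt_map_seed: int = 21
    mirror_maps: bool = True
    noise_rate_hz: float = 1.0
    noise_weight: float = 30.0
    rgc: RGCParams = field(default_factory=RGCParams)
    lgn: LifCondAhpParams = field(default_factory=LifCondAhpParams)
    # cortical neurons integrate sparse afferent volleys: 10 ms PSCs
    lif: LifExpParams = field(
        default_factory=lambda: LifExpParams(tau_syn_ex=10.0, tau_syn_in=10.0)
    )
    lip_lif: LifExpParams = field(
        default_factory=lambda: LifExpParams(tau_syn_ex=40.0, tau_syn_in=40.0)
    )
    # MT operates as a coincidence detector on delay-aligned volleys: short
    # excitatory PSCs; None falls back to `lif`
    mt_lif: LifExpParams | None = field(
        default_factory=lambda: LifExpParams(tau_syn_ex=5.0, tau_syn_in=10.0)
    )
    gains: ProjectionGains = field(default_factory=ProjectionGains)

    def __post_init__(self) -> None:
        if self.grid != 20:
            raise ConfigError("grid: retinotopic layers must be 20 x 20 (400 neurons)")
        if self.inh_grid != 10:
            raise ConfigError("inh_grid: cortical inhibitory grids must be 10 x 10")
        if self.n_lip != 2:
            raise ConfigError("n_lip: LIP holds exactly two decision neurons")
        if not (0 < self.dt <= 0.5):
            raise ConfigError("dt: simulation step must be in (0, 0.5] ms")
        if self.delay < self.dt:
            raise ConfigError("delay: synaptic delay must be at least one step")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NetworkConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key, sub_cls in (
            ("rgc", RGCParams),
            ("lgn", LifCondAhpParams),
            ("lif", LifExpParams),
            ("lip_lif", LifExpParams),
            ("mt_lif", LifExpParams),
            ("gains", ProjectionGains),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub_cls(**raw[key])
        return cls(**raw)


@dataclass
class _Layer:
    name: str
    size: int
    model: str  # 'exp' | 'cond'
    params: object
    positions: np.ndarray
    offset: int = 0


class Network:
    """Assembled layers, preference maps, and connection sets."""

    def __init__(
        self,
        config: NetworkConfig,
        layers: dict[str, _Layer],
        connections: dict[tuple[str, str], conn.ConnectionSet],
        v1_map: OrientationMap,
        mt_map: OrientationMap,
        focal_e: np.ndarray,
        focal_c: np.ndarray,
    ):
        self.config = config
        self.layers = layers
        self.connections = connections
        self.v1_map = v1_map
        self.mt_map = mt_map
        self.focal_e = focal_e
        self.focal_c = focal_c
        self.n_neurons = sum(l.size for l in layers.values())

    def census(self) -> dict[str, pd.DataFrame]:
        """Neuron counts per layer and synapse counts per projection."""
        layers = pd.DataFrame(
            [
                {"layer": l.name, "n_neurons": l.size, "model": l.model}
                for l in self.layers.values()
            ]
        )
        projections = pd.DataFrame(
            [
                {"pre": pre, "post": post, "n_synapses": cs.n_synapses}
                for (pre, post), cs in self.connections.items()
            ]
        )
        return {"layers": layers, "projections": projections}

    def synapse_count(self, pre: str, post: str) -> int:
        cs = self.connections.get((pre, post))
        return cs.n_synapses if cs is not None else 0


def assemble(
    config: NetworkConfig,
    v1_map: OrientationMap | None = None,
    mt_map: OrientationMap | None = None,
) -> Network:
    """Build every layer and projection of the pathway.

    Optional pre-built maps override the seeded map generation (used e.g. for
    mirror-symmetry experiments); by default V1 and MT use independent map
    realizations (period pi orientation map for V1, period 2*pi direction map
    for MT).
    """
    g = config.gains
    grid_pos = conn.grid_coords(config.grid)  # 400 cells, integer spacing
    inh_pos = conn.grid_coords(config.inh_grid, spacing=2.0)  # 100 dispersed
    if v1_map is None:
        v1_map = generate_map(
            (config.grid, config.grid),
            config.lambda_map,
            config.n_waves,
            config.v1_map_seed,
            period=math.pi,
            mirror_symmetric=config.mirror_maps,
        )
    if mt_map is None:
        mt_map = generate_map(
            (config.grid, config.grid),
            config.lambda_map,
            config.n_waves,
            config.mt_map_seed,
            period=2.0 * math.pi,
            mirror_symmetric=config.mirror_maps,
        )

    layers: dict[str, _Layer] = {}

    def add(name, size, model, params, positions):
        layers[name] = _Layer(name, size, model, params, positions)

    n = config.grid**2
    for ch in ("ON", "OFF"):
        add(f"LGN_{ch}", n, "cond", config.lgn, grid_pos)
    for ch in ("ON", "OFF"):
        add(f"IN_{ch}", n, "exp", config.lif, grid_pos)
    for ch in ("ON", "OFF"):
        add(f"TRN_{ch}", n, "exp", config.lif, grid_pos)
    add("V1e", n, "exp", config.lif, grid_pos)
    add("V1i", config.inh_grid**2, "exp", config.lif, inh_pos)
    mt_params = config.mt_lif if config.mt_lif is not None else config.lif
    add("MTe", n, "exp", mt_params, grid_pos)
    add("MTi", config.inh_grid**2, "exp", mt_params, inh_pos)
    add("MSTe", n, "exp", config.lif, grid_pos)
    add("MSTc", n, "exp", config.lif, grid_pos)
    add("LIP", config.n_lip, "exp", config.lip_lif, np.zeros((config.n_lip, 2)))
    offset = 0
    for l in layers.values():
        l.offset = offset
        offset += l.size

    connections: dict[tuple[str, str], conn.ConnectionSet] = {}

    def put(cs_dict_or_pair):
        if isinstance(cs_dict_or_pair, dict):
            for key, cs in cs_dict_or_pair.items():
                connections[key] = cs
        else:
            cs = cs_dict_or_pair
            connections[(cs.pre_layer, cs.post_layer)] = cs

    # LGN -> V1 (both target populations, ON and OFF channels)
    for post, pos in (("V1e", grid_pos), ("V1i", inh_pos)):
        on, off = conn.build_lgn_v1(
            v1_map,
            pos,
            grid_pos,
            post_layer=post,
            gain=g.lgn_v1,
            pull_gain=g.lgn_v1 * g.lgn_v1_pull,
            cutoff_frac=g.lgn_v1_cutoff,
            sigma_x=g.v1_rf_sigma_x,
            sigma_y=g.v1_rf_sigma_y,
            freq=g.v1_rf_freq,
            delay=config.delay,
        )
        put(on)
        put(off)

    # lateral connectivity, same design in V1 and MT
    for prefix, omap in (("V1", v1_map), ("MT", mt_map)):
        put(
            conn.build_v1_lateral(
                omap,
                grid_pos,
                inh_pos,
                layer_prefix=prefix,
                g_exc=g.lat_g_exc,
                g_inh=g.lat_g_inh,
                kappa_phase=g.lat_kappa,
                sigma_inh=g.lat_sigma_inh,
                rf_sigma=g.lat_rf_sigma,
                rf_freq=g.lat_rf_freq,
                delay=config.delay,
            )
        )

    # V1 -> MT
    for post, pos in (("MTe", grid_pos), ("MTi", inh_pos)):
        put(
            conn.build_v1_mt(
                v1_map,
                mt_map,
                grid_pos,
                pos,
                post_layer=post,
                k_c=g.v1_mt_k_c,
                a_c=g.v1_mt_a_c,
                a_s=g.v1_mt_a_s,
                sigma_c=g.v1_mt_sigma_c,
                sigma_s=g.v1_mt_sigma_s,
                delay=config.delay,
                motion_delay_v=g.v1_mt_delay_v,
                motion_delay_base=g.v1_mt_delay_base,
            )
        )

    # MT -> MST templates
    focal_xs = (-g.mst_focal_x, 0.0, g.mst_focal_x)
    focal_e = conn.assign_focal_points(grid_pos, focal_xs)
    focal_c = conn.assign_focal_points(grid_pos, focal_xs)
    for kind, post, focal in (
        ("expansion", "MSTe", focal_e),
        ("contraction", "MSTc", focal_c),
    ):
        put(
            conn.build_mt_mst(
                mt_map,
                grid_pos,
                grid_pos,
                focal,
                kind,
                post,
                gain=g.mt_mst,
                width=g.mst_width,
                tolerance=g.mst_tolerance,
                sigma_I=g.mst_sigma_I,
                normalize=g.mt_mst_normalize,
                delay=config.delay,
            )
        )

    put(
        conn.build_mst_lateral(
            grid_pos, focal_e, focal_c, gain=g.mst_lat,
            sigma_ts=g.mst_sigma_ts, delay=config.delay,
        )
    )
    put(
        conn.build_mst_lip(
            focal_e, focal_c, g_exc=g.mst_lip_exc, g_inh=g.mst_lip_inh,
            g_mutual=g.lip_mutual, left_x=focal_xs[0], right_x=focal_xs[2],
            delay=config.delay,
        )
    )
    put(
        conn.build_feedback_inhibition(
            grid_pos,
            grid_pos,
            g_v1_trn=g.fb_v1_trn,
            g_v1_in=g.fb_v1_in,
            g_trn_lgn=g.fb_trn_lgn,
            g_in_lgn=g.fb_in_lgn,
            delay=config.delay,
        )
    )
    return Network(config, layers, connections, v1_map, mt_map, focal_e, focal_c)


@dataclass
class SimulationResult:
    """Per-layer spikes plus everything needed to reproduce the run."""

    spikes: dict[str, SpikeData]
    duration: float
    stimulus_metadata: dict
    config: NetworkConfig
    noise_seed: int | None
    wall_time_s: float

    def lip_decision(self, window: float = 200.0, step: float = 20.0) -> ro.DecisionTrace:
        times, left, right = ro.lip_rates(
            self.spikes["LIP"], self.duration, window, step
        )
        return ro.decide(times, left, right)

    def save_rasters(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, sd in self.spikes.items():
            sd.save_text(directory / f"spikes_{name}.txt")


class _SynapseRouting:
    """Precompiled synaptic routing: dense matrices for uniform-delay
    projections plus per-presynaptic scatter lists for projections with
    graded (per-synapse) delays."""

    def __init__(self, network: Network):
        n = network.n_neurons
        dt = network.config.dt
        dense: dict[int, np.ndarray] = {}
        het_pre: list[np.ndarray] = []
        het_post: list[np.ndarray] = []
        het_w: list[np.ndarray] = []
        het_d: list[np.ndarray] = []
        max_d = 1
        for (pre, post), cs in network.connections.items():
            if cs.n_synapses == 0:
                continue
            pre_l, post_l = network.layers[pre], network.layers[post]
            d_steps = np.maximum(np.round(cs.delay / dt).astype(np.int64), 1)
            max_d = max(max_d, int(d_steps.max()))
            uniq = np.unique(d_steps)
            if len(uniq) == 1:
                w = dense.setdefault(int(uniq[0]), np.zeros((n, n), dtype=np.float32))
                np.add.at(
                    w,
                    (post_l.offset + cs.post, pre_l.offset + cs.pre),
                    cs.weight.astype(np.float32),
                )
            else:
                het_pre.append(pre_l.offset + cs.pre)
                het_post.append(post_l.offset + cs.post)
                het_w.append(cs.weight)
                het_d.append(d_steps)
        self.dense = {
            d: (
                np.asfortranarray(np.where(w > 0, w, 0)),
                np.asfortranarray(np.where(w < 0, w, 0)),
            )
            for d, w in dense.items()
        }
        self.ring = max_d
        if het_pre:
            pre_all = np.concatenate(het_pre)
            post_all = np.concatenate(het_post)
            w_all = np.concatenate(het_w)
            d_all = np.concatenate(het_d)
            order = np.argsort(pre_all, kind="stable")
            pre_all, post_all = pre_all[order], post_all[order]
            w_all, d_all = w_all[order], d_all[order]
            self.het_ptr = np.searchsorted(pre_all, np.arange(n + 1))
            self.het_post = post_all
            self.het_w = w_all.astype(np.float64)
            self.het_d = d_all
        else:
            self.het_ptr = None

    def deliver(self, idx: np.ndarray, k: int, buf_ex: np.ndarray, buf_in: np.ndarray):
        """Queue the outgoing synapses of the neurons in `idx` (which spiked
        at step k) into the ring buffers."""
        ring = self.ring
        for d, (w_pos, w_neg) in self.dense.items():
            target = (k + d) % ring
            if idx.size == 1:
                buf_ex[target] += w_pos[:, idx[0]]
                buf_in[target] += w_neg[:, idx[0]]
            else:
                buf_ex[target] += w_pos[:, idx].sum(axis=1)
                buf_in[target] += w_neg[:, idx].sum(axis=1)
        if self.het_ptr is not None:
            n = buf_ex.shape[1]
            ex_flat = buf_ex.reshape(-1)
            in_flat = buf_in.reshape(-1)
            for j in idx:
                lo, hi = self.het_ptr[j], self.het_ptr[j + 1]
                if lo == hi:
                    continue
                w = self.het_w[lo:hi]
                flat = ((k + self.het_d[lo:hi]) % ring) * n + self.het_post[lo:hi]
                pos = w > 0
                np.add.at(ex_flat, flat[pos], w[pos])
                np.add.at(in_flat, flat[~pos], w[~pos])


def run(
    network: Network,
    stimulus: FrameSequence,
    duration: float | None = None,
    noise_seed: int | None = 0,
    record_layers: tuple[str, ...] | None = None,
) -> SimulationResult:
    """Simulate the full pathway on a stimulus.

    The retinal stage converts the frames into ON/OFF currents injected
    one-to-one into the LGN relay cells and interneurons; all other layers are
    driven synaptically.  ``duration`` defaults to the stimulus duration and
    may not exceed it.  ``record_layers`` restricts the returned SpikeData
    (all layers are still simulated).
    """
    config = network.config
    dt = config.dt
    if duration is None:
        duration = stimulus.duration
    if duration > stimulus.duration + 1e-9:
        raise ValueError("duration exceeds stimulus length")
    n_steps = int(round(duration / dt))
    t_start = time.perf_counter()

    on = filter_frames(stimulus, config.rgc, "ON", dt)[:n_steps]
    off = filter_frames(stimulus, config.rgc, "OFF", dt)[:n_steps]
    injections = {"LGN_ON": on, "IN_ON": on, "LGN_OFF": off, "IN_OFF": off}

    states: dict[str, object] = {}
    for l in network.layers.values():
        cls = LifCondAhpLayer if l.model == "cond" else LifExpLayer
        states[l.name] = cls(l.params, l.size, dt)

    routing = _SynapseRouting(network)
    n = network.n_neurons
    ring = routing.ring
    buf_ex = np.zeros((ring, n), dtype=np.float64)
    buf_in = np.zeros((ring, n), dtype=np.float64)

    rng = np.random.default_rng(noise_seed)
    noise_layers = ("V1e", "V1i", "MTe", "MTi", "MSTe", "MSTc", "LIP")
    noise_on = config.noise_rate_hz > 0 and config.noise_weight != 0
    if noise_on:
        noise_start = network.layers[noise_layers[0]].offset
        p_noise = config.noise_rate_hz * dt * 1e-3

    spike_ids: list[np.ndarray] = []
    spike_steps: list[np.ndarray] = []
    layer_list = list(network.layers.values())
    for k in range(n_steps):
        slot = k % ring
        d_ex, d_in = buf_ex[slot], buf_in[slot]
        if noise_on:
            kicks = rng.random(n - noise_start) < p_noise
            d_ex[noise_start:] += config.noise_weight * kicks
        spiked_this_step = []
        for l in layer_list:
            sl = slice(l.offset, l.offset + l.size)
            inj = injections.get(l.name)
            spiked = states[l.name].step(
                inj[k] if inj is not None else 0.0, d_ex[sl], d_in[sl]
            )
            if spiked.size:
                spiked_this_step.append(spiked + l.offset)
        d_ex[:] = 0.0
        d_in[:] = 0.0
        if spiked_this_step:
            idx = np.concatenate(spiked_this_step)
            spike_ids.append(idx)
            spike_steps.append(np.full(idx.size, k + 1, dtype=np.int64))
            routing.deliver(idx, k, buf_ex, buf_in)
        if k % 500 == 0:
            for l in layer_list:
                v = states[l.name].V
                if not np.all(np.isfinite(v)) or v.max() > 50.0:
                    raise RuntimeError(
                        f"numerical blow-up in layer {l.name}: "
                        f"V range [{v.min():.1f}, {v.max():.1f}] mV at t={k * dt:.1f} ms"
                    )

    all_ids = np.concatenate(spike_ids) if spike_ids else np.empty(0, dtype=np.int64)
    all_t = (
        np.concatenate(spike_steps) * dt if spike_steps else np.empty(0)
    )
    spikes: dict[str, SpikeData] = {}
    wanted = record_layers if record_layers is not None else tuple(network.layers)
    for l in layer_list:
        if l.name not in wanted:
            continue
        sel = (all_ids >= l.offset) & (all_ids < l.offset + l.size)
        spikes[l.name] = SpikeData(l.name, all_ids[sel] - l.offset, all_t[sel])
    return SimulationResult(
        spikes=spikes,
        duration=duration,
        stimulus_metadata=dict(stimulus.metadata),
        config=config,
        noise_seed=noise_seed,
        wall_time_s=time.perf_counter() - t_start,
    )


def trial_seeds(base_seed: int, condition: int, trial: int) -> tuple[int, int]:
    """Derive independent (stimulus, noise) seeds for one trial."""
    ss = np.random.SeedSequence([int(base_seed), int(condition), int(trial)])
    a, b = ss.generate_state(2)
    return int(a % 2**31), int(b % 2**31)


def run_experiment(
    config: NetworkConfig | Network,
    displacements=(20, 40, 60, 80, 100, 120, 140),
    sides=("left", "right"),
    n_trials: int = 3,
    base_seed: int = 0,
    duration: float = 600.0,
    verbose: bool = False,
) -> pd.DataFrame:
    """Run the heading-discrimination experiment sweep.

    One row per (displacement magnitude, side, trial) with the LIP decision,
    decision latency, and per-LIP spike counts.  The network is assembled once
    and reused; stimulus and noise seeds are derived per trial from
    ``base_seed``.
    """
    from .stimuli import make_dot_stimulus

    network = config if isinstance(config, Network) else assemble(config)
    rows = []
    cond_idx = 0
    for mag in displacements:
        for side in sides:
            signed = -abs(mag) if side == "left" else abs(mag)
            for trial in range(n_trials):
                stim_seed, noise_seed = trial_seeds(base_seed, cond_idx, trial)
                stim = make_dot_stimulus(signed, duration=duration, seed=stim_seed)
                result = run(
                    network, stim, duration, noise_seed, record_layers=("LIP",)
                )
                trace = result.lip_decision()
                counts = result.spikes["LIP"].counts(2)
                rows.append(
                    {
                        "displacement_px": signed,
                        "magnitude_px": abs(mag),
                        "side": side,
                        "trial": trial,
                        "stim_seed": stim_seed,
                        "noise_seed": noise_seed,
                        "decision": trace.decision,
                        "latency_ms": trace.latency,
                        "n_spikes_left": int(counts[0]),
                        "n_spikes_right": int(counts[1]),
                        "wall_time_s": result.wall_time_s,
                    }
                )
                if verbose:
                    r = rows[-1]
                    print(
                        f"{side:>5} {mag:>4}px trial {trial}: "
                        f"decision={r['decision']:<9} latency={r['latency_ms']} "
                        f"L={r['n_spikes_left']} R={r['n_spikes_right']}"
                    )
            cond_idx += 1
    return pd.DataFrame(rows)
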