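"""Integrate-and-fire neuron models and a fixed-step simulation kernel.

Two models are provided:

* :class:`LifExpParams` — current-based leaky integrate-and-fire with
  exponentially decaying postsynaptic currents and an absolute refractory
  period (used for all layers except the LGN relay cells).
* :class:`LifCondAhpParams` — conductance-based leaky integrate-and-fire with
  exponential synaptic conductances and a spike-triggered after-
  hyperpolarization (AHP) conductance instead of a hard reset (used for the
  LGN relay cells; spikes are detected on upward threshold crossings).

Integration uses the exact exponential propagator per step under the
assumption that currents/conductances are constant within a step (they decay
exponentially between steps), not forward Euler.  Threshold detection is at
step boundaries and the spike time is the end of the crossing step, the
convention of fixed-step spiking simulators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LifExpParams",
    "LifCondAhpParams",
    "SpikeData",
    "LifExpLayer",
    "LifCondAhpLayer",
    "simulate_lif_exp",
    "simulate_lif_cond_ahp",
    "run_layer",
    "lif_exp_isi",
]


@dataclass
class LifExpParams:
    """Current-based LIF with exponential PSCs.

    Units: capacitance pF, times ms, potentials mV, currents pA.
    """

    C_m: float = 250.0
    tau_m: float = 10.0
    V_rest: float = -70.0
    V_th: float = -55.0
    V_reset: float = -70.0
    t_ref: float = 2.0
    tau_syn_ex: float = 2.0
    tau_syn_in: float = 2.0

    def __post_init__(self) -> None:
        if self.V_reset >= self.V_th:
            raise ValueError("V_reset must be below V_th")
        for name in ("C_m", "tau_m", "tau_syn_ex", "tau_syn_in"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.t_ref < 0:
            raise ValueError("t_ref must be non-negative")


@dataclass
class LifCondAhpParams:
    """Conductance-based LIF with spike-triggered AHP conductance.

    There is no absolute reset: after an upward threshold crossing the AHP
    conductance (reversal ``E_ahp`` below rest) is incremented and pulls the
    membrane down, mediating refractoriness.  Units: pF, nS, mV, ms.
    """

    C_m: float = 250.0
    g_L: float = 12.5
    E_L: float = -60.0
    E_ex: float = 0.0
    E_in: float = -85.0
    E_ahp: float = -90.0
    V_th: float = -50.0
    g_ahp: float = 80.0  # increment per spike, nS
    tau_ahp: float = 10.0
    tau_syn_ex: float = 2.0
    tau_syn_in: float = 5.0

    def __post_init__(self) -> None:
        if min(self.g_L, self.g_ahp) < 0:
            raise ValueError("conductances must be non-negative")
        if not (self.E_in <= self.E_L < self.V_th):
            raise ValueError("need E_in <= E_L < V_th")
        for name in ("C_m", "tau_ahp", "tau_syn_ex", "tau_syn_in"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SpikeData:
    """Spike events of one layer: parallel arrays of neuron ids and times (ms)."""

    layer: str
    ids: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=float)
        if self.ids.shape != self.times.shape:
            raise ValueError("ids and times must have equal length")

    @property
    def n_spikes(self) -> int:
        return len(self.times)

    def counts(self, n_neurons: int, t_start: float = 0.0, t_stop: float = np.inf) -> np.ndarray:
        """Per-neuron spike counts within [t_start, t_stop]."""
        sel = (self.times >= t_start) & (self.times <= t_stop)
        return np.bincount(self.ids[sel], minlength=n_neurons)

    def validate(self, duration: float, t_ref: float = 0.0) -> None:
        """Check event times lie in [0, duration] and per-neuron ISIs >= t_ref."""
        if self.n_spikes == 0:
            return
        if self.times.min() < 0 or self.times.max() > duration:
            raise ValueError("spike times outside [0, duration]")
        order = np.lexsort((self.times, self.ids))
        ids, times = self.ids[order], self.times[order]
        same = ids[1:] == ids[:-1]
        gaps = np.diff(times)[same]
        if gaps.size and gaps.min() < max(t_ref, 1e-12) - 1e-9:
            raise ValueError("per-neuron inter-spike interval below t_ref")

    def save_text(self, path) -> None:
        """Write as two-column delimited text (neuron_id, time_ms)."""
        np.savetxt(path, np.column_stack([self.ids, self.times]),
                   fmt=("%d", "%.3f"), delimiter="\t", header="neuron_id\ttime_ms")


class LifExpLayer:
    """Vectorized fixed-step state of N current-based LIF neurons."""

    def __init__(self, params: LifExpParams, n: int, dt: float):
        if dt <= 0 or dt > 0.5:
            raise ValueError("dt must be in (0, 0.5] ms")
        self.p = params
        self.n = n
        self.dt = dt
        self.V = np.full(n, params.V_rest)
        self.i_ex = np.zeros(n)
        self.i_in = np.zeros(n)
        self.refr = np.zeros(n, dtype=np.int64)
        self._alpha = math.exp(-dt / params.tau_m)
        self._dex = math.exp(-dt / params.tau_syn_ex)
        self._din = math.exp(-dt / params.tau_syn_in)
        self._ref_steps = int(round(params.t_ref / dt))

    def step(self, i_inj=0.0, deliver_ex=None, deliver_in=None) -> np.ndarray:
        """Advance one step; returns indices of neurons that spiked.

        ``deliver_ex``/``deliver_in`` are PSC increments (pA, signed: the
        inhibitory channel carries negative values) arriving at this step.
        """
        p = self.p
        if deliver_ex is not None:
            self.i_ex += deliver_ex
        if deliver_in is not None:
            self.i_in += deliver_in
        i_tot = self.i_ex + self.i_in + i_inj
        v_inf = p.V_rest + i_tot * p.tau_m / p.C_m
        v_new = v_inf + (self.V - v_inf) * self._alpha
        refractory = self.refr > 0
        v_new[refractory] = p.V_reset
        self.refr[refractory] -= 1
        spiked = np.flatnonzero(~refractory & (v_new >= p.V_th))
        v_new[spiked] = p.V_reset
        self.refr[spiked] = self._ref_steps
        self.V = v_new
        self.i_ex *= self._dex
        self.i_in *= self._din
        return spiked


class LifCondAhpLayer:
    """Vectorized fixed-step state of N conductance-based LIF+AHP neurons."""

    def __init__(self, params: LifCondAhpParams, n: int, dt: float):
        if dt <= 0 or dt > 0.5:
            raise ValueError("dt must be in (0, 0.5] ms")
        self.p = params
        self.n = n
        self.dt = dt
        self.V = np.full(n, params.E_L)
        self.g_ex = np.zeros(n)
        self.g_in = np.zeros(n)
        self.g_ahp = np.zeros(n)
        self._dex = math.exp(-dt / params.tau_syn_ex)
        self._din = math.exp(-dt / params.tau_syn_in)
        self._dahp = math.exp(-dt / params.tau_ahp)

    def step(self, i_inj=0.0, deliver_ex=None, deliver_in=None) -> np.ndarray:
        """Advance one step; `deliver_*` are conductance increments in nS
        (inhibitory increments may be passed signed; magnitudes are used)."""
        p = self.p
        if deliver_ex is not None:
            self.g_ex += deliver_ex
        if deliver_in is not None:
            self.g_in += np.abs(deliver_in)
        g_tot = p.g_L + self.g_ex + self.g_in + self.g_ahp
        v_inf = (
            p.g_L * p.E_L
            + self.g_ex * p.E_ex
            + self.g_in * p.E_in
            + self.g_ahp * p.E_ahp
            + i_inj
        ) / g_tot
        v_new = v_inf + (self.V - v_inf) * np.exp(-g_tot * self.dt / p.C_m)
        spiked = np.flatnonzero((v_new >= p.V_th) & (self.V < p.V_th))
        self.g_ahp[spiked] += p.g_ahp
        self.V = v_new
        self.g_ex *= self._dex
        self.g_in *= self._din
        self.g_ahp *= self._dahp
        return spiked


def _deliveries_from_events(spikes_in, n_steps: int, dt: float):
    """Bin (time, weight, 'exc'|'inh') events into per-step delivery arrays."""
    d_ex = np.zeros(n_steps)
    d_in = np.zeros(n_steps)
    for t, w, kind in spikes_in or []:
        k = int(math.floor(t / dt))
        if k >= n_steps:
            continue
        if kind == "exc":
            d_ex[k] += w
        elif kind == "inh":
            d_in[k] += -abs(w)
        else:
            raise ValueError(f"unknown synapse kind {kind!r}")
    return d_ex, d_in


def _injected_to_array(injected, n_steps: int, dt: float) -> np.ndarray:
    from .retina import CurrentTrace

    if injected is None:
        return np.zeros(n_steps)
    if isinstance(injected, CurrentTrace):
        arr = np.zeros(n_steps)
        m = min(n_steps, len(injected.current))
        arr[:m] = injected.current[:m]
        return arr
    arr = np.asarray(injected, dtype=float)
    if np.isscalar(injected) or arr.ndim == 0:
        return np.full(n_steps, float(arr))
    out = np.zeros(n_steps)
    m = min(n_steps, len(arr))
    out[:m] = arr[:m]
    return out


def _simulate_single(layer_cls, params, injected, spikes_in, dt, duration):
    n_steps = int(round(duration / dt))
    inj = _injected_to_array(injected, n_steps, dt)
    if not np.all(np.isfinite(inj)):
        raise FloatingPointError("injected current contains NaN/inf")
    d_ex, d_in = _deliveries_from_events(spikes_in, n_steps, dt)
    layer = layer_cls(params, 1, dt)
    spike_times = []
    voltage = np.empty(n_steps)
    for k in range(n_steps):
        spiked = layer.step(inj[k], d_ex[k], d_in[k])
        if spiked.size:
            spike_times.append((k + 1) * dt)
        voltage[k] = layer.V[0]
    return np.asarray(spike_times), voltage


def simulate_lif_exp(
    params: LifExpParams,
    injected=None,
    spikes_in=None,
    dt: float = 0.1,
    duration: float = 1000.0,
):
    """Simulate one current-based LIF neuron.

    Parameters
    ----------
    injected:
        Constant current (pA), a per-step array, or a CurrentTrace.
    spikes_in:
        Iterable of ``(time_ms, weight_pA, 'exc'|'inh')`` synaptic events.

    Returns ``(spike_times_ms, voltage_trace)``; the voltage is sampled at the
    end of each step.
    """
    return _simulate_single(LifExpLayer, params, injected, spikes_in, dt, duration)


def simulate_lif_cond_ahp(
    params: LifCondAhpParams,
    injected=None,
    spikes_in=None,
    dt: float = 0.1,
    duration: float = 1000.0,
):
    """Simulate one conductance-based LIF+AHP neuron (weights in nS)."""
    return _simulate_single(LifCondAhpLayer, params, injected, spikes_in, dt, duration)


def run_layer(
    params,
    injected: np.ndarray,
    dt: float = 0.1,
    label: str = "layer",
) -> SpikeData:
    """Simulate an unconnected layer of N neurons driven by injected currents.

    ``injected`` is an (n_steps, N) array of per-neuron currents.  Output is
    deterministic given inputs and parameters.
    """
    injected = np.asarray(injected, dtype=float)
    if injected.ndim != 2:
        raise ValueError("injected must be (n_steps, n_neurons)")
    if not np.all(np.isfinite(injected)):
        raise FloatingPointError("injected current contains NaN/inf")
    n_steps, n = injected.shape
    cls = LifCondAhpLayer if isinstance(params, LifCondAhpParams) else LifExpLayer
    layer = cls(params, n, dt)
    ids, times = [], []
    for k in range(n_steps):
        spiked = layer.step(injected[k])
        if spiked.size:
            ids.append(spiked)
            times.append(np.full(spiked.size, (k + 1) * dt))
    if ids:
        return SpikeData(label, np.concatenate(ids), np.concatenate(times))
    return SpikeData(label, np.empty(0, dtype=np.int64), np.empty(0))


def lif_exp_isi(params: LifExpParams, i_const: float) -> float:
    """Closed-form inter-spike interval of the current-based LIF under constant
    suprathreshold current: ``t_ref + tau_m ln((Vinf-Vreset)/(Vinf-Vth))``.
    Returns inf for subthreshold drive."""
    v_inf = params.V_rest + i_const * params.tau_m / params.C_m
    if v_inf <= params.V_th:
        return math.inf
    return params.t_ref + params.tau_m * math.log(
        (v_inf - params.V_reset) / (v_inf - params.V_th)
    )
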