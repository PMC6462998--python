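"""Population decoding and decision/latency analysis.

The orientation/direction represented by a spiking population is estimated by
the spike-count-weighted vector average of the cells' preferred angles,

    OR_est = atan2(sum_i n_i sin(theta'_i), sum_i n_i cos(theta'_i)),

where n_i is the spike count of cell i.  For direction (period 2*pi)
``theta' = theta``; for orientation (period pi) the angles are doubled before
averaging and the result halved, the standard circular-statistics treatment
of axial data (a plain arctangent is ill-posed on a half-period).

The LIP decision analysis converts the two LIP spike trains into sliding-
window rate series; the decision is the side with the higher rate at the end
of the trial, and the decision latency is the earliest time from which the
winner's rate stays (non-strictly) above the loser's for the remainder — the
end of the initial period of uncertainty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .neurons import SpikeData

__all__ = [
    "DecodeResult",
    "DecisionTrace",
    "population_decode",
    "lip_rates",
    "decide",
    "summarize_experiment",
]


@dataclass
class DecodeResult:
    """Vector-average decode of a population's preferred angle.

    ``angle_deg`` is None when the resultant vector vanishes (no spikes or
    perfectly balanced counts): the estimate is undefined, not a number.
    """

    angle_deg: float | None
    counts: np.ndarray
    preferences_deg: np.ndarray
    period_deg: float

    @property
    def defined(self) -> bool:
        return self.angle_deg is not None

    @property
    def total_spikes(self) -> int:
        return int(self.counts.sum())


def population_decode(
    spikes: SpikeData,
    preferences: np.ndarray,
    period: float = math.pi,
    interval: tuple[float, float] | None = None,
    n_neurons: int | None = None,
) -> DecodeResult:
    """Vector-average population decode of spike counts.

    Parameters
    ----------
    spikes:
        Spike events of the decoded layer.
    preferences:
        Preferred angle (radians) per neuron, length covering all decoded
        neuron ids (e.g. ``OrientationMap.theta_flat()``).
    period:
        ``pi`` for orientation decoding (angles doubled before averaging),
        ``2*pi`` for direction decoding.
    interval:
        Optional (t_start, t_stop) ms; default the whole recording.

    Returns the estimate in degrees within [0, period).
    """
    preferences = np.asarray(preferences, dtype=float).ravel()
    if n_neurons is None:
        n_neurons = len(preferences)
    if spikes.n_spikes and spikes.ids.max() >= len(preferences):
        raise ValueError("preferences do not cover all decoded neurons")
    t0, t1 = interval if interval is not None else (0.0, np.inf)
    counts = spikes.counts(n_neurons, t0, t1)
    wrap = 2.0 * math.pi / period  # 2 for orientation, 1 for direction
    s = float(np.sum(counts * np.sin(wrap * preferences)))
    c = float(np.sum(counts * np.cos(wrap * preferences)))
    if math.hypot(s, c) < 1e-12:
        angle = None
    else:
        angle = math.degrees((math.atan2(s, c) / wrap) % period)
    return DecodeResult(
        angle, counts, np.degrees(preferences % period), math.degrees(period)
    )


@dataclass
class DecisionTrace:
    """Windowed LIP rates and the resulting decision."""

    times: np.ndarray  # window-center times, ms
    left_rate: np.ndarray  # Hz
    right_rate: np.ndarray  # Hz
    decision: str  # 'left' | 'right' | 'undecided'
    latency: float | None  # ms; None when undecided

    def __post_init__(self) -> None:
        if np.any(self.left_rate < 0) or np.any(self.right_rate < 0):
            raise ValueError("rates must be non-negative")


def lip_rates(
    spikes: SpikeData,
    duration: float,
    window: float = 200.0,
    step: float = 20.0,
    neuron_ids: tuple[int, int] = (0, 1),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sliding-window firing-rate series of the two LIP neurons.

    Returns (window-center times ms, left rates Hz, right rates Hz).
    """
    centers = np.arange(window / 2.0, duration - window / 2.0 + 1e-9, step)
    rates = []
    for nid in neuron_ids:
        t = spikes.times[spikes.ids == nid]
        n_in = np.array(
            [np.sum((t > c - window / 2.0) & (t <= c + window / 2.0)) for c in centers]
        )
        rates.append(n_in / (window / 1000.0))
    return centers, rates[0], rates[1]


def decide(
    times: np.ndarray,
    left_rate: np.ndarray,
    right_rate: np.ndarray,
) -> DecisionTrace:
    """Decision and latency from two rate series.

    The decision is the side with the higher total rate over the series'
    final window; the latency is the earliest time after which the winner's
    windowed rate is never below the loser's (when the winner prevails from
    the start the latency is 0).  An exact tie at the end, or two silent
    series, is undecided.  The outcome is invariant to jointly rescaling both
    rate series.
    """
    times = np.asarray(times, dtype=float)
    left = np.asarray(left_rate, dtype=float)
    right = np.asarray(right_rate, dtype=float)
    if len(times) == 0 or left[-1] == right[-1] == 0 and np.all(left == right):
        return DecisionTrace(times, left, right, "undecided", None)
    if left[-1] > right[-1]:
        winner, loser, decision = left, right, "left"
    elif right[-1] > left[-1]:
        winner, loser, decision = right, left, "right"
    else:
        return DecisionTrace(times, left, right, "undecided", None)
    ahead = winner >= loser
    # earliest index from which `ahead` holds for the remainder
    behind = np.flatnonzero(~ahead)
    first = behind[-1] + 1 if behind.size else 0
    latency = 0.0 if first == 0 else float(times[first])
    return DecisionTrace(times, left, right, decision, latency)


def summarize_experiment(results: pd.DataFrame) -> dict:
    """Summarize a heading-discrimination experiment table.

    Expects columns ``displacement_px`` (signed), ``side``, ``decision``,
    ``latency_ms``.  Returns per-condition accuracy and mean latency plus a
    monotonic-trend statistic: the Spearman rank correlation of mean decision
    latency against displacement magnitude over the magnitudes tested
    (negative when larger heading offsets are resolved faster).
    """
    df = results.copy()
    df["magnitude_px"] = df["displacement_px"].abs()
    df["correct"] = df["decision"] == df["side"]
    per_condition = (
        df.groupby(["magnitude_px", "side"])
        .agg(accuracy=("correct", "mean"), mean_latency_ms=("latency_ms", "mean"),
             n_trials=("correct", "size"))
        .reset_index()
    )
    by_magnitude = (
        df.groupby("magnitude_px")
        .agg(accuracy=("correct", "mean"), mean_latency_ms=("latency_ms", "mean"))
        .reset_index()
    )
    if len(by_magnitude) > 1 and by_magnitude["mean_latency_ms"].notna().all():
        rho, pval = spearmanr(
            by_magnitude["magnitude_px"], by_magnitude["mean_latency_ms"]
        )
    else:
        rho, pval = np.nan, np.nan
    return {
        "per_condition": per_condition,
        "by_magnitude": by_magnitude,
        "accuracy": float(df["correct"].mean()),
        "latency_spearman_rho": float(rho),
        "latency_spearman_p": float(pval),
    }
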