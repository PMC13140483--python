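"""Epoch-based Doppler velocity metrics.

Systolic, diastolic and mean velocity are extracted from an envelope
signal over a site-specific epoch plan (MCA: eight 7 s epochs across
2 min; carotid: two 12 s epochs), then combined into the pulsatility
index, Pourcelot resistive index and cerebrovascular conductance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import DomainError, InvalidParameterError, WindowError
from .signal import PERIOD_BOUNDS, SampledSignal


@dataclass
class EpochPlan:
    """Placement of analysis epochs across a recording window."""

    site: str
    n_epochs: int
    epoch_s: float
    total_window_s: float

    def __post_init__(self) -> None:
        if self.n_epochs < 1 or self.epoch_s <= 0:
            raise InvalidParameterError("need n_epochs >= 1 and epoch_s > 0")
        if self.n_epochs * self.epoch_s > self.total_window_s:
            raise InvalidParameterError("epochs do not fit in the window")

    @classmethod
    def mca(cls) -> "EpochPlan":
        """Eight 7 s epochs across a 2 min insonation period."""
        return cls(site="mca", n_epochs=8, epoch_s=7.0, total_window_s=120.0)

    @classmethod
    def carotid(cls) -> "EpochPlan":
        """Two 12 s pulsed-wave Doppler epochs."""
        return cls(site="carotid", n_epochs=2, epoch_s=12.0, total_window_s=24.0)

    def epoch_starts_s(self) -> np.ndarray:
        """Epoch start times, spaced evenly across the window."""
        if self.n_epochs == 1:
            return np.array([0.0])
        return np.linspace(0.0, self.total_window_s - self.epoch_s, self.n_epochs)


@dataclass
class DopplerMetrics:
    """Aggregate velocity metrics for one site and window."""

    site: str
    v_sys: float  # cm/s
    v_dia: float
    v_mean: float
    pi: float
    ri: float
    conductance: float | None  # cm/s/mmHg, needs MAP
    per_epoch: list = field(default_factory=list)  # (v_sys, v_dia, v_mean)


def _beat_extrema(x: np.ndarray, fs: float) -> tuple[float, float]:
    """Per-beat systolic peaks and diastolic troughs, averaged.

    Falls back to the epoch max/min for (near-)constant envelopes where no
    beats are resolvable.
    """
    rng = x.max() - x.min()
    min_dist = max(int(PERIOD_BOUNDS[0] * fs), 1)
    if rng <= 0:
        return float(x.max()), float(x.min())
    peaks, _ = find_peaks(x, distance=min_dist, prominence=0.25 * rng)
    troughs, _ = find_peaks(-x, distance=min_dist, prominence=0.25 * rng)
    if peaks.size == 0 or troughs.size == 0:
        return float(x.max()), float(x.min())
    return float(x[peaks].mean()), float(x[troughs].mean())


def epoch_metrics(
    velocity: SampledSignal, plan: EpochPlan
) -> list[tuple[float, float, float]]:
    """Per-epoch (v_sys, v_dia, v_mean) in cm/s.

    v_sys/v_dia are means of per-beat maxima/minima within the epoch
    (robust to single-beat spikes); v_mean is the epoch time-average.
    """
    fs = velocity.sampling_rate
    if velocity.duration + 0.5 / fs < plan.total_window_s:
        raise WindowError(
            f"recording of {velocity.duration:.1f} s shorter than "
            f"{plan.total_window_s:.1f} s window"
        )
    out = []
    n_epoch = int(round(plan.epoch_s * fs))
    for t0 in plan.epoch_starts_s():
        i0 = int(round(t0 * fs))
        seg = velocity.values[i0 : i0 + n_epoch]
        v_sys, v_dia = _beat_extrema(seg, fs)
        out.append((v_sys, v_dia, float(seg.mean())))
    return out


def pulsatility_index(v_sys: float, v_dia: float, v_mean: float) -> float:
    """PI = (systolic - diastolic velocity) / mean velocity."""
    if v_mean <= 0:
        raise DomainError("mean velocity must be positive")
    return (v_sys - v_dia) / v_mean


def resistive_index(v_sys: float, v_dia: float) -> float:
    """Pourcelot resistive index: (systolic - diastolic velocity) / systolic."""
    if v_sys <= 0:
        raise DomainError("systolic velocity must be positive")
    return (v_sys - v_dia) / v_sys


def conductance(v_mean: float, map_mmhg: float) -> float:
    """Cerebrovascular conductance index: mean velocity / mean arterial pressure."""
    if map_mmhg <= 0:
        raise DomainError("MAP must be positive")
    return v_mean / map_mmhg


def summarize(
    velocity: SampledSignal, plan: EpochPlan, map_mmhg: float | None = None
) -> DopplerMetrics:
    """Epoch extraction plus derived indices in one call.

    Aggregate velocities are means over epochs; indices are computed from
    the aggregated velocities of this one recording. (At the group level
    the package averages per-subject indices — a mean of ratios, which
    differs from the ratio of group-mean velocities.)
    """
    per_epoch = epoch_metrics(velocity, plan)
    arr = np.asarray(per_epoch)
    v_sys, v_dia, v_mean = (float(m) for m in arr.mean(axis=0))
    return DopplerMetrics(
        site=plan.site,
        v_sys=v_sys,
        v_dia=v_dia,
        v_mean=v_mean,
        pi=pulsatility_index(v_sys, v_dia, v_mean),
        ri=resistive_index(v_sys, v_dia),
        conductance=None if map_mmhg is None else conductance(v_mean, map_mmhg),
        per_epoch=per_epoch,
    )
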