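"""Breath-hold cerebrovascular reactivity (CVR).

The protocol is eight paced breaths at 16 breaths/min followed by a 20 s
breath-hold, repeated four times. Per repeat the end-tidal CO2 change is
the post-hold peak minus the average of the last two paced end-tidal
plateaus; the MCA velocity change mirrors that construction (baseline over
the last two paced breaths, response as the post-hold peak of a 3 s
moving average). Reactivity is the mean over valid repeats of the
per-repeat ratio, in absolute (cm/s per mmHg) and relative (%/mmHg) form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .errors import (
    InsufficientDataError,
    InvalidParameterError,
    ProtocolMismatchError,
    WindowError,
)
from .signal import SampledSignal

log = logging.getLogger(__name__)

#: MCAv response window extends this far past the end of the hold (s)
POST_HOLD_RESPONSE_S = 15.0

#: moving-average width applied to MCAv before peak-picking (s)
MCAV_SMOOTH_S = 3.0


@dataclass
class ProtocolSchedule:
    """Timing of the paced-breathing / breath-hold protocol."""

    n_repeats: int = 4
    paced_breaths_per_repeat: int = 8
    paced_rate_bpm: float = 16.0
    hold_s: float = 20.0
    recovery_s: float = 20.0
    lead_in_s: float = 0.0

    def __post_init__(self) -> None:
        if min(self.n_repeats, self.paced_breaths_per_repeat) < 1:
            raise InvalidParameterError("repeats and breaths must be >= 1")
        if min(self.paced_rate_bpm, self.hold_s) <= 0:
            raise InvalidParameterError("rate and hold must be positive")
        if self.recovery_s < POST_HOLD_RESPONSE_S:
            raise InvalidParameterError(
                f"recovery must cover the {POST_HOLD_RESPONSE_S} s response window"
            )

    @property
    def breath_s(self) -> float:
        return 60.0 / self.paced_rate_bpm

    @property
    def paced_s(self) -> float:
        return self.paced_breaths_per_repeat * self.breath_s

    @property
    def repeat_s(self) -> float:
        return self.paced_s + self.hold_s + self.recovery_s

    @property
    def total_s(self) -> float:
        return self.lead_in_s + self.n_repeats * self.repeat_s

    def repeat_start(self, r: int) -> float:
        self._check_repeat(r)
        return self.lead_in_s + r * self.repeat_s

    def breath_windows(self, r: int) -> list[tuple[float, float]]:
        """(start, end) of each paced-breath window in repeat ``r``."""
        t0 = self.repeat_start(r)
        return [
            (t0 + k * self.breath_s, t0 + (k + 1) * self.breath_s)
            for k in range(self.paced_breaths_per_repeat)
        ]

    def hold_window(self, r: int) -> tuple[float, float]:
        t0 = self.repeat_start(r) + self.paced_s
        return (t0, t0 + self.hold_s)

    def response_window(self, r: int) -> tuple[float, float]:
        """Breath-hold plus the post-hold interval where the peak response lands."""
        h0, h1 = self.hold_window(r)
        return (h0, h1 + POST_HOLD_RESPONSE_S)

    def _check_repeat(self, r: int) -> None:
        if not 0 <= r < self.n_repeats:
            raise InvalidParameterError(f"repeat {r} outside 0..{self.n_repeats - 1}")


@dataclass
class CvrResult:
    """Per-repeat deltas and the averaged reactivity indices."""

    per_repeat_delta_etco2: list  # mmHg
    per_repeat_delta_mcav: list  # cm/s
    per_repeat_baseline_mcav: list  # cm/s
    cvr_abs: float  # cm/s per mmHg
    cvr_rel: float  # % per mmHg
    baseline_mcav: float  # cm/s, mean of per-repeat baselines
    excluded_repeats: list = field(default_factory=list)


def _slice(signal: SampledSignal, t0: float, t1: float) -> np.ndarray:
    fs = signal.sampling_rate
    i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
    if i1 > signal.n or i0 < 0:
        raise WindowError(
            f"window [{t0:.1f}, {t1:.1f}] s exceeds {signal.duration:.1f} s recording"
        )
    return signal.values[i0:i1]


def extract_end_tidal(
    etco2: SampledSignal, schedule: ProtocolSchedule, repeat: int
) -> np.ndarray:
    """One end-tidal value per paced breath: the expiratory plateau maximum.

    If the paced phase clearly contains breathing excursions but fewer
    breath cycles than scheduled, the trace does not match the protocol and
    a mismatch error is raised. A flat trace (pre-extracted end-tidal
    level) is accepted as degenerate input.
    """
    windows = schedule.breath_windows(repeat)
    paced = _slice(etco2, windows[0][0], windows[-1][1])
    rng = paced.max() - paced.min()
    if rng > 1.0:  # mmHg; clearly a breathing capnogram
        fs = etco2.sampling_rate
        min_dist = max(int(0.5 * schedule.breath_s * fs), 1)
        peaks, _ = find_peaks(paced, prominence=0.25 * rng, distance=min_dist)
        if peaks.size < schedule.paced_breaths_per_repeat:
            raise ProtocolMismatchError(
                f"repeat {repeat}: {peaks.size} breaths detected, "
                f"{schedule.paced_breaths_per_repeat} scheduled"
            )
    return np.array([float(_slice(etco2, a, b).max()) for a, b in windows])


def post_hold_peak_etco2(
    etco2: SampledSignal, schedule: ProtocolSchedule, repeat: int
) -> float:
    """Peak end-tidal CO2 following the breath-hold."""
    h1 = schedule.hold_window(repeat)[1]
    return float(_slice(etco2, h1, h1 + POST_HOLD_RESPONSE_S).max())


def delta_etco2(end_tidals: np.ndarray, post_hold_peak: float) -> float:
    """Post-hold peak minus the average of the last two paced end-tidals."""
    end_tidals = np.asarray(end_tidals, dtype=float)
    if end_tidals.size < 2:
        raise InsufficientDataError("need at least 2 paced end-tidal values")
    return float(post_hold_peak - end_tidals[-2:].mean())


def delta_mcav(
    mcav: SampledSignal, schedule: ProtocolSchedule, repeat: int
) -> tuple[float, float]:
    """(delta, baseline) of MCA mean velocity for one repeat.

    Baseline is the mean over the last two paced-breath windows; the
    response is the peak of the 3 s moving-averaged velocity inside the
    hold plus post-hold window. Mirrors the end-tidal delta construction.
    """
    windows = schedule.breath_windows(repeat)[-2:]
    baseline = float(
        np.mean(np.concatenate([_slice(mcav, a, b) for a, b in windows]))
    )
    fs = mcav.sampling_rate
    width = max(int(round(MCAV_SMOOTH_S * fs)), 1)
    smooth = uniform_filter1d(mcav.values, size=width, mode="nearest")
    r0, r1 = schedule.response_window(repeat)
    seg = _slice(SampledSignal(smooth, fs), r0, r1)
    return float(seg.max() - baseline), baseline


def cvr_indices(
    per_repeat: list[tuple[float, float, float]]
) -> CvrResult:
    """Combine per-repeat (delta_mcav, delta_etco2, baseline_mcav) triples.

    Repeats with a non-positive end-tidal change (failed hold) are excluded
    and logged. Averaging is the mean of per-repeat ratios, not the ratio
    of means.
    """
    valid, excluded = [], []
    for i, (dv, dc, base) in enumerate(per_repeat):
        if dc <= 0:
            excluded.append(i)
            log.warning("CVR repeat %d excluded: delta ETCO2 = %.2f <= 0", i, dc)
        else:
            valid.append((dv, dc, base))
    if not valid:
        raise InsufficientDataError("no valid breath-hold repeats")
    abs_ratios = [dv / dc for dv, dc, _ in valid]
    rel_ratios = [(100.0 * dv / base) / dc for dv, dc, base in valid]
    return CvrResult(
        per_repeat_delta_etco2=[dc for _, dc, _ in valid],
        per_repeat_delta_mcav=[dv for dv, _, _ in valid],
        per_repeat_baseline_mcav=[base for _, _, base in valid],
        cvr_abs=float(np.mean(abs_ratios)),
        cvr_rel=float(np.mean(rel_ratios)),
        baseline_mcav=float(np.mean([base for _, _, base in valid])),
        excluded_repeats=excluded,
    )


def analyze_session(
    etco2: SampledSignal, mcav: SampledSignal, schedule: ProtocolSchedule | None = None
) -> CvrResult:
    """Full session analysis: end-tidal extraction, per-repeat deltas, indices."""
    schedule = schedule or ProtocolSchedule()
    per_repeat = []
    for r in range(schedule.n_repeats):
        et = extract_end_tidal(etco2, schedule, r)
        peak = post_hold_peak_etco2(etco2, schedule, r)
        dc = delta_etco2(et, peak)
        dv, base = delta_mcav(mcav, schedule, r)
        per_repeat.append((dv, dc, base))
    return cvr_indices(per_repeat)
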