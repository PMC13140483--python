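"""Signal containers, beat detection/gating and ensemble averaging.

All analysis stages consume uniformly sampled time series wrapped in
:class:`SampledSignal` and one-cycle averaged waveforms wrapped in
:class:`EnsembleBeat`. Beat anchors come either from the ECG R wave
(simultaneous gating of tonometric recordings) or from the pressure foot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks

from .errors import (
    InsufficientBeatsError,
    InvalidParameterError,
    WindowError,
)

#: physiologic cardiac period bounds in seconds (30–180 beats/min)
PERIOD_BOUNDS = (0.33, 2.0)

#: QRS energy band used for R-wave gating, Hz
QRS_BAND = (5.0, 25.0)


@dataclass
class SampledSignal:
    """A uniformly sampled physiological time series.

    Parameters
    ----------
    values:
        Real-valued samples; gaps/NaNs are an ingest error, not a state
        this container represents.
    sampling_rate:
        Sampling frequency in Hz.
    units:
        Unit string, e.g. ``"mmHg"`` or ``"cm/s"``.
    label:
        Free-text channel label.
    meta:
        Optional provenance, e.g. ground-truth parameters of a synthetic
        signal. Round-tripped through the waveform CSV dialect.
    """

    values: np.ndarray
    sampling_rate: float
    units: str = ""
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.sampling_rate <= 0:
            raise InvalidParameterError("sampling_rate must be positive")
        if self.values.ndim != 1 or self.values.size < 2:
            raise InvalidParameterError("signal needs at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("signal contains non-finite samples")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.n / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n) / self.sampling_rate


@dataclass
class BeatSet:
    """Beat-onset anchors as strictly increasing sample indices."""

    onset_indices: np.ndarray
    anchor_kind: str  # {"r_wave", "foot"}
    sampling_rate: float

    def __post_init__(self) -> None:
        self.onset_indices = np.asarray(self.onset_indices, dtype=int)
        if np.any(np.diff(self.onset_indices) <= 0):
            raise InvalidParameterError("onsets must be strictly increasing")
        if self.anchor_kind not in ("r_wave", "foot"):
            raise InvalidParameterError(f"unknown anchor kind {self.anchor_kind!r}")

    @property
    def n_beats(self) -> int:
        """Number of complete beats implied by the half-open convention."""
        return max(self.onset_indices.size - 1, 0)

    def periods(self) -> np.ndarray:
        return np.diff(self.onset_indices) / self.sampling_rate


@dataclass
class EnsembleBeat:
    """One averaged cardiac cycle, anchored at the beat onset."""

    values: np.ndarray
    sampling_rate: float
    n_beats_averaged: int = 1
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.n_beats_averaged < 1:
            raise InvalidParameterError("n_beats_averaged must be >= 1")
        if self.sampling_rate <= 0:
            raise InvalidParameterError("sampling_rate must be positive")

    @property
    def duration(self) -> float:
        return self.values.size / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.values.size) / self.sampling_rate


def _bandpass(x: np.ndarray, fs: float, lo: float, hi: float) -> np.ndarray:
    nyq = fs / 2.0
    hi = min(hi, 0.95 * nyq)
    b, a = butter(2, [lo / nyq, hi / nyq], btype="band")
    return filtfilt(b, a, x)


def detect_beats(signal: SampledSignal, anchor_kind: str = "r_wave") -> BeatSet:
    """Locate one onset anchor per cardiac cycle.

    ``r_wave`` anchors are local maxima of the QRS-band-filtered trace,
    which is how simultaneously recorded ECG gates the tonometric and
    Doppler channels. ``foot`` anchors are upstroke onsets of a pulsatile
    waveform, found from peaks of its first derivative stepped back to the
    preceding local minimum.

    Onsets implying a beat period outside ``PERIOD_BOUNDS`` are excluded.
    """
    fs = signal.sampling_rate
    x = signal.values
    min_dist = max(int(PERIOD_BOUNDS[0] * fs), 1)

    if anchor_kind == "r_wave":
        filt = _bandpass(x, fs, *QRS_BAND)
        amp = np.max(np.abs(filt))
        if amp <= 0:
            raise InsufficientBeatsError("no QRS-band energy in signal")
        peaks, _ = find_peaks(filt, height=0.5 * amp, distance=min_dist)
        onsets = peaks
    elif anchor_kind == "foot":
        d = np.gradient(x) * fs
        dmax = d.max()
        if dmax <= 0:
            raise InsufficientBeatsError("no positive upstroke in signal")
        upstrokes, _ = find_peaks(d, height=0.4 * dmax, distance=min_dist)
        onsets = []
        for u in upstrokes:
            j = u
            while j > 0 and x[j - 1] <= x[j]:
                j -= 1
            onsets.append(j)
        onsets = np.unique(onsets)
    else:
        raise InvalidParameterError(f"unknown anchor kind {anchor_kind!r}")

    if onsets.size < 2:
        raise InsufficientBeatsError(
            f"found {onsets.size} onsets; need at least 2"
        )

    # drop onsets that begin a beat with a non-physiologic period
    periods = np.diff(onsets) / fs
    ok = (periods >= PERIOD_BOUNDS[0]) & (periods <= PERIOD_BOUNDS[1])
    keep = np.append(ok, True)  # the final onset only closes a beat
    onsets = onsets[keep]
    if onsets.size < 2:
        raise InsufficientBeatsError("fewer than 2 physiologic beats")
    return BeatSet(onsets, anchor_kind, fs)


def ensemble_average(
    signal: SampledSignal,
    beats: BeatSet,
    epoch_s: float | None = None,
    artifact_sd: float = 3.0,
    min_beats_warn: int | None = None,
) -> EnsembleBeat:
    """Signal-average the beats falling inside an epoch.

    Beats are segmented on half-open intervals ``[onset_i, onset_{i+1})``,
    linearly resampled to the median beat length and averaged pointwise.
    Beats whose peak-to-trough amplitude deviates more than ``artifact_sd``
    standard deviations from the epoch median amplitude are rejected as
    artifacts (one pass). ``min_beats_warn`` emits a quality-control
    warning (never a failure) when fewer beats than a protocol calls for
    survive — e.g. distension sets specified as 7–10 waveforms.
    """
    fs = signal.sampling_rate
    if epoch_s is not None:
        n_epoch = int(round(epoch_s * fs))
        if n_epoch > signal.n:
            raise WindowError(
                f"epoch of {epoch_s} s exceeds {signal.duration:.2f} s recording"
            )
        limit = n_epoch
    else:
        limit = signal.n

    onsets = beats.onset_indices[beats.onset_indices <= limit]
    segments = [
        signal.values[a:b]
        for a, b in zip(onsets[:-1], onsets[1:])
        if b <= limit
    ]
    if len(segments) < 2:
        raise InsufficientBeatsError(
            "need at least 2 complete beats inside the epoch"
        )

    amps = np.array([s.max() - s.min() for s in segments])
    med, sd = np.median(amps), np.std(amps)
    if sd > 0:
        good = np.abs(amps - med) <= artifact_sd * sd
    else:
        good = np.ones(len(segments), dtype=bool)
    segments = [s for s, g in zip(segments, good) if g]
    n_dropped = int(np.sum(~good))
    if n_dropped:
        warnings.warn(
            f"ensemble_average: rejected {n_dropped} artifact beat(s)",
            stacklevel=2,
        )
    if len(segments) < 2:
        raise InsufficientBeatsError("fewer than 2 beats after artifact rejection")
    if min_beats_warn is not None and len(segments) < min_beats_warn:
        warnings.warn(
            f"ensemble_average: only {len(segments)} beats averaged "
            f"(< {min_beats_warn} called for by protocol)",
            stacklevel=2,
        )

    target = int(np.median([s.size for s in segments]))
    grid = np.linspace(0.0, 1.0, target, endpoint=False)
    stack = np.empty((len(segments), target))
    for i, s in enumerate(segments):
        src = np.linspace(0.0, 1.0, s.size, endpoint=False)
        stack[i] = np.interp(grid, src, s)
    return EnsembleBeat(
        stack.mean(axis=0), fs, n_beats_averaged=len(segments), units=signal.units
    )


def signal_mean(beat: EnsembleBeat) -> float:
    """Time-average of the waveform over one full cycle."""
    return float(np.mean(beat.values))


def derivative(beat: EnsembleBeat | SampledSignal) -> SampledSignal:
    """Centered finite-difference derivative, one-sided at the ends.

    Returned in (units of input)/s, same length as the input.
    """
    fs = beat.sampling_rate
    d = np.gradient(np.asarray(beat.values, dtype=float)) * fs
    units = getattr(beat, "units", "")
    return SampledSignal(d, fs, units=f"{units}/s" if units else "1/s",
                         label="derivative")
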