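"""Arterial stiffness, characteristic impedance and wave separation.

Implements carotid–femoral pulse wave velocity (foot-to-foot transit over
a measured path), the pressure-normalised beta stiffness index, common
carotid volumetric flow, the time-domain characteristic impedance
(peak dP/dt over peak dQ/dt), and linear forward/backward wave separation
with the reflection index RIx = Pb/Pf.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import (
    DomainError,
    InsufficientBeatsError,
    NoUpstrokeError,
    OrderingError,
)
from .signal import BeatSet, EnsembleBeat, SampledSignal, derivative


@dataclass
class StiffnessResult:
    """Carotid–femoral PWV and its ingredients (cm, s, cm/s)."""

    cfpwv: float
    transit_time: float
    path_distance: float
    n_beats_used: int
    per_beat_dt: np.ndarray | None = None


@dataclass
class FlowBeat:
    """One-cycle volumetric flow in mL/s with the geometry that produced it."""

    values: np.ndarray
    sampling_rate: float
    diastolic_diameter: float  # mm
    cross_sectional_area: float  # cm^2
    units: str = "mL/s"

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.values.size) / self.sampling_rate


@dataclass
class WaveSepResult:
    """Forward/backward pressure decomposition of one beat."""

    zc: float  # mmHg.s/mL
    pf_wave: np.ndarray  # mmHg, one cycle
    pb_wave: np.ndarray  # mmHg, one cycle
    pf_amplitude: float
    pb_amplitude: float
    reflection_index: float
    foot_index: int


def detect_foot(values: np.ndarray | EnsembleBeat, sampling_rate: float | None = None) -> float:
    """Foot of a pressure upstroke by the intersecting-tangents construction.

    The foot is the intersection of the horizontal line through the
    pre-upstroke minimum with the tangent at the point of maximum upstroke
    slope. Returns time in seconds from the start of the beat (sub-sample
    resolution).
    """
    if isinstance(values, EnsembleBeat):
        sampling_rate = values.sampling_rate
        values = values.values
    if sampling_rate is None:
        raise DomainError("sampling_rate required with a bare array")
    x = np.asarray(values, dtype=float)
    d = np.gradient(x) * sampling_rate
    # a 10 ms moving average keeps the max-slope localization off noise
    # spikes without displacing it on physiologic upstrokes
    win = max(int(round(0.010 * sampling_rate)), 1)
    if win > 1:
        from scipy.ndimage import uniform_filter1d

        d = uniform_filter1d(d, size=win, mode="nearest")
    i_ms = int(np.argmax(d))
    slope = d[i_ms]
    if slope <= 0:
        raise NoUpstrokeError("maximum slope is non-positive; no upstroke")
    pre_min = float(x[: i_ms + 1].min())
    t_ms = i_ms / sampling_rate
    t_foot = t_ms - (x[i_ms] - pre_min) / slope
    return float(max(t_foot, 0.0))


def cfpwv(
    carotid: SampledSignal,
    femoral: SampledSignal,
    beats: BeatSet,
    path_distance_cm: float,
    min_beats: int = 5,
) -> StiffnessResult:
    """Carotid–femoral PWV = path distance / foot-to-foot transit time.

    Both signals share the ECG gating in ``beats``; for every complete beat
    the foot is located in each site's segment and the per-beat lag
    dt = foot(femoral) - foot(carotid) is referenced to the shared R wave.
    The transit time is the median over beats (robust to isolated
    mis-detections).
    """
    if path_distance_cm <= 0:
        raise DomainError("path distance must be positive")
    dts = []
    on = beats.onset_indices
    for a, b in zip(on[:-1], on[1:]):
        if b > carotid.n or b > femoral.n:
            continue
        try:
            fc = detect_foot(carotid.values[a:b], carotid.sampling_rate)
            ff = detect_foot(femoral.values[a:b], femoral.sampling_rate)
        except NoUpstrokeError:
            continue
        dts.append(ff - fc)
    if len(dts) < min_beats:
        raise InsufficientBeatsError(
            f"only {len(dts)} usable beats; need {min_beats}"
        )
    dts = np.asarray(dts)
    tt = float(np.median(dts))
    if tt <= 0:
        raise OrderingError(
            "median transit time <= 0: sites swapped or mis-gated"
        )
    return StiffnessResult(
        cfpwv=path_distance_cm / tt,
        transit_time=tt,
        path_distance=path_distance_cm,
        n_beats_used=len(dts),
        per_beat_dt=dts,
    )


def beta_stiffness(p_sys: float, p_dia: float, d_sys: float, d_dia: float) -> float:
    """Pressure-normalised stiffness index.

    beta = ln(p_sys / p_dia) / ((d_sys - d_dia) / d_dia), dimensionless.
    Pressures in mmHg, diameters in any common unit.
    """
    if p_dia <= 0 or p_sys <= 0 or d_dia <= 0 or d_sys <= 0:
        raise DomainError("pressures and diameters must be positive")
    if p_sys < p_dia:
        raise DomainError("systolic pressure below diastolic")
    if d_sys <= d_dia:
        raise DomainError("zero or negative diameter strain")
    return float(np.log(p_sys / p_dia) / ((d_sys - d_dia) / d_dia))


def volumetric_flow(
    velocity: SampledSignal | EnsembleBeat, diastolic_diameter_mm: float
) -> FlowBeat:
    """Velocity (cm/s) times diastolic cross-sectional area (circular orifice).

    Area = pi * (d/2)^2 with d converted mm -> cm; flow in mL/s since
    1 cm^3 = 1 mL.
    """
    if diastolic_diameter_mm <= 0:
        raise DomainError("diameter must be positive")
    area_cm2 = float(np.pi * (diastolic_diameter_mm / 20.0) ** 2)
    return FlowBeat(
        values=np.asarray(velocity.values, dtype=float) * area_cm2,
        sampling_rate=velocity.sampling_rate,
        diastolic_diameter=diastolic_diameter_mm,
        cross_sectional_area=area_cm2,
    )


def _flow_on_pressure_base(pressure: EnsembleBeat, flow: FlowBeat) -> np.ndarray:
    """Resample the flow beat onto the pressure beat's time base."""
    q = flow.values
    if q.size == pressure.values.size and flow.sampling_rate == pressure.sampling_rate:
        return q
    src = np.linspace(0.0, 1.0, q.size, endpoint=False)
    dst = np.linspace(0.0, 1.0, pressure.values.size, endpoint=False)
    return np.interp(dst, src, q)


def align_flow_to_pressure(pressure: EnsembleBeat, flow: FlowBeat) -> FlowBeat:
    """Circularly align a flow beat to a pressure beat by their feet.

    Pressure and velocity are routinely acquired in separate sweeps and
    gated on different anchors (ECG R wave versus waveform foot), so the
    two one-cycle waveforms are relatively rotated. Both upstrokes belong
    to the same propagating pulse, so rotating the flow beat until its
    foot coincides with the pressure foot restores the physiologic phase
    relation required by impedance estimation and wave separation.
    """
    q = _flow_on_pressure_base(pressure, flow)
    fs = pressure.sampling_rate
    t_p = detect_foot(pressure)
    t_q = detect_foot(q, fs)
    shift = int(round((t_p - t_q) * fs))
    return FlowBeat(
        values=np.roll(q, shift),
        sampling_rate=fs,
        diastolic_diameter=flow.diastolic_diameter,
        cross_sectional_area=flow.cross_sectional_area,
    )


def characteristic_impedance(pressure: EnsembleBeat, flow: FlowBeat) -> float:
    """Time-domain characteristic impedance: max(dP/dt) / max(dQ/dt).

    Both derivatives are centered finite differences taken over the full
    cycle. Valid when the early-systolic flow acceleration is fast relative
    to windkessel charging, so the pressure upstroke is dominated by the
    forward wave. Result in mmHg.s/mL.
    """
    q = _flow_on_pressure_base(pressure, flow)
    fs = pressure.sampling_rate
    dp = derivative(pressure).values
    dq = np.gradient(q) * fs
    dq_max = dq.max()
    if dq_max <= 0:
        raise DomainError("flow has no positive upstroke; Zc undefined")
    return float(dp.max() / dq_max)


def wave_separation(
    pressure: EnsembleBeat, flow: FlowBeat, zc: float
) -> WaveSepResult:
    """Linear time-domain separation of pressure into forward and backward waves.

    On pulsatile components dP = P - min(P) and dQ = Q - Q(at the pressure
    foot): Pf = (dP + Zc*dQ)/2 and Pb = (dP - Zc*dQ)/2, so Pf + Pb
    reconstructs dP identically. Amplitudes are peak minus foot value of
    each separated wave and RIx = Pb/Pf amplitude ratio.
    """
    if zc <= 0:
        raise DomainError("Zc must be positive")
    p = pressure.values
    q = _flow_on_pressure_base(pressure, flow)
    t_foot = detect_foot(pressure)
    i_foot = min(int(round(t_foot * pressure.sampling_rate)), p.size - 1)
    dp = p - p.min()
    dq = q - q[i_foot]
    pf = (dp + zc * dq) / 2.0
    pb = (dp - zc * dq) / 2.0
    pf_amp = float(pf.max() - pf[i_foot])
    pb_amp = float(pb.max() - pb[i_foot])
    if pf_amp <= 0:
        raise DomainError("forward wave has no amplitude")
    rix = pb_amp / pf_amp
    if rix > 1:
        warnings.warn(
            f"reflection index {rix:.2f} > 1 is non-physiologic", stacklevel=2
        )
    return WaveSepResult(
        zc=zc,
        pf_wave=pf,
        pb_wave=pb,
        pf_amplitude=pf_amp,
        pb_amplitude=pb_amp,
        reflection_index=rix,
        foot_index=i_foot,
    )
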