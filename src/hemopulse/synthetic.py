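"""Synthetic waveform and cohort generators with known ground truth.

Raw recordings of the kind this pipeline analyses (tonometric pressure,
ECG, Doppler envelopes, capnograph traces, long-format study tables) are
rarely shareable, so every input class the pipeline consumes can be
simulated here with the quantity of interest programmed in. Each
generator is seeded and bit-reproducible; ground-truth parameters ride
along in the signal ``meta`` dict and in the waveform CSV headers.

The arterial pressure/flow oracle is a three-element windkessel
(characteristic impedance Zc in series with a peripheral resistance R and
compliance C): P = p_wk + Zc*Q with C dp_wk/dt = Q - p_wk/R. The default
inflow is a brief quarter-sine acceleration phase followed by a
raised-cosine decay; the steepest flow slope then occurs at ejection
onset where Q ~ 0, which is the regime in which the time-domain
peak-derivative impedance estimator is valid. A half-sinusoid ejection is
available as ``flow_shape="half_sine"`` for sensitivity checks (it biases
the estimator upward because windkessel charging contaminates peak dP/dt).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cvr import ProtocolSchedule
from .errors import InfeasibleTargetsError, InvalidParameterError
from .signal import PERIOD_BOUNDS, SampledSignal

STUDY_TIMES = ("baseline", "30", "60")


# ---------------------------------------------------------------------------
# windkessel pressure/flow
# ---------------------------------------------------------------------------

@dataclass
class WindkesselParams:
    """Parameters of the three-element windkessel generator.

    Units: zc and r_peripheral in mmHg.s/mL, compliance in mL/mmHg,
    heart_rate in beats/min, stroke_volume in mL, sampling_rate in Hz,
    noise_sd in mmHg (pressure) / mL/s (flow).
    """

    zc: float = 0.1
    r_peripheral: float = 1.0
    compliance: float = 1.5
    heart_rate: float = 60.0
    ejection_fraction_of_cycle: float = 0.3
    stroke_volume: float = 70.0
    sampling_rate: float = 1000.0
    n_beats: int = 10
    noise_sd: float = 0.0
    seed: int = 0
    flow_shape: str = "accelerating"
    flow_rise_s: float = 0.04

    def __post_init__(self) -> None:
        positive = {
            "zc": self.zc,
            "r_peripheral": self.r_peripheral,
            "compliance": self.compliance,
            "heart_rate": self.heart_rate,
            "stroke_volume": self.stroke_volume,
            "flow_rise_s": self.flow_rise_s,
        }
        for name, v in positive.items():
            if v <= 0:
                raise InvalidParameterError(f"{name} must be positive, got {v}")
        if not 0 < self.ejection_fraction_of_cycle < 1:
            raise InvalidParameterError("ejection fraction must be in (0, 1)")
        if self.sampling_rate < 200:
            raise InvalidParameterError("sampling_rate must be >= 200 Hz")
        if self.n_beats < 1:
            raise InvalidParameterError("n_beats must be >= 1")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if self.flow_shape not in ("accelerating", "half_sine"):
            raise InvalidParameterError(f"unknown flow shape {self.flow_shape!r}")

    @property
    def period(self) -> float:
        return 60.0 / self.heart_rate


def _flow_template(params: WindkesselParams, t: np.ndarray) -> np.ndarray:
    """One-beat inflow sampled at times ``t`` in [0, T), integrating to SV."""
    tej = params.ejection_fraction_of_cycle * params.period
    q = np.zeros_like(t)
    if params.flow_shape == "half_sine":
        m = t < tej
        q[m] = np.sin(np.pi * t[m] / tej)
        area = 2.0 * tej / np.pi
    else:
        tr = min(params.flow_rise_s, 0.5 * tej)
        up = t < tr
        dn = (t >= tr) & (t < tej)
        q[up] = np.sin(np.pi * t[up] / (2.0 * tr))
        q[dn] = 0.5 * (1.0 + np.cos(np.pi * (t[dn] - tr) / (tej - tr)))
        area = 2.0 * tr / np.pi + (tej - tr) / 2.0
    return q * (params.stroke_volume / area)


def _rk4_beat(q_half: np.ndarray, p0: float, dt: float, r: float, c: float
              ) -> tuple[np.ndarray, float]:
    """Fixed-step RK4 over one beat; ``q_half`` holds Q at half-step grid."""
    n = (q_half.size - 1) // 2
    p = p0
    out = np.empty(n)

    def f(p: float, q: float) -> float:
        return (q - p / r) / c

    for i in range(n):
        out[i] = p
        q0, qm, q1 = q_half[2 * i], q_half[2 * i + 1], q_half[2 * i + 2]
        k1 = f(p, q0)
        k2 = f(p + 0.5 * dt * k1, qm)
        k3 = f(p + 0.5 * dt * k2, qm)
        k4 = f(p + dt * k3, q1)
        p += dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return out, p


def simulate_windkessel(params: WindkesselParams
                        ) -> tuple[SampledSignal, SampledSignal]:
    """Periodic steady-state pressure and flow of the windkessel model.

    The windkessel ODE is linear, so under the fixed-step RK4 scheme the
    one-beat state map is affine; its fixed point is solved exactly and
    the emitted beats are periodic to machine precision (no warm-up
    transient survives into the output).
    """
    fs = params.sampling_rate
    dt = 1.0 / fs
    n = int(round(params.period * fs))
    t_half = np.arange(2 * n + 1) * (dt / 2.0)
    # half-step grid wraps around the periodic beat
    q_half = _flow_template(params, np.mod(t_half, params.period))
    q_beat = q_half[0:2 * n:2].copy()

    # affine one-beat map p(T) = a + b p(0): two integrations identify a, b
    _, a = _rk4_beat(q_half, 0.0, dt, params.r_peripheral, params.compliance)
    _, ab = _rk4_beat(q_half, 1.0, dt, params.r_peripheral, params.compliance)
    b = ab - a
    p_star = a / (1.0 - b)
    p_wk, _ = _rk4_beat(q_half, p_star, dt, params.r_peripheral, params.compliance)

    pressure_beat = p_wk + params.zc * q_beat
    pressure = np.tile(pressure_beat, params.n_beats)
    flow = np.tile(q_beat, params.n_beats)
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        pressure = pressure + rng.normal(0, params.noise_sd, pressure.size)
        flow = flow + rng.normal(0, params.noise_sd, flow.size)
    meta = {
        "zc": params.zc,
        "r_peripheral": params.r_peripheral,
        "compliance": params.compliance,
        "heart_rate": params.heart_rate,
        "stroke_volume": params.stroke_volume,
        "samples_per_beat": n,
    }
    return (
        SampledSignal(pressure, fs, units="mmHg", label="windkessel_pressure",
                      meta=dict(meta)),
        SampledSignal(flow, fs, units="mL/s", label="windkessel_flow",
                      meta=dict(meta)),
    )


# ---------------------------------------------------------------------------
# transit-time pair for PWV
# ---------------------------------------------------------------------------

def simulate_delayed_pair(
    template: SampledSignal,
    distance_cm: float,
    true_pwv_cm_s: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[SampledSignal, SampledSignal]:
    """Proximal/distal waveform pair with an embedded transit delay.

    The distal signal is the template shifted by distance/PWV using linear
    interpolation (sub-sample shifts are exact for band-limited content);
    the true delay is recorded in both signals' metadata.
    """
    if distance_cm <= 0 or true_pwv_cm_s <= 0:
        raise InvalidParameterError("distance and PWV must be positive")
    delay = distance_cm / true_pwv_cm_s
    if delay >= PERIOD_BOUNDS[1]:
        raise InvalidParameterError(
            f"delay {delay:.2f} s exceeds one cardiac cycle; "
            "foot pairing would be ambiguous"
        )
    t = template.time
    shifted = np.interp(t - delay, t, template.values,
                        left=template.values[0])
    rng = np.random.default_rng(seed)
    prox = template.values.copy()
    dist = shifted
    if noise_sd > 0:
        prox = prox + rng.normal(0, noise_sd, prox.size)
        dist = dist + rng.normal(0, noise_sd, dist.size)
    meta = {"true_delay_s": delay, "distance_cm": distance_cm,
            "true_pwv_cm_s": true_pwv_cm_s}
    fs = template.sampling_rate
    return (
        SampledSignal(prox, fs, units=template.units, label="proximal",
                      meta=dict(meta)),
        SampledSignal(dist, fs, units=template.units, label="distal",
                      meta=dict(meta)),
    )


# ---------------------------------------------------------------------------
# ECG
# ---------------------------------------------------------------------------

def simulate_ecg(
    heart_rate: float = 60.0,
    duration_s: float = 30.0,
    sampling_rate: float = 250.0,
    r_offset_s: float = 0.05,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SampledSignal:
    """Schematic ECG: narrow Gaussian R waves plus a low, broad T wave."""
    if heart_rate <= 0 or duration_s <= 0:
        raise InvalidParameterError("heart rate and duration must be positive")
    fs = sampling_rate
    t = np.arange(int(round(duration_s * fs))) / fs
    period = 60.0 / heart_rate
    x = np.zeros_like(t)
    r_times = np.arange(r_offset_s, duration_s, period)
    for rt in r_times:
        x += np.exp(-0.5 * ((t - rt) / 0.012) ** 2)
        x += 0.15 * np.exp(-0.5 * ((t - rt - 0.25 * period) / 0.05) ** 2)
    if noise_sd > 0:
        x = x + np.random.default_rng(seed).normal(0, noise_sd, x.size)
    return SampledSignal(
        x, fs, units="mV", label="ecg",
        meta={"heart_rate": heart_rate, "r_times_first": r_offset_s},
    )


# ---------------------------------------------------------------------------
# Doppler velocity envelope
# ---------------------------------------------------------------------------

def _envelope_beat(v_sys: float, v_dia: float, width: float, t_up: float,
                   t: np.ndarray) -> np.ndarray:
    amp = v_sys - v_dia
    out = np.full_like(t, v_dia)
    up = t < t_up
    dn = (t >= t_up) & (t < t_up + width)
    out[up] = v_dia + amp * 0.5 * (1.0 - np.cos(np.pi * t[up] / t_up))
    out[dn] = v_dia + amp * 0.5 * (1.0 + np.cos(np.pi * (t[dn] - t_up) / width))
    return out


def simulate_doppler_envelope(
    v_sys: float,
    v_dia: float,
    v_mean: float,
    heart_rate: float = 60.0,
    duration_s: float = 60.0,
    sampling_rate: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SampledSignal:
    """Quasi-periodic velocity envelope hitting programmed beat statistics.

    Each beat is a raised-cosine upstroke to ``v_sys`` followed by a
    raised-cosine decay back to ``v_dia`` whose width is solved (bisection
    on the sampled beat) so that the beat time-average equals ``v_mean``.
    Triples the template family cannot realise raise an infeasibility
    error naming the violated constraint instead of being silently
    clipped.
    """
    if not v_dia < v_mean:
        raise InfeasibleTargetsError(
            f"require v_dia < v_mean, got v_dia={v_dia}, v_mean={v_mean}"
        )
    if not v_mean < v_sys:
        raise InfeasibleTargetsError(
            f"require v_mean < v_sys, got v_mean={v_mean}, v_sys={v_sys}"
        )
    fs = sampling_rate
    period = 60.0 / heart_rate
    n = int(round(period * fs))
    t = np.arange(n) / fs
    t_up = 0.12 * period
    phi = (v_mean - v_dia) / (v_sys - v_dia)

    def sampled_mean(width: float) -> float:
        return float(_envelope_beat(v_sys, v_dia, width, t_up, t).mean())

    w_max = period - t_up
    # continuous-time solution as the bracket centre
    w0 = 2.0 * phi * period - t_up
    if w0 <= 0 or w0 > w_max or sampled_mean(w_max) < v_mean:
        raise InfeasibleTargetsError(
            f"v_mean={v_mean} not reachable: decay width solves to "
            f"{w0:.3f} s outside (0, {w_max:.3f}] s"
        )
    from scipy.optimize import brentq

    lo = min(max(w0 / 4.0, 2.0 / fs), w_max / 2.0)
    if sampled_mean(lo) > v_mean:
        lo = 1e-3
    width = brentq(lambda w: sampled_mean(w) - v_mean, lo, w_max, xtol=1e-10)
    beat = _envelope_beat(v_sys, v_dia, width, t_up, t)
    n_beats = int(np.ceil(duration_s * fs / n))
    x = np.tile(beat, n_beats)
    if noise_sd > 0:
        x = x + np.random.default_rng(seed).normal(0, noise_sd, x.size)
    return SampledSignal(
        x, fs, units="cm/s", label="doppler_envelope",
        meta={"v_sys": v_sys, "v_dia": v_dia, "v_mean": v_mean,
              "heart_rate": heart_rate, "decay_width_s": width},
    )


# ---------------------------------------------------------------------------
# pressure/flow pair with a programmed reflected wave
# ---------------------------------------------------------------------------

def simulate_pressure_with_reflection(
    zc: float = 0.1,
    reflection: float = 0.3,
    heart_rate: float = 60.0,
    sampling_rate: float = 500.0,
    pf_amplitude: float = 30.0,
    diastolic: float = 75.0,
    reflection_delay_s: float = 0.12,
    onset_s: float = 0.05,
    pulse_width_s: float = 0.33,
    n_beats: int = 1,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[SampledSignal, SampledSignal]:
    """Pressure and flow built from explicit forward and backward waves.

    The forward pressure wave is a smooth sin^2 pulse of amplitude
    ``pf_amplitude``; the backward wave is the same pulse scaled by
    ``reflection`` and delayed by ``reflection_delay_s``. Flow is
    (Pf - Pb)/Zc, so both the characteristic impedance and the reflection
    index of the pair are known exactly. Units: mmHg and mL/s.
    """
    if zc <= 0 or not 0 <= reflection:
        raise InvalidParameterError("zc must be positive, reflection >= 0")
    fs = sampling_rate
    period = 60.0 / heart_rate
    n = int(round(period * fs))
    t = np.arange(n) / fs

    def pulse(tt: np.ndarray) -> np.ndarray:
        g = np.zeros_like(tt)
        m = (tt >= onset_s) & (tt <= onset_s + pulse_width_s)
        g[m] = np.sin(np.pi * (tt[m] - onset_s) / pulse_width_s) ** 2
        return g

    pf = pf_amplitude * pulse(t)
    pb = reflection * pf_amplitude * pulse(t - reflection_delay_s)
    p = diastolic + pf + pb
    q = (pf - pb) / zc
    p = np.tile(p, n_beats)
    q = np.tile(q, n_beats)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        p = p + rng.normal(0, noise_sd, p.size)
        q = q + rng.normal(0, noise_sd, q.size)
    meta = {"zc": zc, "reflection": reflection, "pf_amplitude": pf_amplitude,
            "reflection_delay_s": reflection_delay_s, "heart_rate": heart_rate,
            "samples_per_beat": n}
    return (
        SampledSignal(p, fs, units="mmHg", label="pressure_with_reflection",
                      meta=dict(meta)),
        SampledSignal(q, fs, units="mL/s", label="flow_with_reflection",
                      meta=dict(meta)),
    )


# ---------------------------------------------------------------------------
# breath-hold session
# ---------------------------------------------------------------------------

def simulate_breath_hold_session(
    etco2_baseline: float = 39.0,
    delta_etco2_true: float = 8.0,
    mcav_baseline: float = 60.0,
    cvr_true: float = 1.5,
    sampling_rate: float = 25.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    schedule: ProtocolSchedule | None = None,
) -> tuple[SampledSignal, SampledSignal, ProtocolSchedule]:
    """Capnograph and MCA mean-velocity traces for the paced-breathing
    breath-hold protocol.

    Each paced breath carries an expiratory plateau at ``etco2_baseline``;
    the first post-hold breath plateaus at baseline + ``delta_etco2_true``
    and later recovery breaths relax back exponentially. MCA velocity
    climbs during the hold to a plateau of
    baseline + ``cvr_true * delta_etco2_true`` held long enough (> 3 s)
    that the pipeline's moving-average peak recovers it exactly at zero
    noise. The end-tidal trace is emitted as a continuous capnogram, not
    pre-extracted plateau values, so the analysis stage must find the
    plateaus itself.
    """
    if etco2_baseline <= 0 or mcav_baseline <= 0:
        raise InvalidParameterError("baselines must be positive")
    if cvr_true < 0 or delta_etco2_true < 0:
        raise InvalidParameterError("delta and reactivity must be >= 0")
    schedule = schedule or ProtocolSchedule()
    fs = sampling_rate
    n = int(round((schedule.total_s + 2.0) * fs))
    t = np.arange(n) / fs
    insp = 4.0  # inspired CO2 partial pressure floor, mmHg
    etco2 = np.full(n, insp, dtype=float)
    mcav = np.full(n, mcav_baseline, dtype=float)

    def breath(start: float, plateau: float) -> None:
        """One capnogram breath: rise, expiratory plateau, fall."""
        d = schedule.breath_s
        seg = (t >= start) & (t < start + d)
        tau = t[seg] - start
        y = np.full(tau.size, insp)
        rise = (tau >= 0.3) & (tau < 0.8)
        y[rise] = insp + (plateau - insp) * 0.5 * (
            1 - np.cos(np.pi * (tau[rise] - 0.3) / 0.5)
        )
        top = (tau >= 0.8) & (tau < d - 1.0)
        y[top] = plateau
        fall = (tau >= d - 1.0) & (tau < d - 0.5)
        y[fall] = insp + (plateau - insp) * 0.5 * (
            1 + np.cos(np.pi * (tau[fall] - (d - 1.0)) / 0.5)
        )
        etco2[seg] = y

    dv_peak = cvr_true * delta_etco2_true
    for r in range(schedule.n_repeats):
        for a, _b in schedule.breath_windows(r):
            breath(a, etco2_baseline)
        h0, h1 = schedule.hold_window(r)
        # recovery breathing at the paced rate, relaxing back to baseline
        n_rec = int(schedule.recovery_s // schedule.breath_s)
        for k in range(n_rec):
            start = h1 + k * schedule.breath_s
            if k == 0:
                plateau = etco2_baseline + delta_etco2_true
            else:
                plateau = etco2_baseline + delta_etco2_true * np.exp(
                    -(k * schedule.breath_s) / 12.0
                )
            breath(start, plateau)
        # MCAv: raised-cosine climb through the hold, 5 s plateau, decay
        climb = (t >= h0 + 4.0) & (t < h1)
        mcav[climb] += dv_peak * 0.5 * (
            1 - np.cos(np.pi * (t[climb] - h0 - 4.0) / (schedule.hold_s - 4.0))
        )
        plateau_m = (t >= h1) & (t < h1 + 5.0)
        mcav[plateau_m] += dv_peak
        decay = (t >= h1 + 5.0) & (t < h1 + 15.0)
        mcav[decay] += dv_peak * 0.5 * (
            1 + np.cos(np.pi * (t[decay] - h1 - 5.0) / 10.0)
        )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        etco2 = etco2 + rng.normal(0, noise_sd, n)
        mcav = mcav + rng.normal(0, noise_sd, n)
    meta = {"etco2_baseline": etco2_baseline,
            "delta_etco2_true": delta_etco2_true,
            "mcav_baseline": mcav_baseline, "cvr_true": cvr_true}
    return (
        SampledSignal(etco2, fs, units="mmHg", label="etco2", meta=dict(meta)),
        SampledSignal(mcav, fs, units="cm/s", label="mcav", meta=dict(meta)),
        schedule,
    )


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Cell means/SDs for a two-group by three-time repeated-measures design.

    ``cells`` maps outcome -> {(group, time): (mean, sd)}. Within-subject
    dependence follows a compound-symmetry random-intercept model: a
    subject-level standard-normal intercept weighted by
    sqrt(within_subject_correlation) plus independent residual noise, each
    scaled by the cell SD, which induces the requested correlation between
    any two time points of the same subject.
    """

    cells: dict
    n_per_group: dict | int
    within_subject_correlation: float = 0.5
    times: tuple = STUDY_TIMES
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.within_subject_correlation < 1:
            raise InvalidParameterError("correlation must be in [0, 1)")
        if tuple(self.times) != STUDY_TIMES:
            raise InvalidParameterError(
                f"times must be exactly {STUDY_TIMES}, got {self.times}"
            )
        groups = sorted({g for cell in self.cells.values() for g, _ in cell})
        if isinstance(self.n_per_group, int):
            self.n_per_group = {g: self.n_per_group for g in groups}
        for outcome, cell in self.cells.items():
            for g in groups:
                for tm in self.times:
                    if (g, tm) not in cell:
                        raise InvalidParameterError(
                            f"outcome {outcome!r} missing cell ({g}, {tm})"
                        )
                    if cell[(g, tm)][1] < 0:
                        raise InvalidParameterError("cell SD must be >= 0")

    @property
    def groups(self) -> list[str]:
        return sorted(self.n_per_group)


def simulate_cohort(spec: CohortSpec):
    """Long-format study table (subject, group, time, outcome, value)."""
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    rho = spec.within_subject_correlation
    rows = []
    for group in spec.groups:
        n = spec.n_per_group[group]
        for i in range(n):
            sid = f"{group}{i:03d}"
            for outcome, cell in spec.cells.items():
                z = rng.standard_normal()
                for tm in spec.times:
                    mean, sd = cell[(group, tm)]
                    e = rng.standard_normal()
                    value = mean + sd * (
                        np.sqrt(rho) * z + np.sqrt(1.0 - rho) * e
                    )
                    rows.append((sid, group, tm, outcome, value))
    return pd.DataFrame(
        rows, columns=["subject", "group", "time", "outcome", "value"]
    )
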