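"""Visit-level pipeline and whole-study orchestration.

A visit is one subject at one time point (baseline, 30 or 60 min after
the meal) with its battery of recordings. :func:`run_visit` executes
calibration -> stiffness/impedance -> Doppler -> reactivity in order and
emits one flat metrics row; any stage failure nulls that stage's metrics
with an error code instead of producing silent partial values.
:func:`simulate_study` writes a complete synthetic cohort (two groups,
three times) to disk with group-by-time parameter structure patterned on
a high-sugar meal challenge in young versus middle-aged adults, so the
whole pipeline — through the study table and the group-by-time ANOVA —
runs end to end without any real recordings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibrate, cvr, doppler, stiffness, synthetic
from .errors import HemopulseError, IntegrityError
from .io import PipelineConfig, read_waveform_csv, write_waveform_csv
from .signal import detect_beats, ensemble_average
from .stats import validate_study_table

log = logging.getLogger(__name__)

SIGNAL_KEYS = (
    "ecg", "brachial_pressure", "carotid_pressure", "femoral_pressure",
    "carotid_velocity", "mca_velocity", "etco2", "mcav",
)


@dataclass
class VisitRecord:
    """Paths and scalar inputs for one subject-time assessment."""

    subject_id: str
    group: str
    time: str  # {"baseline", "30", "60"}
    paths: dict  # signal key -> CSV path (missing keys allowed)
    cuff_readings: list  # [(systolic, diastolic), ...]
    d_sys_mm: float | None = None
    d_dia_mm: float | None = None
    path_distance_cm: float | None = None
    glucose: float | None = None
    insulin: float | None = None

    def __post_init__(self) -> None:
        if self.time not in synthetic.STUDY_TIMES:
            raise IntegrityError(
                f"time must be one of {synthetic.STUDY_TIMES}, got {self.time!r}"
            )


def _stage(row: dict, errors: dict, keys: tuple, fn) -> None:
    """Run one stage; on a pipeline error, null its keys and record the code."""
    try:
        row.update(fn())
    except (HemopulseError, FileNotFoundError, KeyError) as exc:
        code = getattr(exc, "code", type(exc).__name__)
        for k in keys:
            row.setdefault(k, None)
            errors[k] = code
        log.warning("visit stage failed (%s): %s", code, exc)


def run_visit(visit: VisitRecord, config: PipelineConfig | None = None) -> dict:
    """Execute the full metric battery for one visit.

    Returns a flat dict with one entry per metric plus ``errors`` (metric
    key -> error code for every null) and identification columns.
    """
    config = config or PipelineConfig()
    row: dict = {
        "subject": visit.subject_id,
        "group": visit.group,
        "time": visit.time,
    }
    errors: dict = {}
    sig: dict = {}
    for key, p in visit.paths.items():
        try:
            sig[key] = read_waveform_csv(p)
        except (HemopulseError, FileNotFoundError) as exc:
            log.warning("visit %s/%s: cannot read %s: %s",
                        visit.subject_id, visit.time, key, exc)

    beats = None
    if "ecg" in sig:
        try:
            beats = detect_beats(sig["ecg"], "r_wave")
        except HemopulseError as exc:
            log.warning("ECG gating failed: %s", exc)

    def need(key):
        if key not in sig:
            raise KeyError(f"signal {key!r} unavailable")
        return sig[key]

    # --- brachial calibration and MAP -----------------------------------
    state: dict = {}

    def brachial():
        if beats is None:
            raise KeyError("no ECG gating")
        cuff = calibrate.reconcile_cuff_readings(
            [calibrate.CuffReading(*c) for c in visit.cuff_readings],
            config.cuff_tolerance_mmhg,
        )
        raw = ensemble_average(need("brachial_pressure"), beats,
                               epoch_s=config.epoch_s,
                               artifact_sd=config.artifact_sd)
        cal = calibrate.calibrate_brachial(raw, cuff)
        state["map"] = calibrate.derive_map(cal, config.map_method)
        state["dbp"] = cal.diastolic
        return {
            "heart_rate": 60.0 / float(np.mean(beats.periods())),
            "brachial_systolic": cal.systolic,
            "brachial_diastolic": cal.diastolic,
            "map": state["map"],
        }

    _stage(row, errors,
           ("heart_rate", "brachial_systolic", "brachial_diastolic", "map"),
           brachial)

    def carotid_pressure():
        if "map" not in state:
            raise KeyError("brachial calibration unavailable")
        raw = ensemble_average(need("carotid_pressure"), beats,
                               epoch_s=config.epoch_s,
                               artifact_sd=config.artifact_sd)
        cal = calibrate.calibrate_carotid(raw, state["dbp"], state["map"])
        state["carotid_beat"] = cal
        return {
            "carotid_systolic": cal.systolic,
            "carotid_diastolic": cal.diastolic,
            "carotid_pulse_pressure": cal.pulse_pressure,
        }

    _stage(row, errors,
           ("carotid_systolic", "carotid_diastolic", "carotid_pulse_pressure"),
           carotid_pressure)

    # --- aortic and carotid stiffness ------------------------------------
    def aortic():
        if beats is None:
            raise KeyError("no ECG gating")
        if visit.path_distance_cm is None:
            raise KeyError("path distance unavailable")
        res = stiffness.cfpwv(need("carotid_pressure"),
                              need("femoral_pressure"), beats,
                              visit.path_distance_cm)
        return {"cfpwv": res.cfpwv, "transit_time": res.transit_time}

    _stage(row, errors, ("cfpwv", "transit_time"), aortic)

    def beta():
        cal = state.get("carotid_beat")
        if cal is None or visit.d_sys_mm is None or visit.d_dia_mm is None:
            raise KeyError("carotid pressures or diameters unavailable")
        return {
            "beta_stiffness": stiffness.beta_stiffness(
                cal.systolic, cal.diastolic, visit.d_sys_mm, visit.d_dia_mm
            ),
            "carotid_diameter": visit.d_dia_mm,
        }

    _stage(row, errors, ("beta_stiffness", "carotid_diameter"), beta)

    # --- carotid haemodynamics and wave mechanics ------------------------
    def carotid_doppler():
        v = need("carotid_velocity")
        m = doppler.summarize(v, doppler.EpochPlan.carotid())
        state["carotid_velocity_metrics"] = m
        return {
            "carotid_v_sys": m.v_sys, "carotid_v_dia": m.v_dia,
            "carotid_v_mean": m.v_mean, "carotid_pi": m.pi,
        }

    _stage(row, errors,
           ("carotid_v_sys", "carotid_v_dia", "carotid_v_mean", "carotid_pi"),
           carotid_doppler)

    def wave_mechanics():
        cal = state.get("carotid_beat")
        if cal is None or visit.d_dia_mm is None:
            raise KeyError("carotid pressure beat or diameter unavailable")
        v = need("carotid_velocity")
        vbeats = detect_beats(v, "foot")
        vbeat = ensemble_average(v, vbeats, artifact_sd=config.artifact_sd)
        flow = stiffness.volumetric_flow(vbeat, visit.d_dia_mm)
        flow = stiffness.align_flow_to_pressure(cal.beat, flow)
        zc = stiffness.characteristic_impedance(cal.beat, flow)
        sep = stiffness.wave_separation(cal.beat, flow, zc)
        return {
            "zc": zc,
            "pf_amplitude": sep.pf_amplitude,
            "pb_amplitude": sep.pb_amplitude,
            "reflection_index": sep.reflection_index,
        }

    _stage(row, errors,
           ("zc", "pf_amplitude", "pb_amplitude", "reflection_index"),
           wave_mechanics)

    # --- MCA haemodynamics ------------------------------------------------
    def mca():
        v = need("mca_velocity")
        m = doppler.summarize(v, doppler.EpochPlan.mca(),
                              map_mmhg=state.get("map"))
        out = {
            "mca_v_sys": m.v_sys, "mca_v_dia": m.v_dia,
            "mca_v_mean": m.v_mean, "mca_pi": m.pi, "mca_ri": m.ri,
            "mca_conductance": m.conductance,
        }
        state["mca_v_mean"] = m.v_mean
        return out

    _stage(row, errors,
           ("mca_v_sys", "mca_v_dia", "mca_v_mean", "mca_pi", "mca_ri",
            "mca_conductance"), mca)

    # --- cerebrovascular reactivity --------------------------------------
    def reactivity():
        res = cvr.analyze_session(need("etco2"), need("mcav"))
        out = {
            "cvr_abs": res.cvr_abs,
            "cvr_rel": res.cvr_rel,
            "cvr_baseline_mcav": res.baseline_mcav,
        }
        if res.excluded_repeats:
            errors["cvr_repeats_excluded"] = str(res.excluded_repeats)
        return out

    _stage(row, errors, ("cvr_abs", "cvr_rel", "cvr_baseline_mcav"),
           reactivity)

    def etco2_rest():
        sched = cvr.ProtocolSchedule()
        ets = cvr.extract_end_tidal(need("etco2"), sched, 0)
        val = float(np.mean(ets[-2:]))
        out = {"etco2": val}
        if state.get("mca_v_mean") is not None and val > 0:
            out["mcav_etco2_ratio"] = state["mca_v_mean"] / val
        else:
            out["mcav_etco2_ratio"] = None
        return out

    _stage(row, errors, ("etco2", "mcav_etco2_ratio"), etco2_rest)

    row["glucose"] = visit.glucose
    row["insulin"] = visit.insulin
    row["errors"] = errors
    return row


METRIC_COLUMNS = (
    "heart_rate", "brachial_systolic", "brachial_diastolic", "map",
    "carotid_systolic", "carotid_diastolic", "carotid_pulse_pressure",
    "cfpwv", "transit_time", "beta_stiffness", "carotid_diameter",
    "carotid_v_sys", "carotid_v_dia", "carotid_v_mean", "carotid_pi",
    "zc", "pf_amplitude", "pb_amplitude", "reflection_index",
    "mca_v_sys", "mca_v_dia", "mca_v_mean", "mca_pi", "mca_ri",
    "mca_conductance", "cvr_abs", "cvr_rel", "etco2", "mcav_etco2_ratio",
    "glucose", "insulin",
)


def build_study_table(rows: list[dict],
                      outcomes: tuple = METRIC_COLUMNS) -> pd.DataFrame:
    """Long-format study table from visit rows; duplicate keys rejected."""
    if not rows:
        raise IntegrityError("no visit rows")
    records = []
    for row in rows:
        for outcome in outcomes:
            records.append((
                row["subject"], row["group"], row["time"], outcome,
                row.get(outcome),
            ))
    table = pd.DataFrame(
        records, columns=["subject", "group", "time", "outcome", "value"]
    )
    return validate_study_table(table)


# ---------------------------------------------------------------------------
# synthetic study generation
# ---------------------------------------------------------------------------

def _cells(ya: tuple, ma: tuple, sd_ya: float, sd_ma: float | None = None):
    sd_ma = sd_ya if sd_ma is None else sd_ma
    out = {}
    for tm, v in zip(synthetic.STUDY_TIMES, ya):
        out[("YA", tm)] = (v, sd_ya)
    for tm, v in zip(synthetic.STUDY_TIMES, ma):
        out[("MA", tm)] = (v, sd_ma)
    return out


#: group-by-time ground-truth parameter cells (mean, SD) for the synthetic
#: cohort: young healthy adults (YA) versus middle-aged adults with
#: cardiometabolic risk factors (MA) at baseline and 30/60 min after a
#: high-sugar mixed meal. Magnitudes and directions of change follow the
#: meal-challenge phenotype: carotid dilatation with falling stiffness and
#: impedance in both groups, MCA pulsatility and reactivity rising in the
#: young group only.
PARAM_CELLS = {
    "heart_rate": _cells((56, 63, 65), (59, 63, 65), 7, 6),
    "cuff_systolic": _cells((110, 109, 107), (128, 124, 123), 8),
    "cuff_diastolic": _cells((70, 69, 68), (80, 78, 78), 5),
    "pwv_true": _cells((527, 516, 515), (753, 729, 742), 80, 150),
    "strain": _cells((0.099, 0.104, 0.106), (0.052, 0.057, 0.060), 0.012,
                     0.008),
    "d_dia": _cells((5.3, 5.4, 5.5), (5.7, 5.6, 5.7), 0.4, 0.5),
    "refl_true": _cells((0.32, 0.28, 0.27), (0.33, 0.29, 0.28), 0.05),
    "pf_true": _cells((27, 29, 27), (33, 30, 29), 4),
    "car_v_mean": _cells((42, 41, 41), (43, 42, 40), 5),
    "car_sys_ratio": _cells((2.48, 2.76, 2.76), (1.95, 2.14, 2.15), 0.12),
    "car_dia_ratio": _cells((0.64, 0.59, 0.61), (0.63, 0.60, 0.60), 0.04),
    "mca_v_mean": _cells((63, 65, 63), (56, 58, 57), 14),
    "mca_sys_ratio": _cells((1.56, 1.63, 1.62), (1.59, 1.62, 1.60), 0.08),
    "mca_dia_ratio": _cells((0.73, 0.69, 0.70), (0.71, 0.71, 0.68), 0.04),
    "etco2_base": _cells((39, 39, 39), (40, 40, 39), 3),
    "delta_etco2": _cells((8, 8, 8), (8, 8, 8), 1.2),
    "cvr_true": _cells((1.30, 1.60, 1.45), (1.20, 1.10, 1.05), 0.25),
    "glucose": _cells((73.8, 100.9, 81.1), (86.5, 109.9, 100.9), 18, 15),
    "insulin": _cells((302.6, 1997.6, 1169.6), (483.5, 1991.3, 1183.0),
                      380, 470),
}

#: within-subject correlation of the subject-level random intercepts
SUBJECT_RHO = 0.7


def _draw_subject_params(group: str, rng: np.random.Generator) -> dict:
    """Per-subject z-scores, one per parameter, shared across time points."""
    return {name: rng.standard_normal() for name in PARAM_CELLS}


def _visit_params(group: str, time: str, z: dict,
                  rng: np.random.Generator) -> dict:
    rho = SUBJECT_RHO
    out = {}
    for name, cells in PARAM_CELLS.items():
        mean, sd = cells[(group, time)]
        val = mean + sd * (np.sqrt(rho) * z[name]
                           + np.sqrt(1 - rho) * rng.standard_normal())
        out[name] = val
    # physical guards
    out["heart_rate"] = float(np.clip(out["heart_rate"], 45, 100))
    out["cuff_diastolic"] = max(out["cuff_diastolic"], 50.0)
    out["cuff_systolic"] = max(out["cuff_systolic"],
                               out["cuff_diastolic"] + 20.0)
    out["pwv_true"] = max(out["pwv_true"], 300.0)
    out["strain"] = float(np.clip(out["strain"], 0.02, 0.25))
    out["d_dia"] = max(out["d_dia"], 4.0)
    out["refl_true"] = float(np.clip(out["refl_true"], 0.05, 0.8))
    out["pf_true"] = max(out["pf_true"], 10.0)
    out["delta_etco2"] = max(out["delta_etco2"], 2.0)
    out["cvr_true"] = max(out["cvr_true"], 0.1)
    out["glucose"] = max(out["glucose"], 50.0)
    out["insulin"] = max(out["insulin"], 50.0)
    for site in ("car", "mca"):
        out[f"{site}_v_mean"] = max(out[f"{site}_v_mean"], 20.0)
        out[f"{site}_sys_ratio"] = max(out[f"{site}_sys_ratio"], 1.25)
        out[f"{site}_dia_ratio"] = float(
            np.clip(out[f"{site}_dia_ratio"], 0.30, 0.85)
        )
        # envelope feasibility: the beat-mean fraction
        # (1 - dia)/(sys - dia) must stay below 1/2 with margin, or the
        # raised-cosine decay cannot fit inside the cycle
        dia = out[f"{site}_dia_ratio"]
        out[f"{site}_sys_ratio"] = max(
            out[f"{site}_sys_ratio"], dia + (1.0 - dia) / 0.45
        )
    return out


def simulate_visit_files(directory: str | Path, subject_id: str, group: str,
                         time: str, params: dict, seed: int,
                         noise_sd: float = 0.5) -> VisitRecord:
    """Generate and write the full recording battery for one visit."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    hr = params["heart_rate"]
    sub = np.random.SeedSequence(seed).spawn(8)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in sub]

    ecg = synthetic.simulate_ecg(hr, duration_s=24.0, sampling_rate=250.0,
                                 noise_sd=0.02 * noise_sd, seed=seeds[0])

    n_beats = int(np.ceil(24.0 * hr / 60.0))
    wk = synthetic.WindkesselParams(
        zc=0.06, r_peripheral=1.1, compliance=1.5, heart_rate=hr,
        stroke_volume=70.0, sampling_rate=250.0, n_beats=n_beats,
        noise_sd=0.0, seed=0,
    )
    wk_pressure, _ = synthetic.simulate_windkessel(wk)
    n = wk_pressure.meta["samples_per_beat"]
    rng_noise = np.random.default_rng(seeds[1])
    brachial = synthetic.SampledSignal(
        wk_pressure.values + rng_noise.normal(0, noise_sd,
                                              wk_pressure.values.size),
        250.0, units="a.u.", label="brachial_tonometry",
    )

    # carotid pressure and velocity are built from the same propagating
    # pulse: a windkessel-shaped forward wave plus a delayed, scaled
    # backward wave. Pressure sums the two components while flow takes
    # their difference, so the measured impedance and reflection index of
    # the pair are physiologically coherent.
    beat = wk_pressure.values[:n]
    pulse = beat - beat.min()
    # place the upstroke 0.2 s into the beat so that R-gated segments
    # (R wave 0.05 s into the cycle) keep both the carotid foot and the
    # transit-delayed femoral foot inside one segment
    pulse = np.roll(pulse, int(round(0.20 * 250.0)))
    pf_beat = params["pf_true"] * pulse / pulse.max()
    delay_samples = int(round(0.12 * 250.0))
    pb_beat = params["refl_true"] * np.roll(pf_beat, delay_samples)
    carotid_beat = params["cuff_diastolic"] + pf_beat + pb_beat
    carotid_p = synthetic.SampledSignal(
        np.tile(carotid_beat, n_beats)
        + rng_noise.normal(0, noise_sd, n * n_beats),
        250.0, units="a.u.", label="carotid_tonometry",
        meta={"refl_true": params["refl_true"],
              "pf_true": params["pf_true"]},
    )
    carotid_site, femoral_site = synthetic.simulate_delayed_pair(
        carotid_p, params.get("path_distance_cm", 60.0), params["pwv_true"],
        noise_sd=0.2 * noise_sd, seed=seeds[3],
    )
    carotid_site.units = femoral_site.units = "a.u."

    q_beat = pf_beat - pb_beat
    fs_vel = 100.0
    n_vel = int(round(n * fs_vel / 250.0))
    q_vel = np.interp(np.linspace(0, 1, n_vel, endpoint=False),
                      np.linspace(0, 1, n, endpoint=False), q_beat)
    v_sys = params["car_v_mean"] * params["car_sys_ratio"]
    v_dia = params["car_v_mean"] * params["car_dia_ratio"]
    vel_beat = v_dia + (v_sys - v_dia) * q_vel / q_vel.max()
    n_beats_vel = int(np.ceil(26.0 * fs_vel / n_vel))
    vel_vals = np.tile(vel_beat, n_beats_vel)
    rng_vel = np.random.default_rng(seeds[4])
    if noise_sd > 0:
        vel_vals = vel_vals + rng_vel.normal(0, 0.5 * noise_sd,
                                             vel_vals.size)
    car_vel = synthetic.SampledSignal(
        vel_vals, fs_vel, units="cm/s", label="carotid_velocity",
        meta={"v_sys": v_sys, "v_dia": v_dia,
              "refl_true": params["refl_true"]},
    )
    mca_vel = synthetic.simulate_doppler_envelope(
        v_sys=params["mca_v_mean"] * params["mca_sys_ratio"],
        v_dia=params["mca_v_mean"] * params["mca_dia_ratio"],
        v_mean=params["mca_v_mean"], heart_rate=hr, duration_s=122.0,
        sampling_rate=100.0, noise_sd=0.5 * noise_sd, seed=seeds[5],
    )
    etco2, mcav, _ = synthetic.simulate_breath_hold_session(
        etco2_baseline=params["etco2_base"],
        delta_etco2_true=params["delta_etco2"],
        mcav_baseline=params["mca_v_mean"], cvr_true=params["cvr_true"],
        sampling_rate=25.0, noise_sd=0.2 * noise_sd, seed=seeds[6],
    )

    signals = {
        "ecg": ecg, "brachial_pressure": brachial,
        "carotid_pressure": carotid_site, "femoral_pressure": femoral_site,
        "carotid_velocity": car_vel, "mca_velocity": mca_vel,
        "etco2": etco2, "mcav": mcav,
    }
    paths = {}
    for key, s in signals.items():
        p = directory / f"{key}.csv"
        write_waveform_csv(s, p)
        paths[key] = p

    rng = np.random.default_rng(seeds[7])
    jitter = rng.uniform(-2, 2, size=2)
    cuffs = [
        (params["cuff_systolic"], params["cuff_diastolic"]),
        (params["cuff_systolic"] + jitter[0],
         params["cuff_diastolic"] + jitter[1]),
    ]
    return VisitRecord(
        subject_id=subject_id, group=group, time=time, paths=paths,
        cuff_readings=cuffs,
        d_sys_mm=params["d_dia"] * (1.0 + params["strain"]),
        d_dia_mm=params["d_dia"],
        path_distance_cm=params.get("path_distance_cm", 60.0),
        glucose=params["glucose"], insulin=params["insulin"],
    )


def simulate_study(root: str | Path, n_ya: int = 21, n_ma: int = 20,
                   seed: int = 0, noise_sd: float = 0.5
                   ) -> list[VisitRecord]:
    """Write a full synthetic two-group, three-time study to ``root``."""
    root = Path(root)
    records = []
    top = np.random.SeedSequence(seed)
    group_seqs = dict(zip(("YA", "MA"), top.spawn(2)))
    for group, n in (("YA", n_ya), ("MA", n_ma)):
        subj_seqs = group_seqs[group].spawn(n)
        for i, sseq in enumerate(subj_seqs):
            sid = f"{group}{i:03d}"
            streams = sseq.spawn(len(synthetic.STUDY_TIMES) + 1)
            rng_subject = np.random.default_rng(streams[0])
            z = _draw_subject_params(group, rng_subject)
            distance = float(rng_subject.normal(60.0, 5.0))
            for j, tm in enumerate(synthetic.STUDY_TIMES):
                rng_visit = np.random.default_rng(streams[j + 1])
                params = _visit_params(group, tm, z, rng_visit)
                params["path_distance_cm"] = max(distance, 40.0)
                vseed = int(streams[j + 1].generate_state(2)[1] % (2**31))
                rec = simulate_visit_files(
                    root / sid / tm, sid, group, tm, params, seed=vseed,
                    noise_sd=noise_sd,
                )
                records.append(rec)
    return records


def run_study(records: list[VisitRecord],
              config: PipelineConfig | None = None) -> pd.DataFrame:
    """Run every visit and assemble the long-format study table."""
    rows = [run_visit(rec, config) for rec in records]
    return build_study_table(rows)
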