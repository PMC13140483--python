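"""Cuff calibration of tonometric pressure waveforms.

Brachial tonometry is calibrated to the brachial cuff systolic/diastolic
pair. Brachial diastolic and mean (time-averaged) pressure are then used
to calibrate the carotid waveform, whose systolic pressure is an output of
the transfer, not an input. Both calibrations are affine, so waveform
shape is preserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateShapeError,
    InvalidParameterError,
    ZeroAmplitudeError,
)
from .signal import EnsembleBeat, signal_mean


@dataclass
class CuffReading:
    """Oscillometric brachial cuff pressures in mmHg."""

    systolic: float
    diastolic: float

    def __post_init__(self) -> None:
        if not (self.systolic > self.diastolic > 0):
            raise InvalidParameterError(
                f"require systolic > diastolic > 0, got "
                f"{self.systolic}/{self.diastolic}"
            )


@dataclass
class CalibratedPressureBeat:
    """A pressure beat in mmHg with its summary pressures."""

    beat: EnsembleBeat
    systolic: float
    diastolic: float
    mean: float
    pulse_pressure: float
    site: str

    @classmethod
    def from_beat(cls, beat: EnsembleBeat, site: str) -> "CalibratedPressureBeat":
        v = beat.values
        sys_, dia = float(v.max()), float(v.min())
        return cls(
            beat=beat,
            systolic=sys_,
            diastolic=dia,
            mean=signal_mean(beat),
            pulse_pressure=sys_ - dia,
            site=site,
        )


def reconcile_cuff_readings(
    readings: list[CuffReading], tolerance_mmhg: float = 5.0
) -> CuffReading:
    """Average the first consecutive duplicate pair agreeing within tolerance.

    Mirrors the screening rule of repeating cuff measurements until two
    consecutive readings agree within 5 mmHg, then averaging them.
    """
    if len(readings) < 2:
        raise InvalidParameterError("need at least two cuff readings")
    for a, b in zip(readings[:-1], readings[1:]):
        if (
            abs(a.systolic - b.systolic) <= tolerance_mmhg
            and abs(a.diastolic - b.diastolic) <= tolerance_mmhg
        ):
            return CuffReading(
                (a.systolic + b.systolic) / 2.0,
                (a.diastolic + b.diastolic) / 2.0,
            )
    raise InvalidParameterError(
        f"no consecutive cuff readings agree within {tolerance_mmhg} mmHg"
    )


def calibrate_brachial(
    raw: EnsembleBeat, cuff: CuffReading
) -> CalibratedPressureBeat:
    """Affine-map a raw brachial beat so min -> cuff diastolic, max -> cuff systolic."""
    v = raw.values
    amp = v.max() - v.min()
    if amp <= 0:
        raise ZeroAmplitudeError("flat brachial beat cannot be calibrated")
    scale = (cuff.systolic - cuff.diastolic) / amp
    cal = cuff.diastolic + (v - v.min()) * scale
    beat = EnsembleBeat(cal, raw.sampling_rate, raw.n_beats_averaged, units="mmHg")
    return CalibratedPressureBeat.from_beat(beat, site="brachial")


def derive_map(
    brachial: CalibratedPressureBeat, method: str = "integral"
) -> float:
    """Mean arterial pressure from the calibrated brachial beat.

    ``integral`` (default) is the time-average of the waveform over one
    full cycle. ``form_factor`` is the conventional
    diastolic + pulse pressure / 3 approximation, offered for comparison.
    """
    if method == "integral":
        return signal_mean(brachial.beat)
    if method == "form_factor":
        return brachial.diastolic + brachial.pulse_pressure / 3.0
    raise InvalidParameterError(f"unknown MAP method {method!r}")


def calibrate_carotid(
    raw_carotid: EnsembleBeat, brachial_diastolic: float, brachial_map: float
) -> CalibratedPressureBeat:
    """Affine-map a raw carotid beat so min -> brachial diastolic and
    mean -> brachial MAP; carotid systolic pressure is the mapped maximum.

    Diastolic/mean anchoring is the standard tonometric transfer: diastolic
    and mean pressure are nearly constant along the large arteries, whereas
    systolic pressure amplifies peripherally and so cannot be carried over.
    """
    if brachial_map <= brachial_diastolic:
        raise InvalidParameterError("brachial MAP must exceed brachial diastolic")
    v = raw_carotid.values
    spread = v.mean() - v.min()
    if spread <= 0:
        raise DegenerateShapeError(
            "carotid beat mean equals its minimum; two-point anchor is singular"
        )
    scale = (brachial_map - brachial_diastolic) / spread
    cal = brachial_diastolic + (v - v.min()) * scale
    beat = EnsembleBeat(
        cal, raw_carotid.sampling_rate, raw_carotid.n_beats_averaged, units="mmHg"
    )
    return CalibratedPressureBeat.from_beat(beat, site="carotid")
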