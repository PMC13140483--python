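"""Waveform CSV dialect and pipeline configuration.

Waveform files are two-column CSV (``time_s,value``) preceded by ``#``
metadata lines carrying units, sampling rate, label and any ground-truth
parameters. Values round-trip bit-exactly (shortest-repr float
formatting); the time column must be uniform against the declared
sampling rate within 1 ppm.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from .errors import FormatError
from .signal import SampledSignal

KNOWN_UNITS = {"mmHg", "cm/s", "mL/s", "mV", "a.u."}


def write_waveform_csv(signal: SampledSignal, path: str | Path) -> None:
    """Write a signal with metadata headers; values round-trip bit-exactly."""
    path = Path(path)
    fs = signal.sampling_rate
    lines = [
        f"# units={signal.units}",
        f"# sampling_rate={fs!r}",
        f"# label={signal.label}",
    ]
    for k, v in signal.meta.items():
        v = float(v) if isinstance(v, (float, np.floating)) else v
        lines.append(f"# meta_{k}={v!r}" if isinstance(v, float) else f"# meta_{k}={v}")
    lines.append("time_s,value")
    for i, v in enumerate(signal.values):
        lines.append(f"{i / fs!r},{float(v)!r}")
    path.write_text("\n".join(lines) + "\n")


def _parse_meta_value(s: str):
    for cast in (int, float):
        try:
            return cast(s)
        except ValueError:
            continue
    return s


def read_waveform_csv(path: str | Path) -> SampledSignal:
    """Read a waveform CSV, validating metadata and time-base uniformity."""
    path = Path(path)
    header: dict[str, str] = {}
    times, values = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" not in body:
                    raise FormatError(f"{path}: malformed header line {line!r}")
                k, v = body.split("=", 1)
                header[k.strip()] = v.strip()
            elif line.startswith("time_s"):
                continue
            else:
                try:
                    t_str, v_str = line.split(",")
                    times.append(float(t_str))
                    values.append(float(v_str))
                except ValueError as exc:
                    raise FormatError(f"{path}: bad data row {line!r}") from exc
    for req in ("units", "sampling_rate"):
        if req not in header:
            raise FormatError(f"{path}: missing required header '{req}'")
    units = header["units"]
    if units not in KNOWN_UNITS:
        raise FormatError(
            f"{path}: unknown unit string {units!r} in field 'units' "
            f"(known: {sorted(KNOWN_UNITS)})"
        )
    try:
        fs = float(header["sampling_rate"])
    except ValueError as exc:
        raise FormatError(f"{path}: sampling_rate not numeric") from exc
    t = np.asarray(times)
    expected = np.arange(t.size) / fs
    if t.size and np.max(np.abs(t - expected)) > 1e-6 * max(t[-1], 1.0 / fs):
        raise FormatError(
            f"{path}: time column deviates from uniform {fs} Hz grid by "
            "more than 1 ppm (gap or jitter)"
        )
    meta = {
        k[len("meta_"):]: _parse_meta_value(v)
        for k, v in header.items()
        if k.startswith("meta_")
    }
    return SampledSignal(
        np.asarray(values), fs, units=units,
        label=header.get("label", ""), meta=meta,
    )


@dataclass
class PipelineConfig:
    """User-auditable switches for every open methodological choice."""

    map_method: str = "integral"  # {"integral", "form_factor"}
    epoch_s: float = 20.0  # tonometry ensemble epoch
    artifact_sd: float = 3.0  # beat amplitude rejection threshold
    cuff_tolerance_mmhg: float = 5.0
    ri_formula: str = "pourcelot"
    posthoc_family: str = "time_within_group"
    sphericity_correction: str = "report"  # GG p reported alongside
    path_distance_mode: str = "direct"  # vs "subtracted"
    distension_min_beats: int = 7

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
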