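"""Exception hierarchy.

Every failure mode that a pipeline stage can report maps to one of these
classes so that the visit runner can convert it into a null metric with an
error code instead of a crash.
"""


class HemopulseError(Exception):
    """Base class for all package errors."""

    code = "error"


class InvalidParameterError(HemopulseError, ValueError):
    """A physical or protocol parameter is outside its valid domain."""

    code = "invalid_parameter"


class DomainError(HemopulseError, ValueError):
    """An input value violates the mathematical domain of an operation."""

    code = "domain"


class InsufficientBeatsError(HemopulseError):
    """Fewer cardiac cycles detected than the operation requires."""

    code = "insufficient_beats"


class NoUpstrokeError(HemopulseError):
    """A pressure beat has no positive upstroke; the foot is undefined."""

    code = "no_upstroke"


class OrderingError(HemopulseError):
    """Transit-time ordering violated (e.g. distal foot precedes proximal)."""

    code = "ordering"


class ZeroAmplitudeError(HemopulseError):
    """A waveform is flat where pulsatility is required."""

    code = "zero_amplitude"


class DegenerateShapeError(HemopulseError):
    """A waveform shape makes the requested calibration singular."""

    code = "degenerate_shape"


class WindowError(HemopulseError):
    """A requested analysis window does not fit inside the recording."""

    code = "window"


class InfeasibleTargetsError(HemopulseError, ValueError):
    """Requested waveform summary targets cannot be realised by the
    template family (e.g. velocity ordering violated)."""

    code = "infeasible_targets"


class ProtocolMismatchError(HemopulseError):
    """Recorded signal does not match the declared breathing protocol."""

    code = "protocol_mismatch"


class InsufficientDataError(HemopulseError):
    """Too few observations for the statistic requested."""

    code = "insufficient_data"


class TransformError(HemopulseError):
    """A variance-stabilising transform cannot be applied to the data."""

    code = "transform"


class FormatError(HemopulseError, ValueError):
    """A file does not conform to the waveform CSV dialect."""

    code = "format"


class IntegrityError(HemopulseError):
    """Study-table keys collide or reference inconsistent metadata."""

    code = "integrity"
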