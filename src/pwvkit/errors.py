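"""Exception hierarchy for pwvkit.

All library errors derive from :class:`PwvError` so callers (and the CLI)
can catch one base class.  ``ParameterError`` flags invalid configuration
values, ``InputError`` flags invalid data, and the three method-specific
errors signal conditions a flow curve can legitimately be in (flat signal,
near-parallel tangents, non-positive transit time).
"""

from __future__ import annotations


class PwvError(Exception):
    """Base class for all pwvkit errors."""


class ParameterError(PwvError, ValueError):
    """A configuration or model parameter is out of its valid range."""


class InputError(PwvError, ValueError):
    """Input data violates a precondition (shape, length, ordering)."""


class FormatError(InputError):
    """A text file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class NoUpstrokeError(PwvError):
    """No systolic upstroke (positive-slope region) found in the curve."""


class DegenerateTangentsError(PwvError):
    """Upslope and baseline tangents are near-parallel; no stable foot."""


class NonPhysiologicTransitTime(PwvError):
    """Transit time is zero or negative; carries the measured value in ms."""

    def __init__(self, delta_t: float):
        self.delta_t = float(delta_t)
        super().__init__(
            f"non-physiologic transit time: delta_t = {delta_t:.3f} ms"
        )
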