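"""Bland–Altman agreement between paired measurements.

Used to compare two PWV methods (e.g. phase-contrast CMR versus carotid–
femoral applanation tonometry) or two observers: paired differences
``d = a - b`` are summarised as bias (mean difference), the sample
standard deviation of the differences, and the 95 % limits of agreement
``bias ± 1.96 · SD``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError

__all__ = ["BlandAltmanResult", "bland_altman"]

_LOA_MULTIPLIER = 1.96  # 95 % limits of agreement


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias ± SD with 95 % limits of agreement for paired differences."""

    bias: float
    sd: float
    loa_low: float
    loa_high: float
    n: int

    def __iter__(self):
        # allows: bias, sd, lo, hi = bland_altman(a, b)
        return iter((self.bias, self.sd, self.loa_low, self.loa_high))


def bland_altman(method_a, method_b) -> BlandAltmanResult:
    """Bland–Altman summary of paired measurements.

    Parameters
    ----------
    method_a, method_b : sequence of float
        Element-wise paired measurements in the same units, length >= 2.

    Returns
    -------
    BlandAltmanResult
        ``bias = mean(a - b)``, ``sd`` the sample (n-1) standard deviation
        of the differences, and limits ``bias ± 1.96 · sd``.
    """
    a = np.asarray(method_a, dtype=float)
    b = np.asarray(method_b, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or a.size != b.size:
        raise InputError("method_a and method_b must be 1D and paired")
    if a.size < 2:
        raise InputError(f"need at least 2 pairs, got {a.size}")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise InputError("measurements must be finite")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias, sd=sd,
        loa_low=bias - _LOA_MULTIPLIER * sd,
        loa_high=bias + _LOA_MULTIPLIER * sd,
        n=int(a.size),
    )
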