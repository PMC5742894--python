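"""Evaluation of the bell-shaped diurnal melatonin curve and its markers.

The secretion model is the 24-h-periodic, Gaussian-like bell

    MLT(t) = b1 + b2 * exp( -ln2 * [ (cos(pi (t - b3)/12) - 1)
                                     / (cos(pi b4 / 24) - 1) ]^2 )

This parameterization is fixed by three requirements: the global maximum
``b1 + b2`` is attained at ``t = b3``; the full width at half maximum of
the peak equals ``b4`` (so ``MLT(b3 +/- b4/2) = b1 + b2/2`` exactly); and
the function is 24-h periodic.  The exponent vanishes at the peak and the
``ln 2`` factor makes the bracketed ratio equal +/-1 precisely half a
FWHM away from the peak.

DLMO (dim light melatonin onset/offset) markers are read off the curve at
relative thresholds of the amplitude: 50% markers are exactly
``b3 -/+ b4/2``; 25% markers are conventionally approximated as
``b3 -/+ (2/pi) b4`` (``dlmo``) and can also be computed as the exact
quarter-amplitude crossings (``dlmo25_exact``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import DLMOSet, ModelParams, ParameterError

__all__ = [
    "evaluate_mlt",
    "b_max",
    "dlmo",
    "dlmo25_exact",
    "QuarterCrossing",
    "DEFAULT_QUARTER_FACTOR",
    "EMPIRICAL_QUARTER_FACTOR",
]

_LN2 = math.log(2.0)

#: Half-width factor for the 25% relative threshold, ``on25 = b3 - f*b4``.
DEFAULT_QUARTER_FACTOR = 2.0 / math.pi
#: Alternative factor empirically implied by published reference tables of
#: 25% markers (slightly larger than 2/pi).
EMPIRICAL_QUARTER_FACTOR = 0.636945


def evaluate_mlt(params: ModelParams, t):
    """Melatonin concentration (pg/mL) at clock time(s) ``t`` (decimal hours).

    ``t`` may be a scalar or array; any real value is accepted (the curve
    is 24-h periodic).  The returned values satisfy
    ``b1 < MLT(t) <= b1 + b2``, with the maximum at ``t = b3`` and the
    half-maximum ``b1 + b2/2`` at ``t = b3 +/- b4/2``.
    """
    t = np.asarray(t, dtype=float)
    denom = math.cos(math.pi * params.b4 / 24.0) - 1.0
    if denom == 0.0:  # unreachable for valid params; guard for raw tuples
        raise ParameterError("b4 makes the FWHM normalisation vanish")
    u = (np.cos(np.pi * (t - params.b3) / 12.0) - 1.0) / denom
    out = params.b1 + params.b2 * np.exp(-_LN2 * u * u)
    return out if out.ndim else float(out)


def b_max(params: ModelParams) -> float:
    """Maximum melatonin concentration, ``b1 + b2`` (pg/mL)."""
    return params.b1 + params.b2


def dlmo(params: ModelParams, quarter_factor: float = DEFAULT_QUARTER_FACTOR) -> DLMOSet:
    """DLMO onset/offset markers at the 50% and 25% relative thresholds.

    The 50% markers are exact by the FWHM construction:
    ``on50 = b3 - b4/2``, ``off50 = b3 + b4/2`` (mod 24).  The 25%
    markers use the conventional linear approximation
    ``on25 = b3 - quarter_factor*b4``, ``off25 = b3 + quarter_factor*b4``.

    ``quarter_factor`` must lie in (1/2, 1) so that the 25% interval
    strictly contains the 50% interval.
    """
    if not 0.5 < quarter_factor < 1.0:
        raise ParameterError(
            f"quarter_factor must lie in (1/2, 1), got {quarter_factor}"
        )
    half = params.b4 / 2.0
    quarter = quarter_factor * params.b4
    return DLMOSet(
        on50=params.b3 - half,
        off50=params.b3 + half,
        on25=params.b3 - quarter,
        off25=params.b3 + quarter,
    )


@dataclass(frozen=True)
class QuarterCrossing:
    """Exact 25%-threshold crossings, or a report that none exist.

    For very wide peaks (``b4`` above ~15.26 h) the curve never falls to
    ``b1 + b2/4`` and ``attained`` is False with the times set to None.
    """

    attained: bool
    on25: float | None
    off25: float | None


def dlmo25_exact(params: ModelParams) -> QuarterCrossing:
    """Exact clock times where the curve equals ``b1 + b2/4``.

    Solves ``exp(-ln2 u^2) = 1/4`` for the phase angle, i.e.
    ``cos(pi (t-b3)/12) = 1 + sqrt(2) (cos(pi b4/24) - 1)``.  When the
    right-hand side falls below -1 the quarter amplitude is never reached
    and the threshold is reported as unattained rather than raising.
    """
    target = 1.0 + math.sqrt(2.0) * (math.cos(math.pi * params.b4 / 24.0) - 1.0)
    if target < -1.0:
        return QuarterCrossing(False, None, None)
    half_width = 12.0 / math.pi * math.acos(target)
    return QuarterCrossing(
        True,
        (params.b3 - half_width) % 24.0,
        (params.b3 + half_width) % 24.0,
    )
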