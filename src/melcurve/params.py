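"""Parameter containers for the diurnal melatonin secretion model.

The bell-shaped secretion curve is described by four parameters:

``b1``
    minimum (daytime baseline) melatonin concentration, pg/mL,
``b2``
    nocturnal release amplitude, pg/mL,
``b3``
    phase shift of melatonin release — the clock time of the secretion
    maximum (acrophase), decimal hours,
``b4``
    estimated sleep duration, equal to the full width at half maximum
    (FWHM) of the secretion peak, decimal hours.

Clock times are decimal hours on a 24-h clock and are stored reduced
modulo 24 into ``[0, 24)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ModelParams", "DLMOSet", "ParameterError"]


class ParameterError(ValueError):
    """A parameter set violates the model's domain constraints."""


@dataclass(frozen=True)
class ModelParams:
    """The quadruple (b1, b2, b3, b4) defining one secretion curve.

    Invariants: ``b1 >= 0``, ``b2 > 0``, ``0 < b4 < 24``; ``b3`` is
    reduced modulo 24 on construction.
    """

    b1: float
    b2: float
    b3: float
    b4: float

    def __post_init__(self) -> None:
        b1, b2, b3, b4 = (float(v) for v in (self.b1, self.b2, self.b3, self.b4))
        if not np.isfinite([b1, b2, b3, b4]).all():
            raise ParameterError("model parameters must be finite")
        if b1 < 0:
            raise ParameterError(f"b1 (baseline) must be >= 0, got {b1}")
        if b2 <= 0:
            raise ParameterError(f"b2 (amplitude) must be > 0, got {b2}")
        if not 0 < b4 < 24:
            raise ParameterError(
                f"b4 (FWHM/sleep duration) must lie in (0, 24) h, got {b4}"
            )
        object.__setattr__(self, "b1", b1)
        object.__setattr__(self, "b2", b2)
        object.__setattr__(self, "b3", b3 % 24.0)
        object.__setattr__(self, "b4", b4)

    def as_array(self) -> np.ndarray:
        return np.array([self.b1, self.b2, self.b3, self.b4], dtype=float)

    @classmethod
    def from_array(cls, x) -> "ModelParams":
        b1, b2, b3, b4 = np.asarray(x, dtype=float)
        return cls(b1, b2, b3, b4)


@dataclass(frozen=True)
class DLMOSet:
    """Dim light melatonin onset/offset markers, decimal hours in [0, 24).

    ``on50``/``off50`` are the clock times where the curve crosses the 50%
    relative threshold (half amplitude above baseline); ``on25``/``off25``
    the 25% relative threshold. ``off50 - on50 = b4 (mod 24)`` by the
    FWHM definition of ``b4``.
    """

    on50: float
    off50: float
    on25: float
    off25: float

    def __post_init__(self) -> None:
        for name in ("on50", "off50", "on25", "off25"):
            object.__setattr__(self, name, float(getattr(self, name)) % 24.0)
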