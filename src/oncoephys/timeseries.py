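"""Uniformly sampled single-channel traces.

Current traces are stored in picoampere — the native scale of the
recordings and of every file format here, kept end to end so file round
trips are exact — while voltages are in volt.  The unit tag makes
current/voltage confusion a hard error rather than a silent
factor-of-10⁹ bug.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError, UnitError

UNIT_CURRENT = "current"
UNIT_VOLTAGE = "voltage"
_UNITS = (UNIT_CURRENT, UNIT_VOLTAGE)


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled signal with an explicit unit tag.

    Parameters
    ----------
    values
        Samples, in pA for ``unit="current"`` and V for ``"voltage"``.
    dt
        Sampling interval in seconds; strictly positive.
    unit
        Either ``"current"`` or ``"voltage"``.
    t0
        Time of the first sample in seconds.
    """

    values: np.ndarray
    dt: float
    unit: str
    t0: float = 0.0

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise InputError("a time series needs at least 2 samples in 1-D")
        if not self.dt > 0:
            raise InputError(f"dt must be positive, got {self.dt}")
        if self.unit not in _UNITS:
            raise UnitError(f"unit must be one of {_UNITS}, got {self.unit!r}")

    # -- derived quantities -------------------------------------------------
    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def sampling_rate(self) -> float:
        return 1.0 / self.dt

    @property
    def duration(self) -> float:
        return self.n * self.dt

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) * self.dt

    @property
    def values_pa(self) -> np.ndarray:
        """Samples in picoampere (current traces only)."""
        self.require_unit(UNIT_CURRENT)
        return self.values

    @property
    def values_amperes(self) -> np.ndarray:
        """Samples in ampere (current traces only)."""
        self.require_unit(UNIT_CURRENT)
        return self.values * 1e-12

    # -- helpers ------------------------------------------------------------
    def require_unit(self, unit: str) -> None:
        if self.unit != unit:
            raise UnitError(f"expected a {unit} trace, got {self.unit}")

    def slice_time(self, start: float, end: float) -> "TimeSeries":
        """Sub-trace covering the half-open interval [start, end)."""
        if not end > start:
            raise InputError("slice needs end > start")
        i0 = max(0, int(np.ceil((start - self.t0) / self.dt - 1e-9)))
        i1 = min(self.n, int(np.ceil((end - self.t0) / self.dt - 1e-9)))
        if i1 - i0 < 2:
            raise InputError("slice contains fewer than 2 samples")
        return TimeSeries(self.values[i0:i1], self.dt, self.unit,
                          t0=self.t0 + i0 * self.dt)

    @classmethod
    def from_pa(cls, values_pa, dt: float, t0: float = 0.0) -> "TimeSeries":
        """Build a current trace from samples given in picoampere."""
        return cls(np.asarray(values_pa, dtype=np.float64),
                   dt, UNIT_CURRENT, t0)
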