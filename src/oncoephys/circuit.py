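"""Electrode–electrolyte measurement model.

The recording chain is modelled as a planar metal electrode whose
charge-transfer resistance R_D lies in parallel with the double-layer
(Helmholtz–Gouy–Chapman) capacitance C_D, in series with the spreading
resistance R_c of the electrolyte; the leakage path between sensing and
counter electrode is a very large seal impedance Z_seal.  The cell layer
acts as an extracellular voltage source v_s(t); the displacement current
it forces through C_D,

    i_s(t) = C_D · dv_s/dt · (1 − e^{−(t−t0)/τ}),   τ = C_D · (R_c ∥ R_D),

is converted to a voltage by a transimpedance amplifier with feedback
resistance R_F,

    v_o(t) = −R_F · i_s(t).

τ is the charging time of the R_c‖R_D pair through C_D; the (1 − e^{−t/τ})
factor describes the network charging from the start of the trace.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InputError, ParameterError
from .timeseries import TimeSeries, UNIT_CURRENT, UNIT_VOLTAGE


@dataclass(frozen=True)
class CircuitParams:
    """Equivalent-circuit parameters of one electrode, SI units.

    Defaults describe a mm²-scale planar Au electrode recording pA-scale
    currents: R_D = 10 MΩ, C_D = 1 µF, R_c = 10 kΩ, R_F = 1 GΩ,
    Z_seal = 1 TΩ.  All are overridable via the ``circuit:`` config block.
    """

    rd_ohm: float = 10e6
    cd_farad: float = 1e-6
    rc_ohm: float = 10e3
    rf_ohm: float = 1e9
    zseal_ohm: float = 1e12

    def __post_init__(self):
        for name in ("rd_ohm", "cd_farad", "rc_ohm", "rf_ohm", "zseal_ohm"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be strictly positive")
        if self.zseal_ohm < 10 * max(self.rd_ohm, self.rc_ohm):
            warnings.warn(
                "Zseal is not large relative to RD/Rc; the high-seal "
                "approximation behind the model may not hold",
                stacklevel=2,
            )


def time_constant(params: CircuitParams) -> float:
    """Charging time τ = C_D · (R_c·R_D)/(R_c+R_D) in seconds.

    Strictly positive and linear in C_D.
    """
    r_par = params.rc_ohm * params.rd_ohm / (params.rc_ohm + params.rd_ohm)
    return params.cd_farad * r_par


def transimpedance_output(current: TimeSeries, params: CircuitParams) -> TimeSeries:
    """Amplifier output v_o(t) = −R_F · i_s(t).

    Pointwise and linear; preserves dt, t0 and length.
    """
    current.require_unit(UNIT_CURRENT)
    if not params.rf_ohm > 0:  # CircuitParams already enforces this; defensive
        raise ParameterError("rf_ohm must be positive")
    return TimeSeries(-params.rf_ohm * current.values_amperes, current.dt,
                      UNIT_VOLTAGE, current.t0)


def interface_current(vs: TimeSeries, params: CircuitParams) -> TimeSeries:
    """Displacement current driven through the double layer by v_s(t).

    The derivative is a central difference in the interior and one-sided
    at the two ends; the charging factor (1 − e^{−(t−t0)/τ}) is anchored
    at the start of the supplied trace.
    """
    vs.require_unit(UNIT_VOLTAGE)
    if vs.n < 3:
        raise InputError("need at least 3 samples for the derivative")
    tau = time_constant(params)
    dvdt = np.gradient(vs.values, vs.dt)
    charging = 1.0 - np.exp(-(vs.times - vs.t0) / tau)
    amps = params.cd_farad * dvdt * charging
    return TimeSeries(amps * 1e12, vs.dt, UNIT_CURRENT, vs.t0)
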