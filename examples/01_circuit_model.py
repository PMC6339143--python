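"""Measurement model: from a cell-layer voltage to the amplifier output.

A linear voltage ramp v_s(t) drives a displacement current through the
double-layer capacitance; after the network's charging transient the
current settles at C_D · dv_s/dt, and the transimpedance stage turns it
into an inverted voltage with gain R_F.
"""
import numpy as np

from oncoephys import (CircuitParams, TimeSeries, interface_current,
                       time_constant, transimpedance_output)
from oncoephys.timeseries import UNIT_VOLTAGE

params = CircuitParams()  # 10 MΩ / 1 µF / 10 kΩ / 1 GΩ defaults
tau = time_constant(params)
print(f"charging time constant tau = {tau * 1e3:.2f} ms")

dt = tau / 50
t = np.arange(0.0, 20 * tau, dt)
ramp = TimeSeries(1e-3 * t, dt, UNIT_VOLTAGE)  # 1 mV/s cell-layer ramp

i = interface_current(ramp, params)
print(f"current at t = tau:    {i.values_pa[50]:8.1f} pA  "
      f"(63.2% of the asymptote)")
print(f"current at t = 15 tau: {i.values_pa[750]:8.1f} pA  "
      f"(asymptote C_D*dv/dt = 1000 pA = 1 nA)")

v_out = transimpedance_output(i, params)
print(f"amplifier output at t = 15 tau: {v_out.values[750] * 1e3:6.1f} mV  "
      f"(inverted: -R_F * i_s)")
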