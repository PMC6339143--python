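import numpy as np
import pytest

from oncoephys import DetectionConfig, RecordingConfig, TimeSeries


def naive_detect(x_pa, dt, t0, threshold, refractory):
    """Brute-force per-sample reference detector.

    Pure-Python state machine over the samples: one event per excursion
    beyond ±threshold, first-extremum peak, linearly interpolated
    threshold-crossing width, keep-the-larger refractory merge.  Returns
    (peak_time_s, amplitude_pa, width_s, polarity) tuples sorted by time.
    """
    x_pa = list(x_pa)
    n = len(x_pa)
    events = []
    for pol in (1, -1):
        pol_events = []
        i = 0
        while i < n:
            if pol * x_pa[i] > threshold:
                j = i
                best = i
                while j + 1 < n and pol * x_pa[j + 1] > threshold:
                    j += 1
                    if pol * x_pa[j] > pol * x_pa[best]:
                        best = j
                if i == 0:
                    t_left = t0
                else:
                    a, b = pol * x_pa[i - 1], pol * x_pa[i]
                    t_left = t0 + (i - 1 + (threshold - a) / (b - a)) * dt
                if j == n - 1:
                    t_right = t0 + (n - 1) * dt
                else:
                    a, b = pol * x_pa[j], pol * x_pa[j + 1]
                    t_right = t0 + (j + (a - threshold) / (a - b)) * dt
                pol_events.append((t0 + best * dt, x_pa[best],
                                   t_right - t_left, pol))
                i = j + 1
            else:
                i += 1
        merged = []
        for ev in pol_events:
            if merged and ev[0] - merged[-1][0] < refractory:
                if abs(ev[1]) > abs(merged[-1][1]):
                    merged[-1] = ev
            else:
                merged.append(ev)
        events.extend(merged)
    events.sort(key=lambda e: (e[0], -e[3]))
    return events


def trace_from_pa(x_pa, dt=1e-3, t0=0.0):
    return TimeSeries.from_pa(np.asarray(x_pa, dtype=float), dt, t0=t0)


@pytest.fixture
def det_cfg():
    return DetectionConfig()


@pytest.fixture
def quiet_config():
    """Noiseless 600-s recording config, for calibration checks."""
    return RecordingConfig(duration_s=600.0, seed=7, baseline_noise_pp_pa=0.0)
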