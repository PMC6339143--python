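"""Threshold-based spike detection and biphasic pairing.

An event is one excursion of the current beyond +threshold or below
−threshold (default ±50 pA, the level above which population spikes are
counted).  Peak time is the extremum sample of the excursion (earliest
sample on ties), amplitude the signed extremum, and width the time
between the two threshold crossings with linear interpolation between
samples.  Same-polarity peaks closer than the refractory gap are merged,
keeping the larger.  A greedy left-to-right pass then pairs adjacent
opposite-polarity events within the pairing window into biphasic spikes.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import DataError, InputError, ParameterError
from .timeseries import TimeSeries, UNIT_CURRENT

UNIPOLAR = "unipolar"
BIPHASIC = "biphasic"


@dataclass(frozen=True)
class DetectionConfig:
    """Detector settings.

    threshold_pa is applied symmetrically as ±threshold.  An optional
    sliding-median baseline subtraction (window ``baseline_window_s``)
    can be enabled for drifting traces; it is off by default because the
    drift budget of the recording chain is handled upstream.
    """

    threshold_pa: float = 50.0
    refractory_s: float = 0.05
    pairing_window_s: float = 2.0
    baseline_window_s: float | None = None

    def __post_init__(self):
        if not self.threshold_pa > 0:
            raise ParameterError("threshold_pa must be positive")
        if self.refractory_s < 0:
            raise ParameterError("refractory_s must be >= 0")
        if not self.pairing_window_s > 0:
            raise ParameterError("pairing_window_s must be positive")


@dataclass
class SpikeEvent:
    """One detected excursion; ``kind``/``pair_id`` are set by pairing."""

    peak_time_s: float
    amplitude_pa: float
    width_s: float
    polarity: int  # +1 or -1
    kind: str | None = None
    pair_id: int | None = None


def _scan_polarity(s: np.ndarray, dt: float, t0: float,
                   threshold: float, polarity: int) -> list[SpikeEvent]:
    """Events of one polarity on the already sign-flipped trace ``s``."""
    above = s > threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1  # exclusive
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, s.size]
    events = []
    for i0, i1 in zip(starts, ends):
        seg = s[i0:i1]
        k = i0 + int(np.argmax(seg))  # earliest sample wins ties
        # threshold crossings, linearly interpolated between samples
        if i0 == 0:
            t_left = t0
        else:
            frac = (threshold - s[i0 - 1]) / (s[i0] - s[i0 - 1])
            t_left = t0 + (i0 - 1 + frac) * dt
        if i1 == s.size:
            t_right = t0 + (s.size - 1) * dt
        else:
            frac = (s[i1 - 1] - threshold) / (s[i1 - 1] - s[i1])
            t_right = t0 + (i1 - 1 + frac) * dt
        events.append(SpikeEvent(peak_time_s=t0 + k * dt,
                                 amplitude_pa=polarity * s[k],
                                 width_s=t_right - t_left,
                                 polarity=polarity))
    return events


def _merge_refractory(events: list[SpikeEvent],
                      refractory: float) -> list[SpikeEvent]:
    """Merge same-polarity peaks closer than the refractory gap, keeping
    the larger (the earlier on equal magnitude)."""
    out: list[SpikeEvent] = []
    for ev in events:
        if out and ev.peak_time_s - out[-1].peak_time_s < refractory:
            if abs(ev.amplitude_pa) > abs(out[-1].amplitude_pa):
                out[-1] = ev
        else:
            out.append(ev)
    return out


def detect_spikes(rec: TimeSeries,
                  cfg: DetectionConfig | None = None) -> list[SpikeEvent]:
    """Extract threshold-crossing events from a current trace.

    Returns events sorted by peak time with ``kind`` unset; feed them to
    :func:`pair_biphasic` to classify unipolar vs biphasic.
    """
    cfg = cfg or DetectionConfig()
    rec.require_unit(UNIT_CURRENT)
    if rec.n < 3:
        raise InputError("trace shorter than 3 samples")
    if not np.all(np.isfinite(rec.values)):
        raise DataError("trace contains non-finite samples")
    x = rec.values_pa
    if cfg.baseline_window_s:
        win = max(3, int(round(cfg.baseline_window_s / rec.dt)) | 1)
        med = pd.Series(x).rolling(win, center=True, min_periods=1).median()
        x = x - med.to_numpy()
    events: list[SpikeEvent] = []
    for pol in (1, -1):
        evs = _scan_polarity(pol * x, rec.dt, rec.t0, cfg.threshold_pa, pol)
        events.extend(_merge_refractory(evs, cfg.refractory_s))
    events.sort(key=lambda e: (e.peak_time_s, -e.polarity))
    return events


def pair_biphasic(events: list[SpikeEvent],
                  cfg: DetectionConfig | None = None) -> list[SpikeEvent]:
    """Greedy left-to-right pairing of adjacent opposite-polarity events.

    Two neighbouring events of opposite polarity whose peaks lie within
    the pairing window become one biphasic spike (shared ``pair_id``);
    everything else is unipolar.  Each event joins at most one pair.
    """
    cfg = cfg or DetectionConfig()
    out = [replace(ev, kind=UNIPOLAR, pair_id=None) for ev in events]
    pair_id = 0
    i = 0
    while i < len(out) - 1:
        a, b = out[i], out[i + 1]
        if (a.polarity != b.polarity
                and b.peak_time_s - a.peak_time_s <= cfg.pairing_window_s):
            a.kind = b.kind = BIPHASIC
            a.pair_id = b.pair_id = pair_id
            pair_id += 1
            i += 2
        else:
            i += 1
    return out


def events_to_frame(events: list[SpikeEvent]) -> pd.DataFrame:
    """Tabular view of an event list (times in s, amplitudes in pA)."""
    return pd.DataFrame(
        {
            "peak_time_s": [e.peak_time_s for e in events],
            "amplitude_pA": [e.amplitude_pa for e in events],
            "width_s": [e.width_s for e in events],
            "polarity": ["+" if e.polarity > 0 else "-" for e in events],
            "kind": [e.kind if e.kind is not None else "" for e in events],
            "pair_id": [e.pair_id if e.pair_id is not None else -1
                        for e in events],
        }
    )


def events_from_frame(df: pd.DataFrame) -> list[SpikeEvent]:
    """Inverse of :func:`events_to_frame`."""
    events = []
    for row in df.itertuples(index=False):
        pair_id = int(row.pair_id)
        kind = str(row.kind) if str(row.kind) else None
        events.append(SpikeEvent(
            peak_time_s=float(row.peak_time_s),
            amplitude_pa=float(row.amplitude_pA),
            width_s=float(row.width_s),
            polarity=1 if str(row.polarity) == "+" else -1,
            kind=kind,
            pair_id=pair_id if pair_id >= 0 else None,
        ))
    return events
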