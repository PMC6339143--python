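"""Regime segmentation, spike statistics and wave-speed estimation.

The two activity regimes of a population recording — sporadic
asynchronous firing vs quasi-periodic synchronous firing — are separated
with a sliding-window rule on event rate and inter-spike-interval
regularity: windows whose rate reaches ``rate_cutoff_hz`` AND whose ISI
coefficient of variation stays below ``cv_cutoff`` are synchronous.
A biphasic pair counts as one spike for rates and ISIs (its onset is the
first lobe's peak); amplitude and width histograms remain per lobe so
the signed ±-amplitude distribution is preserved.

Wave speed follows from the biphasic morphology: the positive and
negative lobes mark the wave entering and leaving the electrode, so
per-pair speed = electrode diameter / lobe separation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .detect import BIPHASIC, UNIPOLAR, SpikeEvent
from .errors import InputError, ParameterError
from .simulate import ASYNCHRONOUS, SYNCHRONOUS

#: Signed amplitude bins: 50-pA steps from ±50 to ±350 pA with open outer
#: bins and an (empty by construction) sub-threshold middle bin.
AMPLITUDE_EDGES_PA = np.r_[-np.inf, np.arange(-350.0, -49.0, 50.0),
                           np.arange(50.0, 351.0, 50.0), np.inf]
#: Width bins: 50-ms steps to 0.5 s, open-ended above.
WIDTH_EDGES_S = np.r_[np.arange(0.0, 0.501, 0.05), np.inf]
#: ISI bins at the 1-s resolution used for population ISI histograms.
ISI_EDGES_S = np.r_[np.arange(0.0, 10.001, 1.0), np.inf]


@dataclass
class Histogram:
    edges: np.ndarray
    counts: np.ndarray

    @classmethod
    def from_values(cls, values, edges) -> "Histogram":
        counts, _ = np.histogram(np.asarray(values, dtype=float), bins=edges)
        return cls(edges=np.asarray(edges, dtype=float), counts=counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def modal_bin(self) -> tuple[float, float]:
        """(left, right) edges of the fullest bin (first on ties)."""
        k = int(np.argmax(self.counts))
        return float(self.edges[k]), float(self.edges[k + 1])


@dataclass(frozen=True)
class RegimeSegment:
    """A labelled, half-open interval [start, end) of one regime."""

    start_s: float
    end_s: float
    label: str
    spike_count: int
    spike_rate_hz: float


@dataclass
class SpikeStats:
    """Per-regime statistics.

    ``n_events`` counts detected excursions (lobes); ``mean_rate_hz``
    counts spikes, with a biphasic pair as a single spike.
    """

    label: str
    n_events: int = 0
    amplitude_histogram: Histogram = None
    width_histogram: Histogram = None
    isi_histogram: Histogram = None
    unipolar_fraction: float = float("nan")
    biphasic_separations_s: np.ndarray = field(
        default_factory=lambda: np.empty(0))
    mean_rate_hz: float = 0.0

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n_events": int(self.n_events),
            "amplitude_histogram": {
                "edges_pa": list(self.amplitude_histogram.edges),
                "counts": [int(c) for c in self.amplitude_histogram.counts]},
            "width_histogram": {
                "edges_s": list(self.width_histogram.edges),
                "counts": [int(c) for c in self.width_histogram.counts]},
            "isi_histogram": {
                "edges_s": list(self.isi_histogram.edges),
                "counts": [int(c) for c in self.isi_histogram.counts]},
            "unipolar_fraction": float(self.unipolar_fraction),
            "biphasic_separations_s": [float(x)
                                       for x in self.biphasic_separations_s],
            "mean_rate_hz": float(self.mean_rate_hz),
        }


# ---------------------------------------------------------------------------
# spike-time collapsing
# ---------------------------------------------------------------------------
def collapse_spike_times(events: list[SpikeEvent]) -> np.ndarray:
    """Spike onset times with each biphasic pair collapsed to its first
    lobe; unpaired events keep their peak times."""
    times = []
    seen: set[int] = set()
    for ev in events:
        if ev.kind == BIPHASIC and ev.pair_id is not None:
            if ev.pair_id in seen:
                continue
            seen.add(ev.pair_id)
        times.append(ev.peak_time_s)
    return np.asarray(times)


def pair_onsets_and_separations(events: list[SpikeEvent]):
    """(onset time, lobe separation) per biphasic pair, onset-sorted."""
    pairs: dict[int, list[float]] = {}
    for ev in events:
        if ev.kind == BIPHASIC and ev.pair_id is not None:
            pairs.setdefault(ev.pair_id, []).append(ev.peak_time_s)
    onsets, seps = [], []
    for ts in pairs.values():
        if len(ts) == 2:
            onsets.append(min(ts))
            seps.append(abs(ts[1] - ts[0]))
    order = np.argsort(onsets)
    return np.asarray(onsets)[order], np.asarray(seps)[order]


# ---------------------------------------------------------------------------
# regime segmentation
# ---------------------------------------------------------------------------
def segment_regimes(events: list[SpikeEvent], rec_span: tuple[float, float],
                    window_s: float = 30.0, rate_cutoff_hz: float = 0.2,
                    cv_cutoff: float = 0.6) -> list[RegimeSegment]:
    """Label the recording as asynchronous/synchronous stretches.

    The span is tiled into ``window_s`` windows; a window is synchronous
    when its (pair-collapsed) spike rate reaches ``rate_cutoff_hz`` and
    the coefficient of variation of its ISIs stays at or below
    ``cv_cutoff`` (windows with fewer than 3 spikes cannot establish
    regularity and are asynchronous).  Adjacent same-label windows merge.
    """
    t0, t1 = rec_span
    if not (t1 > t0 and window_s > 0):
        raise InputError("need rec_span end > start and window_s > 0")
    times = np.sort(collapse_spike_times(events))
    edges = np.arange(t0, t1, window_s)
    labels = []
    for left in edges:
        right = min(left + window_s, t1)
        in_win = times[(times >= left) & (times < right)]
        rate = in_win.size / (right - left)
        synchronous = False
        if rate >= rate_cutoff_hz and in_win.size >= 3:
            isis = np.diff(in_win)
            mean_isi = isis.mean()
            cv = isis.std() / mean_isi if mean_isi > 0 else np.inf
            synchronous = cv <= cv_cutoff
        labels.append(SYNCHRONOUS if synchronous else ASYNCHRONOUS)

    segments: list[RegimeSegment] = []
    seg_start = t0
    for i, label in enumerate(labels):
        right = min(t0 + (i + 1) * window_s, t1)
        if i + 1 < len(labels) and labels[i + 1] == label:
            continue
        count = int(((times >= seg_start) & (times < right)).sum())
        segments.append(RegimeSegment(
            start_s=seg_start, end_s=right, label=label, spike_count=count,
            spike_rate_hz=count / (right - seg_start)))
        seg_start = right
    return segments


# ---------------------------------------------------------------------------
# per-regime statistics
# ---------------------------------------------------------------------------
def _events_in(events, segments):
    for ev in events:
        for seg in segments:
            if seg.start_s <= ev.peak_time_s < seg.end_s:
                yield ev
                break


def spike_statistics(events: list[SpikeEvent],
                     segments: list[RegimeSegment]) -> dict[str, SpikeStats]:
    """Histograms and rates per regime label.

    ISIs are measured between consecutive biphasic-pair onsets within
    each synchronous segment (between consecutive collapsed spikes for
    other labels) and binned at 1-s resolution.  The unipolar fraction
    is the fraction of a label's events carrying ``kind='unipolar'``.
    """
    stats: dict[str, SpikeStats] = {}
    for label in sorted({seg.label for seg in segments}):
        segs = [s for s in segments if s.label == label]
        evs = list(_events_in(events, segs))
        amps = [e.amplitude_pa for e in evs]
        widths = [e.width_s for e in evs]
        n_uni = sum(1 for e in evs if e.kind == UNIPOLAR)
        onsets, seps = pair_onsets_and_separations(evs)

        isis = []
        for seg in segs:
            if label == SYNCHRONOUS:
                t = onsets[(onsets >= seg.start_s) & (onsets < seg.end_s)]
            else:
                t = np.sort(collapse_spike_times(
                    [e for e in evs
                     if seg.start_s <= e.peak_time_s < seg.end_s]))
            if t.size >= 2:
                isis.extend(np.diff(t))

        total_dur = sum(s.end_s - s.start_s for s in segs)
        n_spikes = sum(s.spike_count for s in segs) if segs else 0
        stats[label] = SpikeStats(
            label=label,
            n_events=len(evs),
            amplitude_histogram=Histogram.from_values(amps, AMPLITUDE_EDGES_PA),
            width_histogram=Histogram.from_values(widths, WIDTH_EDGES_S),
            isi_histogram=Histogram.from_values(isis, ISI_EDGES_S),
            unipolar_fraction=(n_uni / len(evs)) if evs else float("nan"),
            biphasic_separations_s=seps,
            mean_rate_hz=(n_spikes / total_dur) if total_dur > 0 else 0.0,
        )
    return stats


# ---------------------------------------------------------------------------
# wave speed
# ---------------------------------------------------------------------------
@dataclass
class WaveSpeedResult:
    speeds_um_s: np.ndarray
    median_um_s: float
    n_pairs: int
    empty: bool = False


def electrode_diameter_mm(area_mm2: float) -> float:
    """Diameter of a circular electrode of the given area."""
    if not area_mm2 > 0:
        raise ParameterError("area_mm2 must be positive")
    return 2.0 * math.sqrt(area_mm2 / math.pi)


def estimate_wave_speed(events: list[SpikeEvent],
                        diameter_mm: float | None = None,
                        area_mm2: float | None = None) -> WaveSpeedResult:
    """Per-pair wave speed (µm/s) from biphasic lobe separations.

    speed = electrode diameter (µm) / lobe-peak separation (s).  The
    diameter may be given directly or derived from a circular electrode
    area (default 1 mm² → 1.128 mm).  With no pairs the result is empty
    and flagged rather than raising.
    """
    if diameter_mm is None:
        diameter_mm = electrode_diameter_mm(1.0 if area_mm2 is None
                                            else area_mm2)
    if not diameter_mm > 0:
        raise ParameterError("diameter_mm must be positive")
    _, seps = pair_onsets_and_separations(events)
    if seps.size == 0:
        return WaveSpeedResult(np.empty(0), float("nan"), 0, empty=True)
    speeds = diameter_mm * 1000.0 / seps
    return WaveSpeedResult(speeds, float(np.median(speeds)), int(seps.size))
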