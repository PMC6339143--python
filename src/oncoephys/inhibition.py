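"""Quantification of a channel-blocker experiment.

A three-phase protocol — activity before the inhibitor, during the block,
and after wash-out — is summarised by per-phase spike counts and a robust
per-phase fluctuation magnitude, from which block and recovery calls are
made.  The rules mirror the qualitative readout of a Gd³⁺ calcium-channel
block: during-phase counts collapse to near zero and the trace flattens
below a few pA, while the after phase returns to before-phase levels.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import AnnotationError, InputError
from .timeseries import TimeSeries, UNIT_CURRENT

log = logging.getLogger(__name__)

PHASE_LABELS = ("before", "during", "after")


@dataclass(frozen=True)
class PhaseAnnotation:
    """One labelled experiment phase, a half-open interval [start, end)."""

    label: str
    start_s: float
    end_s: float

    def __post_init__(self):
        if not self.end_s > self.start_s:
            raise AnnotationError(
                f"phase {self.label!r}: end must exceed start")


def validate_phases(phases) -> list[PhaseAnnotation]:
    """Check the before/during/after triple: each label once, ordered,
    non-overlapping."""
    phases = list(phases)
    labels = [p.label for p in phases]
    if sorted(labels) != sorted(PHASE_LABELS):
        raise AnnotationError(
            f"need exactly the labels {PHASE_LABELS}, got {labels}")
    ordered = sorted(phases, key=lambda p: p.start_s)
    for a, b in zip(ordered, ordered[1:]):
        if b.start_s < a.end_s:
            raise AnnotationError(
                f"phases {a.label!r} and {b.label!r} overlap")
    if [p.label for p in ordered] != list(PHASE_LABELS):
        raise AnnotationError("phases must run before → during → after")
    return ordered


@dataclass
class InhibitionReport:
    """Per-phase summary and the block/recovery decision."""

    spike_counts: dict = field(default_factory=dict)
    fluctuation_magnitudes_pa: dict = field(default_factory=dict)
    block_called: bool = False
    recovery_called: bool = False
    undecidable: bool = False
    ignored_events: int = 0

    def to_dict(self) -> dict:
        return {
            "spike_counts": {k: int(v) for k, v in self.spike_counts.items()},
            "fluctuation_magnitudes_pa": {
                k: float(v) for k, v in self.fluctuation_magnitudes_pa.items()},
            "block_called": bool(self.block_called),
            "recovery_called": bool(self.recovery_called),
            "undecidable": bool(self.undecidable),
            "ignored_events": int(self.ignored_events),
        }


def phase_spike_counts(events, phases) -> tuple[dict, int]:
    """Assign each event to the phase containing its peak time.

    Intervals are half-open, so a peak exactly on a boundary belongs to
    the earlier phase.  Events outside every phase are not counted; their
    number is returned (and logged).
    """
    phases = validate_phases(phases)
    counts = {p.label: 0 for p in phases}
    ignored = 0
    for ev in events:
        for p in phases:
            if p.start_s <= ev.peak_time_s < p.end_s:
                counts[p.label] += 1
                break
        else:
            ignored += 1
    if ignored:
        log.info("%d events fell outside all annotated phases", ignored)
    return counts, ignored


def fluctuation_magnitude(rec: TimeSeries, phase: PhaseAnnotation) -> float:
    """Robust peak magnitude of a phase, in pA.

    Defined as the 99.5th percentile of |i − median(i)| over the phase, so
    a single stray noise sample cannot defeat a few-pA criterion, while a
    constant offset on the trace has no effect.
    """
    rec.require_unit(UNIT_CURRENT)
    sub = rec.slice_time(phase.start_s, phase.end_s)
    if sub.n < 10:
        raise InputError("phase spans fewer than 10 samples")
    x = sub.values_pa
    return float(np.percentile(np.abs(x - np.median(x)), 99.5))


def assess_block(counts: dict, magnitudes_pa: dict, *,
                 count_tolerance: float = 0.5,
                 block_magnitude_pa: float = 5.0,
                 ignored_events: int = 0) -> InhibitionReport:
    """Turn per-phase counts and magnitudes into block/recovery calls.

    block_called: during-count ≤ 10% of before-count AND during-phase
    magnitude ≤ ``block_magnitude_pa`` (default 5 pA).
    recovery_called: after-count within ``count_tolerance`` (default ±50%)
    of before-count.  A zero before-count makes the block undecidable.
    """
    report = InhibitionReport(spike_counts=dict(counts),
                              fluctuation_magnitudes_pa=dict(magnitudes_pa),
                              ignored_events=ignored_events)
    before = counts["before"]
    if before == 0:
        report.undecidable = True
        log.warning("no before-phase spikes: block assessment undecidable")
        return report
    report.block_called = (
        counts["during"] <= 0.1 * before
        and magnitudes_pa["during"] <= block_magnitude_pa
    )
    report.recovery_called = (
        abs(counts["after"] - before) <= count_tolerance * before
    )
    return report


def analyze_inhibition(rec: TimeSeries, events, phases, *,
                       count_tolerance: float = 0.5,
                       block_magnitude_pa: float = 5.0) -> InhibitionReport:
    """Full per-phase analysis: counts, magnitudes, and the calls."""
    counts, ignored = phase_spike_counts(events, phases)
    mags = {p.label: fluctuation_magnitude(rec, p)
            for p in validate_phases(phases)}
    return assess_block(counts, mags, count_tolerance=count_tolerance,
                        block_magnitude_pa=block_magnitude_pa,
                        ignored_events=ignored)


def block_onset_time(rec: TimeSeries, during: PhaseAnnotation, *,
                     magnitude_pa: float = 5.0,
                     window_s: float = 60.0):
    """Diagnostic: start of the first ``window_s`` window inside the
    during phase whose robust magnitude falls below ``magnitude_pa``;
    ``None`` if no window qualifies."""
    t = during.start_s
    while t + window_s <= during.end_s:
        win = PhaseAnnotation("during", t, t + window_s)
        if fluctuation_magnitude(rec, win) < magnitude_pa:
            return t
        t += window_s
    return None
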