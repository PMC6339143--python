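"""Synthetic extracellular recordings with ground truth.

The generator emulates the single-channel current signatures of a dense
cancer-cell population on a large (mm²) planar electrode:

* medium-only baseline — white Gaussian noise with a sub-pA peak-to-peak
  span (the 0.01–99.99 percentile span equals ``baseline_noise_pp_pa``);
* an asynchronous-sporadic regime — Poisson-timed unipolar spikes of
  about 100 pA, mostly negative, widths mostly 30–200 ms;
* a synchronous quasi-periodic regime — biphasic spikes of ±150 pA whose
  positive and negative lobes are separated by the transit time of a
  slow extracellular wave across the electrode (0.3–2 s scale) and whose
  inter-spike intervals cluster at 2–3 s (≈0.5 Hz);
* a three-phase inhibition protocol — normal activity, a blocked phase
  whose residual fluctuations stay below a few pA, and recovery.

Spike lobes are Gaussian; the drawn "width" is the full width of the lobe
at the 50-pA detection level (falling back to full width at half maximum
for small lobes), so detector width measurements are directly comparable
to generator draws.  Overlapping events superpose linearly and are
counted, never dropped.  Every inserted event is logged in a
:class:`GroundTruth` table for detection scoring.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .errors import InputError, ParameterError, ResolutionError
from .inhibition import PhaseAnnotation
from .timeseries import TimeSeries, UNIT_CURRENT

ASYNCHRONOUS = "asynchronous"
SYNCHRONOUS = "synchronous"
BLOCKED = "blocked"

#: Φ⁻¹(0.9999): a Gaussian's 0.01–99.99 percentile span is 2·_PP_Z·σ.
_PP_Z = 3.7190164854556804
#: Lobe-width convention: full width at this (detection) level, in pA.
_WIDTH_LEVEL_PA = 50.0


# ---------------------------------------------------------------------------
# parameter blocks
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class RecordingConfig:
    duration_s: float = 600.0
    sampling_rate_hz: float = 1000.0
    seed: int = 0
    baseline_noise_pp_pa: float = 1.0

    def __post_init__(self):
        if not self.duration_s > 0:
            raise ParameterError("duration_s must be positive")
        if not self.sampling_rate_hz > 0:
            raise ParameterError("sampling_rate_hz must be positive")
        if self.baseline_noise_pp_pa < 0:
            raise ParameterError("baseline_noise_pp_pa must be >= 0")


@dataclass(frozen=True)
class AsyncParams:
    """Sporadic unipolar activity.

    Widths are log-uniform on [width_low_s, width_high_s]; the default
    bounds put ≈80% of draws inside the 30–200 ms band.  The event rate
    has no single published value; 0.05 events/s makes the default
    two-regime simulation show the ~10× synchronous/asynchronous count
    disparity seen in long recordings.
    """

    event_rate_hz: float = 0.05
    amplitude_mean_pa: float = 100.0
    amplitude_sd_pa: float = 25.0
    width_low_s: float = 0.02
    width_high_s: float = 0.214
    negative_polarity_prob: float = 0.7

    def __post_init__(self):
        if self.event_rate_hz < 0:
            raise ParameterError("event_rate_hz must be >= 0")
        if not 0 < self.width_low_s < self.width_high_s:
            raise ParameterError("need 0 < width_low_s < width_high_s")
        if not 0 <= self.negative_polarity_prob <= 1:
            raise ParameterError("negative_polarity_prob must be in [0,1]")


@dataclass(frozen=True)
class SyncParams:
    """Quasi-periodic biphasic activity.

    Inter-spike intervals are truncated-normal with centre ``mean_isi_s``,
    spread ``isi_jitter_sd_s`` and hard bounds [isi_low_s, isi_high_s];
    the defaults give a realized mean ISI of ≈2.2 s (rate ≈0.46 Hz) with
    the modal 1-s ISI bin at 2–3 s.  Lobes are ±``amplitude_pa``; the
    positive-to-negative lobe separation defaults to 0.3 s unless wave
    kinematics override it.
    """

    mean_isi_s: float = 2.15
    isi_jitter_sd_s: float = 0.6
    isi_low_s: float = 1.0
    isi_high_s: float = 10.0
    amplitude_pa: float = 150.0
    width_low_s: float = 0.05
    width_high_s: float = 0.3
    biphasic_separation_s: float = 0.3

    def __post_init__(self):
        if not self.amplitude_pa > 0:
            raise ParameterError("amplitude_pa must be positive")
        if not self.mean_isi_s > self.biphasic_separation_s:
            raise ParameterError(
                "mean_isi_s must exceed biphasic_separation_s")
        if not 0 < self.width_low_s < self.width_high_s:
            raise ParameterError("need 0 < width_low_s < width_high_s")
        if not 0 < self.isi_low_s < self.isi_high_s:
            raise ParameterError("need 0 < isi_low_s < isi_high_s")
        if self.isi_jitter_sd_s < 0:
            raise ParameterError("isi_jitter_sd_s must be >= 0")


@dataclass(frozen=True)
class WaveParams:
    """Kinematics of the slow wave crossing the electrode.

    The lobe separation of a biphasic spike equals the wave transit time
    across the electrode, diameter / speed.  Supply either the electrode
    area (diameter derived as 2·√(area/π)) or the diameter directly; if
    both are given they must agree.
    """

    wave_speed_um_s: float = 500.0
    electrode_area_mm2: float | None = 1.0
    electrode_diameter_mm: float | None = None

    def __post_init__(self):
        if not self.wave_speed_um_s > 0:
            raise ParameterError("wave_speed_um_s must be positive")
        if self.electrode_area_mm2 is None and self.electrode_diameter_mm is None:
            raise ParameterError("need electrode area or diameter")
        if (self.electrode_area_mm2 is not None
                and self.electrode_diameter_mm is not None):
            derived = 2.0 * math.sqrt(self.electrode_area_mm2 / math.pi)
            if abs(derived - self.electrode_diameter_mm) > 1e-9:
                raise ParameterError(
                    "electrode_diameter_mm inconsistent with area")

    @property
    def diameter_mm(self) -> float:
        if self.electrode_diameter_mm is not None:
            return self.electrode_diameter_mm
        return 2.0 * math.sqrt(self.electrode_area_mm2 / math.pi)

    @property
    def separation_s(self) -> float:
        """Lobe-peak separation: diameter (µm) / speed (µm/s)."""
        return self.diameter_mm * 1000.0 / self.wave_speed_um_s


@dataclass(frozen=True)
class InhibitionProtocol:
    """Three-phase blocker protocol (durations in s).

    Defaults: 10 min of normal activity, a 20 min block (residual
    fluctuations capped below 5 pA), 10 min of recovery.
    """

    pre_duration_s: float = 600.0
    block_duration_s: float = 1200.0
    post_duration_s: float = 600.0
    residual_amplitude_pa: float = 5.0
    residual_rate_hz: float = 0.2

    def __post_init__(self):
        for name in ("pre_duration_s", "block_duration_s", "post_duration_s"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be positive")
        if self.residual_amplitude_pa < 0:
            raise ParameterError("residual_amplitude_pa must be >= 0")

    @property
    def total_duration_s(self) -> float:
        return (self.pre_duration_s + self.block_duration_s
                + self.post_duration_s)


@dataclass
class GroundTruth:
    """Event log of a simulation.

    ``events`` columns: time_s (peak of the event's first lobe),
    amplitude_pa (signed first-lobe peak), width_s, polarity ('+'/'-'),
    kind ('unipolar' | 'biphasic'), regime.  ``overlap_count`` reports
    how many inserted events superposed with an earlier one.
    """

    events: pd.DataFrame
    overlap_count: int = 0

    def __len__(self) -> int:
        return len(self.events)


GROUND_TRUTH_COLUMNS = ["time_s", "amplitude_pa", "width_s", "polarity",
                        "kind", "regime"]


# ---------------------------------------------------------------------------
# waveform primitives
# ---------------------------------------------------------------------------
def _noise_sigma_pa(pp_pa: float) -> float:
    return pp_pa / (2.0 * _PP_Z)


def _lobe_sigma(amp_pa: float, width_s: float) -> float:
    """Gaussian σ so the lobe's full width at the 50-pA level (or at half
    maximum for lobes below 100 pA) equals ``width_s``."""
    a = abs(amp_pa)
    if a <= 0:
        raise ParameterError("lobe amplitude must be nonzero")
    ref = _WIDTH_LEVEL_PA if a > 2.0 * _WIDTH_LEVEL_PA else a / 2.0
    return width_s / (2.0 * math.sqrt(2.0 * math.log(a / ref)))


class _Canvas:
    """Accumulates Gaussian lobes on a sample grid and counts overlaps."""

    def __init__(self, n: int, fs: float, t0: float = 0.0):
        self.trace = np.zeros(n)
        self.occupied = np.zeros(n, dtype=bool)
        self.n, self.fs, self.t0 = n, fs, t0
        self.overlaps = 0
        self.insertions = 0

    def _lobe_span(self, t_peak: float, sigma: float) -> tuple[int, int]:
        i0 = int(math.floor((t_peak - 5 * sigma - self.t0) * self.fs))
        i1 = int(math.ceil((t_peak + 5 * sigma - self.t0) * self.fs)) + 1
        return max(0, i0), min(self.n, i1)

    def span_free(self, t_peak: float, amp_pa: float, width_s: float) -> bool:
        """True when the lobe's support touches no earlier event."""
        i0, i1 = self._lobe_span(t_peak, _lobe_sigma(amp_pa, width_s))
        return not self.occupied[i0:i1].any()

    def add_event(self, lobes) -> None:
        """Insert one event given as [(t_peak, amp_pa, width_s), ...]."""
        spans = []
        for t_peak, amp_pa, width_s in lobes:
            sigma = _lobe_sigma(amp_pa, width_s)
            i0, i1 = self._lobe_span(t_peak, sigma)
            if i1 <= i0:
                continue
            t = self.t0 + np.arange(i0, i1) / self.fs
            self.trace[i0:i1] += amp_pa * np.exp(-((t - t_peak) ** 2)
                                                 / (2.0 * sigma ** 2))
            spans.append((i0, i1))
        if any(self.occupied[i0:i1].any() for i0, i1 in spans):
            self.overlaps += 1
        for i0, i1 in spans:
            self.occupied[i0:i1] = True
        self.insertions += 1


def biphasic_template(wave: WaveParams | None = None,
                      sync: SyncParams | None = None,
                      sampling_rate_hz: float = 1000.0) -> TimeSeries:
    """Canonical biphasic waveform: a positive then a negative Gaussian
    lobe of equal magnitude and width (zero net charge by symmetry).

    The lobe-peak separation comes from the wave transit time when
    ``wave`` is given, else from ``sync.biphasic_separation_s``.
    """
    sp = sync or SyncParams()
    sep = wave.separation_s if wave is not None else sp.biphasic_separation_s
    if sep < 2.0 / sampling_rate_hz:
        raise ResolutionError(
            f"lobe separation {sep:.3g} s spans fewer than 2 samples at "
            f"{sampling_rate_hz} Hz")
    width = math.sqrt(sp.width_low_s * sp.width_high_s)  # log-uniform median
    sigma = _lobe_sigma(sp.amplitude_pa, width)
    pad = 5.0 * sigma
    n = int(round((sep + 2 * pad) * sampling_rate_hz)) + 1
    t = np.arange(n) / sampling_rate_hz
    y = sp.amplitude_pa * (np.exp(-((t - pad) ** 2) / (2 * sigma ** 2))
                           - np.exp(-((t - pad - sep) ** 2) / (2 * sigma ** 2)))
    return TimeSeries(y, 1.0 / sampling_rate_hz, UNIT_CURRENT)


# ---------------------------------------------------------------------------
# event draws
# ---------------------------------------------------------------------------
def _loguniform(rng, low: float, high: float) -> float:
    return math.exp(rng.uniform(math.log(low), math.log(high)))


def _gen_async(rng, start: float, end: float, p: AsyncParams):
    """Poisson-timed unipolar events inside [start, end)."""
    n_ev = rng.poisson(p.event_rate_hz * (end - start))
    out = []
    for _ in range(n_ev):
        width = _loguniform(rng, p.width_low_s, p.width_high_s)
        amp = abs(rng.normal(p.amplitude_mean_pa, p.amplitude_sd_pa))
        sign = -1.0 if rng.random() < p.negative_polarity_prob else 1.0
        margin = 2.0 * width
        if end - start <= 2.0 * margin or amp <= 0:
            continue
        t = rng.uniform(start + margin, end - margin)
        out.append((t, sign * amp, width))
    out.sort(key=lambda e: e[0])
    return out


def _draw_isi(rng, p: SyncParams) -> float:
    if p.isi_jitter_sd_s == 0:
        return p.mean_isi_s
    a = (p.isi_low_s - p.mean_isi_s) / p.isi_jitter_sd_s
    b = (p.isi_high_s - p.mean_isi_s) / p.isi_jitter_sd_s
    return float(truncnorm.rvs(a, b, loc=p.mean_isi_s,
                               scale=p.isi_jitter_sd_s, random_state=rng))


def _gen_sync(rng, start: float, end: float, p: SyncParams, sep: float):
    """Quasi-periodic biphasic events inside [start, end)."""
    out = []
    t = start
    while True:
        isi = _draw_isi(rng, p)
        width = _loguniform(rng, p.width_low_s, p.width_high_s)
        t_next = t + isi
        if t_next + sep + 2.0 * width >= end:
            break
        out.append((t_next, p.amplitude_pa, width))
        t = t_next
    return out


# ---------------------------------------------------------------------------
# public simulators
# ---------------------------------------------------------------------------
def simulate_baseline(config: RecordingConfig) -> TimeSeries:
    """Medium-only recording: pure baseline noise, reproducible from the
    seed; identically zero when ``baseline_noise_pp_pa`` is 0."""
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.sampling_rate_hz))
    sigma = _noise_sigma_pa(config.baseline_noise_pp_pa)
    values = rng.normal(0.0, sigma, n) if sigma > 0 else np.zeros(n)
    return TimeSeries(values, 1.0 / config.sampling_rate_hz, UNIT_CURRENT)


def _check_sampling(config: RecordingConfig, *width_lows: float) -> None:
    shortest = min(width_lows)
    if config.sampling_rate_hz < 10.0 / shortest:
        raise ParameterError(
            f"sampling rate {config.sampling_rate_hz} Hz is below 10× the "
            f"reciprocal of the shortest spike width {shortest} s")


def simulate_recording(config: RecordingConfig, schedule,
                       async_params: AsyncParams | None = None,
                       sync_params: SyncParams | None = None,
                       wave: WaveParams | None = None,
                       ) -> tuple[TimeSeries, GroundTruth]:
    """Render a recording from a schedule of (regime label, duration).

    Asynchronous segments receive Poisson-timed unipolar spikes;
    synchronous segments receive quasi-periodic biphasic spikes whose
    lobe separation comes from ``wave`` when given, else from
    ``sync_params``.  Baseline noise spans the whole trace.  Events
    superpose linearly; the number that landed on already-occupied
    samples is reported in ``GroundTruth.overlap_count``.
    """
    ap = async_params or AsyncParams()
    sp = sync_params or SyncParams()
    schedule = list(schedule)
    if not schedule or any(d <= 0 for _, d in schedule):
        raise InputError("schedule must be non-empty with positive durations")
    total = float(sum(d for _, d in schedule))
    if abs(total - config.duration_s) > 1e-9 * max(1.0, total):
        raise InputError(
            f"schedule durations sum to {total} s but the recording lasts "
            f"{config.duration_s} s")
    _check_sampling(config, ap.width_low_s, sp.width_low_s)
    sep = wave.separation_s if wave is not None else sp.biphasic_separation_s
    if sep < 2.0 / config.sampling_rate_hz:
        raise ResolutionError("biphasic separation below 2 samples")
    if any(label == SYNCHRONOUS for label, _ in schedule) \
            and sp.mean_isi_s <= sep:
        raise ParameterError("mean_isi_s must exceed the lobe separation")

    fs = config.sampling_rate_hz
    n = int(round(total * fs))
    rng = np.random.default_rng(config.seed)
    sigma = _noise_sigma_pa(config.baseline_noise_pp_pa)
    noise = rng.normal(0.0, sigma, n) if sigma > 0 else np.zeros(n)
    canvas = _Canvas(n, fs)

    rows = []
    cursor = 0.0
    for label, dur in schedule:
        seg_start, seg_end = cursor, cursor + dur
        if label == ASYNCHRONOUS:
            for t, amp, width in _gen_async(rng, seg_start, seg_end, ap):
                canvas.add_event([(t, amp, width)])
                rows.append((t, amp, width, "+" if amp > 0 else "-",
                             "unipolar", label))
        elif label == SYNCHRONOUS:
            for t, amp, width in _gen_sync(rng, seg_start, seg_end, sp, sep):
                canvas.add_event([(t, amp, width), (t + sep, -amp, width)])
                rows.append((t, amp, width, "+", "biphasic", label))
        else:
            raise InputError(f"unknown regime label {label!r}")
        cursor = seg_end

    truth = pd.DataFrame(rows, columns=GROUND_TRUTH_COLUMNS)
    truth = truth.sort_values("time_s", kind="stable").reset_index(drop=True)
    ts = TimeSeries(noise + canvas.trace, 1.0 / fs, UNIT_CURRENT)
    return ts, GroundTruth(truth, canvas.overlaps)


def simulate_inhibition_experiment(config: RecordingConfig,
                                   protocol: InhibitionProtocol | None = None,
                                   async_params: AsyncParams | None = None,
                                   sync_params: SyncParams | None = None,
                                   regime: str = SYNCHRONOUS,
                                   wave: WaveParams | None = None,
                                   ):
    """Three-phase blocker experiment: normal activity, block, recovery.

    The pre and post phases draw from identical event distributions but
    independent random sub-streams, so their expected rates match.  The
    block phase carries only baseline noise plus sporadic sub-threshold
    residual lobes capped at 0.8 × ``residual_amplitude_pa``.  Returns
    (trace, ground truth, phase annotations).
    """
    prot = protocol or InhibitionProtocol()
    ap = async_params or AsyncParams()
    sp = sync_params or SyncParams()
    total = prot.total_duration_s
    if abs(total - config.duration_s) > 1e-9 * max(1.0, total):
        raise InputError(
            f"protocol lasts {total} s but the recording is configured for "
            f"{config.duration_s} s")
    _check_sampling(config, ap.width_low_s, sp.width_low_s)
    sep = wave.separation_s if wave is not None else sp.biphasic_separation_s

    fs = config.sampling_rate_hz
    n = int(round(total * fs))
    ss = np.random.SeedSequence(config.seed)
    s_noise, s_pre, s_block, s_post = ss.spawn(4)
    sigma = _noise_sigma_pa(config.baseline_noise_pp_pa)
    rng_noise = np.random.default_rng(s_noise)
    noise = rng_noise.normal(0.0, sigma, n) if sigma > 0 else np.zeros(n)
    canvas = _Canvas(n, fs)
    rows = []

    def fill_active(seed_seq, start, end):
        rng = np.random.default_rng(seed_seq)
        if regime == SYNCHRONOUS:
            for t, amp, width in _gen_sync(rng, start, end, sp, sep):
                canvas.add_event([(t, amp, width), (t + sep, -amp, width)])
                rows.append((t, amp, width, "+", "biphasic", regime))
        elif regime == ASYNCHRONOUS:
            for t, amp, width in _gen_async(rng, start, end, ap):
                canvas.add_event([(t, amp, width)])
                rows.append((t, amp, width, "+" if amp > 0 else "-",
                             "unipolar", regime))
        else:
            raise InputError(f"unknown regime label {regime!r}")

    t_block = prot.pre_duration_s
    t_post = t_block + prot.block_duration_s
    fill_active(s_pre, 0.0, t_block)
    if prot.residual_amplitude_pa > 0 and prot.residual_rate_hz > 0:
        rng = np.random.default_rng(s_block)
        n_res = rng.poisson(prot.residual_rate_hz * prot.block_duration_s)
        for _ in range(n_res):
            width = _loguniform(rng, ap.width_low_s, ap.width_high_s)
            # residual lobes capped at 0.8×cap so noise on top stays under it
            amp = rng.uniform(0.2, 0.8) * prot.residual_amplitude_pa
            sign = -1.0 if rng.random() < 0.5 else 1.0
            margin = 2.0 * width
            # residual lobes must not superpose, or their sum could break
            # the residual-amplitude cap; re-draw the time a few times
            for _ in range(20):
                t = rng.uniform(t_block + margin, t_post - margin)
                if canvas.span_free(t, sign * amp, width):
                    break
            else:
                continue
            canvas.add_event([(t, sign * amp, width)])
            rows.append((t, sign * amp, width, "+" if sign > 0 else "-",
                         "unipolar", BLOCKED))
    fill_active(s_post, t_post, total)

    truth = pd.DataFrame(rows, columns=GROUND_TRUTH_COLUMNS)
    truth = truth.sort_values("time_s", kind="stable").reset_index(drop=True)
    ts = TimeSeries(noise + canvas.trace, 1.0 / fs, UNIT_CURRENT)
    phases = [PhaseAnnotation("before", 0.0, t_block),
              PhaseAnnotation("during", t_block, t_post),
              PhaseAnnotation("after", t_post, total)]
    return ts, GroundTruth(truth, canvas.overlaps), phases
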