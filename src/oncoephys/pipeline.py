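"""End-to-end pipeline: simulate (or load) → detect → characterize →
optionally quantify inhibition → report and figures.

Outputs land in one directory: ``recording.h5``, ``events.csv``,
``stats.json``, ``report.json`` and publication-style figures (full
trace, zoomed spike, amplitude/width/ISI histograms, per-phase count
bars when an inhibition protocol ran).  Any stage failure removes the
partial outputs and re-raises with the stage name.  Given a fixed config
and seed the bundle is reproducible byte for byte (PNGs aside).
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from . import characterize as chz
from .detect import DetectionConfig, detect_spikes, events_to_frame, pair_biphasic
from .errors import InputError, PipelineError
from .inhibition import analyze_inhibition
from .io import (build_params, config_hash, read_recording, validate_config,
                 write_events_csv, write_phases_csv, write_recording)
from .simulate import (ASYNCHRONOUS, SYNCHRONOUS, RecordingConfig,
                       simulate_inhibition_experiment, simulate_recording)

log = logging.getLogger(__name__)

DEFAULT_SCHEDULE = [[ASYNCHRONOUS, 600.0], [SYNCHRONOUS, 600.0]]


def run_pipeline(config: dict, out_dir, seed: int | None = None) -> dict:
    """Execute the full analysis described by ``config``.

    ``seed`` overrides ``config['seed']`` when given.  Returns the report
    dict that is also written to ``report.json``.
    """
    config = validate_config(dict(config))
    if seed is not None:
        config["seed"] = int(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    meta = {"config_hash": config_hash(config),
            "seed": config.get("seed", 0)}

    stage = "validate"
    try:
        params = build_params(config)
        rec_block = dict(config.get("recording") or {})
        rec_block.setdefault("seed", config.get("seed", 0))
        schedule = [(str(lbl), float(dur))
                    for lbl, dur in config.get("schedule", DEFAULT_SCHEDULE)]
        phases = None
        truth = None

        if config.get("input"):
            stage = "load"
            rec = read_recording(config["input"])
        elif params["inhibition"] is not None:
            stage = "simulate"
            rec_block.setdefault("duration_s",
                                 params["inhibition"].total_duration_s)
            rc = RecordingConfig(**rec_block)
            if rc.duration_s != params["inhibition"].total_duration_s:
                raise InputError("recording duration must match the "
                                 "inhibition protocol duration")
            rec, truth, phases = simulate_inhibition_experiment(
                rc, params["inhibition"], params["async"], params["sync"],
                regime=config.get("regime", SYNCHRONOUS),
                wave=params["wave"])
        else:
            stage = "simulate"
            rec_block.setdefault("duration_s",
                                 sum(d for _, d in schedule))
            rc = RecordingConfig(**rec_block)
            rec, truth = simulate_recording(rc, schedule, params["async"],
                                            params["sync"],
                                            wave=params["wave"])
        if truth is not None:
            written.append(write_recording(out_dir / "recording.h5", rec,
                                           truth=truth, phases=phases,
                                           metadata=meta))

        stage = "detect"
        det_cfg = params["detection"] or DetectionConfig()
        events = pair_biphasic(detect_spikes(rec, det_cfg), det_cfg)
        log.info("detect: %d events", len(events))
        written.append(write_events_csv(out_dir / "events.csv", events,
                                        metadata=meta))

        stage = "characterize"
        ch = dict(config.get("characterization") or {})
        area = ch.pop("electrode_area_mm2", 1.0)
        diameter = ch.pop("electrode_diameter_mm", None)
        span = (rec.t0, rec.t0 + rec.duration)
        segments = chz.segment_regimes(events, span, **ch)
        stats = chz.spike_statistics(events, segments)
        wave_speed = chz.estimate_wave_speed(events, diameter_mm=diameter,
                                             area_mm2=area)
        stats_doc = dict(meta)
        stats_doc["segments"] = [
            {"start_s": s.start_s, "end_s": s.end_s, "label": s.label,
             "spike_count": s.spike_count, "spike_rate_hz": s.spike_rate_hz}
            for s in segments]
        stats_doc["per_regime"] = {k: v.to_dict() for k, v in stats.items()}
        stats_doc["wave_speed"] = {
            "median_um_s": wave_speed.median_um_s,
            "n_pairs": wave_speed.n_pairs,
        }
        path = out_dir / "stats.json"
        path.write_text(json.dumps(stats_doc, indent=2, default=float))
        written.append(path)

        report = dict(meta)
        report["n_events"] = len(events)
        report["per_regime_counts"] = {s.label: s.spike_count
                                       for s in segments}
        report["wave_speed_median_um_s"] = wave_speed.median_um_s
        if truth is not None:
            report["ground_truth_events"] = len(truth)
            report["overlap_count"] = truth.overlap_count

        if phases is not None:
            stage = "inhibition"
            inh = analyze_inhibition(rec, events, phases)
            report["inhibition"] = inh.to_dict()
            written.append(write_phases_csv(out_dir / "phases.csv", phases,
                                            metadata=meta))

        stage = "report"
        path = out_dir / "report.json"
        path.write_text(json.dumps(report, indent=2, default=float))
        written.append(path)

        stage = "plots"
        written.extend(_make_figures(out_dir, rec, events, stats, report))
    except Exception as exc:  # noqa: BLE001 - single cleanup funnel
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc
    return report


def _make_figures(out_dir: Path, rec, events, stats, report) -> list[Path]:
    made = []

    def save(fig, name):
        p = out_dir / name
        fig.savefig(p, dpi=110)
        plt.close(fig)
        made.append(p)

    # full trace, decimated for plotting only
    step = max(1, rec.n // 200_000)
    fig, ax = plt.subplots(figsize=(9, 3))
    ax.plot(rec.times[::step], rec.values_pa[::step], lw=0.4, color="k")
    ax.set(xlabel="time (s)", ylabel="current (pA)", title="recording")
    save(fig, "trace.png")

    if events:
        big = max(events, key=lambda e: abs(e.amplitude_pa))
        sub = rec.slice_time(max(rec.t0, big.peak_time_s - 2.0),
                             min(rec.t0 + rec.duration,
                                 big.peak_time_s + 2.0))
        fig, ax = plt.subplots(figsize=(5, 3))
        ax.plot(sub.times, sub.values_pa, color="k")
        ax.set(xlabel="time (s)", ylabel="current (pA)",
               title="largest spike")
        save(fig, "spike_zoom.png")

    label = SYNCHRONOUS if SYNCHRONOUS in stats else next(iter(stats), None)
    if label is not None:
        st = stats[label]
        fig, axes = plt.subplots(1, 3, figsize=(11, 3))
        for ax, hist, title, unit in (
                (axes[0], st.amplitude_histogram, "amplitude", "pA"),
                (axes[1], st.width_histogram, "width", "s"),
                (axes[2], st.isi_histogram, "inter-spike interval", "s")):
            edges = np.asarray(hist.edges, dtype=float)
            finite = np.isfinite(edges)
            lo = edges[finite].min() if finite.any() else 0.0
            hi = edges[finite].max() if finite.any() else 1.0
            left = np.where(np.isfinite(edges[:-1]), edges[:-1],
                            lo - (hi - lo) * 0.05)
            right = np.where(np.isfinite(edges[1:]), edges[1:],
                             hi + (hi - lo) * 0.05)
            ax.bar(left, hist.counts, width=right - left, align="edge",
                   color="tab:blue", edgecolor="k", lw=0.4)
            ax.set(xlabel=f"{title} ({unit})", ylabel="spikes",
                   title=f"{label}: {title}")
        fig.tight_layout()
        save(fig, "histograms.png")

    if "inhibition" in report:
        counts = report["inhibition"]["spike_counts"]
        fig, ax = plt.subplots(figsize=(4, 3))
        labels = ["before", "during", "after"]
        ax.bar(labels, [counts[k] for k in labels], color="tab:red")
        ax.set(ylabel="spikes detected", title="inhibitor block/recovery")
        save(fig, "phase_counts.png")
    return made
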