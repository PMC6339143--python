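"""File formats and configuration.

Recordings travel as CSV (columns ``time_s,current_pA``) or HDF5
(dataset ``/current_pA`` with ``dt_s``/``t0_s`` attributes, optional
``/truth`` and ``/phases`` groups).  Event tables and phase annotations
are CSV.  Every file written here carries the seed and a config hash in
its metadata (CSV header comments / HDF5 root attributes / JSON fields).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .detect import DetectionConfig, events_from_frame, events_to_frame
from .circuit import CircuitParams
from .errors import FormatError, InputError
from .inhibition import PhaseAnnotation
from .simulate import (AsyncParams, GroundTruth, GROUND_TRUTH_COLUMNS,
                       InhibitionProtocol, RecordingConfig, SyncParams,
                       WaveParams)
from .timeseries import TimeSeries, UNIT_CURRENT

_DT_JITTER_TOL = 0.01  # relative, for CSV time columns


# ---------------------------------------------------------------------------
# metadata helpers
# ---------------------------------------------------------------------------
def config_hash(config: dict) -> str:
    """Short stable hash of a config mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _meta_lines(metadata: dict | None) -> str:
    if not metadata:
        return ""
    return "".join(f"# {k}={v}\n" for k, v in sorted(metadata.items()))


def _read_meta_lines(path: Path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                key, _, value = line[1:].strip().partition("=")
                meta[key.strip()] = value.strip()
    return meta


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------
def write_recording(path, rec: TimeSeries, truth: GroundTruth | None = None,
                    phases=None, metadata: dict | None = None) -> Path:
    """Write a current trace (plus optional truth/phases) to .csv or .h5."""
    rec.require_unit(UNIT_CURRENT)
    path = Path(path)
    if path.suffix == ".csv":
        meta = dict(metadata or {})
        meta["dt_s"] = repr(rec.dt)  # repr round-trips the exact double
        meta["t0_s"] = repr(rec.t0)
        with open(path, "w") as fh:
            fh.write(_meta_lines(meta))
            fh.write("time_s,current_pA\n")
            np.savetxt(fh, np.column_stack([rec.times, rec.values_pa]),
                       fmt="%.17g", delimiter=",")
    elif path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            d = f.create_dataset("current_pA", data=rec.values_pa)
            d.attrs["dt_s"] = rec.dt
            d.attrs["t0_s"] = rec.t0
            d.attrs["units"] = "pA"
            for k, v in (metadata or {}).items():
                f.attrs[k] = v
            if truth is not None:
                g = f.create_group("truth")
                df = truth.events
                for col in ("time_s", "amplitude_pa", "width_s"):
                    g.create_dataset(col, data=df[col].to_numpy(float))
                for col in ("polarity", "kind", "regime"):
                    g.create_dataset(
                        col, data=df[col].astype(str).to_numpy(dtype="S16"))
                g.attrs["overlap_count"] = truth.overlap_count
            if phases is not None:
                g = f.create_group("phases")
                g.create_dataset("label", data=np.array(
                    [p.label for p in phases], dtype="S16"))
                g.create_dataset("start_s",
                                 data=np.array([p.start_s for p in phases]))
                g.create_dataset("end_s",
                                 data=np.array([p.end_s for p in phases]))
    else:
        raise FormatError(f"unsupported recording extension {path.suffix!r}")
    return path


def read_recording(path, strict_units: bool = False) -> TimeSeries:
    """Load a current trace; format inferred from the extension.

    CSV time columns must be uniformly sampled (relative dt jitter below
    1%).  Missing unit information defaults to pA unless ``strict_units``.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.suffix == ".csv":
        header_meta = _read_meta_lines(path)
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
        for col in ("time_s", "current_pA"):
            if col not in df.columns:
                if col == "current_pA" and strict_units:
                    raise FormatError("CSV lacks a current_pA column")
                raise FormatError(f"CSV lacks the {col!r} column")
        t = df["time_s"].to_numpy(float)
        if t.size < 2:
            raise InputError("recording shorter than 2 samples")
        dts = np.diff(t)
        dt = float(np.median(dts))
        if dt <= 0 or np.max(np.abs(dts - dt)) > _DT_JITTER_TOL * dt:
            raise FormatError(
                "time_s column is not uniformly sampled (jitter above 1%)")
        # header metadata carries the exact dt/t0, free of print rounding
        if "dt_s" in header_meta:
            dt = float(header_meta["dt_s"])
        t0 = float(header_meta.get("t0_s", t[0]))
        return TimeSeries.from_pa(df["current_pA"].to_numpy(float), dt,
                                  t0=t0)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if "current_pA" not in f:
                raise FormatError(
                    "HDF5 file lacks the 'current_pA' dataset")
            d = f["current_pA"]
            if strict_units and "units" not in d.attrs:
                raise FormatError("current_pA dataset carries no unit")
            dt = float(d.attrs["dt_s"])
            t0 = float(d.attrs.get("t0_s", 0.0))
            return TimeSeries.from_pa(d[...], dt, t0=t0)
    raise FormatError(f"unsupported recording extension {path.suffix!r}")


def read_truth(path) -> GroundTruth:
    """Ground-truth table from an HDF5 recording written by this package."""
    with h5py.File(path, "r") as f:
        if "truth" not in f:
            raise FormatError("HDF5 file lacks the 'truth' group")
        g = f["truth"]
        data = {col: g[col][...] for col in GROUND_TRUTH_COLUMNS}
        for col in ("polarity", "kind", "regime"):
            data[col] = [b.decode() for b in data[col]]
        return GroundTruth(pd.DataFrame(data)[GROUND_TRUTH_COLUMNS],
                           int(g.attrs.get("overlap_count", 0)))


def read_phases_h5(path) -> list[PhaseAnnotation]:
    with h5py.File(path, "r") as f:
        if "phases" not in f:
            raise FormatError("HDF5 file lacks the 'phases' group")
        g = f["phases"]
        return [PhaseAnnotation(lbl.decode(), float(a), float(b))
                for lbl, a, b in zip(g["label"][...], g["start_s"][...],
                                     g["end_s"][...])]


# ---------------------------------------------------------------------------
# events and phases as CSV
# ---------------------------------------------------------------------------
def write_events_csv(path, events, metadata: dict | None = None) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_meta_lines(metadata))
        events_to_frame(events).to_csv(fh, index=False)
    return path


def read_events_csv(path):
    return events_from_frame(pd.read_csv(Path(path), comment="#",
                                         keep_default_na=False))


def write_phases_csv(path, phases, metadata: dict | None = None) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_meta_lines(metadata))
        fh.write("label,start_s,end_s\n")
        for p in phases:
            fh.write(f"{p.label},{p.start_s!r},{p.end_s!r}\n")
    return path


def read_phases_csv(path) -> list[PhaseAnnotation]:
    df = pd.read_csv(Path(path), comment="#")
    return [PhaseAnnotation(str(r.label), float(r.start_s), float(r.end_s))
            for r in df.itertuples(index=False)]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------
_CONFIG_BLOCKS = {
    "circuit": CircuitParams,
    "recording": RecordingConfig,
    "async": AsyncParams,
    "sync": SyncParams,
    "wave": WaveParams,
    "inhibition": InhibitionProtocol,
    "detection": DetectionConfig,
}
_CHARACTERIZATION_KEYS = {"window_s", "rate_cutoff_hz", "cv_cutoff",
                          "electrode_area_mm2", "electrode_diameter_mm"}
_TOP_LEVEL_KEYS = (set(_CONFIG_BLOCKS) | {"characterization", "schedule",
                                          "seed", "input", "regime"})


def validate_config(config: dict) -> dict:
    """Reject unknown keys at the top level and inside each block."""
    unknown = set(config) - _TOP_LEVEL_KEYS
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}")
    for block, cls in _CONFIG_BLOCKS.items():
        sub = config.get(block)
        if sub is None:
            continue
        allowed = {f.name for f in dataclasses.fields(cls)}
        bad = set(sub) - allowed
        if bad:
            raise FormatError(
                f"unknown keys in {block!r} block: {sorted(bad)}")
    bad = set(config.get("characterization") or {}) - _CHARACTERIZATION_KEYS
    if bad:
        raise FormatError(
            f"unknown keys in 'characterization' block: {sorted(bad)}")
    return config


def load_config(path) -> dict:
    """YAML or JSON pipeline configuration with strict key validation."""
    path = Path(path)
    with open(path) as fh:
        config = (json.load(fh) if path.suffix == ".json"
                  else yaml.safe_load(fh))
    if not isinstance(config, dict):
        raise FormatError("config must be a mapping")
    return validate_config(config)


def build_params(config: dict):
    """Instantiate the dataclass blocks present in a validated config."""
    out = {}
    for block, cls in _CONFIG_BLOCKS.items():
        sub = config.get(block)
        out[block] = cls(**sub) if sub is not None else None
    return out
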