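"""Readers and writers for movies, traces, results, and configuration.

Movies travel as multi-page TIFF (with a mandatory YAML sidecar carrying the
sampling rate) or as HDF5 (one 3-D dataset with ``rate_hz``, ``channel`` and
``saturation_level`` attributes).  Traces are two-column CSV
(``time_s,value``); result objects are JSON with a schema version, the seed,
and an echo of the configuration that produced them.  Rate metadata is never
guessed: a movie file without it is an error.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Any

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .datamodel import Movie, RunConfig, StimulusEvent, StimulusProtocol, Trace

SCHEMA_VERSION = 1


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def save_movie(movie: Movie, path: str | Path, format: str | None = None) -> None:
    """Write a movie as TIFF (+ YAML sidecar) or HDF5.

    The format is inferred from the suffix unless given explicitly.  On disk
    intensities are unsigned 16-bit for TIFF (camera convention); HDF5 keeps
    the in-memory dtype.
    """
    path = Path(path)
    fmt = format or ("hdf5" if path.suffix in {".h5", ".hdf5"} else "tiff")
    meta = {"rate_hz": float(movie.rate), "channel": movie.channel,
            "saturation_level": float(movie.saturation_level)}
    if fmt == "tiff":
        frames = np.clip(np.round(movie.frames), 0, 65535).astype(np.uint16)
        tifffile.imwrite(path, frames)
        with open(_sidecar_path(path), "w") as fh:
            yaml.safe_dump(meta, fh)
    elif fmt == "hdf5":
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("frames", data=movie.frames)
            for k, v in meta.items():
                ds.attrs[k] = v
    else:
        raise ValueError(f"unknown movie format {fmt!r}")


def load_movie(path: str | Path, format: str | None = None) -> Movie:
    """Load a time-major movie from multi-page TIFF or HDF5.

    Raises if the file is unreadable, not 3-D, or lacks rate metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("hdf5" if path.suffix in {".h5", ".hdf5"} else "tiff")
    if fmt == "tiff":
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            raise ValueError("shape not 3-D: single-page image is not a movie")
        if frames.ndim != 3:
            raise ValueError(f"shape not 3-D: got {frames.ndim}-D data")
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise ValueError(f"missing rate metadata: no sidecar {sidecar}")
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}
        if "rate_hz" not in meta:
            raise ValueError("missing rate metadata: sidecar lacks rate_hz")
        return Movie(frames.astype(float), rate=float(meta["rate_hz"]),
                     saturation_level=float(meta.get("saturation_level", 65535)),
                     channel=meta.get("channel", "green"))
    if fmt == "hdf5":
        with h5py.File(path, "r") as fh:
            keys = [k for k in fh.keys()
                    if isinstance(fh[k], h5py.Dataset)]
            if not keys:
                raise ValueError("no dataset found in HDF5 file")
            ds = fh[keys[0]]
            if ds.ndim != 3:
                raise ValueError(f"shape not 3-D: got {ds.ndim}-D dataset")
            if "rate_hz" not in ds.attrs:
                raise ValueError("missing rate metadata: rate_hz attribute")
            return Movie(np.asarray(ds, dtype=float),
                         rate=float(ds.attrs["rate_hz"]),
                         saturation_level=float(
                             ds.attrs.get("saturation_level", 65535)),
                         channel=str(ds.attrs.get("channel", "green")))
    raise ValueError(f"unknown movie format {fmt!r}")


def save_trace(trace: Trace, path: str | Path) -> None:
    """Write a trace as ``time_s,value`` CSV."""
    pd.DataFrame({"time_s": trace.times, "value": trace.values}).to_csv(
        path, index=False)


def load_trace(path: str | Path, units: str = "a.u.",
               polarity: str = "positive_up") -> Trace:
    """Read a ``time_s,value`` CSV written by :func:`save_trace`.

    The rate is recovered from the (uniform) time grid.
    """
    df = pd.read_csv(path)
    if not {"time_s", "value"} <= set(df.columns):
        raise ValueError("trace CSV must have columns time_s,value")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("trace CSV needs at least two samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise ValueError("trace CSV time grid is not uniform")
    return Trace(df["value"].to_numpy(dtype=float), rate=1.0 / dt[0],
                 t0_offset=float(t[0]), units=units, polarity=polarity)


def _encode(obj: Any) -> Any:
    """Recursively convert a result object to JSON-serializable values.

    Non-finite floats become ``None`` with no information loss: a parallel
    ``_nonfinite`` map records which fields were NaN/inf so the round-trip
    is explicit rather than silent.
    """
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        out: dict[str, Any] = {"_type": type(obj).__name__}
        flags = {}
        for f in dataclasses.fields(obj):
            val = getattr(obj, f.name)
            enc = _encode(val)
            if isinstance(val, float) and not math.isfinite(val):
                flags[f.name] = repr(val)
                enc = None
            out[f.name] = enc
        if flags:
            out["_nonfinite"] = flags
        return out
    if isinstance(obj, np.ndarray):
        return {"_ndarray": obj.tolist(), "dtype": str(obj.dtype)}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    if isinstance(obj, dict):
        return {k: _encode(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_encode(v) for v in obj]
    return obj


def save_results(result: Any, path: str | Path, *, config: Any = None,
                 seed: int | None = None) -> None:
    """Serialize a toolkit result object to JSON.

    The document carries a schema version, an echo of the configuration and
    the seed used, and the result payload.  Numeric fields round-trip at full
    precision; non-finite values are stored as explicit nulls with a flag.
    """
    doc = {"schema_version": SCHEMA_VERSION,
           "seed": seed,
           "config": _encode(config),
           "result": _encode(result)}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_results(path: str | Path, registry: dict[str, type] | None = None) -> Any:
    """Load a JSON result document; reconstructs dataclasses via ``registry``."""
    with open(path) as fh:
        doc = json.load(fh)

    def _decode(node: Any) -> Any:
        if isinstance(node, dict):
            if "_ndarray" in node:
                return np.asarray(node["_ndarray"], dtype=node.get("dtype"))
            if "_type" in node:
                flags = node.get("_nonfinite", {})
                fields = {k: _decode(v) for k, v in node.items()
                          if not k.startswith("_")}
                for name, rep in flags.items():
                    fields[name] = float(rep)
                cls = (registry or {}).get(node["_type"])
                if cls is not None:
                    return cls(**fields)
                return fields
            return {k: _decode(v) for k, v in node.items()}
        if isinstance(node, list):
            return [_decode(v) for v in node]
        return node

    doc["result"] = _decode(doc["result"])
    return doc


def save_protocol(protocol: StimulusProtocol, path: str | Path) -> None:
    events = [{"onset": e.onset, "duration": e.duration, "kind": e.kind,
               "frequency": e.frequency, "amplitude": e.amplitude}
              for e in protocol.events]
    with open(path, "w") as fh:
        yaml.safe_dump({"events": events}, fh)


def load_protocol(path: str | Path) -> StimulusProtocol:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return StimulusProtocol([StimulusEvent(**ev) for ev in doc["events"]])


def load_config(path: str | Path) -> RunConfig:
    """Read a :class:`RunConfig` from YAML."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if "band_edges" in doc and doc["band_edges"] is not None:
        doc["band_edges"] = [tuple(b) for b in doc["band_edges"]]
    if "baseline_window" in doc:
        doc["baseline_window"] = tuple(doc["baseline_window"])
    return RunConfig(**doc)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    doc = dataclasses.asdict(cfg)
    doc["band_edges"] = [list(b) for b in cfg.band_edges]
    doc["baseline_window"] = list(cfg.baseline_window)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh)
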