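"""Reading and writing signals as flat binary or delimited text.

A signal on disk is a data file plus a small JSON sidecar (same path with
``.json`` appended) recording the sampling rate, dtype and any generator
parameters — enough to reload it without guessing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .signals import PhaseSeries, TimeSeries

__all__ = ["write_timeseries", "read_timeseries", "write_phases", "read_phases"]

_DTYPES = {"int16": np.int16, "float64": np.float64}


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_timeseries(
    ts: TimeSeries,
    path: str | Path,
    fmt: str = "float64",
    metadata: dict | None = None,
) -> None:
    """Write samples as flat binary (int16 or float64) or text (fmt='txt')."""
    path = Path(path)
    meta = {"fs": ts.fs, "n_samples": len(ts), "format": fmt}
    if metadata:
        meta.update(metadata)
    if fmt == "txt":
        np.savetxt(path, ts.samples)
    elif fmt in _DTYPES:
        x = ts.samples
        if fmt == "int16":
            scale = float(np.max(np.abs(x))) or 1.0
            meta["int16_scale"] = scale
            x = np.round(x / scale * 32767).astype(np.int16)
        else:
            x = x.astype(np.float64)
        x.tofile(path)
    else:
        raise ValueError("format must be 'int16', 'float64' or 'txt'")
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_timeseries(path: str | Path, fs: float | None = None, fmt: str | None = None) -> TimeSeries:
    """Read a signal written by :func:`write_timeseries`, or any flat file.

    Without a sidecar, ``fs`` (and ``fmt`` for binary) must be given.
    """
    path = Path(path)
    meta: dict = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    fs = fs if fs is not None else meta.get("fs")
    if fs is None:
        raise ValueError("sampling rate unknown: pass fs or provide a sidecar")
    fmt = fmt or meta.get("format", "txt")
    if fmt == "txt":
        x = np.loadtxt(path, ndmin=1)
    elif fmt in _DTYPES:
        x = np.fromfile(path, dtype=_DTYPES[fmt]).astype(float)
        if fmt == "int16":
            x = x / 32767.0 * meta.get("int16_scale", 1.0)
    else:
        raise ValueError("format must be 'int16', 'float64' or 'txt'")
    return TimeSeries(x, float(fs))


def write_phases(ps: PhaseSeries, path: str | Path, fmt: str = "float64") -> None:
    """Write a phase series (radians) as float64 binary or text."""
    path = Path(path)
    meta = {"fs": ps.fs, "n_samples": len(ps), "format": fmt, "kind": "phase"}
    if fmt == "txt":
        np.savetxt(path, ps.phases)
    elif fmt == "float64":
        ps.phases.astype(np.float64).tofile(path)
    else:
        raise ValueError("phase format must be 'float64' or 'txt'")
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_phases(path: str | Path, fs: float | None = None) -> PhaseSeries:
    path = Path(path)
    meta: dict = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    fs = fs if fs is not None else meta.get("fs")
    if fs is None:
        raise ValueError("sampling rate unknown: pass fs or provide a sidecar")
    if meta.get("format", "txt") == "txt":
        x = np.loadtxt(path, ndmin=1)
    else:
        x = np.fromfile(path, dtype=np.float64)
    return PhaseSeries(x, float(fs))
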