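"""CSV/JSON readers and writers.

CSV is the canonical interchange format: one numeric column of samples
(sampling rate supplied separately) or two columns (time in seconds, value).
Reports are versioned JSON documents carrying everything needed to replay a
run: resolved configuration, per-layer rules, periodicity scores, and the
full search traces.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import ParseError
from .pipeline import DenoiseResult
from .signals import SampledSignal

__all__ = ["read_signal", "write_signal", "write_result", "REPORT_SCHEMA_VERSION"]

REPORT_SCHEMA_VERSION = 1

# relative tolerance on time-step uniformity for two-column (time, value) input
_MAX_TIME_JITTER = 1e-3


def _sanitize(obj):
    """Replace non-finite floats with JSON-safe string sentinels, recursively."""
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, float):
        if math.isnan(obj):
            return "nan"
        if math.isinf(obj):
            return "inf" if obj > 0 else "-inf"
    return obj


def read_signal(path: Union[str, Path], fs_override: Optional[float] = None) -> SampledSignal:
    """Read a signal from CSV.

    One numeric column: sample values; ``fs_override`` is then required.
    Two columns: (time [s], value); the sampling rate is inferred from the
    median time step, which must be uniform to within 0.1%.  A first row of
    non-numeric text is treated as a header.  Non-numeric or non-finite data
    rows raise :class:`ParseError` naming the offending row (1-based, header
    included).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, header=None, comment="#", skip_blank_lines=True)
    except Exception as exc:
        raise ParseError(f"cannot read CSV {path}: {exc}") from exc
    if df.shape[1] not in (1, 2):
        raise ParseError(f"{path}: expected 1 or 2 columns, found {df.shape[1]}")
    offset = 1
    num = df.apply(pd.to_numeric, errors="coerce")
    if num.iloc[0].isna().all() and not df.iloc[0].isna().all():
        num = num.iloc[1:].reset_index(drop=True)  # header row
        offset = 2
    bad = np.flatnonzero(~np.isfinite(num.to_numpy(dtype=float)).all(axis=1))
    if bad.size:
        raise ParseError(
            f"{path}: non-numeric or non-finite value at row {bad[0] + offset}",
            row=int(bad[0] + offset),
        )
    if num.shape[1] == 1:
        if fs_override is None:
            raise ParseError(f"{path}: single-column CSV requires a sampling rate")
        return SampledSignal(num[0].to_numpy(float), fs_override, label=path.name)
    t = num[0].to_numpy(float)
    v = num[1].to_numpy(float)
    dt = np.diff(t)
    if dt.size == 0 or np.any(dt <= 0):
        raise ParseError(f"{path}: time column must be strictly increasing")
    step = float(np.median(dt))
    jitter = float(np.max(np.abs(dt - step)) / step)
    if jitter > _MAX_TIME_JITTER:
        raise ParseError(
            f"{path}: non-uniform time steps (relative jitter {jitter:.2e} > {_MAX_TIME_JITTER})"
        )
    fs = fs_override if fs_override is not None else 1.0 / step
    return SampledSignal(v, fs, label=path.name)


def write_signal(signal: SampledSignal, path: Union[str, Path]) -> Path:
    """Write sample values to a single-column CSV."""
    path = Path(path)
    np.savetxt(path, signal.samples, fmt="%.12g")
    return path


def write_result(result: DenoiseResult, out_prefix: Union[str, Path]) -> tuple[Path, Path]:
    """Write ``<prefix>.csv`` (denoised samples) and ``<prefix>.report.json``.

    The report carries the schema version, tool version, resolved
    configuration, per-layer (threshold, tuning) rules, periodicity scores
    before/after, and the full search traces.
    """
    prefix = Path(out_prefix)
    csv_path = prefix.with_name(prefix.name + ".csv")
    json_path = prefix.with_name(prefix.name + ".report.json")
    write_signal(result.output, csv_path)
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "tool_version": __version__,
        "fs": result.output.fs,
        "n_samples": len(result.output),
        **result.to_dict(),
    }
    json_path.write_text(json.dumps(_sanitize(report), indent=2))
    return csv_path, json_path
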