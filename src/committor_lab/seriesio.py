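"""Plain columnar exchange format for CV/RC time series.

CSV with header ``frame_index,segment_id,value``; lossless round trip of
the value column at full double precision, segment structure preserved.
A JSON sidecar can carry channel metadata (which sorted-distance element
or named observable a series came from).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = ["write_series", "read_series", "write_meta", "read_meta"]

_HEADER = "frame_index,segment_id,value"


def write_series(path, values: np.ndarray, segment_ids: np.ndarray) -> None:
    values = np.asarray(values, dtype=np.float64)
    segment_ids = np.asarray(segment_ids, dtype=np.int64)
    if len(values) != len(segment_ids):
        raise ValueError("values and segment_ids must have equal length")
    with open(path, "w") as f:
        f.write(_HEADER + "\n")
        for k, (s, v) in enumerate(zip(segment_ids, values)):
            f.write(f"{k},{s},{float(v)!r}\n")


def read_series(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a series file; malformed or non-finite rows are reported with
    their 1-based line number."""
    values, segments = [], []
    with open(path) as f:
        header = f.readline().strip()
        if header != _HEADER:
            raise ValueError(f"{path}: unexpected header {header!r}")
        for lineno, line in enumerate(f, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 3:
                raise ValueError(f"{path}: malformed row at line {lineno}: {line!r}")
            try:
                seg = int(parts[1])
                val = float(parts[2])
            except ValueError as e:
                raise ValueError(f"{path}: unparsable row at line {lineno}") from e
            if not np.isfinite(val):
                raise ValueError(f"{path}: non-finite value at line {lineno}")
            segments.append(seg)
            values.append(val)
    return np.array(values, dtype=np.float64), np.array(segments, dtype=np.int64)


def write_meta(path, meta: dict) -> None:
    Path(path).write_text(json.dumps(meta, indent=2, default=str) + "\n")


def read_meta(path) -> dict:
    return json.loads(Path(path).read_text())
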