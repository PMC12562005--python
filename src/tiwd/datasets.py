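"""Built-in lifetime datasets and plain-text/CSV sample I/O.

Two classical complete samples ship with the package, stored as the printed
decimal strings (parsed, never re-rounded):

* ``metal_fatigue`` — fatigue life of 46 metal components, in cycles.
* ``head_neck_cancer`` — survival times of 44 head-and-neck cancer patients.
  Stored in published order (including 78.26 printed before 74.74);
  estimation routines sort internally.
"""

from __future__ import annotations

import csv
import io
import os

import numpy as np

from .distribution import LifetimeSample

__all__ = ["DATASETS", "load_builtin_dataset", "read_sample", "write_sample"]

_METAL_FATIGUE = """
125 127 135 137 185 187 190 190 195 200
212 242 245 255 283 316 327 355 373 386
456 482 552 580 700 736 745 750 804 852
884 977 1040 1066 1093 1114 1125 1300 1536 1583
2208 2266 2834 3280 4707 5046
"""

_HEAD_NECK_CANCER = """
12.20 23.56 23.74 25.87 31.98 37 41.35 47.38 55.46 58.36
63.47 68.46 78.26 74.74 81.43 84 92 94 110 112
119 127 130 133 140 146 155 159 173 179
194 195 209 249 281 319 339 432 469 519
633 725 817 1776
"""

DATASETS = {
    "metal_fatigue": _METAL_FATIGUE,
    "head_neck_cancer": _HEAD_NECK_CANCER,
}


def load_builtin_dataset(key: str) -> LifetimeSample:
    """Return a packaged dataset by key ('metal_fatigue' or 'head_neck_cancer')."""
    try:
        raw = DATASETS[key]
    except KeyError:
        raise KeyError(
            f"unknown dataset {key!r}; available: {sorted(DATASETS)}"
        ) from None
    return LifetimeSample([float(tok) for tok in raw.split()])


def read_sample(path: str | os.PathLike, column: str | None = None) -> LifetimeSample:
    """Read a sample from one-value-per-line text or a CSV column.

    Nonpositive, NaN or unparsable entries raise with the 1-based row index.
    """
    with open(path, "r", newline="") as fh:
        text = fh.read()
    if not text.strip():
        raise ValueError(f"{path}: empty file")
    first = text.lstrip().splitlines()[0]
    values: list[float] = []
    if column is not None or "," in first:
        reader = csv.DictReader(io.StringIO(text)) if _has_header(first) else None
        if reader is not None:
            col = column or reader.fieldnames[0]
            if col not in reader.fieldnames:
                raise ValueError(f"{path}: no column named {col!r}")
            for i, row in enumerate(reader, start=2):  # row 1 is the header
                values.append(_parse(row[col], path, i))
        else:
            for i, line in enumerate(io.StringIO(text), start=1):
                if line.strip():
                    values.append(_parse(line.split(",")[0], path, i))
    else:
        for i, line in enumerate(io.StringIO(text), start=1):
            if line.strip():
                values.append(_parse(line, path, i))
    if not values:
        raise ValueError(f"{path}: no data rows")
    _validate_rows(values, path)
    return LifetimeSample(values)


def _has_header(first_line: str) -> bool:
    try:
        float(first_line.split(",")[0])
        return False
    except ValueError:
        return True


def _parse(token: str, path, row: int) -> float:
    try:
        v = float(token.strip())
    except (TypeError, ValueError):
        raise ValueError(f"{path}: unparsable value {token!r} at row {row}") from None
    return v


def _validate_rows(values, path) -> None:
    for i, v in enumerate(values, start=1):
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"{path}: nonpositive or non-finite value {v} at row {i}")


def write_sample(sample: LifetimeSample, path: str | os.PathLike) -> None:
    """Write a sample as one value per line (round-trips through read_sample)."""
    with open(path, "w") as fh:
        for v in sample.values:
            fh.write(f"{float(v)!r}\n")
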