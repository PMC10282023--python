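"""Reading angle files.

Field data commonly arrive as compass bearings in degrees, so degrees are the
default input unit (a notice is logged); radians by request.  Two layouts are
supported: plain text with one angle per line, and CSV with a named or
numbered column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .core import AngleSample

logger = logging.getLogger("circart")

__all__ = ["AngleFileSpec", "read_angles"]


@dataclass(frozen=True)
class AngleFileSpec:
    """Where and how to read one sample of angles.

    ``column=None`` means plain text, one angle per line; otherwise the file
    is parsed as CSV and ``column`` names (str) or indexes (int) the column
    holding the angles.
    """

    path: Union[str, Path]
    unit: str = "degrees"
    column: Optional[Union[str, int]] = None
    header: bool = True


def _read_plain(path: Path) -> list[float]:
    values = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            try:
                values.append(float(text))
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: {text!r} is not a number"
                ) from None
    return values


def _read_csv(path: Path, column, header: bool) -> list[float]:
    df = pd.read_csv(path, header=0 if header else None)
    if isinstance(column, int) and column not in df.columns:
        try:
            series = df.iloc[:, column]
        except IndexError:
            raise ValueError(
                f"{path}: no column index {column} (file has {df.shape[1]} columns)"
            ) from None
    else:
        if column not in df.columns:
            raise ValueError(
                f"{path}: no column {column!r}; available: {list(df.columns)}"
            )
        series = df[column]
    numeric = pd.to_numeric(series, errors="coerce")
    bad = numeric.isna() & series.notna()
    if bad.any():
        # +2 = 1-based line numbering plus the header line
        first = int(bad.idxmax()) + (2 if header else 1)
        raise ValueError(
            f"{path}: line {first}: {series[bad.idxmax()]!r} is not a number"
        )
    if numeric.isna().any():
        raise ValueError(f"{path}: column {column!r} contains missing values")
    return numeric.tolist()


def read_angles(spec: AngleFileSpec) -> AngleSample:
    """Read a sample of angles according to ``spec``.

    Returns wrapped radian angles preserving input order.  Distinct errors
    (with line numbers where applicable) are raised for a missing file,
    non-numeric rows and an empty file.
    """
    path = Path(spec.path)
    if not path.exists():
        raise FileNotFoundError(f"angle file not found: {path}")
    if spec.unit not in ("degrees", "radians"):
        raise ValueError(f"unit must be 'degrees' or 'radians', got {spec.unit!r}")
    values = (
        _read_csv(path, spec.column, spec.header)
        if spec.column is not None
        else _read_plain(path)
    )
    if not values:
        raise ValueError(f"{path}: no angles found (empty file?)")
    logger.info("read %d angles from %s (unit: %s)", len(values), path, spec.unit)
    return AngleSample(values, unit=spec.unit)
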