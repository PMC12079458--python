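"""Localization-table I/O and reconstruction rendering.

The central data structure is :class:`LocalizationTable`, a thin wrapper
around a :class:`pandas.DataFrame` with canonical columns ``frame``
(1-based integer), ``x_nm``, ``y_nm`` and ``intensity`` (photons).
Tables are read and written as CSV in the dialect produced by common
localization software (``"frame","x [nm]","y [nm]","intensity [photon]"``)
or in a generic dialect via a user-supplied column map.

Conventions
-----------
* Coordinates are continuous nanometres, origin at the lower-left corner
  of the field of view.
* Frame numbering is 1-based; the acquisition time of frame ``f`` is
  ``(f - 1) * frame_interval_s``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("frame", "x_nm", "y_nm", "intensity")

#: Column names used by the ThunderSTORM-style CSV export.
THUNDERSTORM_COLUMNS: Mapping[str, str] = {
    "frame": "frame",
    "x [nm]": "x_nm",
    "y [nm]": "y_nm",
    "intensity [photon]": "intensity",
}


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ParseError(ValueError):
    """A cell could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


@dataclass
class LocalizationTable:
    """Time-stamped 2D localizations with intensity.

    Parameters
    ----------
    data
        Frame/position/intensity rows; canonical columns ``frame``,
        ``x_nm``, ``y_nm``, ``intensity``. Extra columns are preserved
        untouched.
    frame_interval_s
        Acquisition interval between consecutive frames, in seconds.
    fov_nm
        Optional ``(width, height)`` of the field of view in nm.
    """

    data: pd.DataFrame
    frame_interval_s: float = 30.0
    fov_nm: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        if len(self.data):
            xy = self.data[["x_nm", "y_nm"]].to_numpy(float)
            if not np.isfinite(xy).all():
                raise ValueError("x/y coordinates must be finite")
            if (self.data["intensity"].to_numpy(float) < 0).any():
                raise ValueError("intensities must be non-negative")
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def frames(self) -> np.ndarray:
        return self.data["frame"].to_numpy(int)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of positions in nm."""
        return self.data[["x_nm", "y_nm"]].to_numpy(float)

    @property
    def intensity(self) -> np.ndarray:
        return self.data["intensity"].to_numpy(float)

    @property
    def times_s(self) -> np.ndarray:
        """Acquisition time of each localization in seconds (frame 1 -> 0 s)."""
        return (self.frames - 1) * float(self.frame_interval_s)

    def sorted_by_time(self) -> "LocalizationTable":
        order = np.argsort(self.frames, kind="stable")
        return self.replace_data(self.data.iloc[order])

    def replace_data(self, data: pd.DataFrame) -> "LocalizationTable":
        return LocalizationTable(
            data.reset_index(drop=True),
            frame_interval_s=self.frame_interval_s,
            fov_nm=self.fov_nm,
        )


def read_localizations(
    path: str | Path,
    dialect: str = "thunderstorm_csv",
    column_map: Mapping[str, str] | None = None,
    frame_interval_s: float = 30.0,
) -> LocalizationTable:
    """Read a localization CSV into a :class:`LocalizationTable`.

    Parameters
    ----------
    path
        CSV file to read.
    dialect
        ``"thunderstorm_csv"`` (default) or ``"generic_csv"``. The
        generic dialect requires ``column_map`` mapping file headers to
        canonical names (``frame``, ``x_nm``, ``y_nm``, ``intensity``).
    column_map
        Header renaming applied before validation; required for
        ``generic_csv``.
    frame_interval_s
        Frame interval metadata attached to the table.

    Raises
    ------
    SchemaError
        If a required column is absent (the message names it).
    ParseError
        If a cell in a required column is non-numeric (the message
        carries the 1-based data line number).
    """
    path = Path(path)
    if dialect == "thunderstorm_csv":
        column_map = dict(THUNDERSTORM_COLUMNS)
    elif dialect == "generic_csv":
        if column_map is None:
            raise ValueError("generic_csv dialect requires a column_map")
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")

    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    raw.columns = [c.strip().strip('"') for c in raw.columns]
    rename = {src: dst for src, dst in column_map.items() if src in raw.columns}
    df = raw.rename(columns=rename)

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    for col in REQUIRED_COLUMNS:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise ParseError(
                f"non-numeric value in column {col!r} at line {line}", line=line
            )
        df[col] = converted.astype(float)
    df["frame"] = df["frame"].astype(int)
    return LocalizationTable(df, frame_interval_s=frame_interval_s)


def write_localizations(table: LocalizationTable, path: str | Path) -> None:
    """Write a table as ThunderSTORM-dialect CSV."""
    inverse = {v: k for k, v in THUNDERSTORM_COLUMNS.items()}
    out = table.data.rename(columns=inverse)
    cols = list(THUNDERSTORM_COLUMNS) + [
        c for c in out.columns if c not in THUNDERSTORM_COLUMNS
    ]
    out[cols].to_csv(path, index=False)


def render_reconstruction(
    table: LocalizationTable,
    pixel_nm: float,
    t_max_s: float | None = None,
    bounds_nm: tuple[float, float, float, float] | None = None,
    intensity_weighted: bool = False,
) -> np.ndarray:
    """Render a 2D histogram image of the localizations.

    Bins are half-open ``[k*pixel_nm, (k+1)*pixel_nm)``. Only
    localizations whose frame has completed by ``t_max_s``
    (``frame * frame_interval_s <= t_max_s``) are rendered (all, if
    ``t_max_s`` is None). Returns an array indexed ``[iy, ix]``.

    ``bounds_nm`` is ``(xmin, xmax, ymin, ymax)``; defaults to the FOV
    bounds if present, else the data extent.
    """
    if pixel_nm <= 0:
        raise ValueError("pixel_nm must be positive")
    if bounds_nm is None:
        if table.fov_nm is not None:
            bounds_nm = (0.0, table.fov_nm[0], 0.0, table.fov_nm[1])
        elif len(table):
            xy = table.xy
            bounds_nm = (xy[:, 0].min(), xy[:, 0].max(), xy[:, 1].min(), xy[:, 1].max())
        else:
            bounds_nm = (0.0, pixel_nm, 0.0, pixel_nm)
    xmin, xmax, ymin, ymax = bounds_nm
    nx = max(1, int(np.ceil((xmax - xmin) / pixel_nm)))
    ny = max(1, int(np.ceil((ymax - ymin) / pixel_nm)))
    if len(table) == 0:
        return np.zeros((ny, nx))

    mask = np.ones(len(table), bool)
    if t_max_s is not None:
        mask = table.frames * float(table.frame_interval_s) <= t_max_s
    xy = table.xy[mask]
    weights = table.intensity[mask] if intensity_weighted else None
    img, _, _ = np.histogram2d(
        xy[:, 1],
        xy[:, 0],
        bins=(ny, nx),
        range=((ymin, ymin + ny * pixel_nm), (xmin, xmin + nx * pixel_nm)),
        weights=weights,
    )
    return img
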