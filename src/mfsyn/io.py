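"""Readers and writers for localization tables and confocal images.

A localization table is a :class:`pandas.DataFrame` with one row per MINFLUX
localization and a fixed column schema (:data:`LOC_COLUMNS`).  Rows sharing a
``(fov_id, tid)`` pair form one emission-event trace.  All coordinates are in
nanometers, in a right-handed FOV-local frame; EFO is stored in Hz.

The on-disk format is plain comma-separated text with a header.  A *dialect*
mapping allows files whose columns carry different names, and an ``efo_khz``
column is converted to Hz on read.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, ValidationError

#: Canonical column order of the localization-table dialect.
LOC_COLUMNS = ["fov_id", "tid", "t_s", "x_nm", "y_nm", "z_nm", "efo_hz", "cfr", "dcr"]

_NUMERIC = ["t_s", "x_nm", "y_nm", "z_nm", "efo_hz", "cfr", "dcr"]


@dataclass(frozen=True)
class ConfocalImage:
    """Single-plane confocal intensity image with physical pixel size.

    Pixel centers map to nm coordinates via ``((col + 0.5) * pixel_size_nm,
    (row + 0.5) * pixel_size_nm)`` so that centroid arithmetic is symmetric.
    """

    data: np.ndarray  # 2D, row-major, origin top-left
    pixel_size_nm: float
    fov_id: str = ""

    def __post_init__(self):
        if self.data.ndim != 2:
            raise ValidationError(f"confocal image must be 2D, got {self.data.ndim}D")
        if self.pixel_size_nm <= 0:
            raise ValidationError("pixel_size_nm must be positive")
        if not np.all(np.isfinite(self.data)) or np.any(self.data < 0):
            raise ValidationError("intensities must be finite and non-negative")


def empty_table() -> pd.DataFrame:
    """Return a localization table with zero records."""
    df = pd.DataFrame({c: pd.Series(dtype=float) for c in LOC_COLUMNS})
    df["fov_id"] = df["fov_id"].astype(str)
    df["tid"] = df["tid"].astype(np.int64)
    return df


def validate_localizations(df: pd.DataFrame) -> pd.DataFrame:
    """Check schema and record-level invariants; return the table unchanged.

    Raises
    ------
    FormatError
        if a required column is missing.
    ValidationError
        naming the first offending row, if dcr lies outside [0, 1], efo is
        non-positive, cfr is negative, tid is negative, or a coordinate is
        non-finite.
    """
    for col in LOC_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column: {col!r}")
    if len(df) == 0:
        return df
    checks = [
        ((df["dcr"] < 0) | (df["dcr"] > 1), "dcr outside [0, 1]"),
        (df["efo_hz"] <= 0, "efo must be positive"),
        (df["cfr"] < 0, "cfr must be non-negative"),
        (df["tid"] < 0, "tid must be non-negative"),
        (~np.isfinite(df[["x_nm", "y_nm", "z_nm"]]).all(axis=1), "non-finite coordinate"),
    ]
    for bad, msg in checks:
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(f"{msg} at row {row}")
    return df


def read_localizations(path, dialect: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a localization table from delimited text.

    Parameters
    ----------
    path
        CSV file with a header row.
    dialect
        Optional map from canonical column names (:data:`LOC_COLUMNS`) to the
        names used in the file.  The special canonical key ``efo_khz`` may be
        mapped instead of ``efo_hz``; its values are multiplied by 1000.
    """
    raw = pd.read_csv(path, dtype={0: str})
    dialect = dict(dialect or {})
    khz_col = dialect.pop("efo_khz", None)

    rename = {v: k for k, v in dialect.items()}
    raw = raw.rename(columns=rename)
    if khz_col is not None:
        if khz_col not in raw.columns:
            raise FormatError(f"missing required column: {khz_col!r}")
        raw["efo_hz"] = raw[khz_col].astype(float) * 1000.0
    for col in LOC_COLUMNS:
        if col not in raw.columns:
            raise FormatError(f"missing required column: {col!r}")
    df = raw[LOC_COLUMNS].copy()
    df["fov_id"] = df["fov_id"].astype(str)
    df["tid"] = df["tid"].astype(np.int64)
    for col in _NUMERIC:
        df[col] = df[col].astype(float)
    return validate_localizations(df.reset_index(drop=True))


def write_localizations(df: pd.DataFrame, path) -> None:
    """Write a validated table as CSV with full round-trip float precision."""
    validate_localizations(df)
    out = df[LOC_COLUMNS]
    out.to_csv(path, index=False, float_format="%.17g")


def read_confocal(path, pixel_size_nm: float, fov_id: str = "") -> ConfocalImage:
    """Read a single-plane grayscale TIFF as a :class:`ConfocalImage`."""
    data = tifffile.imread(path)
    if data.ndim != 2:
        raise FormatError(
            f"expected single-plane grayscale TIFF, got shape {data.shape}"
        )
    return ConfocalImage(np.asarray(data, dtype=float), pixel_size_nm, fov_id)


def write_confocal(image: ConfocalImage, path) -> None:
    """Write the image grid as a single-plane float32 TIFF."""
    tifffile.imwrite(path, image.data.astype(np.float32))
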