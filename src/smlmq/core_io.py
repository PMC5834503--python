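"""Domain types and file I/O for localization-microscopy artifacts.

All coordinates inside the package are nanometres.  Conversion from camera
pixels happens exactly once, at the read boundary, driven by a
:class:`Dialect` that maps foreign column headers onto the canonical schema

    ``x_nm, y_nm, frame, intensity[, precision_nm]``

Raster images use a 0-based, pixel-corner origin with half-open pixels:
position ``p`` falls into pixel ``floor((p - origin) / pixel_nm)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "FormatError",
    "Dialect",
    "CANONICAL_DIALECT",
    "LocalizationTable",
    "RasterImage",
    "IntensityTrace",
    "Polyline",
    "ROI",
    "read_localization_table",
    "write_localization_table",
    "read_traces",
    "write_traces",
    "read_polylines",
    "write_polylines",
]

CANONICAL_COLUMNS = ("x_nm", "y_nm", "frame", "intensity")
OPTIONAL_COLUMNS = ("precision_nm",)


class FormatError(ValueError):
    """A file does not conform to the expected tabular schema."""


@dataclass(frozen=True)
class Dialect:
    """Column mapping for localization tables written by other software.

    Parameters
    ----------
    x, y, frame, intensity, precision
        Header names in the foreign file.  ``precision`` and ``intensity``
        may be absent from the file (intensity then defaults to 1 count).
    unit
        ``"nm"`` or ``"px"``; pixel coordinates are multiplied by the
        camera pixel size on read.
    delimiter
        Field separator.
    """

    x: str = "x_nm"
    y: str = "y_nm"
    frame: str = "frame"
    intensity: str = "intensity"
    precision: str = "precision_nm"
    unit: str = "nm"
    delimiter: str = ","

    def __post_init__(self) -> None:
        if self.unit not in ("nm", "px"):
            raise ValueError(f"unit must be 'nm' or 'px', got {self.unit!r}")


CANONICAL_DIALECT = Dialect()


@dataclass
class LocalizationTable:
    """Per-emission records of a localization experiment.

    ``df`` holds one row per localization with canonical columns; acquisition
    metadata travels alongside.  Defaults mirror a typical EMCCD dSTORM
    acquisition (129-nm pixels, 70-ms exposure).
    """

    df: pd.DataFrame
    pixel_size_nm: float = 129.0
    exposure_ms: float = 70.0
    n_frames: int | None = None

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")
        df = self.df.reset_index(drop=True)
        for col in ("x_nm", "y_nm", "intensity"):
            df[col] = df[col].astype(float)
        df["frame"] = df["frame"].astype(np.int64)
        if len(df):
            if not np.isfinite(df[["x_nm", "y_nm"]].to_numpy()).all():
                raise ValueError("non-finite coordinates")
            if (df["frame"] < 0).any():
                raise ValueError("negative frame index")
            if (df["intensity"] < 0).any():
                raise ValueError("negative intensity")
        if self.n_frames is None:
            self.n_frames = int(df["frame"].max()) + 1 if len(df) else 0
        elif len(df) and int(df["frame"].max()) >= self.n_frames:
            raise ValueError("frame index >= n_frames")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of positions in nm."""
        return self.df[["x_nm", "y_nm"]].to_numpy()

    @property
    def frames(self) -> np.ndarray:
        return self.df["frame"].to_numpy()

    @property
    def intensity(self) -> np.ndarray:
        return self.df["intensity"].to_numpy()

    def with_df(self, df: pd.DataFrame) -> "LocalizationTable":
        """Copy of this table with replaced records, keeping metadata."""
        return LocalizationTable(
            df,
            pixel_size_nm=self.pixel_size_nm,
            exposure_ms=self.exposure_ms,
            n_frames=max(self.n_frames or 0, int(df["frame"].max()) + 1 if len(df) else 0),
        )

    def select(self, mask: np.ndarray) -> "LocalizationTable":
        return self.with_df(self.df.loc[np.asarray(mask)].reset_index(drop=True))

    @staticmethod
    def from_arrays(
        x_nm: np.ndarray,
        y_nm: np.ndarray,
        frame: np.ndarray,
        intensity: np.ndarray | None = None,
        **extra_columns,
    ) -> "LocalizationTable":
        x_nm = np.asarray(x_nm, float)
        if intensity is None:
            intensity = np.ones_like(x_nm)
        data = {
            "x_nm": x_nm,
            "y_nm": np.asarray(y_nm, float),
            "frame": np.asarray(frame, np.int64),
            "intensity": np.asarray(intensity, float),
        }
        data.update(extra_columns)
        return LocalizationTable(pd.DataFrame(data))


@dataclass
class RasterImage:
    """2D intensity grid with physical pixel size.

    ``values[i, j]`` covers the half-open square
    ``[origin + (j, i) * pixel_nm, origin + (j+1, i+1) * pixel_nm)`` —
    row index is y, column index is x, matching image convention.
    """

    values: np.ndarray
    pixel_nm: float
    origin_nm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2D")
        if self.pixel_nm <= 0:
            raise ValueError("pixel_nm must be positive")
        if (self.values < 0).any():
            raise ValueError("negative pixel values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_tiff(self, path: str | Path) -> None:
        """Write as 16-bit grayscale TIFF (values rounded and clipped)."""
        out = np.clip(np.round(self.values), 0, 65535).astype(np.uint16)
        tifffile.imwrite(
            str(path),
            out,
            resolution=(1e7 / self.pixel_nm, 1e7 / self.pixel_nm),
            metadata={"pixel_nm": self.pixel_nm, "origin_nm": list(self.origin_nm)},
        )

    @staticmethod
    def from_tiff(path: str | Path, pixel_nm: float | None = None) -> "RasterImage":
        with tifffile.TiffFile(str(path)) as tif:
            values = tif.asarray().astype(float)
            meta = tif.shaped_metadata or tif.imagej_metadata or {}
            if isinstance(meta, (list, tuple)):
                meta = meta[0] if meta else {}
        if pixel_nm is None:
            pixel_nm = float(meta.get("pixel_nm", 10.0))
        origin = tuple(meta.get("origin_nm", (0.0, 0.0)))
        return RasterImage(values, pixel_nm, origin)


@dataclass
class IntensityTrace:
    """Frame-indexed integrated AD counts of one circular ROI."""

    trace_id: str
    counts: np.ndarray
    roi_diameter_px: int = 10

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, float)
        if self.counts.ndim != 1:
            raise ValueError("counts must be 1D")
        if not np.isfinite(self.counts).all():
            raise ValueError(f"trace {self.trace_id}: non-finite counts")

    @property
    def n_frames(self) -> int:
        return len(self.counts)


@dataclass
class Polyline:
    """Ordered vertices in nm with an associated strip thickness in pixels."""

    vertices: np.ndarray
    thickness_px: float = 5.0
    line_id: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, float).reshape(-1, 2)
        if len(self.vertices) < 2:
            raise ValueError("polyline needs >= 2 vertices")
        if (np.linalg.norm(np.diff(self.vertices, axis=0), axis=1) == 0).any():
            raise ValueError("consecutive vertices must be distinct")

    @property
    def length_nm(self) -> float:
        return float(np.linalg.norm(np.diff(self.vertices, axis=0), axis=1).sum())

    @property
    def midpoint_nm(self) -> np.ndarray:
        """Point at half the arclength (used for tile assignment)."""
        seg = np.diff(self.vertices, axis=0)
        seglen = np.linalg.norm(seg, axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seglen)])
        half = cum[-1] / 2.0
        i = int(np.searchsorted(cum, half, side="right") - 1)
        i = min(i, len(seg) - 1)
        t = (half - cum[i]) / seglen[i]
        return self.vertices[i] + t * seg[i]


@dataclass(frozen=True)
class ROI:
    """Axis-aligned rectangle in nm."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError("ROI must have positive extent")

    @property
    def area_um2(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min) / 1e6

    def contains(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, float)
        return (
            (xy[:, 0] >= self.x_min)
            & (xy[:, 0] < self.x_max)
            & (xy[:, 1] >= self.y_min)
            & (xy[:, 1] < self.y_max)
        )


# ---------------------------------------------------------------------------
# localization tables


def read_localization_table(
    path: str | Path,
    dialect: Dialect = CANONICAL_DIALECT,
    pixel_size_nm: float = 129.0,
    exposure_ms: float = 70.0,
    n_frames: int | None = None,
) -> LocalizationTable:
    """Read a delimited localization table, converting to canonical nm schema.

    Raises
    ------
    FormatError
        If a mandatory column (x, y, frame) is absent or a cell fails to
        parse as a number (the error names the offending column/row).
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep=dialect.delimiter, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file without header") from None
    for name, col in (("x", dialect.x), ("y", dialect.y), ("frame", dialect.frame)):
        if col not in raw.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r} (maps to {name})")
    out = pd.DataFrame()
    scale = pixel_size_nm if dialect.unit == "px" else 1.0
    for canon, col in (("x_nm", dialect.x), ("y_nm", dialect.y)):
        out[canon] = _numeric(raw[col], col, path) * scale
    out["frame"] = _numeric(raw[dialect.frame], dialect.frame, path).astype(np.int64)
    if dialect.intensity in raw.columns:
        out["intensity"] = _numeric(raw[dialect.intensity], dialect.intensity, path)
    else:
        out["intensity"] = 1.0
    if dialect.precision in raw.columns:
        out["precision_nm"] = _numeric(raw[dialect.precision], dialect.precision, path) * scale
    return LocalizationTable(
        out, pixel_size_nm=pixel_size_nm, exposure_ms=exposure_ms, n_frames=n_frames
    )


def _numeric(series: pd.Series, col: str, path: Path) -> pd.Series:
    converted = pd.to_numeric(series, errors="coerce")
    bad = converted.isna() & series.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(f"{path}: non-numeric value in column {col!r} at data row {row}")
    if converted.isna().any():
        row = int(np.flatnonzero(converted.isna().to_numpy())[0])
        raise FormatError(f"{path}: missing value in column {col!r} at data row {row}")
    return converted.astype(float)


def write_localization_table(table: LocalizationTable, path: str | Path) -> None:
    """Write the canonical CSV dialect; exact inverse of the canonical read."""
    cols = list(CANONICAL_COLUMNS) + [c for c in OPTIONAL_COLUMNS if c in table.df.columns]
    table.df[cols].to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# intensity traces (long format: trace_id,frame,counts)


def read_traces(path: str | Path, roi_diameter_px: int = 10) -> list[IntensityTrace]:
    path = Path(path)
    raw = pd.read_csv(path, float_precision="round_trip")
    for col in ("trace_id", "frame", "counts"):
        if col not in raw.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    traces = []
    for tid, grp in raw.groupby("trace_id", sort=False):
        frames = grp["frame"].to_numpy()
        expected = np.arange(len(frames))
        if not np.array_equal(np.sort(frames), expected):
            raise FormatError(f"{path}: trace {tid!r} has missing or duplicated frames")
        counts = grp.sort_values("frame")["counts"].to_numpy(float)
        traces.append(IntensityTrace(str(tid), counts, roi_diameter_px))
    lengths = {t.n_frames for t in traces}
    if len(lengths) > 1:
        raise FormatError(f"{path}: ragged trace lengths {sorted(lengths)}")
    return traces


def write_traces(traces: Sequence[IntensityTrace], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {"trace_id": t.trace_id, "frame": np.arange(t.n_frames), "counts": t.counts}
        )
        for t in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# polylines


def read_polylines(path: str | Path) -> list[Polyline]:
    path = Path(path)
    raw = pd.read_csv(path, float_precision="round_trip")
    for col in ("line_id", "x_nm", "y_nm"):
        if col not in raw.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    lines = []
    for lid, grp in raw.groupby("line_id", sort=False):
        thickness = float(grp["thickness_px"].iloc[0]) if "thickness_px" in grp else 5.0
        lines.append(
            Polyline(grp[["x_nm", "y_nm"]].to_numpy(float), thickness, line_id=str(lid))
        )
    return lines


def write_polylines(lines: Sequence[Polyline], path: str | Path) -> None:
    rows = []
    for i, line in enumerate(lines):
        lid = line.line_id or str(i)
        for v in line.vertices:
            rows.append(
                {"line_id": lid, "x_nm": v[0], "y_nm": v[1], "thickness_px": line.thickness_px}
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")
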