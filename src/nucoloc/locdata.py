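"""Single-molecule localization tables: reading, writing, validation, rendering.

A localization table is the standard product of SMLM software (one row per
fitted single-molecule localization, coordinates in nanometers).  The reader
understands ThunderSTORM-style CSV headers (``"x [nm]"``, ``"y [nm]"``, ...)
out of the box and arbitrary delimited files through a column map.  Rendering
follows the normalized-Gaussian convention: every localization is drawn as an
isotropic 2-D Gaussian of unit mass whose width is the localization
uncertainty times an expansion factor, rasterized at (by default) 10 nm/px.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError

logger = logging.getLogger(__name__)

#: canonical column order of a localization table
COLUMNS = ["frame", "x_nm", "y_nm", "intensity_photons", "sigma_nm", "uncertainty_nm"]

#: ThunderSTORM-style header names (case-insensitive) for each canonical column
THUNDERSTORM_HEADERS = {
    "frame": ("frame",),
    "x_nm": ("x [nm]", "x"),
    "y_nm": ("y [nm]", "y"),
    "intensity_photons": ("intensity [photon]", "intensity [photons]", "intensity"),
    "sigma_nm": ("sigma [nm]", "sigma"),
    "uncertainty_nm": ("uncertainty [nm]", "uncertainty_xy [nm]", "uncertainty"),
}

REQUIRED = ("frame", "x_nm", "y_nm")

#: fallback localization precision when the table carries no uncertainty column
DEFAULT_UNCERTAINTY_NM = 20.0


@dataclass(frozen=True)
class Roi:
    """Axis-aligned rectangle in nm, ``[x_min, x_max) x [y_min, y_max)``."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    def transposed(self) -> "Roi":
        return Roi(self.y_min, self.x_min, self.y_max, self.x_max)

    def contains(self, x: np.ndarray, y: np.ndarray, atol: float = 1e-9) -> np.ndarray:
        return (
            (x >= self.x_min - atol)
            & (x <= self.x_max + atol)
            & (y >= self.y_min - atol)
            & (y <= self.y_max + atol)
        )


@dataclass(frozen=True)
class Localization:
    """One fitted single-molecule localization."""

    frame: int
    x_nm: float
    y_nm: float
    intensity_photons: float = 0.0
    sigma_nm: float = 150.0
    uncertainty_nm: float = DEFAULT_UNCERTAINTY_NM

    def __post_init__(self):
        if self.frame < 1:
            raise ValueError(f"frame must be >= 1, got {self.frame}")
        if not (math.isfinite(self.x_nm) and math.isfinite(self.y_nm)):
            raise ValueError("x_nm and y_nm must be finite")
        if self.sigma_nm <= 0 or self.uncertainty_nm <= 0:
            raise ValueError("sigma_nm and uncertainty_nm must be positive")


@dataclass
class LocalizationTable:
    """Per-channel collection of localizations plus acquisition context.

    ``data`` holds one row per localization in the canonical columns; the ROI
    (nm) and total frame count carry the acquisition geometry needed by
    density-matched null models.
    """

    data: pd.DataFrame
    roi_bounds: Roi
    n_frames: int
    channel_label: str = ""

    def __post_init__(self):
        missing = [c for c in COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"localization table missing columns: {missing}")
        self.data = self.data[COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def x(self) -> np.ndarray:
        return self.data["x_nm"].to_numpy(float)

    @property
    def y(self) -> np.ndarray:
        return self.data["y_nm"].to_numpy(float)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) coordinate array in nm."""
        return self.data[["x_nm", "y_nm"]].to_numpy(float)

    @property
    def density_per_nm2(self) -> float:
        """Localizations per nm^2 of ROI."""
        if self.roi_bounds.area <= 0:
            raise ValueError("ROI has zero area")
        return len(self) / self.roi_bounds.area

    def validate(self) -> None:
        d = self.data
        if len(d) == 0:
            return
        if (d["frame"] < 1).any():
            raise ValueError("frame indices must be >= 1")
        for c in ("x_nm", "y_nm"):
            if not np.isfinite(d[c].to_numpy(float)).all():
                raise ValueError(f"non-finite values in {c}")
        if (d["sigma_nm"] <= 0).any() or (d["uncertainty_nm"] <= 0).any():
            raise ValueError("sigma_nm and uncertainty_nm must be positive")
        inside = self.roi_bounds.contains(self.x, self.y)
        if not inside.all():
            raise ValueError(
                f"{int((~inside).sum())} localizations fall outside roi_bounds"
            )

    def with_data(self, data: pd.DataFrame, **kw) -> "LocalizationTable":
        return LocalizationTable(
            data=data,
            roi_bounds=kw.get("roi_bounds", self.roi_bounds),
            n_frames=kw.get("n_frames", self.n_frames),
            channel_label=kw.get("channel_label", self.channel_label),
        )


@dataclass
class RenderedImage:
    """Raster of unit-mass Gaussians, one per localization.

    Pixel ``(i, j)`` covers the half-open square
    ``[x0 + j*s, x0 + (j+1)*s) x [y0 + i*s, y0 + (i+1)*s)`` with ``s`` the
    pixel size and ``(x0, y0) = origin_nm``; y grows downward with the row
    index (raster convention).
    """

    pixels: np.ndarray
    pixel_size_nm: float
    origin_nm: tuple[float, float]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def bounding_box(x: np.ndarray, y: np.ndarray) -> Roi:
    return Roi(float(np.min(x)), float(np.min(y)), float(np.max(x)), float(np.max(y)))


def make_table(
    x_nm,
    y_nm,
    frame=None,
    intensity_photons=None,
    sigma_nm=150.0,
    uncertainty_nm=DEFAULT_UNCERTAINTY_NM,
    roi_bounds: Roi | None = None,
    n_frames: int | None = None,
    channel_label: str = "",
) -> LocalizationTable:
    """Assemble a table from coordinate arrays, broadcasting scalar fields."""
    x = np.asarray(x_nm, float).ravel()
    y = np.asarray(y_nm, float).ravel()
    n = len(x)
    frame = np.ones(n, dtype=int) if frame is None else np.asarray(frame, int).ravel()
    data = pd.DataFrame(
        {
            "frame": frame,
            "x_nm": x,
            "y_nm": y,
            "intensity_photons": np.broadcast_to(
                np.asarray(0.0 if intensity_photons is None else intensity_photons, float), (n,)
            ).copy(),
            "sigma_nm": np.broadcast_to(np.asarray(sigma_nm, float), (n,)).copy(),
            "uncertainty_nm": np.broadcast_to(np.asarray(uncertainty_nm, float), (n,)).copy(),
        }
    )
    if roi_bounds is None:
        roi_bounds = bounding_box(x, y) if n else Roi(0.0, 0.0, 1.0, 1.0)
    if n_frames is None:
        n_frames = int(frame.max()) if n else 1
    return LocalizationTable(data, roi_bounds, n_frames, channel_label)


def _resolve_columns(columns, dialect, column_map):
    """Map canonical names to (file column, scale-to-nm factor)."""
    lower = {c.lower().strip(): c for c in columns}
    resolved: dict[str, tuple[str, float]] = {}
    column_map = column_map or {}
    for canon in COLUMNS:
        if canon in column_map:
            spec = column_map[canon]
            name, scale = spec if isinstance(spec, tuple) else (spec, 1.0)
            if name.lower().strip() in lower:
                resolved[canon] = (lower[name.lower().strip()], float(scale))
            continue
        if dialect == "thunderstorm_csv":
            for alias in THUNDERSTORM_HEADERS[canon]:
                if alias in lower:
                    resolved[canon] = (lower[alias], 1.0)
                    break
        else:  # generic_delimited: exact canonical names only
            if canon.lower() in lower:
                resolved[canon] = (lower[canon.lower()], 1.0)
    return resolved


def read_localization_table(
    path,
    dialect: str = "thunderstorm_csv",
    column_map: dict | None = None,
    sep: str = ",",
    roi_bounds: Roi | None = None,
    n_frames: int | None = None,
    channel_label: str = "",
    default_uncertainty_nm: float = DEFAULT_UNCERTAINTY_NM,
) -> LocalizationTable:
    """Read a delimited localization table and normalize units to nm.

    ``column_map`` maps canonical names (``x_nm`` ...) to either a file column
    name or a ``(name, scale_to_nm)`` tuple (e.g. ``("x", 1000.0)`` for
    micrometer data).  ROI defaults to the bounding box of the coordinates.
    """
    if dialect not in ("thunderstorm_csv", "generic_delimited"):
        raise ValueError(f"unknown dialect {dialect!r}")
    raw = pd.read_csv(path, sep=sep)
    resolved = _resolve_columns(raw.columns, dialect, column_map)
    for canon in REQUIRED:
        if canon not in resolved:
            raise FormatError(f"required column {canon!r} not found in {list(raw.columns)}")

    data = {}
    for canon, (col, scale) in resolved.items():
        series = pd.to_numeric(raw[col], errors="coerce")
        bad = series.isna() & raw[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric value {raw[col].iloc[row]!r} in column {col!r} at data row {row}",
                row=row,
            )
        data[canon] = series.to_numpy(float) * scale
    n = len(raw)
    frame = data.get("frame", np.ones(n)).astype(int)
    if "uncertainty_nm" not in data:
        logger.warning(
            "no uncertainty column in %s; falling back to constant %.1f nm",
            path,
            default_uncertainty_nm,
        )
    table = make_table(
        data["x_nm"],
        data["y_nm"],
        frame=frame,
        intensity_photons=data.get("intensity_photons", 0.0),
        sigma_nm=data.get("sigma_nm", 150.0),
        uncertainty_nm=data.get("uncertainty_nm", default_uncertainty_nm),
        roi_bounds=roi_bounds,
        n_frames=n_frames,
        channel_label=channel_label,
    )
    return table


_WRITE_HEADERS = {
    "frame": "frame",
    "x_nm": "x [nm]",
    "y_nm": "y [nm]",
    "intensity_photons": "intensity [photon]",
    "sigma_nm": "sigma [nm]",
    "uncertainty_nm": "uncertainty [nm]",
}


def write_localization_table(table: LocalizationTable, path) -> None:
    """Write a table as ThunderSTORM-style CSV (full float precision)."""
    out = table.data.rename(columns=_WRITE_HEADERS)
    out.to_csv(path, index=False, float_format="%.9f")


def render_gaussian(
    table: LocalizationTable,
    pixel_size_nm: float = 10.0,
    psf_expansion: float = 1.0,
    sigma_override_nm: float | None = None,
) -> RenderedImage:
    """Render localizations as unit-mass Gaussians (normalized-Gaussian method).

    Each localization contributes an isotropic Gaussian of standard deviation
    ``uncertainty_nm * psf_expansion`` (or ``sigma_override_nm`` for all
    localizations), evaluated at pixel centers, truncated at 4 sigma, and
    normalized so the *untruncated* in-window mass is 1; mass falling outside
    the image is lost, which only affects localizations near the ROI edge.
    """
    if pixel_size_nm <= 0:
        raise ValueError("pixel_size_nm must be positive")
    roi = table.roi_bounds
    n_rows = max(1, int(math.ceil(roi.height / pixel_size_nm - 1e-9)))
    n_cols = max(1, int(math.ceil(roi.width / pixel_size_nm - 1e-9)))
    img = np.zeros((n_rows, n_cols), dtype=np.float64)
    if len(table) == 0:
        return RenderedImage(img, pixel_size_nm, (roi.x_min, roi.y_min))

    xs = table.x - roi.x_min
    ys = table.y - roi.y_min
    if sigma_override_nm is not None:
        sigmas = np.full(len(table), float(sigma_override_nm))
    else:
        sigmas = table.data["uncertainty_nm"].to_numpy(float) * psf_expansion
    s = pixel_size_nm
    for x0, y0, sig in zip(xs, ys, sigmas):
        if sig <= 0:
            # degenerate width: deposit the whole mass in the containing pixel
            j = min(n_cols - 1, max(0, int(x0 / s)))
            i = min(n_rows - 1, max(0, int(y0 / s)))
            img[i, j] += 1.0
            continue
        r = 4.0 * sig
        j0 = int(math.floor((x0 - r) / s))
        j1 = int(math.ceil((x0 + r) / s))
        i0 = int(math.floor((y0 - r) / s))
        i1 = int(math.ceil((y0 + r) / s))
        # 1-D separable profiles over the full (unclipped) 4-sigma window
        jj = np.arange(j0, j1 + 1)
        ii = np.arange(i0, i1 + 1)
        gx = np.exp(-((jj + 0.5) * s - x0) ** 2 / (2.0 * sig * sig))
        gy = np.exp(-((ii + 0.5) * s - y0) ** 2 / (2.0 * sig * sig))
        total = gx.sum() * gy.sum()
        if total <= 0:
            continue
        jin = (jj >= 0) & (jj < n_cols)
        iin = (ii >= 0) & (ii < n_rows)
        if not (jin.any() and iin.any()):
            continue
        img[np.ix_(ii[iin], jj[jin])] += np.outer(gy[iin], gx[jin]) / total
    return RenderedImage(img, pixel_size_nm, (roi.x_min, roi.y_min))
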