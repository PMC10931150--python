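"""Randomized null models for cross-channel colocalization analysis.

Two nulls destroy cross-channel registration while controlling for density:

* **coordinate swap** — exchange x and y of one channel; within-channel
  structure (all inter-point distances) is preserved, the registration with
  the other channel is destroyed;
* **matched CSR** — completely spatially random localizations with exactly
  the point count, ROI and frame count of the real acquisition.

The analytic CSR nearest-neighbor law (Rayleigh form) is provided as a
closed-form oracle: for a homogeneous planar Poisson process of intensity
``lambda``, the NND density is ``f(r) = 2 pi lambda r exp(-pi lambda r^2)``
with mode ``1 / sqrt(2 pi lambda)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .locdata import LocalizationTable, Roi, make_table


@dataclass(frozen=True)
class CsrSpec:
    """Specification of a completely-spatially-random localization set."""

    roi_bounds: Roi
    n_points: int
    n_frames: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_points < 1:
            raise ParameterError("n_points must be >= 1")
        if self.roi_bounds.area <= 0:
            raise ParameterError("ROI area must be positive")


def swap_xy(table: LocalizationTable, rescale_to_roi: bool = False) -> LocalizationTable:
    """Exchange x and y of every localization (coordinate-swap null).

    With ``rescale_to_roi`` the swapped coordinates are affinely mapped back
    onto the original ROI (useful for non-square ROIs); the default is the
    plain swap with a transposed ROI.
    """
    if len(table) == 0:
        raise ValueError("cannot swap an empty table")
    data = table.data.copy()
    data["x_nm"], data["y_nm"] = table.y.copy(), table.x.copy()
    roi = table.roi_bounds
    if rescale_to_roi:
        tr = roi.transposed()
        sx = roi.width / tr.width if tr.width > 0 else 1.0
        sy = roi.height / tr.height if tr.height > 0 else 1.0
        data["x_nm"] = roi.x_min + (data["x_nm"] - tr.x_min) * sx
        data["y_nm"] = roi.y_min + (data["y_nm"] - tr.y_min) * sy
        new_roi = roi
    else:
        new_roi = roi.transposed()
    return LocalizationTable(data, new_roi, table.n_frames, table.channel_label)


def simulate_csr(spec: CsrSpec, template: LocalizationTable | None = None) -> LocalizationTable:
    """Draw exactly ``n_points`` i.i.d.-uniform localizations on the ROI.

    Frames are assigned uniformly in ``[1, n_frames]``.  When a ``template``
    table is given, per-localization intensity/sigma/uncertainty are resampled
    (with replacement) from its empirical values so the null inherits the real
    acquisition's photophysics; otherwise defaults are used.
    """
    rng = np.random.default_rng(spec.seed)
    roi = spec.roi_bounds
    n = spec.n_points
    x = rng.uniform(roi.x_min, roi.x_max, n)
    y = rng.uniform(roi.y_min, roi.y_max, n)
    frames = rng.integers(1, spec.n_frames + 1, n)
    kw = {}
    if template is not None and len(template) > 0:
        idx = rng.integers(0, len(template), n)
        td = template.data
        kw = dict(
            intensity_photons=td["intensity_photons"].to_numpy(float)[idx],
            sigma_nm=td["sigma_nm"].to_numpy(float)[idx],
            uncertainty_nm=td["uncertainty_nm"].to_numpy(float)[idx],
        )
    return make_table(
        x, y, frame=frames, roi_bounds=roi, n_frames=spec.n_frames, channel_label="csr", **kw
    )


def matched_csr_for(table: LocalizationTable, seed: int = 0) -> LocalizationTable:
    """CSR null matched to a real acquisition's count, ROI and frame number."""
    if len(table) == 0:
        raise ValueError("cannot match an empty table")
    spec = CsrSpec(
        roi_bounds=table.roi_bounds,
        n_points=len(table),
        n_frames=table.n_frames,
        seed=seed,
    )
    out = simulate_csr(spec, template=table)
    out.channel_label = f"{table.channel_label}-csr" if table.channel_label else "csr"
    return out


def csr_nnd_density(r, lambda_: float):
    """Rayleigh-form NND probability density of planar CSR at intensity lambda."""
    if lambda_ <= 0:
        raise ParameterError("lambda_ must be positive")
    r = np.asarray(r, float)
    if np.any(r < 0):
        raise ParameterError("r must be nonnegative")
    out = 2.0 * math.pi * lambda_ * r * np.exp(-math.pi * lambda_ * r * r)
    return float(out) if out.ndim == 0 else out


def csr_nnd_cdf(r, lambda_: float):
    """CDF of the CSR nearest-neighbor distance, ``1 - exp(-pi lambda r^2)``."""
    if lambda_ <= 0:
        raise ParameterError("lambda_ must be positive")
    r = np.asarray(r, float)
    out = 1.0 - np.exp(-math.pi * lambda_ * r * r)
    return float(out) if out.ndim == 0 else out


def csr_nnd_mode(lambda_: float) -> float:
    """Mode of the CSR NND density, ``1 / sqrt(2 pi lambda)``."""
    if lambda_ <= 0:
        raise ParameterError("lambda_ must be positive")
    return 1.0 / math.sqrt(2.0 * math.pi * lambda_)
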