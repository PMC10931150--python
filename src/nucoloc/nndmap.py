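"""In-cellulo NND maps: source-channel renderings color-coded by cross-channel NND.

Each pixel covered by the rendered footprint of at least one source
localization carries the cross-channel NND of the nearest contributing source
localization (per-molecule readout, not an average); pixels without source
signal hold a NaN sentinel and render black.  The composite view modulates a
perceptually uniform colormap by the rendered intensity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .locdata import LocalizationTable, RenderedImage, render_gaussian
from .nnd import cross_nnd


@dataclass
class NndMap:
    """Value/intensity pixel pair for the color-coded NND visualization."""

    value_pixels: np.ndarray  # NND in nm where source signal exists, NaN elsewhere
    intensity_pixels: RenderedImage
    pixel_size_nm: float
    color_scale: tuple[float, float]

    @property
    def defined_mask(self) -> np.ndarray:
        return ~np.isnan(self.value_pixels)


def build_nnd_map(
    source: LocalizationTable,
    target: LocalizationTable,
    pixel_size_nm: float = 10.0,
    color_scale: tuple[float, float] = (0.0, 250.0),
    psf_expansion: float = 1.0,
    attribution: str = "nearest",
) -> NndMap:
    """Build the color-coded NND map of ``source`` with respect to ``target``.

    ``attribution='nearest'`` assigns each footprint pixel the NND of the
    closest contributing source localization (default); ``'mean'`` assigns the
    intensity-weighted mean NND of all contributing localizations.
    """
    if attribution not in ("nearest", "mean"):
        raise ValueError(f"unknown attribution {attribution!r}")
    result = cross_nnd(source, target)
    nnds = result.distances_nm
    intensity = render_gaussian(source, pixel_size_nm=pixel_size_nm, psf_expansion=psf_expansion)
    shape = intensity.shape
    roi = source.roi_bounds
    s = pixel_size_nm

    values = np.full(shape, np.nan)
    if attribution == "nearest":
        best = np.full(shape, np.inf)
    else:
        wsum = np.zeros(shape)
        vsum = np.zeros(shape)

    xs = source.x - roi.x_min
    ys = source.y - roi.y_min
    sigmas = source.data["uncertainty_nm"].to_numpy(float) * psf_expansion
    for x0, y0, sig, nnd in zip(xs, ys, sigmas, nnds):
        r = max(4.0 * sig, s)
        j0 = max(0, int(math.floor((x0 - r) / s)))
        j1 = min(shape[1] - 1, int(math.ceil((x0 + r) / s)))
        i0 = max(0, int(math.floor((y0 - r) / s)))
        i1 = min(shape[0] - 1, int(math.ceil((y0 + r) / s)))
        if j1 < j0 or i1 < i0:
            continue
        jj = np.arange(j0, j1 + 1)
        ii = np.arange(i0, i1 + 1)
        dx = (jj + 0.5) * s - x0
        dy = (ii + 0.5) * s - y0
        d2 = dy[:, None] ** 2 + dx[None, :] ** 2
        if attribution == "nearest":
            sub = (slice(i0, i1 + 1), slice(j0, j1 + 1))
            closer = d2 < best[sub]
            best[sub] = np.where(closer, d2, best[sub])
            values[sub] = np.where(closer, nnd, values[sub])
        else:
            w = np.exp(-d2 / (2.0 * max(sig, 1e-9) ** 2))
            wsum[i0 : i1 + 1, j0 : j1 + 1] += w
            vsum[i0 : i1 + 1, j0 : j1 + 1] += w * nnd

    footprint = intensity.pixels > 0
    if attribution == "nearest":
        values[~footprint] = np.nan
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(footprint & (wsum > 0), vsum / np.maximum(wsum, 1e-300), np.nan)
    return NndMap(values, intensity, pixel_size_nm, tuple(color_scale))


def composite_rgb(nnd_map: NndMap, cmap_name: str = "viridis") -> np.ndarray:
    """Intensity-modulated RGB composite; sentinel pixels render black."""
    import matplotlib

    lo, hi = nnd_map.color_scale
    vals = np.clip((nnd_map.value_pixels - lo) / max(hi - lo, 1e-12), 0.0, 1.0)
    defined = nnd_map.defined_mask
    vals = np.where(defined, vals, 0.0)
    rgba = matplotlib.colormaps[cmap_name](vals)
    inten = nnd_map.intensity_pixels.pixels
    peak = inten.max()
    weight = inten / peak if peak > 0 else inten
    rgb = rgba[..., :3] * (weight * defined)[..., None]
    return rgb
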