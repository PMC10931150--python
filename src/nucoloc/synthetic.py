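"""Synthetic ground-truth generators for every analysis stage.

Three generators emulate the data the analyses consume:

* :func:`generate_pattern` — two-channel nuclear point patterns (CSR, paired
  at a controlled cross-channel distance, or Thomas-clustered), with
  per-molecule blinking multiplicity and localization-precision scatter;
* :func:`generate_frames` — EMCCD-like camera frames of blinking emitters
  (integrated Gaussian PSF, Poisson shot noise, EM gain, baseline, readout
  noise) to exercise the detection/fitting loop;
* :func:`generate_nucleus_image` — two-channel confocal-like nucleus images
  with a nuclear-envelope ring, nucleoplasmic foci, controllable co-signal
  fraction, PSF blur and noise, plus ground-truth masks.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, special

from .confocal import ConfocalImagePair, NucleusSegmentation
from .errors import ParameterError, PlacementError
from .localize import CameraModel, FrameStack
from .locdata import LocalizationTable, Roi, make_table


@dataclass(frozen=True)
class PatternSpec:
    """Study conditions for a two-channel point pattern.

    Defaults are dSTORM-realistic: ~100 molecules/um^2, ~10 nm localization
    precision, mild blinking (mean 1.5 localizations per molecule), and a
    few-nm cross-channel pairing distance with small jitter.
    """

    process: str = "paired"  # csr | paired | thomas
    roi_bounds: Roi = field(default_factory=lambda: Roi(0.0, 0.0, 5000.0, 5000.0))
    density_per_nm2: float = 1e-4
    pairing_distance_nm: float = 8.0
    jitter_sd_nm: float = 5.0
    localization_precision_nm: float = 10.0
    blink_mean: float = 1.5
    n_frames: int = 1000
    seed: int = 0
    # Thomas-process parameters (clustered alternative)
    thomas_mean_per_cluster: float = 5.0
    thomas_cluster_sd_nm: float = 50.0

    def __post_init__(self):
        if self.process not in ("csr", "paired", "thomas"):
            raise ParameterError(f"unknown process {self.process!r}")
        if self.density_per_nm2 <= 0:
            raise ParameterError("density must be positive")
        if self.pairing_distance_nm < 0 or self.jitter_sd_nm < 0:
            raise ParameterError("distances must be nonnegative")
        if self.blink_mean < 1:
            raise ParameterError("blink_mean must be >= 1")


def _molecules(spec: PatternSpec, rng: np.random.Generator) -> np.ndarray:
    """Channel-A molecule positions for the requested process (fixed count)."""
    roi = spec.roi_bounds
    n = max(1, round(spec.density_per_nm2 * roi.area))
    if spec.process in ("csr", "paired"):
        x = rng.uniform(roi.x_min, roi.x_max, n)
        y = rng.uniform(roi.y_min, roi.y_max, n)
        return np.column_stack([x, y])
    # Thomas: Poisson parents, Gaussian-scattered offspring, truncated to n
    n_parents = max(1, round(n / spec.thomas_mean_per_cluster))
    px = rng.uniform(roi.x_min, roi.x_max, n_parents)
    py = rng.uniform(roi.y_min, roi.y_max, n_parents)
    counts = rng.poisson(spec.thomas_mean_per_cluster, n_parents)
    parents = np.repeat(np.column_stack([px, py]), counts, axis=0)
    while len(parents) < n:  # top up sparse draws
        extra = rng.integers(0, n_parents)
        parents = np.vstack([parents, [[px[extra], py[extra]]]])
    pts = parents[:n] + rng.normal(0.0, spec.thomas_cluster_sd_nm, (n, 2))
    pts[:, 0] = np.clip(pts[:, 0], roi.x_min, roi.x_max)
    pts[:, 1] = np.clip(pts[:, 1], roi.y_min, roi.y_max)
    return pts


def _blinks(
    molecules: np.ndarray, spec: PatternSpec, rng: np.random.Generator, label: str
) -> LocalizationTable:
    """Expand molecules into localizations: blinking + precision scatter."""
    n = len(molecules)
    k = 1 + rng.poisson(spec.blink_mean - 1.0, n)
    pos = np.repeat(molecules, k, axis=0)
    if spec.localization_precision_nm > 0:
        pos = pos + rng.normal(0.0, spec.localization_precision_nm, pos.shape)
    roi = spec.roi_bounds
    pos[:, 0] = np.clip(pos[:, 0], roi.x_min, roi.x_max)
    pos[:, 1] = np.clip(pos[:, 1], roi.y_min, roi.y_max)
    frames = rng.integers(1, spec.n_frames + 1, len(pos))
    unc = spec.localization_precision_nm if spec.localization_precision_nm > 0 else 1.0
    return make_table(
        pos[:, 0],
        pos[:, 1],
        frame=frames,
        sigma_nm=150.0,
        uncertainty_nm=unc,
        roi_bounds=roi,
        n_frames=spec.n_frames,
        channel_label=label,
    )


def generate_pattern(spec: PatternSpec):
    """Generate a two-channel localization pattern with known ground truth.

    Returns ``(channel_a, channel_b, truth)`` where ``truth`` holds the
    underlying molecule positions per channel.  For ``paired``, each B
    molecule sits at ``pairing_distance_nm`` from its A partner in a uniform
    random direction, plus isotropic Gaussian jitter; for ``csr`` the
    channels are independent; for ``thomas`` each channel is an independent
    cluster process.
    """
    rng = np.random.default_rng(spec.seed)
    mol_a = _molecules(spec, rng)
    roi = spec.roi_bounds
    if spec.process == "paired":
        theta = rng.uniform(0.0, 2.0 * math.pi, len(mol_a))
        disp = spec.pairing_distance_nm * np.column_stack([np.cos(theta), np.sin(theta)])
        mol_b = mol_a + disp
        if spec.jitter_sd_nm > 0:
            mol_b = mol_b + rng.normal(0.0, spec.jitter_sd_nm, mol_b.shape)
        mol_b[:, 0] = np.clip(mol_b[:, 0], roi.x_min, roi.x_max)
        mol_b[:, 1] = np.clip(mol_b[:, 1], roi.y_min, roi.y_max)
    else:
        mol_b = _molecules(spec, rng)
    table_a = _blinks(mol_a, spec, rng, "A")
    table_b = _blinks(mol_b, spec, rng, "B")
    truth = {"molecules_a": mol_a, "molecules_b": mol_b}
    return table_a, table_b, truth


def _integrated_psf(shape, x_px, y_px, sigma_px):
    """Expected photon fraction per pixel for a Gaussian PSF (erf-integrated)."""
    h, w = shape
    xe = np.arange(w + 1, dtype=float)
    ye = np.arange(h + 1, dtype=float)
    cx = special.erf((xe - x_px) / (sigma_px * math.sqrt(2.0)))
    cy = special.erf((ye - y_px) / (sigma_px * math.sqrt(2.0)))
    fx = 0.5 * np.diff(cx)
    fy = 0.5 * np.diff(cy)
    return np.outer(fy, fx)


def generate_frames(
    molecules_nm: np.ndarray,
    camera: CameraModel,
    n_frames: int,
    photons_per_blink: float,
    background_photons: float,
    seed: int = 0,
    pixel_size_nm: float = 100.0,
    frame_shape_px: tuple[int, int] | None = None,
    psf_sigma_nm: float = 150.0,
    blinks_per_molecule: int = 1,
    return_events: bool = False,
):
    """Render EMCCD-like frames of blinking emitters.

    Each molecule emits ``blinks_per_molecule`` events, each placed in a
    uniformly random frame and rendered as an integrated-Gaussian PSF spot
    with Poisson shot noise on (signal + background) photons, deterministic
    EM-gain amplification, camera baseline, and Gaussian readout noise.

    With ``return_events`` the ground-truth blink list is returned alongside
    the stack as an ``(n_events, 4)`` array of
    ``(frame_index_1based, molecule_index, x_nm, y_nm)``.
    """
    if n_frames < 1:
        raise ParameterError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    molecules_nm = np.asarray(molecules_nm, float).reshape(-1, 2)
    if frame_shape_px is None:
        if len(molecules_nm):
            extent = molecules_nm.max(axis=0) / pixel_size_nm
            frame_shape_px = (int(math.ceil(extent[1])) + 8, int(math.ceil(extent[0])) + 8)
        else:
            frame_shape_px = (32, 32)
    h, w = frame_shape_px
    sigma_px = psf_sigma_nm / pixel_size_nm

    expected = np.full((n_frames, h, w), float(background_photons))
    events = []
    for mi, (x_nm, y_nm) in enumerate(molecules_nm):
        x_px = x_nm / pixel_size_nm
        y_px = y_nm / pixel_size_nm
        spot = _integrated_psf((h, w), x_px, y_px, sigma_px)
        for _ in range(blinks_per_molecule):
            f = int(rng.integers(0, n_frames))
            expected[f] += photons_per_blink * spot
            events.append((f + 1, mi, x_nm, y_nm))
    photons = rng.poisson(expected).astype(float)
    counts = camera.photons_to_counts(photons)
    if camera.readout_sd > 0:
        counts = counts + rng.normal(0.0, camera.readout_sd, counts.shape)
    counts = np.maximum(counts, 0.0)
    stack = FrameStack(frames=counts, pixel_size_nm=pixel_size_nm, camera=camera)
    if return_events:
        return stack, np.array(events, dtype=float).reshape(-1, 4)
    return stack


@dataclass(frozen=True)
class NucleusImageSpec:
    """Study conditions for a synthetic two-channel nucleus image.

    Channel A mimics a lamin-like signal (bright NE ring plus diffuse
    nucleoplasm), channel B a punctate nucleoplasmic signal; ``co_fraction``
    of the B foci also carry co-varying channel-A puncta.
    """

    image_shape_px: tuple[int, int] = (128, 128)
    pixel_size_um: float = 0.1
    nucleus_radius_px: float = 50.0
    ne_ring_intensity: float = 200.0
    nucleoplasm_intensity: float = 40.0
    n_foci: int = 12
    focus_radius_px: float = 3.0
    focus_intensity: float = 150.0
    co_fraction: float = 1.0
    ne_ring_width_px: int = 3
    psf_blur_sd_px: float = 1.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.nucleus_radius_px <= 0 or self.focus_radius_px <= 0:
            raise ParameterError("radii must be positive")
        if not (0.0 <= self.co_fraction <= 1.0):
            raise ParameterError("co_fraction must be in [0, 1]")


def generate_nucleus_image(spec: NucleusImageSpec):
    """Generate a two-channel nucleus image with ground truth.

    Returns ``(pair, truth)``; ``truth`` is a dict with the geometric
    :class:`NucleusSegmentation` and the planted foci (centers, radius).
    Foci are placed without overlap inside the nucleoplasm; if placement
    fails after bounded retries a :class:`PlacementError` is raised.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape_px
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r = np.hypot(yy - cy, xx - cx)

    nucleus = r <= spec.nucleus_radius_px
    interior = r <= spec.nucleus_radius_px - spec.ne_ring_width_px
    ring = nucleus & ~interior
    truth_seg = NucleusSegmentation(
        nucleus_mask=nucleus,
        ne_ring_mask=ring,
        nucleoplasm_mask=interior,
        ring_width_px=spec.ne_ring_width_px,
    )

    chan_a = np.zeros((h, w))
    chan_a[ring] = spec.ne_ring_intensity
    chan_a[interior] = spec.nucleoplasm_intensity
    chan_b = np.zeros((h, w))

    # place non-overlapping foci fully inside the nucleoplasm
    margin = spec.nucleus_radius_px - spec.ne_ring_width_px - spec.focus_radius_px - 1
    if margin <= 0:
        raise PlacementError("nucleus too small for the requested foci")
    centers = []
    max_tries = 200 * max(spec.n_foci, 1)
    tries = 0
    while len(centers) < spec.n_foci:
        tries += 1
        if tries > max_tries:
            raise PlacementError(
                f"could not place {spec.n_foci} non-overlapping foci after {max_tries} tries"
            )
        rho = margin * math.sqrt(rng.uniform())
        phi = rng.uniform(0.0, 2.0 * math.pi)
        c = (cy + rho * math.sin(phi), cx + rho * math.cos(phi))
        # +2.5 px over the touching distance: rasterized disks must not become
        # 8-connected neighbors after thresholding
        min_sep = 2.0 * spec.focus_radius_px + 2.5
        if all((c[0] - c2[0]) ** 2 + (c[1] - c2[1]) ** 2 >= min_sep**2 for c2 in centers):
            centers.append(c)
    n_co = int(round(spec.co_fraction * spec.n_foci))
    for i, (fy, fx) in enumerate(centers):
        disk = np.hypot(yy - fy, xx - fx) <= spec.focus_radius_px
        chan_b[disk] += spec.focus_intensity
        if i < n_co:
            chan_a[disk] += spec.focus_intensity

    if spec.psf_blur_sd_px > 0:
        chan_a = ndimage.gaussian_filter(chan_a, spec.psf_blur_sd_px)
        chan_b = ndimage.gaussian_filter(chan_b, spec.psf_blur_sd_px)
    if spec.noise_sd > 0:
        chan_a = chan_a + rng.normal(0.0, spec.noise_sd, chan_a.shape)
        chan_b = chan_b + rng.normal(0.0, spec.noise_sd, chan_b.shape)
    chan_a = np.maximum(chan_a, 0.0)
    chan_b = np.maximum(chan_b, 0.0)

    pair = ConfocalImagePair(chan_a, chan_b, pixel_size_um=spec.pixel_size_um)
    truth = {
        "segmentation": truth_seg,
        "foci_centers": np.array(centers),
        "focus_radius_px": spec.focus_radius_px,
        "n_co_foci": n_co,
    }
    return pair, truth
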