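# Methods

## Coordinate-based colocalization model

The SMLM arm treats each channel as a planar point pattern of localizations
in nanometer coordinates. The colocalization statistic is the cross-channel
nearest-neighbor distance: for each localization in a *source* channel, the
Euclidean distance to the nearest localization of the *target* channel. The
statistic is directional — both directions (A→B and B→A) are always
reported, since the two channels generally have different densities and
cluster structure.

Distances are summarized two ways:

* **Display distribution** — histogram on radius steps of 50 nm, 10 bins
  (edges 0–500 nm). Each acquisition's histogram is normalized by that
  acquisition's source localization count, so bins are fractions of
  molecules; distances beyond the last edge are reported as a separate
  overflow fraction, and per acquisition the fractions plus overflow sum to
  exactly 1. Across acquisitions the mean and SEM per bin are reported.
* **Mode NND** — the peak of the pooled distance histogram on a *fine* grid
  (default 2 nm), returned as the maximal bin's center with ties broken
  toward smaller distances. The fine grid is deliberately separate from the
  50 nm display grid: nanometer-scale modes cannot be resolved at 50 nm
  resolution. The fine-bin width is configurable; for broad Rayleigh-like
  distributions (CSR at low density) a wider bin (we use ~0.4× the expected
  mode) trades a small quantization bias for much lower estimator variance —
  with nanometer bins the argmax tracks sampling noise across the flat peak
  rather than the peak location.

### Null models

Two randomized controls are constructed per acquisition:

* **Coordinate swap**: x and y of the target channel are exchanged. This
  preserves the channel's point count, its within-channel distance multiset
  and (on square ROIs) its density, while destroying any registration with
  the source channel. On non-square ROIs the plain swap transposes the ROI;
  an opt-in flag instead rescales the swapped coordinates back onto the
  original ROI.
* **Matched CSR**: exactly n i.i.d.-uniform points on the acquisition's ROI
  with frames uniform in [1, n_frames], where n, ROI and frame count are
  taken from the real channel. The count is fixed rather than Poisson-drawn
  so the null matches the real acquisition's density exactly and count
  variance does not enter the comparison. Per-localization intensity, PSF
  width and uncertainty are resampled from the real channel's empirical
  values.

No edge correction is applied to reported distributions: the real data and
both nulls share the same ROI geometry, hence the same edge bias. An
optional guard zone (exclude sources within a margin of the border) exists
for comparisons against the analytic CSR law, where the infinite-plane
formula would otherwise disagree near the boundary; 3/√λ is used as the
guard margin in the oracle tests.

For homogeneous planar CSR at intensity λ the NND density is
f(r) = 2πλ r·exp(−πλ r²) with CDF 1 − exp(−πλ r²) and mode 1/√(2πλ); this
closed form is the independent oracle for the simulators and the NND path.

### Statistical comparison

Real and null per-acquisition summaries (default: the mean cross-NND of the
acquisition; per-acquisition mode is available) are compared by a paired
t-test, one-tailed in the direction "real distances smaller than random"
(the alternative of interest for attraction between channels). A
Kolmogorov–Smirnov check of the standardized paired differences is run
first; if it fails, the t-test is still reported with a logged warning and
a `normality_ok=False` flag, since no fallback test is defined for this
analysis. Degenerate input (identical real and null lists) reports t = 0
with one-sided p = 0.5 rather than NaN. Significance bands: * p < 0.05,
** p < 0.01, *** p < 0.005.

The nearest-neighbor search uses a KD-tree (scipy.spatial.cKDTree) under an
exactness contract: results must equal exhaustive all-pairs search, which
the tests verify on random instances up to 500 points.

## Rendering and NND maps

Localizations are rendered by the normalized-Gaussian method: each
localization contributes an isotropic 2-D Gaussian of unit mass with
standard deviation equal to its localization uncertainty times an expansion
factor (default 1), rasterized at 10 nm/px by evaluating separable 1-D
profiles at pixel centers, truncating at 4σ, and normalizing per
localization. Mass is conserved to better than 1% for localizations more
than ~3σ from the ROI border; rendering is exactly linear in the point set.
Whether the source data's renderer used per-localization uncertainty or a
fixed width is not generally knowable from exported tables; per-localization
uncertainty is the default here and a fixed override is provided.

The NND map assigns every pixel covered by a source localization's rendered
footprint the cross-channel NND of the *nearest contributing* localization
(distance measured from the pixel center), preserving the per-molecule
readout; an intensity-weighted mean attribution is available as an option.
Pixels with no source footprint hold a NaN sentinel and render black. The
default color scale is 0–250 nm on a perceptually uniform colormap.

## Single-emitter localization

Candidate spots are local maxima within a peak-mask window (default 9 px)
whose background-subtracted amplitude exceeds a robust noise estimate —
1.4826 × the median absolute deviation of the frame, robust against sparse
bright spots — by the peak intensity-to-noise threshold (default 6).
Candidates closer than the mask size are merged to the brighter one;
multi-emitter joint fitting is deliberately not implemented, and synthetic
densities are kept low enough that single-emitter fitting is adequate.

Each candidate is fit on its window with a pixel-integrated (erf) 2-D
Gaussian plus constant background, by least squares with residuals weighted
by the model's shot-noise standard deviation (a Gaussian approximation of
the Poisson likelihood — unweighted least squares costs ~30–40% precision at
these photon counts). The initial σ is the configured PSF half width
(177.9 nm by default, interpreted as the initial Gaussian σ; vendor
conventions differ, so this is configurable). Fits whose σ leaves
[0.3, 3]× the initial value, or whose window is clipped by the frame edge,
are rejected non-fatally. Photon counts are the fitted Gaussian volume
divided by the camera gain (counts = baseline + photons × EM gain ×
counts-per-electron). The localization precision estimate is Thompson-style,

    σ_loc² = F·(σ² + a²/12)/N + 8π σ⁴ b²/(a² N²),

with pixel size a, photon count N, background noise b in photons/pixel, and
F = 2 the standard EMCCD excess-noise variance inflation.

## Synthetic data generators

The generators define the study conditions under which the pipeline is
validated; defaults are chosen as dSTORM- and confocal-realistic values.

* **Point patterns** (`generate_pattern`): channel A is CSR, or
  Thomas-clustered (Poisson parents, Gaussian-scattered offspring); for the
  `paired` process each channel-B molecule sits at the pairing distance from
  its A partner in a uniformly random direction (isotropy matches the NND
  statistic's rotation invariance) plus isotropic Gaussian jitter. Each
  molecule emits 1 + Poisson(blink_mean − 1) localizations — a simple
  bounded-mean blinking model, sufficient to exercise multi-localization
  clustering artifacts without photophysics kinetics — each scattered by the
  localization precision. Defaults: 100 molecules/µm² (1e-4 /nm²), pairing
  8 nm, jitter 5 nm, precision 10 nm, blink mean 1.5. Coordinates are
  clipped to the ROI, which slightly perturbs the few molecules within a
  precision-length of the border.
* **Frame stacks** (`generate_frames`): integrated-Gaussian PSF spots
  (σ 150 nm on 100 nm pixels), Poisson shot noise on signal + background,
  deterministic EM-gain amplification, camera baseline and Gaussian readout
  noise. The stochastic excess noise of EM multiplication is *not*
  simulated; it is accounted for on the estimation side as the factor-2
  variance inflation above. Camera defaults echo common EMCCD settings
  (EM gain 300).
* **Nucleus images** (`generate_nucleus_image`): channel A is a bright
  nuclear-envelope ring (default 3 px wide) plus a dimmer diffuse
  nucleoplasm (lamin-like); channel B is punctate nucleoplasmic foci, a
  controllable fraction of which carry co-varying channel-A puncta; both
  channels are PSF-blurred and noise-corrupted. Foci are placed by rejection
  sampling with a minimum separation of 2r + 2.5 px so rasterized disks
  cannot merge under 8-connectivity; bounded retries, then a placement
  error.

What these generators do *not* emulate: drift, chromatic/affine channel
misregistration, anisotropic PSFs, photophysics kinetics (on/off rates,
bleaching), non-uniform background, and 3-D structure. Passing tests
therefore demonstrate correctness of the statistics and estimators under
the stated model, not robustness to those instrument effects — which the
upstream acquisition software is assumed to have corrected.

## Confocal arm

Segmentation: Otsu threshold on the nucleus channel, hole filling, largest
connected component; the nuclear-envelope ring is the band within
ring_width_px (default 3 px, ≈ the envelope thickness at confocal
resolution; configurable) of the boundary, obtained by erosion with a disk
structuring element (iterated 3×3 erosion would give a city-block band,
thinner along diagonals); the nucleoplasm is the eroded remainder. Ring and
nucleoplasm partition the nucleus exactly, by construction. The original
macro behind this style of analysis is unpublished, so this pipeline is
declared on its own terms rather than claimed equivalent.

Coefficients per compartment: Pearson correlation; Manders overlap
MOC = Σab/√(Σa²Σb²) (invariant to per-channel rescaling); directional
M1 = Σa·[b > t_b]/Σa and the symmetric M2, with thresholds defaulting to
per-channel Otsu within the nucleus. Both MOC and M1/M2 are reported
because "overlap of X over Y" is used ambiguously across the literature.
Zero-variance or zero-energy masks raise an undefined-result error rather
than returning a silent number; if only one directional denominator
vanishes, that coefficient alone is NaN.

Foci: connected components of the thresholded channel within a mask,
components under min_area_px (default 4) discarded; count, total area
(µm²), total integrated intensity (from the raw image) and mean focus area
are reported. An optional Gaussian pre-filter (`smooth_sd_px`) guards
against noise-driven spurious components on low-SNR images — Otsu on a
strongly unbalanced foreground/background histogram otherwise thresholds
inside the noise mode; smoothing at the PSF scale (1 px) restores exact
count recovery at focus-amplitude-to-noise ratio 5 in the validation runs.
Group comparison is a two-tailed t-test on a chosen metric with mean ± SEM
per group.

## Pipelines, determinism, problem sizes

Both pipelines are deterministic: every random draw derives from the run
seed through a fixed integer hash (sub-seeds stay below 2³¹), and reruns
with the same configuration produce byte-identical numeric tables (floats
are written at fixed precision; JSON keys are sorted). The run manifest
records package and numpy versions, the seed and all parameters.

Validation problem sizes are chosen to give tight statistical checks at
desk-scale runtimes: CSR oracle at λ = 10⁻³/nm² with 10⁴ points per channel
(sup-CDF tolerance 0.02); planted-distance recovery at 20–200 nm with 10
acquisitions of ~3,800 molecules on a 200 µm square ROI — density
~0.094 molecules/µm², low enough that planted partners are mutual nearest
neighbors, so the 10⁶-sample isolated-pair Monte-Carlo oracle applies;
null-model calibration with 100 replicate pipeline runs of 10 acquisitions
each; localization-loop checks on 5 emitters × 60 frames at three photon
levels (10³–10⁴); confocal checks on batches of 50–100 nuclei of 128² px.

## Known limitations

* Localization handles 2-D data only; no astigmatic 3-D, no drift
  correction, no channel alignment (assumed done upstream).
* The paired t-test is reported even when the KS normality check fails
  (flagged); with few acquisitions the check has little power either way.
* Mode-NND estimates are quantized to the fine-bin width; the bias-variance
  trade-off of the bin width is the user's responsibility for unusual
  densities.
* Cluster-process (Thomas) fitting is out of scope; the Thomas generator
  exists only to produce clustered test patterns.
* Foci metrics assume roughly disk-like puncta; heavily overlapping foci
  merge into single components by design.
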