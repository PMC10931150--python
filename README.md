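# nucoloc

Colocalization analysis for two-color nuclear microscopy, built around two
arms:

1. **Coordinate-based colocalization of SMLM data.** Given two channels of
   single-molecule localizations (e.g. lamin A/C and the nuclear
   phosphoinositide PI(4,5)P2 imaged by dSTORM), the package computes, for
   every localization of one channel, the nearest-neighbor distance (NND) to
   the other channel, aggregates the per-acquisition-normalized NND
   distributions (50 nm radius steps, 10 bins, SEM error bars across
   acquisitions), estimates the mode (peak) NND on a fine grid, and tests
   the real data against two randomized controls: **coordinate-swapped**
   localizations (x and y exchanged — within-channel structure preserved,
   cross-channel registration destroyed) and **matched CSR** (completely
   spatially random points with exactly the real acquisition's count, area
   and frame number). Real-vs-random comparison is a paired one-tailed
   t-test with a Kolmogorov–Smirnov normality check. The in-cellulo view is
   an NND map: the rendered source channel with each pixel color-coded by
   the NND of its localization.

2. **Confocal compartment colocalization.** Nuclei are segmented (Otsu
   threshold, hole filling, largest component) and split into a
   nuclear-envelope ring and the nucleoplasm; Pearson (PCC), Manders overlap
   (MOC = Σab/√(Σa²Σb²)) and directional Manders (M1/M2) coefficients are
   reported per compartment, and punctate foci are quantified per nucleus
   (count, total area, total intensity, mean focus area) with two-group
   t-test comparison.

Supporting modules close the loop from raw data: a single-emitter localizer
(local-maximum detection at a configurable intensity-to-noise ratio plus
pixel-integrated 2-D Gaussian fitting with a Thompson-style precision
estimate) and synthetic generators for two-channel point patterns (CSR,
paired at a controlled distance, Thomas-clustered), EMCCD-like frame stacks,
and two-channel nucleus images — so every stage is testable against known
ground truth without any external data.

For homogeneous planar CSR at intensity λ, the NND law used as the analytic
oracle throughout is

    f(r) = 2πλ r exp(−πλ r²),   F(r) = 1 − exp(−πλ r²),   mode = 1/√(2πλ).

## Worked example

Simulate five acquisitions of a paired two-channel pattern (molecules of
channel B planted 8 nm from their channel-A partners, 5 nm jitter, 10 nm
localization precision, mild blinking) and run the full NND pipeline:

```python
from nucoloc import PatternSpec, Roi
from nucoloc.pipeline import NndRunConfig, run_nnd_pipeline

cfg = NndRunConfig(
    n_acquisitions=5,
    pattern=PatternSpec(process="paired", roi_bounds=Roi(0, 0, 20000, 20000),
                        density_per_nm2=2e-6, pairing_distance_nm=8.0,
                        jitter_sd_nm=5.0, localization_precision_nm=10.0,
                        blink_mean=1.5),
    seed=1,
)
report = run_nnd_pipeline(cfg)
entry = report["directions"]["a_to_b"]
for cond in ("real", "swap", "csr"):
    print(cond, entry["conditions"][cond]["mode_nnd_nm"])
print(entry["tests"]["real_vs_swap"])
```

This prints a mode NND of **13 nm** for the real data versus **225 nm** for
the coordinate-swap null and **231 nm** for the matched-CSR null, and the
paired one-tailed t-tests give

```
real_vs_swap  t = -149.4   p = 6.0e-09  ***
real_vs_csr   t = -115.4   p = 1.7e-08  ***
```

i.e. the planted 8 nm pairing (broadened to ~13 nm by the combined 5 nm
jitter and two 10 nm localization scatters) is detected as a highly
non-random cross-channel proximity, while both density-matched nulls sit at
the distances expected for unrelated points at this density. Significance
bands follow * p < 0.05, ** p < 0.01, *** p < 0.005.

The same run can be driven from the shell:

```bash
nucoloc simulate --process paired --distance 8 --seed 1 --out-a a.csv --out-b b.csv
nucoloc nnd --source a.csv --target b.csv --null swap
nucoloc map --source a.csv --target b.csv --out-tif map.tif --out-png map.png
nucoloc coloc --image nucleus.tif --nucleus-channel a --ring-width 3
```

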