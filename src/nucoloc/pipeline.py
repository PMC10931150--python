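"""End-to-end orchestration of the NND and confocal colocalization analyses.

``run_nnd_pipeline`` takes a set of two-channel acquisitions (simulated or
loaded from tables), computes cross-channel NNDs in both directions for the
real data and both randomized nulls (coordinate swap, matched CSR),
aggregates normalized distributions with SEM, estimates mode NNDs, and runs
the paired real-vs-random tests.  ``run_coloc_pipeline`` does the confocal
arm: per-nucleus segmentation, compartment-resolved coefficients, foci
statistics, and group comparisons.  Both are deterministic under a fixed
seed and can write their report bundles (delimited tables + JSON) to disk.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .confocal import (
    compare_foci_groups,
    manders_m1_m2,
    manders_overlap,
    pearson,
    quantify_foci,
    segment_nucleus,
)
from .errors import ParameterError, SegmentationError, UndefinedResultError
from .locdata import LocalizationTable, Roi, read_localization_table
from .nnd import compare_real_vs_random, cross_nnd, mode_nnd, nnd_histogram
from .nulls import matched_csr_for, swap_xy
from .synthetic import NucleusImageSpec, PatternSpec, generate_nucleus_image, generate_pattern

logger = logging.getLogger(__name__)

_SEED_MOD = 2**31 - 1


def _subseed(seed: int, *streams: int) -> int:
    """Derive a reproducible sub-seed (< 2^31) from a base seed and indices."""
    h = seed % _SEED_MOD
    for s in streams:
        h = (h * 1_000_003 + s + 1) % _SEED_MOD
    return h


@dataclass
class NndRunConfig:
    """Configuration of a full NND pipeline run.

    Either ``acquisition_paths`` (list of ``(source_csv, target_csv)``) or a
    simulated-study block (``n_acquisitions`` + pattern parameters) must be
    given.  Analysis defaults carry the standard settings: 50 nm radius
    step, 10 bins, 2 nm mode grid, 10 nm/px rendering.
    """

    n_acquisitions: int = 5
    pattern: PatternSpec = field(default_factory=PatternSpec)
    acquisition_paths: list | None = None
    step_nm: float = 50.0
    n_bins: int = 10
    mode_step_nm: float = 2.0
    pixel_size_nm: float = 10.0
    summary: str = "mean"  # per-acquisition paired summary: mean | mode
    tail: str = "one_sided_less"
    seed: int = 0
    output_dir: str | None = None
    make_maps: bool = False


CONDITIONS = ("real", "swap", "csr")


def _load_acquisitions(config: NndRunConfig):
    acqs = []
    if config.acquisition_paths:
        for i, (src, tgt) in enumerate(config.acquisition_paths):
            a = read_localization_table(src, channel_label="A")
            b = read_localization_table(tgt, channel_label="B")
            if a.roi_bounds != b.roi_bounds:
                # channels of one acquisition must share a coordinate frame
                union = Roi(
                    min(a.roi_bounds.x_min, b.roi_bounds.x_min),
                    min(a.roi_bounds.y_min, b.roi_bounds.y_min),
                    max(a.roi_bounds.x_max, b.roi_bounds.x_max),
                    max(a.roi_bounds.y_max, b.roi_bounds.y_max),
                )
                a = a.with_data(a.data, roi_bounds=union)
                b = b.with_data(b.data, roi_bounds=union)
            acqs.append((a, b))
    else:
        if config.n_acquisitions < 1:
            raise ParameterError("n_acquisitions must be >= 1")
        for i in range(config.n_acquisitions):
            spec = PatternSpec(
                **{
                    **asdict(config.pattern),
                    "roi_bounds": config.pattern.roi_bounds,
                    "seed": _subseed(config.seed, 0, i),
                }
            )
            a, b, _ = generate_pattern(spec)
            acqs.append((a, b))
    return acqs


def run_nnd_pipeline(config: NndRunConfig) -> dict:
    """Run the full NND analysis; returns the report dict (and writes files).

    The report holds, per direction (``a_to_b``, ``b_to_a``) and condition
    (real, coordinate-swap null, matched-CSR null): the aggregated
    distribution, the pooled fine-grid mode NND, per-acquisition summary
    statistics, and the paired real-vs-null test reports.
    """
    acqs = _load_acquisitions(config)
    directions = {"a_to_b": (0, 1), "b_to_a": (1, 0)}
    results = {d: {c: [] for c in CONDITIONS} for d in directions}

    for i, (a, b) in enumerate(acqs):
        channels = (a, b)
        for dname, (si, ti) in directions.items():
            src, tgt = channels[si], channels[ti]
            results[dname]["real"].append(cross_nnd(src, tgt, acquisition_id=str(i)))
            results[dname]["swap"].append(
                cross_nnd(src, swap_xy(tgt), acquisition_id=str(i))
            )
            csr_tgt = matched_csr_for(tgt, seed=_subseed(config.seed, 1, i, si))
            results[dname]["csr"].append(cross_nnd(src, csr_tgt, acquisition_id=str(i)))

    report: dict = {
        "n_acquisitions": len(acqs),
        "parameters": {
            "step_nm": config.step_nm,
            "n_bins": config.n_bins,
            "mode_step_nm": config.mode_step_nm,
            "summary": config.summary,
            "tail": config.tail,
            "seed": config.seed,
        },
        "directions": {},
    }
    distributions = {}
    for dname in directions:
        entry: dict = {"conditions": {}}
        for cond in CONDITIONS:
            res = results[dname][cond]
            dist = nnd_histogram(res, step_nm=config.step_nm, n_bins=config.n_bins)
            distributions[(dname, cond)] = dist
            mode = mode_nnd(res, fine_step_nm=config.mode_step_nm)
            if config.summary == "mean":
                summaries = [float(r.distances_nm.mean()) for r in res]
            elif config.summary == "mode":
                summaries = [mode_nnd([r], fine_step_nm=config.mode_step_nm) for r in res]
            else:
                raise ParameterError(f"unknown summary {config.summary!r}")
            entry["conditions"][cond] = {
                "mode_nnd_nm": mode,
                "coarse_mode_nm": dist.mode_nm,
                "per_acquisition_summary": summaries,
                "overflow_fraction": dist.overflow,
            }
        entry["tests"] = {}
        real = entry["conditions"]["real"]["per_acquisition_summary"]
        for cond in ("swap", "csr"):
            null = entry["conditions"][cond]["per_acquisition_summary"]
            rep = compare_real_vs_random(real, null, tail=config.tail)
            if not rep.normality_ok:
                logger.warning(
                    "KS normality check failed (p=%.3g) for %s vs %s; "
                    "paired t-test reported regardless",
                    rep.normality_p,
                    dname,
                    cond,
                )
            entry["tests"][f"real_vs_{cond}"] = rep.to_dict()
        report["directions"][dname] = entry

    if config.output_dir is not None:
        _write_nnd_bundle(config, acqs, distributions, report)
    return report


def _write_nnd_bundle(config, acqs, distributions, report):
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (dname, cond), dist in distributions.items():
        path = out / f"nnd_distribution_{dname}_{cond}.csv"
        with open(path, "w") as fh:
            fh.write("bin_start_nm,bin_end_nm,mean_fraction,sem\n")
            for lo, hi, m, s in zip(
                dist.bin_edges_nm[:-1], dist.bin_edges_nm[1:], dist.normalized_counts, dist.sem
            ):
                fh.write(f"{lo:.6f},{hi:.6f},{m:.9f},{s:.9f}\n")
            fh.write(f"{dist.bin_edges_nm[-1]:.6f},inf,{dist.overflow:.9f},{dist.overflow_sem:.9f}\n")
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    manifest = {
        "nucoloc_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "n_acquisitions": len(acqs),
        "parameters": report["parameters"],
        "pattern": None
        if config.acquisition_paths
        else {
            **{k: v for k, v in asdict(config.pattern).items() if k != "roi_bounds"},
            "roi_bounds": list(asdict(config.pattern)["roi_bounds"].values()),
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    if config.make_maps and acqs:
        from tifffile import imwrite

        from .nndmap import build_nnd_map, composite_rgb

        a, b = acqs[0]
        nmap = build_nnd_map(a, b, pixel_size_nm=config.pixel_size_nm)
        imwrite(out / "nnd_map_a_to_b.tif", nmap.value_pixels.astype(np.float32))
        rgb = (composite_rgb(nmap) * 255).astype(np.uint8)
        try:
            import matplotlib

            matplotlib.use("Agg", force=False)
            import matplotlib.pyplot as plt

            fig, ax = plt.subplots(figsize=(6, 6))
            ax.imshow(rgb)
            ax.set_axis_off()
            fig.savefig(out / "nnd_map_a_to_b.png", dpi=150, bbox_inches="tight")
            plt.close(fig)
        except Exception:  # plotting must never fail the run
            logger.exception("could not write composite PNG")


@dataclass
class ColocRunConfig:
    """Configuration of a confocal colocalization run over a nucleus batch."""

    n_nuclei: int = 10
    image_spec: NucleusImageSpec = field(default_factory=NucleusImageSpec)
    group2_image_spec: NucleusImageSpec | None = None
    nucleus_channel: str = "a"
    ring_width_px: int = 3
    foci_metric: str = "n_foci"
    seed: int = 0
    output_dir: str | None = None


REGIONS = ("whole_nucleus", "ne", "nucleoplasm")


def _nucleus_row(pair, seg, spec: ColocRunConfig):
    from skimage import filters

    masks = {
        "whole_nucleus": seg.nucleus_mask,
        "ne": seg.ne_ring_mask,
        "nucleoplasm": seg.nucleoplasm_mask,
    }
    # directional-Manders thresholds: Otsu per channel within the nucleus
    ta = float(filters.threshold_otsu(pair.channel_a[seg.nucleus_mask]))
    tb = float(filters.threshold_otsu(pair.channel_b[seg.nucleus_mask]))
    row = {}
    for region, mask in masks.items():
        try:
            row[f"pcc_{region}"] = pearson(pair, mask)
        except UndefinedResultError:
            row[f"pcc_{region}"] = float("nan")
        try:
            row[f"moc_{region}"] = manders_overlap(pair, mask)
        except UndefinedResultError:
            row[f"moc_{region}"] = float("nan")
        try:
            m1, m2 = manders_m1_m2(pair, mask, threshold_a=ta, threshold_b=tb)
        except UndefinedResultError:
            m1 = m2 = float("nan")
        row[f"m1_{region}"] = m1
        row[f"m2_{region}"] = m2
    foci = quantify_foci(
        pair.channel_b,
        seg.nucleoplasm_mask,
        threshold="otsu",
        pixel_size_um=pair.pixel_size_um,
    )
    row.update(
        n_foci=foci.n_foci,
        total_area_um2=foci.total_area_um2,
        total_intensity=foci.total_intensity,
        mean_focus_area_um2=foci.mean_focus_area_um2,
    )
    return row, foci


def run_coloc_pipeline(config: ColocRunConfig) -> dict:
    """Run the confocal colocalization analysis on a synthetic nucleus batch.

    Generates ``n_nuclei`` images per group (one group by default, a second
    when ``group2_image_spec`` is set), segments each nucleus, computes
    compartment-resolved PCC/MOC/M1/M2 and nucleoplasmic foci statistics, and
    compares the groups on ``foci_metric``.  Nuclei whose segmentation fails
    are skipped and counted.
    """
    import pandas as pd

    groups = {"group1": config.image_spec}
    if config.group2_image_spec is not None:
        groups["group2"] = config.group2_image_spec
    rows = []
    foci_by_group: dict[str, list] = {g: [] for g in groups}
    n_skipped = 0
    for gi, (gname, spec0) in enumerate(groups.items()):
        for i in range(config.n_nuclei):
            spec = NucleusImageSpec(
                **{**asdict(spec0), "seed": _subseed(config.seed, 10 + gi, i)}
            )
            pair, _ = generate_nucleus_image(spec)
            try:
                seg = segment_nucleus(
                    pair,
                    nucleus_channel=config.nucleus_channel,
                    ring_width_px=config.ring_width_px,
                )
            except SegmentationError:
                logger.warning("segmentation failed for %s nucleus %d; skipped", gname, i)
                n_skipped += 1
                continue
            row, foci = _nucleus_row(pair, seg, config)
            row.update(group=gname, nucleus=i)
            rows.append(row)
            foci_by_group[gname].append(foci)

    table = pd.DataFrame(rows)
    report: dict = {"n_nuclei": len(rows), "n_skipped": n_skipped, "groups": list(groups)}
    for region in REGIONS:
        sub = table[f"moc_{region}"].dropna()
        report[f"moc_{region}_mean"] = float(sub.mean()) if len(sub) else float("nan")
    if len(groups) == 2 and all(len(v) >= 3 for v in foci_by_group.values()):
        report["group_test"] = compare_foci_groups(
            foci_by_group["group1"], foci_by_group["group2"], metric=config.foci_metric
        )
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "per_nucleus_results.csv", index=False, float_format="%.9f")
        with open(out / "coloc_report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    report["table"] = table
    return report
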