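"""End-to-end pipeline: image directory + layout -> descriptors + statistics.

Each chip runs preprocess -> segment -> postprocess -> skeletonize ->
descriptors; the per-chip descriptor table then feeds the group statistics
and the PCA embedding. Every chip's parameters and any exclusion are
recorded in a machine-readable JSON log, and the effective configuration is
echoed next to the outputs so a run is fully reproducible.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import pandas as pd

from . import io as asio
from .config import PipelineConfig
from .preprocess import rolling_ball_subtract
from .screen_stats import analyte_tests, compare_groups, embed, results_table
from .segment import postprocess_mask, segment_vessels
from .skeleton import measure_chip
from .types import DESCRIPTOR_NAMES


def process_chip_image(image, config: PipelineConfig):
    """Single-chip measurement: returns (VesselDescriptors, SkeletonGraph, mask)."""
    geometry = config.chip_geometry()
    if image.geometry is None:
        image.geometry = geometry
    pre = rolling_ball_subtract(
        image,
        radius=config.preprocess.rolling_ball_radius,
        smooth_sigma=config.preprocess.smooth_sigma,
    )
    mask = segment_vessels(
        pre,
        backend=config.segmentation.backend,
        width_cutoff=config.segmentation.thick_width_px,
    )
    mask = postprocess_mask(mask, geometry, config.segmentation.min_object_px)
    desc, graph = measure_chip(mask, geometry, config.segmentation.spur_prune_px)
    return desc, graph, mask


def run_pipeline(
    image_dir,
    layout_csv,
    config: PipelineConfig,
    out_dir,
    viability_csv=None,
    analytes_csv=None,
) -> dict:
    """Run the full analysis; returns a summary dict (also written as log).

    Images are looked up as ``<image_dir>/<chip>.tif``. A layout row whose
    image is missing is recorded as excluded and the run continues.
    """
    image_dir = Path(image_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    layout = pd.read_csv(layout_csv)
    geometry = config.chip_geometry()
    excluded_cfg = set(config.statistics.exclude_chips)

    log: dict = {"chips": {}, "excluded": []}
    rows = []
    for chip in layout["chip"]:
        path = image_dir / f"{chip}.tif"
        if chip in excluded_cfg:
            log["excluded"].append({"chip": chip, "reason": "config exclusion list"})
            continue
        if not path.exists():
            log["excluded"].append({"chip": chip, "reason": "missing image"})
            continue
        image = asio.read_image(path, geometry=geometry,
                                pixel_size_um=config.geometry.pixel_size_um)
        desc, graph, mask = process_chip_image(image, config)
        rows.append({"chip": chip, **desc.as_dict()})
        log["chips"][chip] = {
            "flags": list(desc.flags),
            "n_nodes": len(graph.nodes),
            "n_edges": len(graph.edges),
            "params": {
                "rolling_ball_radius": config.preprocess.rolling_ball_radius,
                "backend": config.segmentation.backend,
                "thick_width_px": config.segmentation.thick_width_px,
                "min_object_px": config.segmentation.min_object_px,
                "spur_prune_px": config.segmentation.spur_prune_px,
            },
        }

    desc_df = pd.DataFrame(rows, columns=["chip", *DESCRIPTOR_NAMES])
    desc_df.to_csv(out / "descriptors.csv", index=False)

    merged = desc_df.merge(layout[["chip", "treatment"]], on="chip")
    control = config.statistics.control_label
    results = []
    if control in set(merged["treatment"]) and merged["treatment"].nunique() >= 2:
        counts = merged.groupby("treatment").size()
        usable = counts[counts >= 2].index
        sub = merged[merged["treatment"].isin(usable)]
        if control in set(sub["treatment"]) and sub["treatment"].nunique() >= 2:
            for name in DESCRIPTOR_NAMES:
                col = sub[["treatment", name]].dropna()
                groups = {t: g[name].to_numpy() for t, g in col.groupby("treatment")}
                groups = {t: v for t, v in groups.items() if len(v) >= 2}
                if control not in groups or len(groups) < 2:
                    continue
                res = compare_groups(groups, design=config.statistics.design,
                                     readout=name)
                results.extend(r for r in res if control in (r.group_a, r.group_b))
    results_table(results).to_csv(out / "results.csv", index=False)

    if len(desc_df) >= 3:
        coords, explained = embed(desc_df, method="pca", seed=config.seed)
        coords = coords.merge(layout[["chip", "treatment"]], on="chip")
        coords.to_csv(out / "embedding.csv", index=False)
        log["pca_explained_variance"] = [float(x) for x in explained[:2]]

    if analytes_csv is not None:
        analytes = pd.read_csv(analytes_csv)
        ares = analyte_tests(analytes, layout, control=control)
        results_table(ares).to_csv(out / "analyte_results.csv", index=False)

    config.save(out / "effective_config.yaml")
    log["n_chips_measured"] = len(desc_df)
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return log
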