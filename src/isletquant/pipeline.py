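"""Whole-section quantification pipeline.

Chains the stages in the workflow's order — background subtraction, tissue
mask with the exclusion rule, per-channel binarization, islet segmentation
and morphometry, watershed nucleus segmentation with perinuclear-ring cell
typing, and size/shape analytics — and emits the tabular outputs.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import analytics, celltype, preprocess, segment
from .config import RunConfig, save_config
from .io import BinaryMask, ContourSet, SectionImage, read_contours, read_section
from .preprocess import ThresholdSpec, TissueMask
from .segment import SectionSummary

logger = logging.getLogger("isletquant")

__all__ = ["PipelineResult", "quantify_section", "run_pipeline"]


@dataclass
class PipelineResult:
    summary: SectionSummary
    tissue: TissueMask
    islet_labels: object                    # np.ndarray
    nucleus_labels: object                  # np.ndarray
    hormone_masks: dict[str, BinaryMask]
    endocrine_mask: BinaryMask
    nuclei: list[celltype.NucleusRecord]
    thresholds: dict[str, ThresholdSpec]
    size_histogram: analytics.SizeHistogram | None = None
    shape_points: list[analytics.ShapePoint] = field(default_factory=list)


def quantify_section(
    section: SectionImage,
    contours: ContourSet,
    cfg: RunConfig | None = None,
) -> PipelineResult:
    """Run the full quantification on an in-memory section."""
    cfg = cfg or RunConfig(pixel_size=section.pixel_size)
    px = section.pixel_size

    channels = dict(section.channels)
    if cfg.background_subtraction:
        logger.info("rolling-ball background subtraction, radius %d px",
                    cfg.rolling_ball_radius_px)
        channels = {role: preprocess.subtract_background(ch, cfg.rolling_ball_radius_px)
                    for role, ch in channels.items()}

    tissue = preprocess.build_tissue_mask(section, contours,
                                          cfg.exclusion_min_fraction)
    logger.info("tissue mask: %.0f µm² pancreas, %d exclusions applied",
                tissue.pancreas_area, len(tissue.applied_exclusions))

    thresholds: dict[str, ThresholdSpec] = {}
    for role, ch in channels.items():
        if role in cfg.thresholds:
            thresholds[role] = ThresholdSpec(float(cfg.thresholds[role]), "manual")
        else:
            thresholds[role] = preprocess.auto_threshold(ch)

    hormone_masks = {
        role: preprocess.binarize(channels[role], thresholds[role], tissue, label=role)
        for role in section.hormone_roles
    }
    nuclei_mask = preprocess.binarize(channels["nuclei"], thresholds["nuclei"],
                                      tissue, label="nuclei")

    endocrine = segment.composite_endocrine_mask(list(hormone_masks.values()))
    islet_labels, records = segment.segment_islets(
        endocrine, px, cfg.close_radius_um, cfg.min_islet_area_um2)
    segment.complete_metrics(islet_labels, records, px)
    logger.info("segmented %d islet structures", len(records))

    nucleus_labels = celltype.segment_nuclei(
        nuclei_mask, px, cfg.expected_nucleus_diameter_um)
    priority = cfg.hormone_priority or list(hormone_masks)
    nuclei = celltype.classify_all(nucleus_labels, hormone_masks, px,
                                   cfg.ring_width_px, priority)
    celltype.assign_to_islets(nuclei, islet_labels, px, records)
    logger.info("classified %d nuclei", len(nuclei))

    hormone_areas = {role: m.count() * px**2 for role, m in hormone_masks.items()}
    summary = segment.summarize_section(tissue.pancreas_area, hormone_areas, records)

    hist = None
    points: list[analytics.ShapePoint] = []
    if records:
        hist = analytics.log_size_histogram(
            records, cfg.bin_width_log10, cfg.single_cell_area_um2)
        points = analytics.shape_scatter(records,
                                         single_cell_area=cfg.single_cell_area_um2)
        if cfg.pp_channel in hormone_masks:
            analytics.flag_pp_islets(records, cfg.min_pp_cells, cfg.pp_channel)

    return PipelineResult(
        summary=summary,
        tissue=tissue,
        islet_labels=islet_labels,
        nucleus_labels=nucleus_labels,
        hormone_masks=hormone_masks,
        endocrine_mask=endocrine,
        nuclei=nuclei,
        thresholds=thresholds,
        size_histogram=hist,
        shape_points=points,
    )


def _histogram_table(hist: analytics.SizeHistogram) -> pd.DataFrame:
    df = pd.DataFrame({
        "bin_lo_log10ce": hist.bin_edges[:-1],
        "bin_hi_log10ce": hist.bin_edges[1:],
        "n_islets": hist.counts,
        "summed_area_um2": hist.bin_area,
        "area_fraction": hist.area_fraction,
    })
    for t in hist.comp_mean.columns:
        df[f"frac_{t}_mean"] = hist.comp_mean[t].values
        df[f"frac_{t}_sem"] = hist.comp_sem[t].values
    return df


def run_pipeline(cfg: RunConfig) -> SectionSummary:
    """File-to-file pipeline: read inputs, quantify, write all tables."""
    cfg.validate()
    if not cfg.channel_map:
        raise ValueError("config must provide a channel_map")
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        level=logging.INFO,
        format="%(asctime)s %(levelname)s %(message)s",
        handlers=[logging.FileHandler(out / "run.log"), logging.StreamHandler()],
        force=True,
    )
    logger.info("run started %s", datetime.datetime.now().isoformat())
    save_config(cfg, out / "effective_config.yaml")

    section = read_section(cfg.image_path or None, cfg.channel_map, cfg.pixel_size)
    contours = read_contours(cfg.contours_path)
    result = quantify_section(section, contours, cfg)

    segment.islet_table(result.summary.records).to_csv(out / "islets.csv", index=False)
    celltype.nucleus_table(result.nuclei).to_csv(out / "nuclei.csv", index=False)
    preprocess.save_thresholds(result.thresholds, out / "thresholds.txt")

    s = result.summary
    summary_rows = [
        ("pancreas_area_um2", s.pancreas_area),
        ("total_endocrine_area_um2", s.total_endocrine_area),
        ("total_islet_area_um2", s.total_islet_area),
        ("percent_endocrine_area", s.percent_endocrine_area),
        ("islet_count", s.islet_count),
    ] + [(f"{h}_area_um2", a) for h, a in s.hormone_areas.items()]
    pd.DataFrame(summary_rows, columns=["quantity", "value"]).to_csv(
        out / "summary.csv", index=False)

    if result.size_histogram is not None:
        _histogram_table(result.size_histogram).to_csv(
            out / "size_histogram.csv", index=False)
    if result.shape_points:
        pd.DataFrame([vars(p) for p in result.shape_points]).to_csv(
            out / "shape_scatter.csv", index=False)
    logger.info("run finished; outputs in %s", out)
    return result.summary
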