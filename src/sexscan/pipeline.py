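"""Stage composition: filter -> GWAS -> classify -> segment."""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .depth_linkage import (
    OutlierThresholds,
    classify_snps,
    depth_ratio,
    iqr_thresholds,
    window_depth_summary,
)
from .io_formats import GenomeLayout, SexMap, SnpTable
from .par_segmentation import SegmentationResult, segment_focal_scaffold
from .sex_association import heterozygosity_by_sex, sex_gwas
from .variant_filtering import FilterConfig, FilterReport, apply_filters

logger = logging.getLogger(__name__)


def compute_site_stats(
    table: SnpTable, sexes: SexMap, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-site statistics table: Fisher p, heterozygosities, depth ratio."""
    stats = sex_gwas(table, sexes, alpha=alpha)
    het = heterozygosity_by_sex(table, sexes)
    stats[["H_m", "H_f", "delta_H"]] = het[["H_m", "H_f", "delta_H"]]
    stats["depth_ratio_r"] = depth_ratio(table, sexes)
    return stats


@dataclass
class PipelineResult:
    stats: pd.DataFrame  # classified per-site statistics
    filter_report: FilterReport
    thresholds: OutlierThresholds
    segmentation: SegmentationResult | None
    depth_windows: pd.DataFrame


def run_pipeline(
    table: SnpTable,
    sexes: SexMap,
    layout: GenomeLayout,
    filter_config: FilterConfig | None = None,
    alpha: float = 0.05,
    tau: float | None = None,
    gap_tolerance: int = 2,
    tally_window: int = 1_000_000,
    depth_window: int = 2_000_000,
    depth_step: int = 500_000,
    focal_scaffold: str | None = None,
) -> PipelineResult:
    """Full analysis on one genotype panel.

    Segmentation is skipped (result None, with a warning) when no sex-linked
    SNPs exist — e.g. on an all-autosomal panel.
    """
    filtered, report = apply_filters(table, filter_config)
    logger.info(
        "filters: %d -> %d sites (%d genotypes masked, %d dropped for "
        "missingness, %d for MAF)",
        report.n_input_sites,
        report.n_output_sites,
        report.genotypes_masked_low_depth,
        report.sites_dropped_missingness,
        report.sites_dropped_maf,
    )
    stats = compute_site_stats(filtered, sexes, alpha=alpha)
    thresholds = iqr_thresholds(stats["depth_ratio_r"])
    logger.info(
        "depth-ratio IQR thresholds: low %.4f, high %.4f",
        thresholds.low,
        thresholds.high,
    )
    stats = classify_snps(stats, thresholds)
    windows = window_depth_summary(stats, layout, depth_window, depth_step)
    try:
        seg = segment_focal_scaffold(
            stats,
            layout,
            focal=focal_scaffold,
            tau=tau,
            window=tally_window,
            gap_tolerance=gap_tolerance,
        )
    except ValueError as exc:
        logger.warning("segmentation skipped: %s", exc)
        seg = None
    return PipelineResult(
        stats=stats,
        filter_report=report,
        thresholds=thresholds,
        segmentation=seg,
        depth_windows=windows,
    )
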