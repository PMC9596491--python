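"""PAR/HRX boundary recovery from windowed sex-linked SNP tallies.

Sex-linked (X- or Y-linked) SNPs cluster inside the hemizygous region of the
X; the flanking pseudoautosomal regions behave autosomally. Tallying the
percent of sex-linked SNPs in non-overlapping 1 Mb windows along the focal
scaffold and taking the maximal run of windows above a threshold tau
recovers the HRX span; PAR1 and PAR2 are the flanks.

tau is data driven by default: the maximum window percent observed on any
non-focal scaffold (an empirical null for misclassification noise) plus one
percentage point, with a floor of 5%. Runs may bridge up to ``gap_tolerance``
consecutive sub-threshold or SNP-free windows, so an HRX window that is
locally sparse does not split the region.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .depth_linkage import SEX_LINKED_CLASSES, CLASS_UNCLASSIFIED, make_windows
from .io_formats import GenomeLayout

logger = logging.getLogger(__name__)


@dataclass
class SegmentationResult:
    scaffold: str
    par1: tuple[int, int] | None  # 1-based inclusive bp spans
    hrx: tuple[int, int] | None
    par2: tuple[int, int] | None
    tau: float
    windows: pd.DataFrame

    def spans(self) -> dict[str, tuple[int, int]]:
        out = {}
        for name, span in (("PAR1", self.par1), ("HRX", self.hrx), ("PAR2", self.par2)):
            if span is not None:
                out[name] = span
        return out


def tally_sex_linked(
    stats: pd.DataFrame,
    scaffold: str,
    scaffold_length: int,
    window: int = 1_000_000,
) -> pd.DataFrame:
    """Percent of sex-linked SNPs per non-overlapping window on a scaffold.

    percent = 100 * (#X-linked + #Y-linked) / (#classified SNPs in window);
    windows without classified SNPs are flagged uninformative (percent NaN).
    """
    sub = stats[stats["scaffold"] == scaffold]
    pos = sub["pos"].to_numpy()
    cls = sub["linkage_class"].to_numpy(dtype=object)
    classified = cls != CLASS_UNCLASSIFIED
    sex_linked = np.isin(cls, SEX_LINKED_CLASSES)
    rows = []
    for start, end in make_windows(scaffold_length, window, window):
        in_win = (pos >= start) & (pos <= end)
        n_classified = int((in_win & classified).sum())
        n_sex = int((in_win & sex_linked).sum())
        rows.append(
            {
                "scaffold": scaffold,
                "start": start,
                "end": end,
                "n_classified": n_classified,
                "n_sex_linked": n_sex,
                "percent_sex_linked": 100.0 * n_sex / n_classified
                if n_classified
                else np.nan,
                "informative": n_classified > 0,
            }
        )
    return pd.DataFrame(rows)


def choose_focal_scaffold(stats: pd.DataFrame) -> str:
    """Scaffold carrying the highest share of all sex-linked SNPs."""
    sex = stats[stats["linkage_class"].isin(SEX_LINKED_CLASSES)]
    if len(sex) == 0:
        raise ValueError("no sex-linked SNPs; cannot choose a focal scaffold")
    return sex["scaffold"].value_counts().idxmax()


def default_tau(
    stats: pd.DataFrame,
    layout: GenomeLayout,
    focal: str,
    window: int = 1_000_000,
    floor: float = 5.0,
) -> float:
    """Data-driven threshold: max non-focal window percent + 1, floored."""
    best = 0.0
    for scaffold, length in layout.scaffolds:
        if scaffold == focal:
            continue
        tally = tally_sex_linked(stats, scaffold, length, window)
        pct = tally["percent_sex_linked"].dropna()
        if len(pct):
            best = max(best, float(pct.max()))
    return max(floor, best + 1.0)


def segment_regions(
    tally: pd.DataFrame,
    tau: float,
    scaffold_length: int | None = None,
    gap_tolerance: int = 2,
) -> SegmentationResult:
    """Segment a windowed tally into PAR1 / HRX / PAR2 spans.

    The HRX is the maximal-length run of windows with percent > tau; runs may
    bridge up to ``gap_tolerance`` consecutive sub-threshold or uninformative
    windows. When no window exceeds tau, no HRX is reported (with a warning)
    and both PAR spans are absent.
    """
    if len(tally) == 0 or not tally["informative"].any():
        raise ValueError("need at least one informative window")
    scaffold = tally["scaffold"].iloc[0]
    if scaffold_length is None:
        scaffold_length = int(tally["end"].iloc[-1])
    pct = tally["percent_sex_linked"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        above = np.where(np.isnan(pct), False, pct > tau)

    if not above.any():
        logger.warning(
            "segment_regions: no window exceeds tau=%.2f on %s; no HRX reported",
            tau,
            scaffold,
        )
        return SegmentationResult(scaffold, None, None, None, tau, tally)

    idx = np.flatnonzero(above)
    # group above-threshold windows, bridging gaps of <= gap_tolerance windows
    runs: list[tuple[int, int]] = []
    run_start = prev = idx[0]
    for i in idx[1:]:
        if i - prev - 1 <= gap_tolerance:
            prev = i
        else:
            runs.append((run_start, prev))
            run_start = prev = i
    runs.append((run_start, prev))
    first, last = max(runs, key=lambda r: r[1] - r[0])

    hrx = (int(tally["start"].iloc[first]), int(tally["end"].iloc[last]))
    par1 = (1, hrx[0] - 1) if hrx[0] > 1 else None
    par2 = (hrx[1] + 1, scaffold_length) if hrx[1] < scaffold_length else None
    return SegmentationResult(scaffold, par1, hrx, par2, tau, tally)


def segment_focal_scaffold(
    stats: pd.DataFrame,
    layout: GenomeLayout,
    focal: str | None = None,
    tau: float | None = None,
    window: int = 1_000_000,
    gap_tolerance: int = 2,
) -> SegmentationResult:
    """End-to-end segmentation: pick the focal scaffold, derive tau, segment."""
    if focal is None:
        focal = choose_focal_scaffold(stats)
    if tau is None:
        tau = default_tau(stats, layout, focal, window)
    length = layout.scaffold_length(focal)
    tally = tally_sex_linked(stats, focal, length, window)
    logger.info("segmenting %s with tau=%.2f%%, gap tolerance %d", focal, tau,
                gap_tolerance)
    return segment_regions(tally, tau, scaffold_length=length,
                           gap_tolerance=gap_tolerance)
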