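"""Male/female depth ratios, IQR outlier thresholds, sliding-window depth
summaries, and X-/Y-linked SNP classification.

The per-site statistic is r = mean male depth / mean female depth. Autosomes
are expected near r = 1; the hemizygous region of the X near r = 0.5 because
males carry a single copy. Outliers of the genome-wide r distribution are
called with the Tukey rule (quartiles +/- 1.5 IQR, type-7 quantiles).

Classification (precedence top to bottom):

* duplicated-candidate — significant sex GWAS hit with a *high* depth-ratio
  outlier: the autosome/Y duplication signature (male coverage excess);
* Y-linked — any remaining significant sex GWAS hit;
* X-linked — low depth-ratio outlier with male heterozygosity equal to or
  lower than female heterozygosity (delta_H <= 0);
* autosomal — everything else; sites with undefined statistics are
  'unclassified'.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenomeLayout, SexMap, SnpTable

CLASS_AUTOSOMAL = "autosomal"
CLASS_X = "X-linked"
CLASS_Y = "Y-linked"
CLASS_DUP = "duplicated-candidate"
CLASS_UNCLASSIFIED = "unclassified"
SEX_LINKED_CLASSES = (CLASS_X, CLASS_Y)


def depth_ratio(table: SnpTable, sexes: SexMap) -> np.ndarray:
    """Per-site mean male depth / mean female depth.

    All samples of each sex contribute, including zero-depth ones —
    hemizygosity manifests as reduced depth, not as missingness. NaN where
    the female mean is zero.
    """
    male = sexes.male_mask(table.samples)
    mean_m = table.depths[:, male].mean(axis=1)
    mean_f = table.depths[:, ~male].mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(mean_f > 0, mean_m / np.where(mean_f > 0, mean_f, 1), np.nan)


@dataclass(frozen=True)
class OutlierThresholds:
    q1: float
    q3: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def low(self) -> float:
        return self.q1 - 1.5 * self.iqr

    @property
    def high(self) -> float:
        return self.q3 + 1.5 * self.iqr


def iqr_thresholds(values) -> OutlierThresholds:
    """Tukey outlier thresholds from the finite values of a statistic.

    Quartiles use linear interpolation between order statistics (the type-7
    convention, numpy's default).
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 4:
        raise ValueError(f"need >= 4 finite values, got {v.size}")
    q1, q3 = np.quantile(v, [0.25, 0.75])  # type-7 linear interpolation
    return OutlierThresholds(q1=float(q1), q3=float(q3))


def classify_snps(
    stats: pd.DataFrame, thresholds: OutlierThresholds | None = None
) -> pd.DataFrame:
    """Fill the ``linkage_class`` column of a per-site statistics table.

    ``stats`` must carry ``fisher_p``/``significant``, ``delta_H`` and
    ``depth_ratio_r``. Thresholds default to the IQR rule on the genome-wide
    depth-ratio distribution of ``stats`` itself.
    """
    if thresholds is None:
        thresholds = iqr_thresholds(stats["depth_ratio_r"])
    r = stats["depth_ratio_r"].to_numpy(dtype=float)
    dh = stats["delta_H"].to_numpy(dtype=float)
    sig = stats["significant"].to_numpy(dtype=bool)
    tested = (
        stats["tested"].to_numpy(dtype=bool)
        if "tested" in stats
        else np.ones(len(stats), dtype=bool)
    )

    defined = np.isfinite(r) & np.isfinite(dh) & tested
    cls = np.full(len(stats), CLASS_UNCLASSIFIED, dtype=object)
    with np.errstate(invalid="ignore"):
        is_dup = sig & (r > thresholds.high)
        is_x = (r < thresholds.low) & (dh <= 0)
    cls[defined] = CLASS_AUTOSOMAL
    cls[defined & is_x] = CLASS_X
    cls[defined & sig] = CLASS_Y
    cls[defined & is_dup] = CLASS_DUP

    out = stats.copy()
    out["linkage_class"] = cls
    out.attrs.update(stats.attrs)
    out.attrs["r_low_threshold"] = thresholds.low
    out.attrs["r_high_threshold"] = thresholds.high
    return out


def make_windows(length: int, window: int, step: int) -> list[tuple[int, int]]:
    """1-based inclusive sliding windows covering [1, length]; the terminal
    window may be partial."""
    if step > window:
        raise ValueError("step must not exceed window size")
    out = []
    start = 1
    while start <= length:
        out.append((start, min(start + window - 1, length)))
        if start + window - 1 >= length:
            break
        start += step
    return out


def window_depth_summary(
    stats: pd.DataFrame,
    layout: GenomeLayout,
    window: int = 2_000_000,
    step: int = 500_000,
) -> pd.DataFrame:
    """Sliding-window summary of the (log2) depth ratio and sex-linked share.

    Per window: SNP count, mean log2(r) over sites with defined r (NaN when
    empty), and the percentage of classified SNPs that are sex-linked.
    """
    rows = []
    for scaffold, length in layout.scaffolds:
        sub = stats[stats["scaffold"] == scaffold]
        pos = sub["pos"].to_numpy()
        r = sub["depth_ratio_r"].to_numpy(dtype=float)
        cls = (
            sub["linkage_class"].to_numpy(dtype=object)
            if "linkage_class" in sub
            else np.full(len(sub), CLASS_UNCLASSIFIED, dtype=object)
        )
        for start, end in make_windows(length, window, step):
            in_win = (pos >= start) & (pos <= end)
            r_win = r[in_win]
            r_def = r_win[np.isfinite(r_win) & (r_win > 0)]
            classified = np.isin(cls[in_win], (CLASS_AUTOSOMAL,) + SEX_LINKED_CLASSES + (CLASS_DUP,))
            sex_linked = np.isin(cls[in_win], SEX_LINKED_CLASSES)
            n_classified = int(classified.sum())
            rows.append(
                {
                    "scaffold": scaffold,
                    "start": start,
                    "end": end,
                    "n_snps": int(in_win.sum()),
                    "mean_log2_ratio": float(np.mean(np.log2(r_def)))
                    if r_def.size
                    else np.nan,
                    "pct_sex_linked": 100.0 * sex_linked.sum() / n_classified
                    if n_classified
                    else np.nan,
                }
            )
    return pd.DataFrame(rows)
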