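"""Karyotype-scaffold concordance.

Chromosome nucleotide content is estimated from karyotype image areas: each
chromosome's fraction of the total measured karyotype area (an XX metaphase
complement) times the total assembly size. Concordance with assembled
scaffold sizes is an ordinary least-squares regression of scaffold size on
the estimate; a high r-squared supports chromosome-scale scaffolds paired to
the right karyotype entries.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


def estimate_sizes(areas, assembly_total: float) -> np.ndarray:
    """est_i = (area_i / sum(areas)) * assembly_total.

    Estimates sum exactly to the assembly total.
    """
    areas = np.asarray(areas, dtype=float)
    if (areas <= 0).any():
        raise ValueError("areas must be positive")
    total = areas.sum()
    if total == 0:
        raise ValueError("zero total area")
    return areas / total * float(assembly_total)


@dataclass(frozen=True)
class ConcordanceResult:
    r2: float
    slope: float
    intercept: float
    p_value: float  # F test on the slope (equivalently the slope t test)
    n: int


def concordance(estimates, scaffold_sizes) -> ConcordanceResult:
    """OLS of scaffold size on estimated chromosome size."""
    x = np.asarray(estimates, dtype=float)
    y = np.asarray(scaffold_sizes, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in estimates")
    fit = sps.linregress(x, y)
    return ConcordanceResult(
        r2=float(fit.rvalue**2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p_value=float(fit.pvalue),
        n=int(x.size),
    )


def karyotype_concordance(table: pd.DataFrame, assembly_total: float | None = None):
    """Run the full analysis on a measurement table.

    ``table`` needs columns ``area`` and ``scaffold_bp``; ``assembly_total``
    defaults to the summed scaffold sizes. Returns (estimates, result).
    """
    if assembly_total is None:
        assembly_total = float(table["scaffold_bp"].sum())
    est = estimate_sizes(table["area"].to_numpy(), assembly_total)
    return est, concordance(est, table["scaffold_bp"].to_numpy())
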