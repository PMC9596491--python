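"""Per-SNP sex association: Fisher's exact GWAS and relative male heterozygosity.

Sex is treated as a binary case/control trait. Each site is tested with a
two-sided Fisher's exact test on the allelic 2x2 table

    rows:    male, female
    columns: ref-allele count, alt-allele count

built from non-missing genotypes (a homozygote contributes 2 copies of one
allele, a heterozygote 1 of each). Allelic coding makes male-limited
heterozygosity — the signature of fixed X-Y gametolog differences read
through the X scaffold — detectable as a sex-by-allele association.

Genome-wide significance uses the Bonferroni threshold alpha / M where M is
the number of *tested* markers: sites with a zero margin in the 2x2 table
(e.g. monomorphic) or fewer than 2 non-missing samples in either sex are
untested and excluded from M.
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io_formats import HET, MISSING, SexMap, SnpTable

_TIE_TOL = 1.0 + 1e-7  # tables with pmf <= observed * (1 + 1e-7) count as extreme


def _two_sided_p(a: int, r1: int, c1: int, n: int) -> float:
    """Two-sided Fisher p for entry ``a`` of a 2x2 table with row-1 margin
    ``r1``, column-1 margin ``c1`` and total ``n``: the sum of hypergeometric
    point probabilities not exceeding the observed one (with a small relative
    tie tolerance)."""
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    log_pmf = (
        gammaln(c1 + 1)
        - gammaln(support + 1)
        - gammaln(c1 - support + 1)
        + gammaln(n - c1 + 1)
        - gammaln(r1 - support + 1)
        - gammaln(n - c1 - r1 + support + 1)
        - (gammaln(n + 1) - gammaln(r1 + 1) - gammaln(n - r1 + 1))
    )
    pmf = np.exp(log_pmf)
    p_obs = pmf[a - lo]
    return float(min(1.0, pmf[pmf <= p_obs * _TIE_TOL].sum()))


def fisher_exact_two_sided(table) -> float:
    """Exact two-sided Fisher p-value for a 2x2 table of non-negative counts.

    The all-zero table returns 1.0 by convention.
    """
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n == 0:
        return 1.0
    return _two_sided_p(a, a + b, a + c, n)


def allelic_counts_by_sex(
    table: SnpTable, sexes: SexMap
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (male_ref, male_alt, female_ref, female_alt) allele counts."""
    male = sexes.male_mask(table.samples)
    g = table.genotypes
    non_missing = g != MISSING
    dose = np.where(non_missing, np.maximum(g, 0), 0)  # alt-allele dose 0/1/2

    def counts(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        alt = dose[:, mask].sum(axis=1)
        tot = 2 * non_missing[:, mask].sum(axis=1)
        return tot - alt, alt

    m_ref, m_alt = counts(male)
    f_ref, f_alt = counts(~male)
    return m_ref, m_alt, f_ref, f_alt


def sex_gwas(table: SnpTable, sexes: SexMap, alpha: float = 0.05) -> pd.DataFrame:
    """Fisher exact sex GWAS over all sites of a (filtered) SnpTable.

    Returns a DataFrame aligned with ``table.sites`` carrying ``fisher_p``
    (NaN for untested sites), ``tested``, ``significant`` and the Bonferroni
    threshold actually used (``alpha / M``) as the attribute
    ``df.attrs['bonferroni_threshold']``.
    """
    sexes.validate(table.samples)
    male = sexes.male_mask(table.samples)
    non_missing = table.genotypes != MISSING
    n_male_obs = non_missing[:, male].sum(axis=1)
    n_female_obs = non_missing[:, ~male].sum(axis=1)

    m_ref, m_alt, f_ref, f_alt = allelic_counts_by_sex(table, sexes)
    row_m = m_ref + m_alt
    row_f = f_ref + f_alt
    col_ref = m_ref + f_ref
    col_alt = m_alt + f_alt
    testable = (
        (n_male_obs >= 2)
        & (n_female_obs >= 2)
        & (row_m > 0)
        & (row_f > 0)
        & (col_ref > 0)
        & (col_alt > 0)
    )

    p = np.full(table.n_sites, np.nan)
    for i in np.flatnonzero(testable):
        p[i] = _two_sided_p(
            int(m_ref[i]), int(row_m[i]), int(col_ref[i]), int(row_m[i] + row_f[i])
        )

    m_tested = int(testable.sum())
    threshold = alpha / m_tested if m_tested else np.nan
    significant = np.zeros(table.n_sites, dtype=bool)
    if m_tested:
        with np.errstate(invalid="ignore"):
            significant = np.where(np.isnan(p), False, p < threshold)

    out = pd.DataFrame(
        {
            "scaffold": table.sites["scaffold"].to_numpy(),
            "pos": table.sites["pos"].to_numpy(),
            "fisher_p": p,
            "tested": testable,
            "significant": significant.astype(bool),
        }
    )
    out.attrs["bonferroni_threshold"] = threshold
    out.attrs["n_tested"] = m_tested
    out.attrs["alpha"] = alpha
    return out


def heterozygosity_by_sex(table: SnpTable, sexes: SexMap) -> pd.DataFrame:
    """Per-site heterozygosity within each sex and their difference.

    H_s = (# het genotypes among non-missing samples of sex s) / (# non-missing
    of sex s); NaN when a sex has no non-missing samples. delta_H = H_m - H_f
    (relative male heterozygosity): strongly positive at gametolog sites,
    zero-or-negative at X-linked polymorphisms where males are hemizygous.
    """
    male = sexes.male_mask(table.samples)
    g = table.genotypes
    non_missing = g != MISSING
    het = g == HET

    def h(mask: np.ndarray) -> np.ndarray:
        n_obs = non_missing[:, mask].sum(axis=1).astype(float)
        n_het = het[:, mask].sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_obs > 0, n_het / np.where(n_obs > 0, n_obs, 1), np.nan)

    h_m = h(male)
    h_f = h(~male)
    return pd.DataFrame(
        {
            "scaffold": table.sites["scaffold"].to_numpy(),
            "pos": table.sites["pos"].to_numpy(),
            "H_m": h_m,
            "H_f": h_f,
            "delta_H": h_m - h_f,
        }
    )
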