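"""Genotype- and site-level quality filters.

Three stages, applied in order:

1. genotype depth — calls supported by fewer than ``min_genotype_depth`` reads
   are set to missing;
2. site completeness — sites with data in less than ``1 - max_missingness`` of
   samples are dropped;
3. minor allele frequency — sites whose MAF (allele scale, from non-missing
   genotypes: hom contributes 2 alleles, het 1 of each) is not strictly above
   ``min_maf`` are dropped.

"At least 70% of samples" is read as non-missing fraction >= 0.70 (ties pass);
"larger than 5%" is strict. MAF is computed from observed genotypes, never
imputed.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import HET, HOM_ALT, HOM_REF, MISSING, SnpTable


@dataclass
class FilterConfig:
    min_genotype_depth: int = 4
    max_site_missingness: float = 0.30
    min_maf: float = 0.05

    def validate(self) -> None:
        if not 0 <= self.max_site_missingness <= 1:
            raise ValueError("max_site_missingness must be in [0, 1]")
        if not 0 <= self.min_maf <= 1:
            raise ValueError("min_maf must be in [0, 1]")
        if self.min_genotype_depth < 0:
            raise ValueError("min_genotype_depth must be >= 0")


@dataclass
class FilterReport:
    """Per-stage accounting of what the filters removed."""

    n_input_sites: int
    genotypes_masked_low_depth: int
    sites_dropped_missingness: int
    sites_dropped_maf: int
    n_output_sites: int


def site_maf(genotypes: np.ndarray) -> np.ndarray:
    """Minor allele frequency per site from a coded genotype matrix.

    Computed on the allele scale over non-missing genotypes only; sites with
    no data get NaN.
    """
    non_missing = genotypes != MISSING
    alt = np.where(non_missing, np.maximum(genotypes, 0), 0).sum(axis=1).astype(float)
    total = 2.0 * non_missing.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(total > 0, alt / np.where(total > 0, total, 1), np.nan)
    return np.minimum(p, 1.0 - p)


def apply_filters(
    table: SnpTable, config: FilterConfig | None = None
) -> tuple[SnpTable, FilterReport]:
    """Apply the three filter stages; returns the filtered table and counts."""
    if config is None:
        config = FilterConfig()
    config.validate()
    if table.n_sites == 0:
        raise ValueError("empty SnpTable")

    genotypes = table.genotypes.copy()
    low_depth = (table.depths < config.min_genotype_depth) & (genotypes != MISSING)
    genotypes[low_depth] = MISSING
    masked = table.subset(np.ones(table.n_sites, dtype=bool))
    masked.genotypes = genotypes

    non_missing_frac = (genotypes != MISSING).mean(axis=1)
    keep_complete = non_missing_frac >= (1.0 - config.max_site_missingness)
    n_drop_missing = int((~keep_complete).sum())

    maf = site_maf(genotypes)
    with np.errstate(invalid="ignore"):
        keep_maf = maf > config.min_maf  # NaN compares False -> dropped
    n_drop_maf = int((keep_complete & ~keep_maf).sum())

    keep = keep_complete & keep_maf
    out = masked.subset(keep)
    report = FilterReport(
        n_input_sites=table.n_sites,
        genotypes_masked_low_depth=int(low_depth.sum()),
        sites_dropped_missingness=n_drop_missing,
        sites_dropped_maf=n_drop_maf,
        n_output_sites=out.n_sites,
    )
    return out, report
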