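"""Synthetic XY-population, repeat-alignment and karyotype generators.

The population generator emulates the data a diploid variant caller produces
from a male-heterogametic species: females are XX and diploid everywhere;
males are XY, so on the hemizygous core of the X (HRX) they carry one X copy.
Three consequences drive the downstream analysis and are reproduced here:

* depth: per-sample read depth is Poisson with mean proportional to copy
  number, so male HRX depth is half female depth;
* male-limited heterozygosity: at fixed X-Y differences (gametologs), reads
  from the diverged Y copy map onto the X scaffold and the caller emits a
  heterozygous male genotype while every female is hom-ref;
* X-restricted polymorphism: HRX sites polymorphic on the X give hemizygous
  males a single allele that diploid-assuming callers report as homozygous.

Ground-truth per-site labels are returned so recovery can be scored exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    FEMALE,
    HET,
    HOM_ALT,
    HOM_REF,
    MALE,
    MISSING,
    GenomeLayout,
    Region,
    SexMap,
    SnpTable,
)

# per-site truth labels emitted by simulate_population
TRUTH_AUTOSOMAL = "autosomal"
TRUTH_PAR = "PAR"
TRUTH_X_POLY = "x_poly"  # HRX, polymorphic on X only
TRUTH_GAMETOLOG = "gametolog"  # HRX, fixed X-Y difference
TRUTH_HEMI_FIXED = "hemizygous_fixed"  # HRX, monomorphic filler

_BASES = np.array(list("ACGT"))


def default_layout() -> GenomeLayout:
    """Desk-scale genome: three autosomal scaffolds plus an X scaffold whose
    111 Mb are split 21 Mb PAR1 / 71 Mb HRX / 19 Mb PAR2."""
    return GenomeLayout(
        scaffolds=[
            ("scaffold_1", 150_000_000),
            ("scaffold_2", 130_000_000),
            ("scaffold_3", 120_000_000),
            ("scaffold_7", 111_000_000),
        ],
        regions=[
            Region("scaffold_7", 1, 21_000_000, "PAR1"),
            Region("scaffold_7", 21_000_001, 92_000_000, "HRX"),
            Region("scaffold_7", 92_000_001, 111_000_000, "PAR2"),
        ],
    )


@dataclass
class SimConfig:
    """Parameters of the population simulation.

    ``depth_per_copy`` is the Poisson mean per chromosome copy, so a diploid
    sample has mean depth ``2 * depth_per_copy``. ``gametolog_fraction`` and
    ``x_poly_fraction`` partition HRX sites (any remainder is monomorphic
    hemizygous filler). ``y_mapping_rate`` is the probability that Y-derived
    reads map onto the X scaffold at a gametolog site, producing both the
    heterozygous male call and the extra depth copy.
    """

    seed: int = 1
    n_males: int = 25
    n_females: int = 25
    layout: GenomeLayout = field(default_factory=default_layout)
    snp_spacing: float = 25_000.0  # mean bp between SNPs (exponential)
    maf_range: tuple[float, float] = (0.05, 0.5)
    depth_per_copy: float = 10.0
    gametolog_fraction: float = 0.1
    x_poly_fraction: float = 0.9
    y_mapping_rate: float = 1.0
    dropout_rate: float = 0.01
    depth_overdispersion: float = 0.0  # >0 switches to gamma-Poisson mixing

    def validate(self) -> None:
        if self.gametolog_fraction + self.x_poly_fraction > 1 + 1e-12:
            raise ValueError("gametolog + x_poly fractions must be <= 1")
        if self.depth_per_copy <= 0:
            raise ValueError("depth_per_copy must be > 0")
        if not 0 <= self.y_mapping_rate <= 1:
            raise ValueError("y_mapping_rate must be in [0, 1]")
        if not 0 <= self.dropout_rate <= 1:
            raise ValueError("dropout_rate must be in [0, 1]")
        if self.n_males < 2 or self.n_females < 2:
            raise ValueError("need at least 2 samples per sex")
        self.layout.validate()
        if self.gametolog_fraction > 0 and self.layout.sex_scaffold() is None:
            raise ValueError(
                "layout has no HRX region but gametolog_fraction > 0"
            )


@dataclass
class SimulatedPopulation:
    """Simulation output: data as the pipeline sees it, plus ground truth."""

    table: SnpTable
    sex_map: SexMap
    layout: GenomeLayout
    site_truth: np.ndarray  # per-site truth label, aligned with table.sites

    def truth_mask(self, *labels: str) -> np.ndarray:
        return np.isin(self.site_truth, labels)


def _positions(rng: np.random.Generator, length: int, mean_spacing: float) -> np.ndarray:
    """Strictly increasing 1-based positions with ~exponential spacing."""
    n_expected = int(length / mean_spacing * 1.5) + 10
    gaps = np.maximum(1, np.ceil(rng.exponential(mean_spacing, n_expected))).astype(
        np.int64
    )
    pos = np.cumsum(gaps)
    pos = pos[pos <= length]
    while len(pos) and pos[-1] < length - 10 * mean_spacing:  # pragma: no cover
        extra = np.maximum(
            1, np.ceil(rng.exponential(mean_spacing, n_expected))
        ).astype(np.int64)
        pos = np.concatenate([pos, pos[-1] + np.cumsum(extra)])
        pos = pos[pos <= length]
    return pos


def simulate_population(config: SimConfig) -> SimulatedPopulation:
    """Simulate genotypes and depths for an XY population.

    Autosomal and PAR sites are Hardy-Weinberg diploid in both sexes. HRX
    sites follow the hemizygosity model documented at module level. Depth is
    ``Poisson(copy_number * depth_per_copy)`` per sample per site; genotypes
    are then masked at ``dropout_rate``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_m, n_f = config.n_males, config.n_females
    n = n_m + n_f
    samples = [f"m{i + 1}" for i in range(n_m)] + [f"f{i + 1}" for i in range(n_f)]
    male = np.zeros(n, dtype=bool)
    male[:n_m] = True

    scaffold_col, pos_col, truth = [], [], []
    for scaffold, length in config.layout.scaffolds:
        pos = _positions(rng, length, config.snp_spacing)
        scaffold_col.extend([scaffold] * len(pos))
        pos_col.extend(pos.tolist())
        labels = np.array(
            [config.layout.region_label(scaffold, int(p)) for p in pos], dtype=object
        )
        site_labels = np.where(
            labels == "autosomal",
            TRUTH_AUTOSOMAL,
            np.where(labels == "HRX", "HRX", TRUTH_PAR),
        )
        # partition HRX sites into gametolog / x-poly / monomorphic filler
        hrx = site_labels == "HRX"
        if hrx.any():
            u = rng.random(hrx.sum())
            gf, xf = config.gametolog_fraction, config.x_poly_fraction
            hrx_kind = np.where(
                u < gf, TRUTH_GAMETOLOG, np.where(u < gf + xf, TRUTH_X_POLY, TRUTH_HEMI_FIXED)
            )
            site_labels = site_labels.astype(object)
            site_labels[hrx] = hrx_kind
        truth.extend(site_labels.tolist())

    n_sites = len(pos_col)
    truth = np.array(truth, dtype=object)

    ref_idx = rng.integers(0, 4, n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, n_sites)) % 4
    sites = pd.DataFrame(
        {
            "scaffold": scaffold_col,
            "pos": np.array(pos_col, dtype=np.int64),
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
        }
    )

    lo, hi = config.maf_range
    p_alt = rng.uniform(lo, hi, n_sites)

    genotypes = np.full((n_sites, n), HOM_REF, dtype=np.int8)
    copy_number = np.full((n_sites, n), 2, dtype=np.int8)

    diploid_like = np.isin(truth, (TRUTH_AUTOSOMAL, TRUTH_PAR))
    if diploid_like.any():
        idx = np.flatnonzero(diploid_like)
        genotypes[idx] = rng.binomial(
            2, p_alt[idx][:, None], (len(idx), n)
        ).astype(np.int8)

    x_poly = truth == TRUTH_X_POLY
    if x_poly.any():
        idx = np.flatnonzero(x_poly)
        g = np.empty((len(idx), n), dtype=np.int8)
        # females: HW diploid; males: one X allele, called homozygous for it
        g[:, ~male] = rng.binomial(2, p_alt[idx][:, None], (len(idx), (~male).sum()))
        g[:, male] = 2 * rng.binomial(1, p_alt[idx][:, None], (len(idx), male.sum()))
        genotypes[idx] = g
        copy_number[np.ix_(idx, np.flatnonzero(male))] = 1

    gam = truth == TRUTH_GAMETOLOG
    if gam.any():
        idx = np.flatnonzero(gam)
        # females hom-ref diploid; males het iff the Y read maps (prob rho)
        y_maps = rng.random((len(idx), male.sum())) < config.y_mapping_rate
        g = np.zeros((len(idx), n), dtype=np.int8)
        g[:, male] = np.where(y_maps, HET, HOM_REF)
        genotypes[idx] = g
        copy_number[np.ix_(idx, np.flatnonzero(male))] = (1 + y_maps).astype(np.int8)

    hemi = truth == TRUTH_HEMI_FIXED
    if hemi.any():
        idx = np.flatnonzero(hemi)
        copy_number[np.ix_(idx, np.flatnonzero(male))] = 1

    mean_depth = copy_number.astype(float) * config.depth_per_copy
    if config.depth_overdispersion > 0:
        od = config.depth_overdispersion
        mean_depth = mean_depth * rng.gamma(1.0 / od, od, mean_depth.shape)
    depths = rng.poisson(mean_depth).astype(np.int32)

    dropped = rng.random((n_sites, n)) < config.dropout_rate
    genotypes[dropped] = MISSING

    table = SnpTable(sites=sites, genotypes=genotypes, depths=depths, samples=samples)
    sex_map = SexMap(
        {s: (MALE if is_m else FEMALE) for s, is_m in zip(samples, male)}
    )
    return SimulatedPopulation(table=table, sex_map=sex_map, layout=config.layout,
                               site_truth=truth)


# ---------------------------------------------------------------------------
# Repeat insert-vs-consensus alignment fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepeatAlignmentRecord:
    """One insert-vs-consensus pairwise alignment (equal-length, gapped)."""

    family: str
    repeat_class: str  # SINE / LINE / LTR / DNA / Unclassified
    consensus: str
    insert: str
    genome: str = "genomeA"
    true_divergence: float | None = None

    def __post_init__(self) -> None:
        if len(self.consensus) != len(self.insert):
            raise ValueError("aligned sequences must have equal length")


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def _k2p_of_rates(p: float, q: float) -> float:
    return -0.5 * np.log((1 - 2 * p - q) * np.sqrt(1 - 2 * q))


def _rates_for_divergence(k: float, ts_tv_ratio: float = 2.0) -> tuple[float, float]:
    """Per-site transition/transversion probabilities (p, q) with p = R*q
    whose K2P closed form equals ``k``."""
    if k == 0:
        return 0.0, 0.0
    from scipy.optimize import brentq

    def f(q: float) -> float:
        return _k2p_of_rates(ts_tv_ratio * q, q) - k

    q_hi = 0.999 / (2 * ts_tv_ratio + 1)  # keep 1 - 2p - q positive
    q = brentq(f, 1e-12, q_hi, xtol=1e-14)
    return ts_tv_ratio * q, q


def simulate_repeat_alignments(
    seed: int,
    n_per_class: int = 5,
    true_divergence: dict[str, float] | float = 0.10,
    cpg_density: float = 0.0,
    length: int = 2000,
    genome: str = "genomeA",
    classes: Sequence[str] = ("SINE", "LINE", "LTR", "DNA"),
    ts_tv_ratio: float = 2.0,
    cpg_transition_multiplier: float = 10.0,
) -> list[RepeatAlignmentRecord]:
    """Generate insert-vs-consensus alignments with known K2P divergence.

    Substitutions are applied per aligned site at probabilities (p, q) solved
    so that the K2P closed form of the expected mismatch proportions equals
    the requested divergence, with transitions ``ts_tv_ratio`` times as likely
    as transversions. When ``cpg_density`` > 0, CpG dinucleotides are planted
    in the consensus at that per-position rate and transitions there occur at
    ``cpg_transition_multiplier`` times the background rate — the hypermutable
    behaviour the 1/10 CpG weighting of the estimator is designed to undo.
    """
    rng = np.random.default_rng(seed)
    if not isinstance(true_divergence, dict):
        true_divergence = {c: float(true_divergence) for c in classes}
    records: list[RepeatAlignmentRecord] = []
    for cls in classes:
        k = true_divergence[cls]
        if not 0 <= k <= 0.45:
            raise ValueError(f"divergence {k} outside [0, 0.45]")
        p, q = _rates_for_divergence(k, ts_tv_ratio)
        for i in range(n_per_class):
            cons = rng.choice(list("ACGT"), length)
            if cpg_density == 0:
                # CpG-free consensus so the estimator's CpG correction is an
                # exact no-op under this setting
                for j in range(length - 1):
                    if cons[j] == "C" and cons[j + 1] == "G":
                        cons[j + 1] = "A"
            if cpg_density > 0:
                # plant non-overlapping CpG dinucleotides at the requested rate
                last = -2
                for s in np.flatnonzero(rng.random(length - 1) < cpg_density):
                    if s > last + 1:
                        cons[s], cons[s + 1] = "C", "G"
                        last = s
            cons_str = "".join(cons)
            is_cpg = np.zeros(length, dtype=bool)
            for j in range(length - 1):
                if cons_str[j] == "C" and cons_str[j + 1] == "G":
                    is_cpg[j] = is_cpg[j + 1] = True
            p_site = np.where(is_cpg, min(cpg_transition_multiplier * p, 0.95 - q), p)
            u = rng.random(length)
            insert = cons.copy()
            ts = u < p_site
            tv = (u >= p_site) & (u < p_site + q)
            for j in np.flatnonzero(ts):
                insert[j] = _TRANSITION[cons[j]]
            pick = rng.integers(0, 2, length)
            for j in np.flatnonzero(tv):
                insert[j] = _TRANSVERSIONS[cons[j]][pick[j]]
            records.append(
                RepeatAlignmentRecord(
                    family=f"{cls}-fam{i + 1}",
                    repeat_class=cls,
                    consensus=cons_str,
                    insert="".join(insert),
                    genome=genome,
                    true_divergence=k,
                )
            )
    return records


def write_repeat_alignments_tsv(
    records: Sequence[RepeatAlignmentRecord], path
) -> None:
    """Write records in the project's tabular alignment format (TSV with
    columns genome, family, class, consensus, insert)."""
    with open(path, "w") as fh:
        fh.write("genome\tfamily\tclass\tconsensus\tinsert\n")
        for r in records:
            fh.write(
                f"{r.genome}\t{r.family}\t{r.repeat_class}\t{r.consensus}\t{r.insert}\n"
            )


def read_repeat_alignments_tsv(path) -> list[RepeatAlignmentRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        RepeatAlignmentRecord(
            family=row["family"],
            repeat_class=row["class"],
            consensus=row["consensus"],
            insert=row["insert"],
            genome=row["genome"],
        )
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# Karyotype fixture
# ---------------------------------------------------------------------------

def simulate_karyotype_table(
    seed: int,
    scaffold_sizes: Sequence[int] | None = None,
    measurement_cv: float = 0.03,
) -> pd.DataFrame:
    """Synthetic karyotype measurement table (labelled synthetic; stands in
    for image-based chromosome area measurements).

    Areas emulate a female (XX) metaphase complement: every chromosome is
    measured as the summed area of its two homologs — the X contributes two X
    areas rather than X + Y — with lognormal measurement noise, so expected
    areas stay proportional to haploid chromosome sizes. Returns a DataFrame
    with columns ``chromosome``, ``area``, ``scaffold``, ``scaffold_bp``.
    """
    rng = np.random.default_rng(seed)
    if scaffold_sizes is None:
        # 14-chromosome complement: macro-, X-sized, and micro-chromosomes
        scaffold_sizes = [
            320, 280, 250, 210, 160, 140, 111, 30, 25, 22, 20, 18, 15, 12
        ]
        scaffold_sizes = [s * 1_000_000 for s in scaffold_sizes]
    sizes = np.asarray(scaffold_sizes, dtype=float)
    noise = rng.lognormal(0.0, measurement_cv, len(sizes))
    areas = 2.0 * sizes * noise  # two homologs per chromosome in the spread
    return pd.DataFrame(
        {
            "chromosome": [f"chr{i + 1}" for i in range(len(sizes))],
            "area": areas,
            "scaffold": [f"scaffold_{i + 1}" for i in range(len(sizes))],
            "scaffold_bp": sizes.astype(np.int64),
        }
    )
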