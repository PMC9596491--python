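"""Readers, writers and the core in-memory containers shared by every stage.

The pipeline's central object is a :class:`SnpTable`: per-site genotypes and
per-sample read depths for a panel of individuals, as produced by a diploid
variant caller. Genotypes are coded as small integers (0 hom-ref, 1 het,
2 hom-alt, -1 missing); a missing genotype may still carry a depth.

Coordinate conventions: all internal positions are 1-based inclusive (VCF
convention); BED output is 0-based half-open.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1

_BASES = frozenset("ACGT")
MALE, FEMALE = "male", "female"

REGION_LABELS = ("autosomal", "PAR1", "HRX", "PAR2")


class VcfFormatError(ValueError):
    """A VCF violates the subset of the format this pipeline reads."""


@dataclass
class SnpTable:
    """Biallelic SNP genotype/depth matrix for a sample panel.

    Attributes
    ----------
    sites : pandas.DataFrame
        One row per site with columns ``scaffold`` (str), ``pos`` (1-based
        int), ``ref`` and ``alt`` (single bases).
    genotypes : numpy.ndarray
        ``(n_sites, n_samples)`` int8 matrix coded 0/1/2/-1.
    depths : numpy.ndarray
        ``(n_sites, n_samples)`` non-negative integer read depths.
    samples : list of str
        Sample identifiers, column order of the matrices.
    """

    sites: pd.DataFrame
    genotypes: np.ndarray
    depths: np.ndarray
    samples: list[str]

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def validate(self) -> None:
        """Check structural invariants; raise ``ValueError`` on violation."""
        n, m = self.genotypes.shape
        if n != self.n_sites or m != self.n_samples:
            raise ValueError("genotype matrix shape disagrees with sites/samples")
        if self.depths.shape != (n, m):
            raise ValueError("depth matrix shape disagrees with genotype matrix")
        if (self.depths < 0).any():
            raise ValueError("negative depths")
        valid = np.isin(self.genotypes, (HOM_REF, HET, HOM_ALT, MISSING))
        if not valid.all():
            raise ValueError("genotype codes outside {0,1,2,-1}")
        for col in ("ref", "alt"):
            bad = ~self.sites[col].isin(list(_BASES))
            if bad.any():
                raise ValueError(f"non-ACGT {col} allele at site {bad.idxmax()}")
        if (self.sites["ref"] == self.sites["alt"]).any():
            raise ValueError("ref == alt at some site")
        for scaffold, grp in self.sites.groupby("scaffold", sort=False):
            pos = grp["pos"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise ValueError(f"positions not strictly increasing on {scaffold}")

    def subset(self, mask: np.ndarray) -> "SnpTable":
        """Return a new table restricted to sites where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        return SnpTable(
            sites=self.sites.loc[mask].reset_index(drop=True),
            genotypes=self.genotypes[mask].copy(),
            depths=self.depths[mask].copy(),
            samples=list(self.samples),
        )


@dataclass
class SexMap:
    """Sample -> sex assignment for a male-heterogametic (XY) panel."""

    assignments: dict[str, str]

    def male_mask(self, samples: Sequence[str]) -> np.ndarray:
        """Boolean mask (True = male) aligned with ``samples``.

        Every sample must have an assignment.
        """
        try:
            return np.array([self.assignments[s] == MALE for s in samples])
        except KeyError as exc:  # pragma: no cover - defensive
            raise ValueError(f"sample {exc.args[0]!r} has no sex assignment") from exc

    def validate(self, samples: Sequence[str] | None = None) -> None:
        for s, v in self.assignments.items():
            if v not in (MALE, FEMALE):
                raise ValueError(f"bad sex value {v!r} for sample {s!r}")
        sexes = list(self.assignments.values())
        if sexes.count(MALE) < 2 or sexes.count(FEMALE) < 2:
            raise ValueError("need at least 2 males and 2 females")
        if samples is not None:
            missing = set(samples) - set(self.assignments)
            if missing:
                raise ValueError(f"samples without sex assignment: {sorted(missing)}")


@dataclass(frozen=True)
class Region:
    scaffold: str
    start: int  # 1-based inclusive
    end: int  # inclusive
    label: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeLayout:
    """Scaffold lengths plus region annotations (autosomal / PAR1 / HRX / PAR2).

    A scaffold carrying PAR/HRX labels must be tiled completely by the ordered
    sequence PAR1, HRX, PAR2 — the geometry of an X scaffold whose hemizygous
    core is flanked by two recombining pseudoautosomal ends.
    """

    scaffolds: list[tuple[str, int]]
    regions: list[Region] = field(default_factory=list)

    def validate(self) -> None:
        lengths = dict(self.scaffolds)
        by_scaffold: dict[str, list[Region]] = {}
        for r in self.regions:
            if r.label not in REGION_LABELS:
                raise ValueError(f"unknown region label {r.label!r}")
            if r.scaffold not in lengths:
                raise ValueError(f"region on unknown scaffold {r.scaffold!r}")
            if not (1 <= r.start <= r.end <= lengths[r.scaffold]):
                raise ValueError(f"region {r} out of scaffold bounds")
            by_scaffold.setdefault(r.scaffold, []).append(r)
        for scaffold, regs in by_scaffold.items():
            prev_end = 0
            for r in regs:
                if r.start <= prev_end:
                    raise ValueError(f"overlapping/unordered regions on {scaffold}")
                prev_end = r.end
            labels = [r.label for r in regs if r.label != "autosomal"]
            if labels:
                if labels != ["PAR1", "HRX", "PAR2"]:
                    raise ValueError(
                        f"sex scaffold {scaffold} must carry PAR1,HRX,PAR2 in order"
                    )
                sex_regs = [r for r in regs if r.label != "autosomal"]
                if sex_regs[0].start != 1 or sex_regs[-1].end != lengths[scaffold]:
                    raise ValueError(f"PAR1..PAR2 must tile scaffold {scaffold}")
                for a, b in zip(sex_regs, sex_regs[1:]):
                    if b.start != a.end + 1:
                        raise ValueError(f"gaps between sex regions on {scaffold}")

    def scaffold_length(self, scaffold: str) -> int:
        return dict(self.scaffolds)[scaffold]

    def sex_scaffold(self) -> str | None:
        """Id of the scaffold carrying the PAR1/HRX/PAR2 structure, if any."""
        for r in self.regions:
            if r.label == "HRX":
                return r.scaffold
        return None

    def region_label(self, scaffold: str, pos: int) -> str:
        """Label of the region containing ``pos`` ('autosomal' by default)."""
        for r in self.regions:
            if r.scaffold == scaffold and r.start <= pos <= r.end:
                return r.label
        return "autosomal"


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> SnpTable:
    """Read a VCF v4.x into a :class:`SnpTable`.

    Only biallelic SNP records (REF and single ALT of length 1) are kept;
    indel and multi-allelic records are skipped with a logged count. Genotype
    ``./.`` maps to missing; phased separators are accepted. Records lacking
    a DP value get depth 0.

    Raises
    ------
    VcfFormatError
        Malformed header, or non-monotone positions within a scaffold (the
        offending line number is named).
    """
    path = str(path)
    try:
        vf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise VcfFormatError(f"{path}: malformed VCF header ({exc})") from exc
    with vf:
        samples = list(vf.header.samples)
        header_lines = str(vf.header).count("\n")
        scaffolds, positions, refs, alts = [], [], [], []
        gt_rows, dp_rows = [], []
        skipped = 0
        last_pos: dict[str, int] = {}
        for i, rec in enumerate(vf.fetch() if vf.index else vf):
            line_no = header_lines + i + 1
            alts_rec = rec.alts or ()
            if (
                len(alts_rec) != 1
                or rec.ref is None
                or len(rec.ref) != 1
                or len(alts_rec[0]) != 1
                or rec.ref.upper() not in _BASES
                or alts_rec[0].upper() not in _BASES
            ):
                skipped += 1
                continue
            if rec.chrom in last_pos and rec.pos <= last_pos[rec.chrom]:
                raise VcfFormatError(
                    f"{path}:{line_no}: non-monotone position {rec.pos} on "
                    f"{rec.chrom}"
                )
            last_pos[rec.chrom] = rec.pos
            gt_row = np.empty(len(samples), dtype=np.int8)
            dp_row = np.zeros(len(samples), dtype=np.int32)
            for j, s in enumerate(samples):
                call = rec.samples[s]
                gt = call.get("GT")
                if gt is None or any(a is None for a in gt):
                    gt_row[j] = MISSING
                else:
                    gt_row[j] = int(sum(gt))
                dp = call.get("DP")
                dp_row[j] = 0 if dp is None else int(dp)
            scaffolds.append(rec.chrom)
            positions.append(rec.pos)
            refs.append(rec.ref.upper())
            alts.append(alts_rec[0].upper())
            gt_rows.append(gt_row)
            dp_rows.append(dp_row)
    if skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", skipped)
    sites = pd.DataFrame(
        {"scaffold": scaffolds, "pos": positions, "ref": refs, "alt": alts}
    )
    n = len(sites)
    genotypes = (
        np.vstack(gt_rows) if n else np.empty((0, len(samples)), dtype=np.int8)
    )
    depths = np.vstack(dp_rows) if n else np.empty((0, len(samples)), dtype=np.int32)
    table = SnpTable(sites=sites, genotypes=genotypes, depths=depths, samples=samples)
    if n:
        table.validate()
    return table


_GT_TUPLES = {HOM_REF: (0, 0), HET: (0, 1), HOM_ALT: (1, 1), MISSING: (None, None)}


def write_vcf(
    table: SnpTable, path: str | Path, layout: GenomeLayout | None = None
) -> None:
    """Write a SnpTable as an uncompressed VCF v4.2 with FORMAT GT:DP.

    Contig lengths come from ``layout`` when given, else from the maximum
    observed position per scaffold.
    """
    header = pysam.VariantHeader()
    if layout is not None:
        contigs = layout.scaffolds
    else:
        maxpos = table.sites.groupby("scaffold", sort=False)["pos"].max()
        contigs = [(str(s), int(p)) for s, p in maxpos.items()]
    for name, length in contigs:
        header.contigs.add(name, length=length)
    header.add_meta(
        "FORMAT",
        items=[("ID", "GT"), ("Number", "1"), ("Type", "String"),
               ("Description", "Genotype")],
    )
    header.add_meta(
        "FORMAT",
        items=[("ID", "DP"), ("Number", "1"), ("Type", "Integer"),
               ("Description", "Read depth")],
    )
    for s in table.samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i in range(table.n_sites):
            row = table.sites.iloc[i]
            rec = out.new_record(
                contig=str(row["scaffold"]),
                start=int(row["pos"]) - 1,
                alleles=(str(row["ref"]), str(row["alt"])),
            )
            for j, s in enumerate(table.samples):
                rec.samples[s]["GT"] = _GT_TUPLES[int(table.genotypes[i, j])]
                rec.samples[s]["DP"] = int(table.depths[i, j])
            out.write(rec)


# ---------------------------------------------------------------------------
# Sex map (two-column TSV: sample id, M/F)
# ---------------------------------------------------------------------------

_SEX_TOKENS = {"m": MALE, "male": MALE, "f": FEMALE, "female": FEMALE}


def read_sex_map(path: str | Path) -> SexMap:
    """Read a two-column TSV (sample id, M/F) into a :class:`SexMap`."""
    assignments: dict[str, str] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{line_no}: expected 2 tab-separated fields")
            sample, token = fields[0].strip(), fields[1].strip().lower()
            if token not in _SEX_TOKENS:
                raise ValueError(
                    f"{path}:{line_no}: sex token {fields[1]!r} not in "
                    "{M,F,male,female}"
                )
            if sample in assignments:
                raise ValueError(f"{path}:{line_no}: duplicate sample {sample!r}")
            assignments[sample] = _SEX_TOKENS[token]
    return SexMap(assignments)


def write_sex_map(sex_map: SexMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, sex in sex_map.assignments.items():
            fh.write(f"{sample}\t{'M' if sex == MALE else 'F'}\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_regions_bed(regions: Iterable[Region], path: str | Path) -> None:
    """Write regions as BED4 (0-based, half-open; name column = label)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.scaffold}\t{r.start - 1}\t{r.end}\t{r.label}\n")


def read_regions_bed(path: str | Path) -> list[Region]:
    """Read a BED4 file back into 1-based inclusive :class:`Region` records."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            scaffold, start, end, label = line.rstrip("\n").split("\t")[:4]
            out.append(Region(scaffold, int(start) + 1, int(end), label))
    return out
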