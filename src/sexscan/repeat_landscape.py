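"""Repeat-landscape analysis: CpG-corrected Kimura 2-parameter divergence of
repeat inserts from their family consensus, divergence binning, and the
cross-genome comparison of recent insertion activity.

K2P treats transitions (p) and transversions (q) separately:

    K = -1/2 * ln((1 - 2p - q) * sqrt(1 - 2q))

Because CpG dinucleotides are hypermutable (C->T deamination), transitions at
consensus CpG positions would inflate the divergence of old elements; with the
CpG correction each such transition is down-weighted to 1/10 of a transition
before p is computed.

A repeat landscape bins each insert's aligned bp by floor(100*K) and its
repeat class, expressed as a proportion of the genome — a histogram of
insertion ages, recent activity on the left.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import kruskal

from .synthetic_data import RepeatAlignmentRecord

logger = logging.getLogger(__name__)

_VALID = frozenset("ACGT")
_PURINES = frozenset("AG")
CPG_TRANSITION_WEIGHT = 0.1  # convention of the repeat-annotation tooling
MIN_ALIGNED_SITES = 20


class AlignmentTooShort(ValueError):
    """Fewer than MIN_ALIGNED_SITES usable aligned columns."""


@dataclass(frozen=True)
class K2PResult:
    k: float  # NaN when saturated
    p: float  # (weighted) transition proportion
    q: float  # transversion proportion
    n_sites: int
    saturated: bool


def k2p_divergence(
    record: RepeatAlignmentRecord, cpg_correction: bool = True
) -> K2PResult:
    """Kimura 2-parameter divergence of an insert from its consensus.

    Gapped or ambiguous columns are ignored. With ``cpg_correction``, a
    transition whose consensus position lies in a consensus CpG dinucleotide
    counts 1/10. Saturated alignments (log argument <= 0) are flagged rather
    than raised; too-short alignments raise :class:`AlignmentTooShort`.
    """
    cons = record.consensus.upper()
    ins = record.insert.upper()
    is_cpg = [False] * len(cons)
    if cpg_correction:
        # CpG adjacency on the consensus, skipping alignment gaps
        prev = -1
        for i, c in enumerate(cons):
            if c == "-":
                continue
            if prev >= 0 and cons[prev] == "C" and c == "G":
                is_cpg[prev] = is_cpg[i] = True
            prev = i

    n = 0
    transitions = 0.0
    transversions = 0
    for i, (c, x) in enumerate(zip(cons, ins)):
        if c not in _VALID or x not in _VALID:
            continue
        n += 1
        if c == x:
            continue
        if (c in _PURINES) == (x in _PURINES):
            transitions += CPG_TRANSITION_WEIGHT if is_cpg[i] else 1.0
        else:
            transversions += 1
    if n < MIN_ALIGNED_SITES:
        raise AlignmentTooShort(
            f"{record.family}: only {n} usable aligned positions"
        )
    p = transitions / n
    q = transversions / n
    arg1 = 1.0 - 2.0 * p - q
    arg2 = 1.0 - 2.0 * q
    if arg1 <= 0 or arg2 <= 0:
        return K2PResult(k=float("nan"), p=p, q=q, n_sites=n, saturated=True)
    k = -0.5 * math.log(arg1 * math.sqrt(arg2))
    return K2PResult(k=k, p=p, q=q, n_sites=n, saturated=False)


def k2p_closed_form(p: float, q: float) -> float:
    """K2P distance from given mismatch proportions (no alignment needed)."""
    return -0.5 * math.log((1.0 - 2.0 * p - q) * math.sqrt(1.0 - 2.0 * q))


def _insert_bp(record: RepeatAlignmentRecord) -> int:
    return sum(1 for c in record.insert if c != "-")


def divergence_table(
    records: Iterable[RepeatAlignmentRecord], cpg_correction: bool = True
) -> pd.DataFrame:
    """Per-record K2P divergence with bookkeeping columns.

    Saturated and too-short records get NaN divergence and are counted in the
    log; downstream landscape builders drop them.
    """
    rows = []
    n_saturated = n_short = 0
    for rec in records:
        try:
            res = k2p_divergence(rec, cpg_correction=cpg_correction)
        except AlignmentTooShort:
            n_short += 1
            rows.append((rec.genome, rec.family, rec.repeat_class, np.nan,
                         _insert_bp(rec), False))
            continue
        if res.saturated:
            n_saturated += 1
        rows.append((rec.genome, rec.family, rec.repeat_class,
                     res.k if not res.saturated else np.nan,
                     _insert_bp(rec), res.saturated))
    if n_saturated or n_short:
        logger.info(
            "divergence_table: %d saturated, %d too-short records excluded",
            n_saturated, n_short,
        )
    return pd.DataFrame(
        rows, columns=["genome", "family", "class", "k2p", "insert_bp", "saturated"]
    )


def build_landscape(
    records: Iterable[RepeatAlignmentRecord],
    genome_size: int,
    cpg_correction: bool = True,
) -> pd.DataFrame:
    """Bin insert bp by repeat class and integer percent-divergence.

    Bin edges are left-closed: bin k holds K in [k%, (k+1)%). Proportions
    divide by ``genome_size``.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    div = divergence_table(records, cpg_correction=cpg_correction)
    ok = div.dropna(subset=["k2p"])
    if len(ok) == 0:
        return pd.DataFrame(columns=["class", "bin", "bp", "proportion"])
    ok = ok.assign(bin=np.floor(100.0 * ok["k2p"]).astype(int))
    out = (
        ok.groupby(["class", "bin"], as_index=False)["insert_bp"]
        .sum()
        .rename(columns={"insert_bp": "bp"})
    )
    out["proportion"] = out["bp"] / float(genome_size)
    return out


def recent_fraction_by_family(
    records: Iterable[RepeatAlignmentRecord],
    genome_size: int,
    cutoff: float = 0.10,
    cpg_correction: bool = True,
) -> pd.DataFrame:
    """Per-family genome proportion of insert bp with K2P <= cutoff."""
    div = divergence_table(records, cpg_correction=cpg_correction)
    ok = div.dropna(subset=["k2p"])
    recent = ok[ok["k2p"] <= cutoff]
    all_fams = ok[["genome", "family", "class"]].drop_duplicates()
    sums = recent.groupby(["genome", "family", "class"], as_index=False)[
        "insert_bp"
    ].sum()
    merged = all_fams.merge(sums, on=["genome", "family", "class"], how="left")
    merged["insert_bp"] = merged["insert_bp"].fillna(0)
    merged["recent_proportion"] = merged["insert_bp"] / float(genome_size)
    return merged.drop(columns="insert_bp")


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H with midranks and tie correction; p from chi-square.

    All-identical data (zero rank variance) returns H = 0, p = 1.
    """
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = kruskal(*groups)
    return float(h), float(p)


def compare_recent_fraction(
    records_a: Iterable[RepeatAlignmentRecord],
    records_b: Iterable[RepeatAlignmentRecord],
    genome_size_a: int,
    genome_size_b: int,
    cutoff: float = 0.10,
    cpg_correction: bool = True,
) -> pd.DataFrame:
    """Per-class comparison of recent (K2P <= cutoff) repeat activity.

    The observation unit is the repeat family; its value is the family's
    genome-proportion of recently diverged insert bp. Groups are the two
    genomes; the test is Kruskal-Wallis (chi-square, 1 df). Classes absent
    from either genome are skipped with a warning. Also reports each genome's
    aggregate recent proportion per class.
    """
    fa = recent_fraction_by_family(records_a, genome_size_a, cutoff, cpg_correction)
    fb = recent_fraction_by_family(records_b, genome_size_b, cutoff, cpg_correction)
    rows = []
    classes = sorted(set(fa["class"]) | set(fb["class"]))
    for cls in classes:
        va = fa.loc[fa["class"] == cls, "recent_proportion"].to_numpy()
        vb = fb.loc[fb["class"] == cls, "recent_proportion"].to_numpy()
        if len(va) == 0 or len(vb) == 0:
            logger.warning("class %s absent from one genome; skipped", cls)
            continue
        h, p = kruskal_wallis([va, vb])
        rows.append(
            {
                "class": cls,
                "n_families_a": len(va),
                "n_families_b": len(vb),
                "recent_proportion_a": float(va.sum()),
                "recent_proportion_b": float(vb.sum()),
                "kruskal_H": h,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
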