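"""K2P divergence, landscape binning, and the Kruskal-Wallis comparison."""
import math

import numpy as np
import pytest

from sexscan import RepeatAlignmentRecord, build_landscape, compare_recent_fraction, k2p_divergence
from sexscan.repeat_landscape import (
    AlignmentTooShort,
    divergence_table,
    k2p_closed_form,
    kruskal_wallis,
)
from sexscan.synthetic_data import simulate_repeat_alignments


def rec(consensus, insert, family="fam1", cls="LINE", genome="gA"):
    return RepeatAlignmentRecord(family=family, repeat_class=cls,
                                 consensus=consensus, insert=insert,
                                 genome=genome)


class TestK2P:
    def test_identical_sequences_zero(self):
        r = rec("ACGT" * 10, "ACGT" * 10)
        assert k2p_divergence(r).k == 0.0

    def test_closed_form_value(self):
        # p=0.2, q=0.1 -> K = -0.5*ln(0.5*sqrt(0.8)) = 0.40236
        assert k2p_closed_form(0.2, 0.1) == pytest.approx(0.40236, abs=1e-5)

    def test_estimator_matches_closed_form_on_constructed_alignment(self):
        # 100 sites: 20 transitions (A->G), 10 transversions (A->C), 70 matches
        cons = "A" * 100
        ins = "G" * 20 + "C" * 10 + "A" * 70
        res = k2p_divergence(rec(cons, ins), cpg_correction=False)
        assert res.p == pytest.approx(0.2)
        assert res.q == pytest.approx(0.1)
        assert res.k == pytest.approx(k2p_closed_form(0.2, 0.1), abs=1e-12)

    def test_cpg_transitions_downweighted(self):
        # consensus CG dinucleotides; C->T transitions at the C positions
        cons = "CG" * 30
        ins = "TG" * 10 + "CG" * 20
        corrected = k2p_divergence(rec(cons, ins), cpg_correction=True)
        plain = k2p_divergence(rec(cons, ins), cpg_correction=False)
        assert corrected.k < plain.k
        assert corrected.p == pytest.approx(0.1 * plain.p)

    def test_gaps_and_ambiguous_columns_ignored(self):
        cons = "AAAA--AAANAAAAAAAAAAAAAAA"
        ins = "AAAAGGAAAAAAAAAAAAAAAAAA-"
        res = k2p_divergence(rec(cons, ins), cpg_correction=False)
        assert res.n_sites == 21  # 25 cols minus 2 cons gaps, 1 N, 1 ins gap
        assert res.k == 0.0

    def test_saturation_flagged(self):
        cons = "A" * 40
        ins = "G" * 30 + "A" * 10  # p = 0.75: 1 - 2p - q < 0
        res = k2p_divergence(rec(cons, ins))
        assert res.saturated
        assert math.isnan(res.k)

    def test_too_short_alignment_raises(self):
        with pytest.raises(AlignmentTooShort):
            k2p_divergence(rec("ACGTACGTAC", "ACGTACGTAC"))

    def test_monotone_in_transitions_at_fixed_transversions(self):
        ks = [k2p_closed_form(p, 0.05) for p in np.linspace(0.0, 0.35, 20)]
        assert all(b >= a for a, b in zip(ks, ks[1:]))


class TestLandscape:
    def test_single_record_binning(self):
        # 1000 bp insert with exact p=0.04, q=0.01 -> K=0.0522: bin 5,
        # proportion 1e-3 of a 1 Mb genome
        record = rec("A" * 1000, "G" * 40 + "C" * 10 + "A" * 950, cls="DNA")
        assert 0.05 <= k2p_divergence(record).k < 0.06
        land = build_landscape([record], genome_size=10**6)
        assert len(land) == 1
        assert land["bin"].iloc[0] == 5
        assert land["proportion"].iloc[0] == pytest.approx(1e-3)

    def test_empty_records_empty_table(self):
        assert len(build_landscape([], genome_size=1000)) == 0

    def test_bimodal_fixture(self):
        recs = simulate_repeat_alignments(
            seed=10, n_per_class=20, true_divergence={"LINE": 0.05, "DNA": 0.25},
            classes=("LINE", "DNA"), length=2000,
        )
        land = build_landscape(recs, genome_size=10**7)
        line_bins = land[land["class"] == "LINE"].nlargest(1, "bp")["bin"].iloc[0]
        dna_bins = land[land["class"] == "DNA"].nlargest(1, "bp")["bin"].iloc[0]
        assert abs(line_bins - 5) <= 1
        assert abs(dna_bins - 25) <= 1

    def test_total_bp_conserved(self):
        recs = simulate_repeat_alignments(seed=11, n_per_class=10,
                                          true_divergence=0.15)
        land = build_landscape(recs, genome_size=10**6)
        div = divergence_table(recs)
        expected_bp = div.dropna(subset=["k2p"])["insert_bp"].sum()
        assert land["bp"].sum() == expected_bp

    def test_bad_genome_size_rejected(self):
        with pytest.raises(ValueError):
            build_landscape([], genome_size=0)


def kruskal_oracle(groups):
    """Rank-formula oracle: H = 12/(N(N+1)) * sum(R_i^2/n_i) - 3(N+1),
    with midranks and the tie correction divisor."""
    flat = np.concatenate([np.asarray(g, float) for g in groups])
    n = len(flat)
    order = np.argsort(flat, kind="mergesort")
    ranks = np.empty(n)
    sv = flat[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(flat, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    return h / tie


class TestKruskalWallis:
    def test_identical_groups(self):
        h, p = kruskal_wallis([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_all_identical_values(self):
        h, p = kruskal_wallis([[2.0, 2.0], [2.0, 2.0]])
        assert h == 0.0 and p == 1.0

    def test_separated_groups_rank_formula(self):
        h, _ = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert h == pytest.approx(3.857, abs=1e-3)
        assert h == pytest.approx(kruskal_oracle([[1, 2, 3], [4, 5, 6]]), abs=1e-12)

    def test_matches_oracle_on_random_tied_data(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            a = rng.integers(0, 6, rng.integers(4, 15)).astype(float)
            b = rng.integers(0, 6, rng.integers(4, 15)).astype(float)
            if np.all(np.concatenate([a, b]) == a[0]):
                continue
            h, _ = kruskal_wallis([a, b])
            assert h == pytest.approx(kruskal_oracle([a, b]), abs=1e-9)


class TestCompareRecentFraction:
    def test_identical_landscapes_null(self):
        recs = simulate_repeat_alignments(seed=13, n_per_class=6,
                                          true_divergence=0.05)
        out = compare_recent_fraction(recs, recs, 10**6, 10**6)
        assert (out["kruskal_H"] == 0).all()
        assert (out["p_value"] == 1).all()

    def test_recent_vs_ancient_genomes_detected(self):
        recent = simulate_repeat_alignments(seed=14, n_per_class=12,
                                            true_divergence=0.05,
                                            genome="recent")
        ancient = simulate_repeat_alignments(seed=15, n_per_class=12,
                                             true_divergence=0.30,
                                             genome="ancient")
        out = compare_recent_fraction(recent, ancient, 10**6, 10**6)
        assert (out["recent_proportion_a"] > out["recent_proportion_b"]).all()
        assert (out["p_value"] < 0.01).all()

    def test_class_missing_from_one_genome_skipped(self):
        a = simulate_repeat_alignments(seed=16, n_per_class=5,
                                       true_divergence=0.05,
                                       classes=("LINE", "SINE"))
        b = simulate_repeat_alignments(seed=17, n_per_class=5,
                                       true_divergence=0.05, classes=("LINE",),
                                       genome="gB")
        out = compare_recent_fraction(a, b, 10**6, 10**6)
        assert list(out["class"]) == ["LINE"]
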