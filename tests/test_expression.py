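"""Fold change, BH adjustment, DE filter, C_co, K factor and correlation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nucorg import (
    ExpressionRecord,
    LocusAnnotation,
    bh_adjust,
    change_coefficient,
    chromosome_activity_table,
    classify_chromosome,
    correlate_kgoi_kmean,
    differential_filter,
    fold_change,
    intrachromosomal_distance,
    k_factor,
    neighborhood_k_mean,
)
from nucorg.errors import (
    AnnotationError,
    InsufficientDataError,
    InvalidInputError,
    PipelineOrderError,
)
from nucorg.expression import attach_adjusted_p


def _rec(gene, log2fc, p_adj=None, chrom="chr1", mid_bp=1_000_000, p_raw=None):
    return ExpressionRecord(
        probe_id=f"p_{gene}", gene_symbol=gene, chromosome=chrom,
        start_bp=int(mid_bp - 10_000), end_bp=int(mid_bp + 10_000),
        mean_log2_mb=8.0, mean_log2_mt=8.0 + log2fc, p_raw=p_raw, p_adj=p_adj,
    )


class TestFoldChange:
    @pytest.mark.parametrize("diff,fc", [(0.0, 1.0), (1.0, 2.0), (-2.0, 0.25)])
    def test_values(self, diff, fc):
        assert fold_change(8.0, 8.0 + diff) == pytest.approx(fc, rel=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(InvalidInputError):
            fold_change(float("nan"), 1.0)


def _bh_oracle(p):
    """From-scratch step-up adjustment."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * n / rank_from_top)
        adj[i] = running_min
    return adj


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_worked_stepup(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_all_equal_unchanged(self):
        assert np.allclose(bh_adjust([0.2] * 5), 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            bh_adjust([0.5, 1.2])

    def test_matches_from_scratch_oracle(self, rng):
        for _ in range(100):
            p = rng.random(rng.integers(1, 51))
            assert np.allclose(bh_adjust(p), _bh_oracle(p), atol=1e-12)


class TestDifferentialFilter:
    def test_toy_table(self):
        recs = [
            _rec("a", math.log2(2.5), 0.005),
            _rec("b", math.log2(1.8), 0.001),
            _rec("c", math.log2(0.4), 0.005),
            _rec("d", math.log2(3.0), 0.02),
            _rec("e", math.log2(0.5), 0.009),
        ]
        up, down = differential_filter(recs)
        assert [r.gene_symbol for r in up] == ["a"]
        assert sorted(r.gene_symbol for r in down) == ["c", "e"]

    def test_empty_and_null_tables(self):
        assert differential_filter([]) == ([], [])
        up, down = differential_filter([_rec("a", 0.0, 0.001)])
        assert up == [] and down == []

    def test_requires_adjusted_p(self):
        with pytest.raises(PipelineOrderError):
            differential_filter([_rec("a", 2.0)])

    def test_counts_match_row_oracle(self, rng):
        recs = [
            _rec(f"g{i}", rng.normal(0, 1.5), float(rng.random()))
            for i in range(300)
        ]
        up, down = differential_filter(recs)
        expected = sum(
            1
            for r in recs
            if r.p_adj < 0.01 and (r.fold_change >= 2.0 or r.fold_change <= 0.5)
        )
        assert len(up) + len(down) == expected

    def test_attach_adjusted_p_round(self):
        recs = [_rec(f"g{i}", 0.0, p_raw=p) for i, p in enumerate([0.01, 0.02, 0.03, 0.04])]
        adj = attach_adjusted_p(recs)
        assert all(r.p_adj == pytest.approx(0.04) for r in adj)


class TestChangeCoefficient:
    def test_values(self):
        assert change_coefficient(10, 5) == 2.0
        assert change_coefficient(0, 5) == 0.0
        assert change_coefficient(3, 0) == math.inf
        assert math.isnan(change_coefficient(0, 0))

    def test_negative_rejected(self):
        with pytest.raises(InvalidInputError):
            change_coefficient(-1, 5)

    @pytest.mark.parametrize(
        "c,group",
        [
            (0.4, "up_dominant"), (0.5, "up_dominant"),
            (1.0, "intermediate"),
            (1.5, "down_dominant"), (2.0, "down_dominant"),
            (math.inf, "undefined"), (math.nan, "undefined"),
        ],
    )
    def test_classification(self, c, group):
        assert classify_chromosome(c) == group

    def test_activity_groups_partition_chromosomes(self, rng):
        recs = []
        for i in range(200):
            chrom = f"chr{rng.integers(1, 8)}"
            recs.append(_rec(f"g{i}", float(rng.choice([-2.0, 2.0])), 0.001, chrom=chrom))
        up, down = differential_filter(recs)
        table = chromosome_activity_table(up, down)
        chroms_with_de = {r.chromosome for r in up} | {r.chromosome for r in down}
        assert len(table) == len(chroms_with_de)
        assert all(a.group in ("up_dominant", "intermediate", "down_dominant", "undefined")
                   for a in table)


class TestKFactor:
    @pytest.mark.parametrize("fc,k", [(2.0, 1.0), (0.5, 1.0), (1.0, 0.0), (8.0, 3.0)])
    def test_values(self, fc, k):
        assert k_factor(fc) == pytest.approx(k, abs=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(InvalidInputError):
            k_factor(0.0)

    @given(st.floats(1e-3, 1e3))
    def test_symmetry(self, f):
        assert k_factor(f) == pytest.approx(k_factor(1.0 / f), abs=1e-12)


class TestNeighborhoodKMean:
    def test_simple_mean(self):
        recs = [
            _rec("GOI", 1.0, mid_bp=1_000_000),
            _rec("n1", 1.0, mid_bp=1_100_000),   # K = 1
            _rec("n2", 2.0, mid_bp=1_200_000),   # K = 2
            _rec("n3", -3.0, mid_bp=900_000),    # K = 3
        ]
        r = neighborhood_k_mean("GOI", recs, window_mbp=1.0)
        assert r.k_mean == pytest.approx(2.0)
        assert r.n_neighbors == 3

    def test_whole_chromosome_hand_example(self):
        # 4 neighbours with fc {2, 0.5, 1, 4} -> K {1, 1, 0, 2}, mean 1.0
        recs = [
            _rec("GOI", 0.5, mid_bp=5_000_000),
            _rec("a", 1.0, mid_bp=1_000_000),
            _rec("b", -1.0, mid_bp=2_000_000),
            _rec("c", 0.0, mid_bp=3_000_000),
            _rec("d", 2.0, mid_bp=4_000_000),
        ]
        r = neighborhood_k_mean("GOI", recs, window_mbp=20.0)
        assert r.k_mean == pytest.approx(1.0)
        assert r.n_neighbors == 4

    def test_empty_neighbourhood_flagged(self):
        r = neighborhood_k_mean("GOI", [_rec("GOI", 1.0)], window_mbp=1.0)
        assert r.k_mean is None and not r.defined and r.n_neighbors == 0

    def test_goi_inclusion_flag(self):
        recs = [_rec("GOI", 2.0, mid_bp=1_000_000), _rec("n", 0.0, mid_bp=1_050_000)]
        excl = neighborhood_k_mean("GOI", recs, 1.0)
        incl = neighborhood_k_mean("GOI", recs, 1.0, include_goi=True)
        assert excl.k_mean == pytest.approx(0.0)
        assert incl.k_mean == pytest.approx(1.0)  # mean of K {2, 0}

    def test_unknown_goi_rejected(self):
        with pytest.raises(InvalidInputError):
            neighborhood_k_mean("missing", [_rec("GOI", 1.0)], 1.0)


class TestCorrelation:
    def test_perfect_monotone(self):
        inc = [(i, i * 2.0) for i in range(6)]
        dec = [(i, -i) for i in range(6)]
        assert correlate_kgoi_kmean(inc)["rho"] == pytest.approx(1.0)
        assert correlate_kgoi_kmean(dec)["rho"] == pytest.approx(-1.0)

    def test_fisher_ci_at_published_strength(self, rng):
        # construct n=11 pairs, verify the CI equals the Fisher-z formula
        x = rng.normal(size=11)
        y = 0.9 * x + rng.normal(0, 0.5, size=11)
        out = correlate_kgoi_kmean(list(zip(x, y)))
        z = math.atanh(out["rho"])
        half = 1.959963984540054 / math.sqrt(11 - 3)
        assert out["ci_low"] == pytest.approx(math.tanh(z - half), abs=1e-12)
        assert out["ci_high"] == pytest.approx(math.tanh(z + half), abs=1e-12)
        # at rho ~= 0.83 and n=11 the band is approximately (0.46, 0.96)
        ref = math.atanh(0.83)
        assert math.tanh(ref - half) == pytest.approx(0.458, abs=5e-3)
        assert math.tanh(ref + half) == pytest.approx(0.956, abs=5e-3)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InsufficientDataError):
            correlate_kgoi_kmean([(1.0, 1.0)] * 3)

    def test_missing_values_rejected(self):
        with pytest.raises(InvalidInputError):
            correlate_kgoi_kmean([(1.0, float("nan"))] * 5)


class TestIntrachromosomalDistance:
    def test_arithmetic(self):
        locus = LocusAnnotation("G", "chr2", 161_990_000, 162_010_000, 93_000_000)
        assert intrachromosomal_distance(locus) == pytest.approx(69.0)

    def test_zero_at_centromere(self):
        locus = LocusAnnotation("G", "chr2", 92_990_000, 93_010_000, 93_000_000)
        assert intrachromosomal_distance(locus) == 0.0

    def test_chromosome_mismatch_rejected(self):
        locus = LocusAnnotation("G", "chr2", 1, 100, 50)
        with pytest.raises(AnnotationError):
            intrachromosomal_distance(locus, chromosome="chr3")
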