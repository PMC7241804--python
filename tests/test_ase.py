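import math

import numpy as np
import pytest

from splicestruct.ase import (
    SampleAseCount,
    assign_high_ase_group,
    call_outliers,
    compare_expression_groups,
    count_ases_per_sample,
    normalize_junctions,
    select_ases,
)
from splicestruct.io import GeneExpressionMatrix, JunctionCountMatrix, JunctionID


def make_counts(counts, genes=None, samples=None):
    counts = np.asarray(counts)
    n_j, n_s = counts.shape
    genes = genes or ["G"] * n_j
    samples = samples or [f"s{i + 1}" for i in range(n_s)]
    junctions = [
        JunctionID("chr1", 100 + i * 10, 105 + i * 10, g) for i, g in enumerate(genes)
    ]
    return JunctionCountMatrix(junctions, samples, counts)


def make_expr(values, genes, samples):
    return GeneExpressionMatrix(genes, samples, np.asarray(values, dtype=float))


class TestNormalizeJunctions:
    def test_stated_formula(self):
        # count 100 out of a library of 1e6 reads, expression 1, pseudocount 1
        counts = np.zeros((2, 1), dtype=np.int64)
        counts[0, 0] = 100
        counts[1, 0] = 1_000_000 - 100
        m = make_counts(counts, genes=["GA", "GB"])
        expr = make_expr([[1.0], [1.0]], ["GA", "GB"], m.samples)
        norm = normalize_junctions(m, expr, pseudocount=1.0)
        assert norm.values[0, 0] == pytest.approx(math.log((100 + 1) / (1 + 1)))

    def test_all_zero_counts_are_finite(self):
        m = make_counts(np.zeros((3, 4), dtype=np.int64))
        expr = make_expr(np.ones((1, 4)), ["G"], m.samples)
        norm = normalize_junctions(m, expr)
        assert np.all(np.isfinite(norm.values))
        # one constant value per sample
        assert np.unique(norm.values).size == 1

    def test_library_size_invariance(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 100, (4, 3))
        m1 = make_counts(counts)
        m2 = make_counts(counts * np.array([2, 1, 1]))  # double sample 1
        expr = make_expr(np.ones((1, 3)), ["G"], m1.samples)
        n1 = normalize_junctions(m1, expr)
        n2 = normalize_junctions(m2, expr)
        np.testing.assert_allclose(n1.values, n2.values)

    def test_missing_gene_reported(self):
        m = make_counts(np.ones((2, 2), dtype=np.int64), genes=["GA", "GB"])
        expr = make_expr(np.ones((1, 2)), ["GA"], m.samples)
        with pytest.raises(KeyError, match="GB"):
            normalize_junctions(m, expr)


def norm_from_values(values, samples=None):
    """Wrap a plain value matrix as a NormalizedJunctionMatrix."""
    from splicestruct.ase import NormalizedJunctionMatrix

    values = np.asarray(values, dtype=float)
    n_j, n_s = values.shape
    samples = samples or [f"s{i + 1}" for i in range(n_s)]
    junctions = [JunctionID("chr1", 100 + i * 10, 105 + i * 10, f"G{i}") for i in range(n_j)]
    return NormalizedJunctionMatrix(junctions, samples, values, 1.0, np.ones(n_s))


class TestCallOutliers:
    def test_degenerate_spread_gives_no_outliers(self):
        norm = norm_from_values(np.full((2, 8), 3.0))
        res = call_outliers(norm, norm.samples[:4], norm.samples[4:])
        assert not res.is_outlier.any()

    def test_planted_extreme_tumor_flagged(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(1, 10))
        iqr = np.percentile(values[0, :6], 75) - np.percentile(values[0, :6], 25)
        values[0, 9] = values[0, :6].max() + 10 * iqr
        norm = norm_from_values(values)
        res = call_outliers(norm, norm.samples[:6], norm.samples[6:])
        assert res.is_outlier[0, res.samples.index("s10")]

    def test_hand_computed_tukey_fence(self):
        # normals 1..12: Q1=3.75, Q3=9.25, fence = 9.25 + 1.5*5.5 = 17.5
        normals = np.arange(1, 13, dtype=float)
        for tumor_value, expected in [(20.0, True), (12.0, False)]:
            values = np.concatenate([normals, [tumor_value]])[None, :]
            norm = norm_from_values(values)
            res = call_outliers(norm, norm.samples[:12], norm.samples[12:], k_fence=1.5)
            assert res.fences[0] == pytest.approx(17.5)
            assert bool(res.is_outlier[0, -1]) is expected

    def test_monotone_in_k_fence(self):
        rng = np.random.default_rng(2)
        norm = norm_from_values(rng.normal(size=(20, 30)))
        normals, tumors = norm.samples[:15], norm.samples[15:]
        previous = None
        for k in (0.5, 1.0, 1.5, 3.0):
            total = call_outliers(norm, normals, tumors, k_fence=k).is_outlier.sum()
            if previous is not None:
                assert total <= previous
            previous = total

    def test_too_few_normals_rejected(self):
        norm = norm_from_values(np.ones((1, 4)))
        with pytest.raises(ValueError, match="normal"):
            call_outliers(norm, norm.samples[:2], norm.samples[2:])


def _fisher_oracle(t_out, n_t, n_out, n_n):
    """One-sided enrichment p by exhaustive hypergeometric summation."""
    total = n_t + n_n
    k = t_out + n_out  # outliers in the margin
    denom = math.comb(total, k)
    p = 0.0
    for a in range(t_out, min(k, n_t) + 1):
        if k - a <= n_n:
            p += math.comb(n_t, a) * math.comb(n_n, k - a) / denom
    return p


class TestSelectAses:
    def test_no_outliers_is_not_ase(self):
        norm = norm_from_values(np.full((3, 10), 1.0))
        res = call_outliers(norm, norm.samples[:5], norm.samples[5:])
        calls = select_ases(res)
        assert all(c.p_enrichment == 1.0 and not c.is_ase for c in calls)

    def test_fisher_matches_hypergeometric_oracle(self):
        rng = np.random.default_rng(3)
        n_n = n_t = 20
        values = rng.normal(size=(30, n_n + n_t))
        # push random tumor cells upward to create a spread of tables
        bump = rng.random(size=(30, n_t)) < 0.25
        values[:, n_n:] += bump * 10.0
        norm = norm_from_values(values)
        res = call_outliers(norm, norm.samples[:n_n], norm.samples[n_n:])
        for call in select_ases(res):
            expected = _fisher_oracle(
                call.n_outlier_tumor, call.n_tumor, call.n_outlier_normal, call.n_normal
            )
            assert call.p_enrichment == pytest.approx(expected, rel=1e-9)

    def test_strong_tumor_enrichment_called(self):
        values = np.zeros((1, 40))
        values[0, 20:30] = 10.0  # 10/20 tumors outlying, 0/20 normals
        norm = norm_from_values(values)
        res = call_outliers(norm, norm.samples[:20], norm.samples[20:])
        call = select_ases(res)[0]
        assert call.is_ase
        assert call.p_enrichment == pytest.approx(_fisher_oracle(10, 20, 0, 20), rel=1e-9)

    def test_alpha_zero_selects_nothing(self):
        values = np.zeros((1, 40))
        values[0, 20:] = 10.0
        norm = norm_from_values(values)
        res = call_outliers(norm, norm.samples[:20], norm.samples[20:])
        assert not any(c.is_ase for c in select_ases(res, alpha=0.0))

    def test_nested_in_alpha(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=(40, 30))
        values[:, 15:] += (rng.random(size=(40, 15)) < 0.3) * 8.0
        norm = norm_from_values(values)
        res = call_outliers(norm, norm.samples[:15], norm.samples[15:])
        loose = {str(c.junction) for c in select_ases(res, alpha=0.05) if c.is_ase}
        strict = {str(c.junction) for c in select_ases(res, alpha=0.01) if c.is_ase}
        assert strict <= loose


class TestSampleAseCounts:
    def _setup(self):
        values = np.zeros((3, 10))
        values[0, 6] = 5.0  # junction 0: tumor s7 outlier
        values[1, 6:9] = 5.0  # junction 1: tumors s7, s8, s9
        norm = norm_from_values(values)
        res = call_outliers(norm, norm.samples[:5], norm.samples[5:])
        calls = select_ases(res, alpha=0.5)
        return res, calls

    def test_counts_are_column_sums_of_ase_rows(self):
        res, calls = self._setup()
        counts = count_ases_per_sample(calls, res)
        ase_rows = [i for i, c in enumerate(calls) if c.is_ase]
        expected = res.is_outlier[ase_rows, :].sum(axis=0)
        assert [c.n_ases for c in counts] == list(expected)

    def test_no_ases_means_all_zero(self):
        norm = norm_from_values(np.zeros((2, 10)))
        res = call_outliers(norm, norm.samples[:5], norm.samples[5:])
        calls = select_ases(res)
        assert all(c.n_ases == 0 for c in count_ases_per_sample(calls, res))


class TestGroups:
    def test_equal_counts_yield_no_high_group(self):
        counts = [SampleAseCount(f"s{i}", 7) for i in range(6)]
        assert not any(assign_high_ase_group(counts).values())

    def test_single_extreme_sample_is_high(self):
        counts = [SampleAseCount(f"s{i}", v) for i, v in enumerate([0, 0, 0, 0, 100])]
        labels = assign_high_ase_group(counts, k_sd=0.5)
        # median 0, sample SD ~44.7: only the 100-count sample exceeds 22.4
        assert labels == {"s0": False, "s1": False, "s2": False, "s3": False, "s4": True}

    def test_huge_k_sd_empties_high_group(self):
        counts = [SampleAseCount(f"s{i}", v) for i, v in enumerate([1, 5, 9, 2, 8])]
        assert not any(assign_high_ase_group(counts, k_sd=100.0).values())

    def test_identical_distributions_give_large_p(self):
        rng = np.random.default_rng(5)
        base = rng.poisson(20, size=20)
        counts = [SampleAseCount(f"s{i}", int(v)) for i, v in enumerate(np.concatenate([base, base]))]
        z = {f"s{i}": (3.0 if i < 20 else 0.0) for i in range(40)}
        cmp = compare_expression_groups(counts, z)
        assert cmp.p_value > 0.9
        assert cmp.mean_difference == pytest.approx(0.0)

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(6)
        low = rng.normal(20, 5, 20).round().astype(int)
        high = low + 50
        counts = [SampleAseCount(f"s{i}", int(v)) for i, v in enumerate(np.concatenate([high, low]))]
        z = {f"s{i}": (3.0 if i < 20 else 0.0) for i in range(40)}
        cmp = compare_expression_groups(counts, z)
        assert cmp.p_value < 0.01 and cmp.mean_difference == pytest.approx(50.0)

    def test_single_group_rejected(self):
        counts = [SampleAseCount(f"s{i}", i) for i in range(6)]
        z = {f"s{i}": 1.0 for i in range(6)}
        with pytest.raises(ValueError, match=">= 2"):
            compare_expression_groups(counts, z, z_threshold=-math.inf)


class TestEndToEndRecall:
    def test_planted_tumor_junctions_recalled(self):
        """Planting tumor-specific junction over-expression yields recall
        > 0.8 and higher per-sample burdens in tumors."""
        rng = np.random.default_rng(7)
        n_genes, n_n, n_t = 60, 20, 20
        samples = [f"N{i}" for i in range(n_n)] + [f"T{i}" for i in range(n_t)]
        counts = rng.poisson(30, size=(n_genes, n_n + n_t))
        planted = rng.choice(n_genes, size=15, replace=False)
        for j in planted:
            hot = n_n + rng.choice(n_t, size=8, replace=False)
            counts[j, hot] *= 12
        m = make_counts(counts.astype(np.int64), genes=[f"G{i}" for i in range(n_genes)],
                        samples=samples)
        expr = make_expr(np.ones((n_genes, n_n + n_t)), [f"G{i}" for i in range(n_genes)], samples)
        norm = normalize_junctions(m, expr)
        res = call_outliers(norm, samples[:n_n], samples[n_n:])
        calls = select_ases(res)
        called = {i for i, c in enumerate(calls) if c.is_ase}
        recall = len(called & set(planted)) / len(planted)
        assert recall > 0.8
        per_sample = count_ases_per_sample(calls, res)
        tumor_mean = np.mean([c.n_ases for c in per_sample if c.sample.startswith("T")])
        normal_mean = np.mean([c.n_ases for c in per_sample if c.sample.startswith("N")])
        assert tumor_mean > normal_mean
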