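"""Diversity indices and group tests against closed forms and oracles."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats

from gutflux.diversity import (
    alpha_indices,
    bray_curtis,
    f_test_variance,
    mann_whitney_u,
    to_counts,
    unifrac,
)

count_vectors = st.lists(st.integers(min_value=0, max_value=50), min_size=2, max_size=10)


class TestAlphaIndices:
    def test_single_taxon(self):
        out = alpha_indices([7, 0, 0])
        assert out["richness"] == 1
        assert out["shannon"] == pytest.approx(0.0)
        assert out["simpson_D"] == pytest.approx(1.0)
        assert out["evenness"] == pytest.approx(1.0)

    def test_uniform_four_taxa(self):
        out = alpha_indices([5, 5, 5, 5])
        assert out["shannon"] == pytest.approx(np.log(4))
        assert out["simpson_D"] == pytest.approx(0.25)
        assert out["evenness"] == pytest.approx(1.0)

    def test_chao1_with_doubleton(self):
        # F1=2 singletons, F2=1 doubleton: chao1 = 5 + 4/2 = 7
        out = alpha_indices([4, 3, 2, 1, 1])
        assert out["chao1"] == pytest.approx(7.0)

    def test_chao1_bias_corrected_without_doubletons(self):
        # F1=2, F2=0: chao1 = 3 + 2*1/2 = 4
        out = alpha_indices([5, 1, 1])
        assert out["chao1"] == pytest.approx(4.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            alpha_indices([0, 0])

    @settings(max_examples=80, deadline=None)
    @given(count_vectors.filter(lambda v: sum(v) > 0))
    def test_index_bounds(self, counts):
        out = alpha_indices(counts)
        S = out["richness"]
        assert out["shannon"] <= np.log(S) + 1e-12
        assert 1.0 / S - 1e-12 <= out["simpson_D"] <= 1.0 + 1e-12
        assert 0.0 < out["evenness"] <= 1.0 + 1e-12
        assert out["chao1"] >= S

    def test_pseudo_depth_counts(self):
        counts = to_counts([0.5, 0.3, 0.2], depth=10)
        np.testing.assert_array_equal(counts, [5, 3, 2])


class TestBrayCurtis:
    def test_identity(self):
        assert bray_curtis([3, 1, 4], [3, 1, 4]) == pytest.approx(0.0)

    def test_disjoint_support(self):
        assert bray_curtis([5, 0], [0, 7]) == pytest.approx(1.0)

    def test_worked_example(self):
        # shared: min(2,1)+min(2,2)=3; totals 4 and 4 -> 1 - 6/8
        assert bray_curtis([2, 2, 0], [1, 2, 1]) == pytest.approx(0.25)

    def test_mismatched_universe_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis([1, 2], [1, 2, 3])

    def test_empty_pair_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [0, 0])

    @settings(max_examples=100, deadline=None)
    @given(count_vectors, count_vectors)
    def test_bounded_and_symmetric(self, x, y):
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        if sum(x) + sum(y) == 0:
            return
        d = bray_curtis(x, y)
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(bray_curtis(y, x))


FIXTURE_TREE = "((t1:0.3,t2:0.4):0.5,(t3:0.2,t4:0.6):0.1);"
FIXTURE_TAXA = ["t1", "t2", "t3", "t4"]


class TestUniFrac:
    @pytest.mark.parametrize("weighted", [False, True])
    def test_identity(self, weighted):
        x = [3, 1, 2, 4]
        assert unifrac(x, x, FIXTURE_TAXA, FIXTURE_TREE, weighted=weighted) == pytest.approx(0.0)

    def test_disjoint_clades_unweighted_is_one(self):
        tree = "((A:1,B:1):1,(C:1,D:1):1);"
        d = unifrac([3, 2, 0, 0], [0, 0, 1, 5], ["A", "B", "C", "D"], tree)
        assert d == pytest.approx(1.0)

    @pytest.mark.parametrize("weighted", [False, True])
    def test_matches_scikit_bio(self, weighted):
        skbio_diversity = pytest.importorskip("skbio.diversity.beta")
        from skbio import TreeNode

        x = np.array([5, 2, 0, 1])
        y = np.array([0, 3, 4, 1])
        tree = TreeNode.read(io.StringIO(FIXTURE_TREE))
        if weighted:
            ref = skbio_diversity.weighted_unifrac(x, y, taxa=FIXTURE_TAXA, tree=tree,
                                                   normalized=True)
        else:
            ref = skbio_diversity.unweighted_unifrac(x, y, taxa=FIXTURE_TAXA, tree=tree)
        mine = unifrac(x, y, FIXTURE_TAXA, FIXTURE_TREE, weighted=weighted)
        assert mine == pytest.approx(float(ref), abs=1e-6)

    def test_symmetry(self):
        a = unifrac([5, 0, 1, 2], [1, 3, 0, 0], FIXTURE_TAXA, FIXTURE_TREE, weighted=True)
        b = unifrac([1, 3, 0, 0], [5, 0, 1, 2], FIXTURE_TAXA, FIXTURE_TREE, weighted=True)
        assert a == pytest.approx(b)

    def test_missing_taxon_named(self):
        with pytest.raises(ValueError, match="t9"):
            unifrac([1, 1], [1, 1], ["t1", "t9"], FIXTURE_TREE)


class TestMannWhitney:
    def test_identical_groups_half_u(self):
        out = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert out["U"] == pytest.approx(4.5)  # n1*n2/2

    def test_tiny_exact_example(self):
        out = mann_whitney_u([1, 2], [3, 4])
        assert out["U"] == pytest.approx(0.0)
        assert out["p"] == pytest.approx(2.0 / 6.0)
        assert out["method"] == "exact"

    def test_monotone_transform_invariant(self):
        a = [0.3, 1.2, 2.5, 0.9]
        b = [1.7, 0.1, 3.3]
        base = mann_whitney_u(a, b)
        warped = mann_whitney_u(np.exp(a), np.exp(b))
        assert base["U"] == pytest.approx(warped["U"])
        assert base["p"] == pytest.approx(warped["p"])

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=int(rng.integers(3, 9)))
        b = rng.normal(size=int(rng.integers(3, 9))) + rng.normal() * 0.5
        mine = mann_whitney_u(a, b)
        ref = sstats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert mine["U"] == pytest.approx(float(ref.statistic))
        assert mine["p"] == pytest.approx(float(ref.pvalue), rel=1e-9)

    def test_normal_approx_with_ties_close_to_scipy(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 5, size=25).astype(float)
        b = rng.integers(0, 5, size=25).astype(float)
        mine = mann_whitney_u(a, b)
        ref = sstats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert mine["p"] == pytest.approx(float(ref.pvalue), abs=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestFTest:
    def test_same_data_unit_f(self):
        out = f_test_variance([1, 2, 3, 4], [1, 2, 3, 4])
        assert out["F"] == pytest.approx(1.0)
        assert out["p"] == pytest.approx(1.0)

    def test_scaled_copy(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        out = f_test_variance(2 * a, a)
        assert out["F"] == pytest.approx(4.0)
        out_rev = f_test_variance(a, 2 * a)
        assert out_rev["F"] == pytest.approx(0.25)

    def test_symmetric_p(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=8), 1.7 * rng.normal(size=6)
        assert f_test_variance(a, b)["p"] == pytest.approx(f_test_variance(b, a)["p"])

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            f_test_variance([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
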