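"""Kernel correctness against hand computations, independent brute-force
oracles (explicit descendant leaf sets, skbio's reference UniFracs), and
the algebraic invariants of the metric family."""

import io

import numpy as np
import pandas as pd
import pytest
from skbio.diversity.beta import unweighted_unifrac as skbio_unweighted
from skbio.diversity.beta import weighted_unifrac as skbio_weighted

import absunifrac as au
from absunifrac.model_io import ValidationError

from conftest import (
    make_table,
    naive_generalized,
    naive_unweighted,
    naive_weighted,
    profiles_for,
)


class TestWeightedUnifrac:
    def test_disjoint_support_is_maximal(self, two_leaf_tree):
        pa, pb = profiles_for(two_leaf_tree, {"A": 1, "B": 0}, {"A": 0, "B": 1})
        assert au.weighted_unifrac(pa, pb) == pytest.approx(1.0)

    def test_hand_example(self, two_leaf_tree):
        # a=(2,0), b=(1,1): numerator 1+1, denominator 3+1
        pa, pb = profiles_for(two_leaf_tree, {"A": 2, "B": 0}, {"A": 1, "B": 1})
        assert au.weighted_unifrac(pa, pb) == pytest.approx(0.5)

    def test_identical_profiles_zero(self, balanced_tree):
        pa, pb = profiles_for(
            balanced_tree, {"A": 3, "B": 1, "C": 0, "D": 2}, {"A": 3, "B": 1, "C": 0, "D": 2}
        )
        assert au.weighted_unifrac(pa, pb) == 0.0

    def test_scenario_identical_composition_100x_load(self, balanced_tree):
        """Identical relative composition, 100-fold biomass difference:
        invisible to U^R, (k-1)/(k+1) = 99/101 for U^A."""
        a = {"A": 1, "B": 2, "C": 3, "D": 4}
        b = {k: 100 * v for k, v in a.items()}
        pa, pb = profiles_for(balanced_tree, a, b)
        assert au.weighted_unifrac(pa, pb) == pytest.approx(99 / 101)
        ra = {k: v / 10 for k, v in a.items()}
        rb = {k: v / 1000 for k, v in b.items()}
        pra, prb = profiles_for(balanced_tree, ra, rb, mode="relative")
        assert au.weighted_unifrac(pra, prb) == pytest.approx(0.0, abs=1e-15)

    def test_all_zero_pair_rejected(self, two_leaf_tree):
        pa, pb = profiles_for(two_leaf_tree, {"A": 0, "B": 0}, {"A": 0, "B": 0})
        with pytest.raises(ValidationError):
            au.weighted_unifrac(pa, pb)

    def test_mode_mismatch_rejected(self, two_leaf_tree):
        pa = au.branch_profile(two_leaf_tree, {"A": 1, "B": 0}, mode="absolute")
        pb = au.branch_profile(two_leaf_tree, {"A": 0, "B": 1}, mode="relative")
        with pytest.raises(ValidationError):
            au.weighted_unifrac(pa, pb)


class TestGeneralizedUnifrac:
    def test_alpha0_hand_example(self, two_leaf_tree):
        pa, pb = profiles_for(two_leaf_tree, {"A": 2, "B": 0}, {"A": 1, "B": 1})
        assert au.generalized_unifrac(pa, pb, 0.0) == pytest.approx((1 / 3 + 1) / 2)

    def test_alpha_half_hand_example(self, two_leaf_tree):
        pa, pb = profiles_for(two_leaf_tree, {"A": 2, "B": 0}, {"A": 1, "B": 1})
        expect = (np.sqrt(3) * (1 / 3) + 1) / (np.sqrt(3) + 1)
        assert au.generalized_unifrac(pa, pb, 0.5) == pytest.approx(expect)

    def test_alpha_out_of_range(self, two_leaf_tree):
        pa, pb = profiles_for(two_leaf_tree, {"A": 2, "B": 0}, {"A": 1, "B": 1})
        with pytest.raises(ValidationError):
            au.generalized_unifrac(pa, pb, 1.1)

    @pytest.mark.parametrize("seed", range(20))
    def test_alpha1_identical_to_weighted(self, seed):
        tree, table, loads = au.random_fixture(n_taxa=10, n_samples=2, seed=seed)
        abs_table = table.to_absolute(loads)
        a = dict(zip(abs_table.taxa, abs_table.values[0]))
        b = dict(zip(abs_table.taxa, abs_table.values[1]))
        pa, pb = profiles_for(tree, a, b)
        gu = au.generalized_unifrac(pa, pb, 1.0)
        assert gu == pytest.approx(au.weighted_unifrac(pa, pb), abs=1e-15)


class TestUnweightedUnifrac:
    def test_disjoint(self, two_leaf_tree):
        pa, pb = profiles_for(two_leaf_tree, {"A": 5, "B": 0}, {"A": 0, "B": 3})
        assert au.unweighted_unifrac(pa, pb) == pytest.approx(1.0)

    def test_incidence_only(self, balanced_tree):
        pa, pb = profiles_for(
            balanced_tree, {"A": 1, "B": 9, "C": 4, "D": 1}, {"A": 7, "B": 1, "C": 1, "D": 9}
        )
        assert au.unweighted_unifrac(pa, pb) == 0.0

    def test_partial_overlap_matches_edge_classification(self, balanced_tree):
        a = {"A": 1, "B": 1, "C": 0, "D": 0}
        b = {"A": 1, "B": 0, "C": 1, "D": 0}
        pa, pb = profiles_for(balanced_tree, a, b)
        assert au.unweighted_unifrac(pa, pb) == pytest.approx(
            naive_unweighted(balanced_tree, a, b)
        )


class TestBrayCurtis:
    @pytest.mark.parametrize(
        "a,b,expect",
        [((2, 0), (1, 1), 0.5), ((3, 1, 2), (3, 1, 2), 0.0), ((1, 2), (5, 10), 4 / 6)],
    )
    def test_examples(self, a, b, expect):
        assert au.bray_curtis(a, b) == pytest.approx(expect)

    def test_both_zero_rejected(self):
        with pytest.raises(ValidationError):
            au.bray_curtis((0, 0), (0, 0))


class TestClosedForms:
    """Property: whenever b = k*a elementwise (identical composition,
    k-fold load difference), every absolute metric equals (k-1)/(k+1)."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        k=st.floats(min_value=1.0, max_value=1e4),
        counts=st.lists(st.floats(min_value=0, max_value=1e6), min_size=4, max_size=4),
    )
    def test_k_fold_scaling(self, two_leaf_tree_module, k, counts):
        a = {"A": counts[0] + 1.0, "B": counts[1]}  # ensure nonzero total
        b = {t: k * v for t, v in a.items()}
        pa, pb = profiles_for(two_leaf_tree_module, a, b)
        expect = (k - 1) / (k + 1)
        assert au.weighted_unifrac(pa, pb) == pytest.approx(expect, abs=1e-9)
        assert au.bray_curtis(list(a.values()), list(b.values())) == pytest.approx(
            expect, abs=1e-9
        )
        # symmetry of the kernel
        assert au.weighted_unifrac(pb, pa) == pytest.approx(
            au.weighted_unifrac(pa, pb), abs=1e-12
        )


class TestKernelOracles:
    """Vectorized kernels vs naive per-branch loops over explicit leaf sets."""

    @pytest.mark.parametrize("seed", range(30))
    def test_all_kernels_match_naive(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 51))
        tree, table, loads = au.random_fixture(n_taxa=n, n_samples=2, seed=seed + 1000)
        abs_table = table.to_absolute(loads)
        a = dict(zip(abs_table.taxa, abs_table.values[0]))
        b = dict(zip(abs_table.taxa, abs_table.values[1]))
        pa, pb = profiles_for(tree, a, b)
        assert au.weighted_unifrac(pa, pb) == pytest.approx(
            naive_weighted(tree, a, b), abs=1e-12
        )
        assert au.unweighted_unifrac(pa, pb) == pytest.approx(
            naive_unweighted(tree, a, b), abs=1e-12
        )
        for alpha in (0.0, 0.3, 1.0):
            assert au.generalized_unifrac(pa, pb, alpha) == pytest.approx(
                naive_generalized(tree, a, b, alpha), abs=1e-12
            )

    @pytest.mark.parametrize("seed", range(10))
    def test_relative_weighted_matches_skbio(self, seed):
        """Independent reference: skbio's normalized weighted UniFrac equals
        U^R (the branch-sum and leaf-depth normalizations are algebraically
        identical when the root edge has zero length)."""
        tree, table, _ = au.random_fixture(n_taxa=15, n_samples=2, seed=seed)
        rel = table.to_relative()
        pa, pb = profiles_for(
            tree,
            dict(zip(rel.taxa, rel.values[0])),
            dict(zip(rel.taxa, rel.values[1])),
            mode="relative",
        )
        expect = skbio_weighted(
            table.values[0], table.values[1], taxa=table.taxa,
            tree=tree.skbio_tree, normalized=True,
        )
        assert au.weighted_unifrac(pa, pb) == pytest.approx(expect, abs=1e-10)
        expect_uw = skbio_unweighted(
            table.values[0], table.values[1], taxa=table.taxa, tree=tree.skbio_tree
        )
        assert au.unweighted_unifrac(pa, pb) == pytest.approx(expect_uw, abs=1e-10)


class TestInvariants:
    @pytest.mark.parametrize("seed", range(15))
    def test_range_symmetry_and_self_distance(self, seed):
        tree, table, loads = au.random_fixture(n_taxa=8, n_samples=6, seed=seed)
        for spec in (
            au.MetricSpec("unifrac_weighted", "absolute"),
            au.MetricSpec("unifrac_unweighted"),
            au.MetricSpec("bray_curtis", "relative"),
            au.MetricSpec("unifrac_generalized", "absolute", (0.0, 0.5, 1.0)),
        ):
            out = au.pairwise_distances(table, tree, spec, loads)
            mats = out.values() if isinstance(out, dict) else [out]
            for dm in mats:
                assert (dm.data >= 0).all() and (dm.data <= 1 + 1e-12).all()
                assert np.allclose(dm.data, dm.data.T)
                assert np.diag(dm.data) == pytest.approx(np.zeros(6))

    @pytest.mark.parametrize("seed", range(10))
    def test_equal_totals_collapse(self, seed):
        """With equal per-sample totals the load factors cancel: absolute
        and relative forms coincide for U and GU(alpha)."""
        tree, table, _ = au.random_fixture(n_taxa=10, n_samples=5, seed=seed)
        equal_loads = au.LoadVector(pd.Series(1e8, index=table.samples))
        for family, alphas in (("unifrac_weighted", ()), ("unifrac_generalized", (0.0, 0.4, 1.0))):
            rel = au.pairwise_distances(table, tree, au.MetricSpec(family, "relative", alphas))
            ab = au.pairwise_distances(
                table, tree, au.MetricSpec(family, "absolute", alphas), equal_loads
            )
            if isinstance(rel, dict):
                for a in alphas:
                    assert np.allclose(rel[a].data, ab[a].data, atol=1e-12)
            else:
                assert np.allclose(rel.data, ab.data, atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_joint_scale_invariance(self, seed):
        """Multiplying both samples' absolute counts by the same k > 0
        leaves U^A and GU^A unchanged."""
        tree, table, loads = au.random_fixture(n_taxa=10, n_samples=4, seed=seed)
        abs_table = table.to_absolute(loads)
        k = 37.5
        scaled = au.CountTable(abs_table.data * k, mode="absolute")
        for spec in (
            au.MetricSpec("unifrac_weighted", "absolute"),
            au.MetricSpec("unifrac_generalized", "absolute", (0.2, 1.0)),
        ):
            d1 = au.pairwise_distances(abs_table, tree, spec)
            d2 = au.pairwise_distances(scaled, tree, spec)
            if isinstance(d1, dict):
                for a in spec.alphas:
                    assert np.allclose(d1[a].data, d2[a].data, atol=1e-12)
            else:
                assert np.allclose(d1.data, d2.data, atol=1e-12)


class TestEqualBranchLengthBound:
    def test_unbalanced_tree_counterexample(self):
        """U^A <= BC^A under equal branch lengths requires all leaves to sit
        at the same depth.  On an unbalanced equal-length tree the bound
        fails: this pins the counterexample so the qualification on the
        leveled-tree property (see test_acceptance) stays visible."""
        tree = au.read_newick(io.StringIO("((A:1,B:1):1,C:1):0;"))
        a = {"A": 5.0, "B": 0.0, "C": 100.0}
        b = {"A": 0.0, "B": 1.0, "C": 100.0}
        pa, pb = profiles_for(tree, a, b)
        ua = au.weighted_unifrac(pa, pb)
        bca = au.bray_curtis([5, 0, 100], [0, 1, 100])
        assert ua == pytest.approx(10 / 212)
        assert bca == pytest.approx(6 / 206)
        assert ua > bca  # the unqualified claim is falsified here


class TestPairwiseBuilder:
    def test_grid_matrix_shape(self, grid, grid_tree):
        dm = au.pairwise_distances(grid, grid_tree, au.MetricSpec("unifrac_weighted", "absolute"))
        assert dm.shape == (81, 81)
        assert len(dm.condensed_form()) == 3240

    def test_single_sample(self, grid_tree):
        table = make_table([[1, 1, 1, 1]], ["only"], ["ASV_1", "ASV_2", "ASV_3", "ASV_4"],
                           mode="absolute")
        dm = au.pairwise_distances(table, grid_tree, au.MetricSpec("unifrac_weighted", "absolute"))
        assert dm.shape == (1, 1) and dm.data[0, 0] == 0.0

    def test_missing_tree_rejected(self, grid):
        with pytest.raises(ValidationError):
            au.pairwise_distances(grid, None, au.MetricSpec("unifrac_weighted", "absolute"))

    def test_missing_loads_rejected(self, grid_tree, small_fixture):
        _, table, _ = small_fixture
        with pytest.raises(ValidationError):
            au.pairwise_distances(table, grid_tree, au.MetricSpec("unifrac_weighted", "absolute"))

    @pytest.mark.parametrize("seed", range(5))
    def test_matrix_entries_match_kernels(self, seed):
        """All-pairs builder agrees with the pairwise kernels it vectorizes."""
        tree, table, loads = au.random_fixture(n_taxa=7, n_samples=5, seed=seed)
        abs_table = table.to_absolute(loads)
        dm = au.pairwise_distances(table, tree, au.MetricSpec("unifrac_weighted", "absolute"), loads)
        gdm = au.pairwise_distances(
            table, tree, au.MetricSpec("unifrac_generalized", "absolute", (0.3,)), loads
        )[0.3]
        for i in range(5):
            for j in range(i + 1, 5):
                a = dict(zip(abs_table.taxa, abs_table.values[i]))
                b = dict(zip(abs_table.taxa, abs_table.values[j]))
                pa, pb = profiles_for(tree, a, b)
                assert dm.data[i, j] == pytest.approx(au.weighted_unifrac(pa, pb), abs=1e-12)
                assert gdm.data[i, j] == pytest.approx(
                    au.generalized_unifrac(pa, pb, 0.3), abs=1e-12
                )
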