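import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import ndtri

from mtmat.tree_taxa import CountTable, enumerate_test_nodes, parse_tree
from mtmat.tree_taxa import TestNode as PhyloNode
from mtmat.transforms import (
    inverse_normal_transform,
    log_cpm,
    node_covariate,
    pooled_covariate,
)
from mtmat.association import genus_covariates
from mtmat import GenusPartition


def one_sample_table(counts):
    counts = np.asarray(counts).reshape(-1, 1)
    taxa = [f"t{i}" for i in range(counts.shape[0])]
    samples = pd.DataFrame(
        {"subject_id": ["a"], "visit": [1]}, index=pd.Index(["s0"])
    )
    return CountTable(counts=pd.DataFrame(counts, index=taxa, columns=["s0"]),
                      samples=samples)


class TestLogCpm:
    def test_zero_count_closed_form(self):
        # c=0, L=1000, prior 1: log2(0.5/1001 * 1e6 + 1) = log2(500.4995...)
        table = one_sample_table([0, 1000])
        r = log_cpm(table).r
        expected = math.log2(0.5 / 1001 * 1e6 + 1)
        assert r.loc["t0", "s0"] == pytest.approx(expected, abs=1e-10)
        assert expected == pytest.approx(8.9674, abs=5e-4)

    def test_single_nonzero_taxon_closed_form(self):
        table = one_sample_table([10**4, 0])
        r = log_cpm(table).r
        expected = math.log2((10000.5 / 10001) * 1e6 + 1)
        assert r.loc["t0", "s0"] == pytest.approx(expected, abs=1e-10)
        assert expected == pytest.approx(19.9315, abs=5e-4)

    @given(st.integers(0, 5000), st.integers(0, 5000))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_count_at_fixed_library(self, c1, c2):
        if c1 == c2:
            return
        lo, hi = sorted((c1, c2))
        table = one_sample_table([lo, hi, 10000 - lo - hi + 5000])
        r = log_cpm(table).r["s0"]
        assert r.iloc[0] < r.iloc[1]

    def test_zero_library_rejected(self):
        table = one_sample_table([0, 0])
        with pytest.raises(ValueError, match="library"):
            log_cpm(table)

    def test_library_scaled_prior(self):
        table = one_sample_table([5, 95])
        r = log_cpm(table, prior_policy="library_scaled")
        assert r.prior_scale.iloc[0] == pytest.approx(1.0)  # single sample


class TestNodeCovariate:
    def test_antisymmetric_under_child_swap(self, small_logcpm):
        taxa = list(small_logcpm.r.index[:2])
        node_lr = PhyloNode(k=1, left_leaves=frozenset([taxa[0]]),
                           right_leaves=frozenset([taxa[1]]))
        node_rl = PhyloNode(k=1, left_leaves=frozenset([taxa[1]]),
                           right_leaves=frozenset([taxa[0]]))
        x_lr = node_covariate(small_logcpm, node_lr)
        x_rl = node_covariate(small_logcpm, node_rl)
        np.testing.assert_allclose(x_lr.values, -x_rl.values, atol=1e-12)

    def test_c_twice_d_gives_log2(self):
        # two taxa engineered so pooled left sum is twice the right sum
        table = one_sample_table([100, 100, 800])
        r = log_cpm(table)
        r.r.loc["t0", "s0"] = 6.0
        r.r.loc["t1", "s0"] = 3.0
        node = PhyloNode(k=1, left_leaves=frozenset(["t0"]),
                        right_leaves=frozenset(["t1"]))
        assert node_covariate(r, node).iloc[0] == pytest.approx(math.log(2))


class TestPooledCovariate:
    def test_default_mode_is_log_ratio_of_sums(self, small_logcpm, small_study):
        _, tree, taxonomy, _ = small_study
        genus_taxa = [t for t in small_logcpm.r.index if taxonomy[t] == "g01"]
        part = enumerate_test_nodes(tree, genus_taxa, "g01")
        part.other_taxa = tuple(t for t in small_logcpm.r.index
                                if t not in set(genus_taxa))
        x0 = pooled_covariate(small_logcpm, part)
        E = small_logcpm.r.loc[list(part.member_taxa)].sum(axis=0)
        G = small_logcpm.r.loc[list(part.other_taxa)].sum(axis=0)
        np.testing.assert_allclose(x0.values, np.log(E / G).values, atol=1e-12)

    def test_alr_with_reference_equal_to_genus_rejected(self, small_logcpm,
                                                        small_study):
        _, tree, taxonomy, _ = small_study
        genus_taxa = [t for t in small_logcpm.r.index if taxonomy[t] == "g01"]
        part = enumerate_test_nodes(tree, genus_taxa, "g01")
        with pytest.raises(ValueError, match="overlaps"):
            pooled_covariate(small_logcpm, part, mode="alr_reference",
                            reference_genus=part)

    def test_clr_equal_genus_sums_give_zero(self):
        table = one_sample_table([10, 10, 10, 10])
        r = log_cpm(table)
        part = GenusPartition(genus="a", member_taxa=("t0", "t1"),
                              other_taxa=("t2", "t3"))
        x0 = pooled_covariate(
            r, part, mode="clr_geomean",
            all_genus_taxa={"a": ["t0", "t1"], "b": ["t2", "t3"]})
        assert x0.iloc[0] == pytest.approx(0.0, abs=1e-12)


class TestInverseNormalTransform:
    def test_three_values_closed_form(self):
        z = inverse_normal_transform([2.1, 5.3, 0.7])
        expected = [0.0, ndtri(5 / 6), ndtri(1 / 6)]
        np.testing.assert_allclose(z, expected, atol=1e-12)
        assert z[1] == pytest.approx(0.9674, abs=5e-4)

    def test_ties_map_to_same_value(self):
        z = inverse_normal_transform([1, 1, 2])
        assert z[0] == z[1] == pytest.approx(ndtri((1.5 - 0.5) / 3))
        assert z[2] == pytest.approx(ndtri((3 - 0.5) / 3))

    def test_constant_vector_maps_to_zero(self):
        with pytest.warns(UserWarning, match="identical"):
            z = inverse_normal_transform([3.0, 3.0, 3.0])
        assert (z == 0).all()

    @given(st.lists(st.floats(-1e6, 1e6, allow_nan=False), min_size=2,
                    max_size=40, unique=True))
    @settings(max_examples=50, deadline=None)
    def test_rank_preserving(self, xs):
        z = inverse_normal_transform(xs)
        order_x = np.argsort(xs)
        order_z = np.argsort(z)
        np.testing.assert_array_equal(order_x, order_z)

    def test_tie_free_output_matches_exact_quantiles(self, rng):
        x = rng.normal(size=25)
        z = np.sort(inverse_normal_transform(x))
        expected = ndtri((np.arange(1, 26) - 0.5) / 25)
        np.testing.assert_allclose(z, expected, atol=1e-12)


def dense_positive_table(rng, n_taxa=12, n_samples=60):
    """Fixture with strictly positive counts and libraries >= 1e4: the
    regime where the pseudo-count is negligible and log-CPM is close to
    scale invariant per sample."""
    counts = rng.poisson(1000, size=(n_taxa, n_samples)) + 50
    sids = [f"s{i}" for i in range(n_samples)]
    samples = pd.DataFrame(
        {"subject_id": [f"u{i // 3}" for i in range(n_samples)],
         "visit": [i % 3 + 1 for i in range(n_samples)]},
        index=pd.Index(sids),
    )
    taxa = [f"t{i}" for i in range(n_taxa)]
    return CountTable(
        counts=pd.DataFrame(counts, index=taxa, columns=sids), samples=samples
    )


class TestCompositionalRobustness:
    @pytest.mark.parametrize("policy", ["constant", "library_scaled"])
    def test_log_cpm_stable_under_per_sample_scaling(self, rng, policy):
        # multiplying a sample's counts (sequencing depth) by a common
        # factor in [0.5, 2] barely moves log-CPM when counts dwarf the
        # pseudo-count; zero cells are exactly where this breaks, hence the
        # strictly positive fixture
        table = dense_positive_table(rng)
        assert table.library_size.min() >= 1e4
        factors = rng.uniform(0.5, 2.0, size=table.n_samples)
        scaled = CountTable(counts=table.counts * factors,
                            samples=table.samples)
        r0 = log_cpm(table, policy).r.values
        r1 = log_cpm(scaled, policy).r.values
        assert np.abs(r0 - r1).max() < 1e-2

    def test_node_covariates_stable_under_per_sample_scaling(self, rng):
        table = dense_positive_table(rng)
        factors = rng.uniform(0.5, 2.0, size=table.n_samples)
        scaled = CountTable(counts=table.counts * factors,
                            samples=table.samples)
        part = GenusPartition(genus="a", member_taxa=("t0", "t1", "t2"),
                              other_taxa=tuple(f"t{i}" for i in range(3, 12)))
        X0 = genus_covariates(log_cpm(table), part)
        X1 = genus_covariates(log_cpm(scaled), part)
        assert np.abs(X0 - X1).max() < 1e-2
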