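"""Unit and property tests of the correlation-equality test machinery."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from dconet import (
    ExpressionMatrix,
    GroupAssignment,
    InteractionNetwork,
    analytic_pvalue,
    asymptotic_variance,
    bh_adjust,
    fisher_transform,
    group_correlation,
    run_ztest,
    ztest_statistic,
)
from dconet.core import _pair_correlations

from conftest import make_changed_pairs, make_null_pairs


class TestFisherTransform:
    @pytest.mark.parametrize(
        "r, expected",
        [
            (0.0, 0.0),
            (0.5, 0.5 * math.log(1.5 / 0.5)),  # closed form arctanh
            (-0.5, -0.5 * math.log(1.5 / 0.5)),
        ],
    )
    def test_closed_form(self, r, expected):
        assert fisher_transform(r) == pytest.approx(expected, abs=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            fisher_transform(float("nan"))

    def test_collinear_input_clamped_with_warning(self):
        with pytest.warns(RuntimeWarning):
            z = fisher_transform(1.0)
        assert np.isfinite(z) and z > 13  # arctanh(1 - 1e-12)

    @given(st.floats(min_value=-0.999, max_value=0.999))
    @settings(max_examples=50, deadline=None)
    def test_odd_function(self, r):
        assert fisher_transform(-r) == pytest.approx(-fisher_transform(r), abs=1e-12)

    @given(
        st.floats(min_value=-0.99, max_value=0.98),
        st.floats(min_value=1e-6, max_value=0.01),
    )
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing(self, r, eps):
        assert fisher_transform(r + eps) > fisher_transform(r)


class TestAsymptoticVariance:
    @pytest.mark.parametrize(
        "M, kind, mode, r, expected",
        [
            (103, "pearson", "worst_case", None, 0.01),
            (103, "spearman", "worst_case", None, 0.015),
            (103, "spearman", "plugin", 0.0, 0.01),
            (103, "spearman", "plugin", 0.6, (1 + 0.18) / 100),
        ],
    )
    def test_formulas(self, M, kind, mode, r, expected):
        assert asymptotic_variance(M, kind, mode, r) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("M", [3, 2, 0, -1])
    def test_small_groups_rejected(self, M):
        with pytest.raises(ValueError):
            asymptotic_variance(M, "pearson")


class TestZtestStatistic:
    def test_equal_correlations_give_zero(self):
        assert ztest_statistic(0.4, 0.4, 50, 80, "pearson") == 0.0

    def test_pearson_oracle(self):
        # 2*arctanh(0.5)/sqrt(2/100)
        expected = 2 * math.atanh(0.5) / math.sqrt(0.02)
        assert ztest_statistic(0.5, -0.5, 103, 103, "pearson") == pytest.approx(
            expected, abs=1e-9
        )
        assert expected == pytest.approx(7.7682, abs=5e-4)

    def test_spearman_uses_worst_case_variance(self):
        expected = 2 * math.atanh(0.5) / math.sqrt(0.03)
        assert ztest_statistic(0.5, -0.5, 103, 103, "spearman") == pytest.approx(
            expected, abs=1e-9
        )

    @given(
        st.floats(min_value=-0.95, max_value=0.95),
        st.floats(min_value=-0.95, max_value=0.95),
        st.integers(min_value=5, max_value=200),
        st.integers(min_value=5, max_value=200),
    )
    @settings(max_examples=50, deadline=None)
    def test_antisymmetric_in_groups(self, ra, rb, K, L):
        forward = ztest_statistic(ra, rb, K, L, "pearson")
        backward = ztest_statistic(rb, ra, L, K, "pearson")
        assert forward == pytest.approx(-backward, abs=1e-12)


class TestAnalyticPvalue:
    def test_null_center(self):
        assert analytic_pvalue(0.0, "two_sided") == 1.0

    def test_quantile_inversion(self):
        assert analytic_pvalue(1.959964, "two_sided") == pytest.approx(0.05, abs=1e-6)

    def test_extreme_tail_against_erfc(self):
        z = 2 * math.atanh(0.5) / math.sqrt(0.02)
        expected = math.erfc(z / math.sqrt(2))  # independent CDF route
        assert analytic_pvalue(z, "two_sided") == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(7.98e-15, rel=5e-3)

    def test_one_sided(self):
        assert analytic_pvalue(0.0, "one_sided_greater") == pytest.approx(0.5)
        assert analytic_pvalue(-3.0, "one_sided_greater") > 0.99


class TestBHAdjust:
    @pytest.mark.parametrize(
        "pvals, expected",
        [
            ([0.05], [0.05]),
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.5, 1.0], [1.0, 1.0]),
        ],
    )
    def test_hand_computed(self, pvals, expected):
        assert bh_adjust(pvals) == pytest.approx(expected, abs=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        p = rng.uniform(size=200)
        expected = multipletests(p, method="fdr_bh")[1]
        assert bh_adjust(p) == pytest.approx(expected, abs=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_adjusted_at_least_raw_and_order_free(self, pvals):
        adj = bh_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)
        assert np.all(adj <= 1.0)
        # adjustment commutes with any reordering of the input
        order = np.argsort(pvals)
        assert bh_adjust(np.asarray(pvals)[order]) == pytest.approx(adj[order])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestGroupCorrelation:
    def test_perfect_monotone_and_reversal(self):
        values = np.array(
            [
                [1.0, 2.0, 3.0, 4.0, 1.0, 2.0, 3.0, 4.0],
                [1.0, 2.0, 3.0, 4.0, 4.0, 3.0, 2.0, 1.0],
            ]
        )
        matrix = ExpressionMatrix.from_arrays(values, ["X", "Y"])
        samples = list(matrix.sample_ids)
        groups = GroupAssignment(
            labels={s: ("A" if i < 4 else "B") for i, s in enumerate(samples)},
            group_a="A",
            group_b="B",
        )
        net = InteractionNetwork((("X", "Y"),))
        for kind in ("pearson", "spearman"):
            table = group_correlation(matrix, groups, net, kind)
            assert table["r_a"].iloc[0] == pytest.approx(1.0)
            assert table["r_b"].iloc[0] == pytest.approx(-1.0)

    def test_monotone_nonlinear_pair(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = x**2
        values = np.vstack([np.tile(x, 2), np.tile(y, 2)])
        matrix = ExpressionMatrix.from_arrays(values, ["X", "Y"])
        samples = list(matrix.sample_ids)
        groups = GroupAssignment(
            labels={s: ("A" if i < 5 else "B") for i, s in enumerate(samples)},
            group_a="A",
            group_b="B",
        )
        net = InteractionNetwork((("X", "Y"),))
        pearson = group_correlation(matrix, groups, net, "pearson")["r_a"].iloc[0]
        spearman = group_correlation(matrix, groups, net, "spearman")["r_a"].iloc[0]
        expected_pearson = np.corrcoef(x, y)[0, 1]
        assert pearson == pytest.approx(expected_pearson, abs=1e-12)
        # hand computation: cov = 60, var_x = 10, var_y = 374
        assert expected_pearson == pytest.approx(60 / np.sqrt(10 * 374), abs=1e-12)
        assert spearman == pytest.approx(1.0)

    def test_constant_row_names_molecule_and_group(self):
        values = np.vstack([np.ones(8), np.arange(8.0)])
        matrix = ExpressionMatrix.from_arrays(values, ["flat", "Y"])
        samples = list(matrix.sample_ids)
        groups = GroupAssignment(
            labels={s: ("A" if i < 4 else "B") for i, s in enumerate(samples)},
            group_a="A",
            group_b="B",
        )
        net = InteractionNetwork((("flat", "Y"),))
        with pytest.raises(ValueError, match="group 'A'.*'flat'"):
            group_correlation(matrix, groups, net, "pearson")

    def test_vectorized_matches_naive_loop(self):
        """Vectorized correlations equal scipy's per-pair routines to 1e-12."""
        rng = np.random.default_rng(11)
        values = rng.standard_normal((50, 40))
        cols = np.arange(40)
        src = rng.integers(0, 50, size=100)
        tgt = (src + 1 + rng.integers(0, 48, size=100)) % 50
        for kind, oracle in (
            ("pearson", lambda a, b: sps.pearsonr(a, b).statistic),
            ("spearman", lambda a, b: sps.spearmanr(a, b).statistic),
        ):
            fast = _pair_correlations(values, cols, src, tgt, kind)
            slow = np.array([oracle(values[s], values[t]) for s, t in zip(src, tgt)])
            assert fast == pytest.approx(slow, abs=1e-12)


class TestRunZtest:
    def test_identical_groups_give_null_result(self):
        rng = np.random.default_rng(3)
        half = rng.standard_normal((2, 10))
        matrix = ExpressionMatrix.from_arrays(np.hstack([half, half]), ["X", "Y"])
        samples = list(matrix.sample_ids)
        groups = GroupAssignment(
            labels={s: ("A" if i < 10 else "B") for i, s in enumerate(samples)},
            group_a="A",
            group_b="B",
        )
        res = run_ztest(matrix, groups, InteractionNetwork((("X", "Y"),)))
        assert res["statistic"].iloc[0] == 0.0
        assert res["pvalue"].iloc[0] == 1.0
        assert res["adjusted_pvalue"].iloc[0] == 1.0

    def test_bh_composition(self, small_dataset):
        matrix, groups, network = small_dataset
        res = run_ztest(matrix, groups, network)
        assert res["adjusted_pvalue"].to_numpy() == pytest.approx(
            bh_adjust(res["pvalue"].to_numpy())
        )
        assert list(res["source"]) == [s for s, _ in network.pairs]

    def test_group_swap_negates_statistics(self, small_dataset):
        """Exchanging the two group labels flips every z exactly and leaves
        two-sided p-values unchanged."""
        matrix, groups, network = small_dataset
        forward = run_ztest(matrix, groups, network)
        backward = run_ztest(matrix, groups.swapped(), network)
        assert backward["statistic"].to_numpy() == pytest.approx(
            -forward["statistic"].to_numpy(), abs=0.0
        )
        assert backward["pvalue"].to_numpy() == pytest.approx(
            forward["pvalue"].to_numpy(), abs=0.0
        )

    def test_spearman_bound_conservative_vs_plugin(self):
        """The worst-case-variance p-value upper-bounds the plug-in one."""
        rng = np.random.default_rng(5)
        for _ in range(1000):
            ra, rb = rng.uniform(-0.99, 0.99, size=2)
            K, L = rng.integers(5, 150, size=2)
            z_bound = ztest_statistic(ra, rb, K, L, "spearman")
            var_plug = asymptotic_variance(K, "spearman", "plugin", ra) + \
                asymptotic_variance(L, "spearman", "plugin", rb)
            z_plug = (math.atanh(ra) - math.atanh(rb)) / math.sqrt(var_plug)
            assert analytic_pvalue(z_bound) >= analytic_pvalue(z_plug) - 1e-15

    def test_mean_abs_statistic_monotone_in_correlation_change(self):
        """Power grows with the simulated correlation difference."""
        means = []
        for delta in (0.0, 0.3, 0.6, 0.9):
            matrix, groups, network = make_changed_pairs(
                200, 30, 30, rho_a=delta / 2, rho_b=-delta / 2, seed=17
            )
            res = run_ztest(matrix, groups, network)
            means.append(np.abs(res["statistic"]).mean())
        assert all(b >= a for a, b in zip(means, means[1:]))


class TestContainers:
    def test_nonfinite_matrix_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            ExpressionMatrix.from_arrays(np.array([[1.0, np.nan], [0.0, 1.0]]))

    def test_duplicate_molecule_rejected(self):
        with pytest.raises(ValueError, match="duplicate molecule"):
            ExpressionMatrix(
                pd.DataFrame(np.zeros((2, 2)), index=["a", "a"], columns=["s1", "s2"])
            )

    def test_tiny_group_rejected(self):
        labels = {f"s{i}": ("A" if i < 3 else "B") for i in range(8)}
        with pytest.raises(ValueError, match=">= 4"):
            GroupAssignment(labels=labels, group_a="A", group_b="B")

    def test_network_rejects_self_and_duplicate_pairs(self):
        with pytest.raises(ValueError, match="self-interaction"):
            InteractionNetwork((("a", "a"),))
        with pytest.raises(ValueError, match="duplicate"):
            InteractionNetwork((("a", "b"), ("a", "b")))

    def test_exhaustive_pair_count(self):
        net = InteractionNetwork.exhaustive([f"m{i}" for i in range(5)])
        assert len(net) == 10
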