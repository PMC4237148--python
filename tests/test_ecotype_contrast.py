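"""Ratio sets, Mann-Whitney rank test and Yates contingency contrasts."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency, mannwhitneyu, norm

from popdiff import datasets
from popdiff.ecotype_contrast import (
    chi2_contrast,
    mann_whitney,
    outgroup_contrast,
    ratio_set,
)
from popdiff.popgen_stats import PairwiseLayer

from ._oracles import mann_whitney_u_enum

RESIDENTS = ["SR", "AR", "BS"]
TRANSIENTS = ["AT", "CT"]


def _uniform_layer(pops, value, diag=0.0):
    n = len(pops)
    vals = np.full((n, n), float(value))
    np.fill_diagonal(vals, diag)
    return PairwiseLayer(populations=list(pops), values=vals)


class TestRatioSet:
    def test_killerwhale_outlier_layer(self):
        rc = ratio_set(datasets.killerwhale_fst_layer("outlier"), RESIDENTS, TRANSIENTS)
        assert rc.n == 24
        assert round(rc.mean, 2) == 8.18
        assert round(rc.max, 2) == 14.48
        assert rc.min == pytest.approx(2.61, abs=0.01)

    def test_killerwhale_neutral_layer(self):
        rc = ratio_set(datasets.killerwhale_fst_layer("neutral"), RESIDENTS, TRANSIENTS)
        assert rc.n == 24
        assert round(rc.max, 2) == 8.59

    def test_all_equal_layer_gives_unit_ratios(self):
        layer = _uniform_layer(["a", "b", "c", "d"], 0.2)
        rc = ratio_set(layer, ["a", "b"], ["c", "d"])
        np.testing.assert_allclose(rc.ratios, 1.0)
        assert rc.mean == 1.0

    def test_scale_invariance(self):
        layer = datasets.killerwhale_fst_layer("neutral")
        r1 = ratio_set(layer, RESIDENTS, TRANSIENTS)
        r2 = ratio_set(layer.scaled(3.7), RESIDENTS, TRANSIENTS)
        np.testing.assert_allclose(r1.ratios, r2.ratios)

    def test_no_within_pair_rejected(self):
        layer = _uniform_layer(["a", "b"], 0.2)
        with pytest.raises(ValueError):
            ratio_set(layer, ["a"], ["b"])

    def test_pair_bookkeeping(self):
        rc = ratio_set(datasets.killerwhale_fst_layer("outlier"), RESIDENTS, TRANSIENTS)
        assert len(rc.between_pairs) == 6
        assert len(rc.within_pairs) == 4
        assert rc.n == len(rc.between_pairs) * len(rc.within_pairs)


class TestMannWhitney:
    def test_killerwhale_ratio_sets_reproduce_z(self):
        r_neu = ratio_set(datasets.killerwhale_fst_layer("neutral"), RESIDENTS, TRANSIENTS)
        r_out = ratio_set(datasets.killerwhale_fst_layer("outlier"), RESIDENTS, TRANSIENTS)
        res = mann_whitney(r_neu.ratios, r_out.ratios)
        assert round(res.z, 2) == -2.96
        assert res.p == pytest.approx(0.003, abs=0.001)

    def test_identical_sets_z_zero(self):
        res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.z == 0.0
        assert res.p == 1.0

    def test_small_exact_enumeration(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.u == 0.0
        assert res.method == "exact"
        assert res.p == pytest.approx(2 / 6)

    def test_degenerate_all_identical(self):
        res = mann_whitney([2.0, 2.0], [2.0, 2.0])
        assert res.z == 0.0 and res.p == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_p_matches_enumeration_and_scipy(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=5)
        y = rng.normal(size=4) + 0.5
        res = mann_whitney(x, y)
        assert res.method == "exact"
        assert res.p == pytest.approx(mann_whitney_u_enum(list(x), list(y)), abs=1e-9)
        scipy_p = mannwhitneyu(x, y, method="exact").pvalue
        assert res.p == pytest.approx(scipy_p, abs=1e-9)

    def test_normal_approx_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=25)
        y = rng.normal(size=30) + 0.4
        res = mann_whitney(x, y)
        assert res.method == "normal"
        ref = mannwhitneyu(x, y, method="asymptotic", use_continuity=True)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_normal_close_to_exact_for_moderate_samples(self, seed):
        # continuity-corrected normal Z vs the Z implied by the exact p
        rng = np.random.default_rng(seed)
        x = rng.normal(size=8)
        y = rng.normal(size=8) + 0.8
        res = mann_whitney(x, y)
        assert res.method == "exact"
        z_exact = -norm.isf(res.p / 2) if res.z < 0 else norm.isf(res.p / 2)
        assert abs(res.z - z_exact) < 0.1


class TestContingency:
    def test_flat_table_chi2_zero(self):
        layer_n = _uniform_layer(["a", "b", "c", "d"], 10.0)
        layer_o = _uniform_layer(["a", "b", "c", "d"], 10.0)
        res = chi2_contrast(layer_n, layer_o, ["a", "b"], ["c", "d"])
        assert res.chi2 == 0.0
        assert res.fold_ratios[0] == pytest.approx(res.fold_ratios[1])

    def test_hand_built_table_matches_closed_form(self):
        # Yates: chi2 = N (|ad - bc| - N/2)^2 / ((a+b)(c+d)(a+c)(b+d))
        a, b, c, d = 20, 5, 40, 2
        N = a + b + c + d
        expected = N * (abs(a * d - b * c) - N / 2) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d)
        )
        ref = chi2_contingency([[a, b], [c, d]], correction=True)
        assert ref.statistic == pytest.approx(expected)

    def test_yates_never_exceeds_uncorrected(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            t = rng.integers(1, 60, size=(2, 2))
            with_y = chi2_contingency(t, correction=True).statistic
            without = chi2_contingency(t, correction=False).statistic
            assert with_y <= without + 1e-12

    def test_planted_selection_increases_outlier_fold_ratio(self, planted_dataset):
        from popdiff.popgen_stats import allelic_difference_matrix

        _, matrix, popmap, truth = planted_dataset
        labels = truth.loc[matrix.loci["id"]].to_numpy()
        idx_n = np.flatnonzero(labels == "neutral")
        idx_o = np.flatnonzero(np.isin(labels, ["positive", "fixed"]))
        diff_n = allelic_difference_matrix(matrix, popmap, locus_idx=idx_n)
        diff_o = allelic_difference_matrix(matrix, popmap, locus_idx=idx_o)
        res_pops = popmap.populations_of_ecotype("ecotype1")
        tra_pops = popmap.populations_of_ecotype("ecotype2")
        res = chi2_contrast(diff_n, diff_o, res_pops, tra_pops)
        assert res.fold_ratios[1] > res.fold_ratios[0]
        assert res.chi2 > 0

    def test_outgroup_contrast_symmetric_layers_zero(self):
        layer = _uniform_layer(["r1", "r2", "t1", "t2", "o1", "o2"], 8.0)
        res = outgroup_contrast(layer, layer, ["r1", "r2"], ["t1", "t2"], ["o1", "o2"])
        assert res.chi2 == 0.0

    def test_outgroup_contrast_requires_disjoint_groups(self):
        layer = _uniform_layer(["a", "b", "c"], 1.0)
        with pytest.raises(ValueError):
            outgroup_contrast(layer, layer, ["a"], ["a"], ["c"])

    def test_zero_marginal_rejected(self):
        layer0 = _uniform_layer(["a", "b", "c", "d"], 0.0)
        layer1 = _uniform_layer(["a", "b", "c", "d"], 5.0)
        with pytest.raises(ValueError):
            chi2_contrast(layer0, layer0, ["a", "b"], ["c", "d"])
        # one zero row is also degenerate
        with pytest.raises(ValueError):
            chi2_contrast(layer0, layer1, ["a", "b"], ["c", "d"])
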