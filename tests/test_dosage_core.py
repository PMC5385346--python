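from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from xdosage.data_model import DataError, validate_dataset
from xdosage.dosage_core import (compare_distributions, expressed_counts,
                                 fm_exceed_proportions, fm_histogram,
                                 fm_mean_ratio, fm_ratios, group_means,
                                 sexed_xa_test, xa_ratios)


# --- independent enumeration oracles ---------------------------------------

def exact_mw_two_sided_p(a, b):
    """Exact two-sided Mann-Whitney p by enumerating all label assignments."""
    pooled = sorted(list(a) + list(b))
    n, m = len(a), len(b)

    def u_stat(idx_a):
        ua = 0
        set_a = set(idx_a)
        vals_a = [pooled[i] for i in idx_a]
        vals_b = [pooled[i] for i in range(n + m) if i not in set_a]
        for x in vals_a:
            for y in vals_b:
                ua += (x > y) + 0.5 * (x == y)
        return ua

    obs = 0
    for x in a:
        for y in b:
            obs += (x > y) + 0.5 * (x == y)
    us = [u_stat(idx) for idx in combinations(range(n + m), n)]
    total = len(us)
    lo = sum(u <= obs for u in us) / total
    hi = sum(u >= obs for u in us) / total
    return min(1.0, 2 * min(lo, hi))


def exact_ks_p(a, b):
    """Exact two-sample KS p by enumerating all label assignments."""
    pooled = sorted(list(a) + list(b))
    n, m = len(a), len(b)

    def d_stat(vals_a, vals_b):
        grid = sorted(set(vals_a) | set(vals_b))
        return max(abs(sum(v <= g for v in vals_a) / n
                       - sum(v <= g for v in vals_b) / m) for g in grid)

    obs = d_stat(list(a), list(b))
    count = total = 0
    for idx in combinations(range(n + m), n):
        set_a = set(idx)
        va = [pooled[i] for i in idx]
        vb = [pooled[i] for i in range(n + m) if i not in set_a]
        total += 1
        if d_stat(va, vb) >= obs - 1e-12:
            count += 1
    return count / total


# --- group means / ratios ---------------------------------------------------

class TestGroupMeans:
    def test_single_sample_cells_return_that_sample(self, tiny_dataset):
        one = validate_dataset(tiny_dataset.annotation,
                               tiny_dataset.matrix.iloc[:, [0, 2]],
                               tiny_dataset.samples.iloc[[0, 2]])
        means = group_means(one)
        assert means[("male", "IVF")].equals(one.matrix["IVF_m_1"])

    def test_hand_table_means(self, tiny_dataset):
        means = group_means(tiny_dataset)
        # gA2: male {4, 6} -> 5; female {4, 6} -> 5 ; gX2: male 2, female 4
        assert means.loc["gA2", ("male", "IVF")] == 5.0
        assert means.loc["gX2", ("female", "IVF")] == 4.0
        assert means.loc["gY1", ("female", "IVF")] == 0.0


class TestFmRatios:
    def test_log2_values(self, tiny_dataset):
        fm = fm_ratios(group_means(tiny_dataset), "IVF")
        assert fm.loc["gA1", "log2_fm"] == 0.0           # 10 vs 10
        assert fm.loc["gX2", "log2_fm"] == 1.0           # 4 vs 2
        assert np.isnan(fm.loc["gY1", "log2_fm"])        # male only
        assert np.isnan(fm.loc["gX1", "log2_fm"])        # female only

    def test_pseudocount_defines_all_ratios(self, tiny_dataset):
        fm = fm_ratios(group_means(tiny_dataset), "IVF", pseudocount=0.01)
        assert fm["log2_fm"].notna().all()

    def test_filter_flag_uses_larger_sex_mean(self, tiny_dataset):
        fm = fm_ratios(group_means(tiny_dataset), "IVF", min_fpkm=4.5)
        assert bool(fm.loc["gA2", "passes_min_fpkm"])    # max(5,5) > 4.5
        assert not bool(fm.loc["gX2", "passes_min_fpkm"])  # max(4,2)

    def test_missing_sex_is_hard_error(self, tiny_dataset):
        males = validate_dataset(tiny_dataset.annotation,
                                 tiny_dataset.matrix.iloc[:, :2],
                                 tiny_dataset.samples.iloc[:2])
        with pytest.raises(DataError):
            fm_ratios(group_means(males), "IVF")


class TestFmMeanRatio:
    def test_identical_sexes_give_unity(self, tiny_dataset):
        ds = tiny_dataset
        sym = ds.matrix.copy()
        sym[["IVF_f_1", "IVF_f_2"]] = sym[["IVF_m_1", "IVF_m_2"]].values
        ds2 = validate_dataset(ds.annotation, sym, ds.samples)
        val = fm_mean_ratio(group_means(ds2), "IVF", ds2.annotation,
                            gene_class="autosomal", min_fpkm=1.0)
        assert val == pytest.approx(1.0)

    def test_aggregate_of_hand_means(self):
        # females {2, 4}, males {1, 2} -> (3)/(1.5) = 2.0
        means = pd.DataFrame({("female", "G"): [2.0, 4.0],
                              ("male", "G"): [1.0, 2.0]},
                             index=["g1", "g2"])
        means.columns = pd.MultiIndex.from_tuples(means.columns,
                                                  names=["sex", "group"])
        assert fm_mean_ratio(means, "G", min_fpkm=0.5) == pytest.approx(2.0)

    def test_invariant_under_gene_reordering(self, small_ivf_dataset):
        ds = small_ivf_dataset
        means = group_means(ds)
        shuffled = means.sample(frac=1.0, random_state=0)
        a = fm_mean_ratio(means, "IVF", ds.annotation)
        b = fm_mean_ratio(shuffled, "IVF", ds.annotation.loc[shuffled.index])
        assert a == pytest.approx(b)

    def test_sex_label_swap_inverts_log2_ratios(self, tiny_dataset):
        ds = tiny_dataset
        swapped = ds.samples.copy()
        swapped["sex"] = swapped["sex"].map({"male": "female",
                                             "female": "male"})
        ds2 = validate_dataset(ds.annotation, ds.matrix, swapped)
        fm1 = fm_ratios(group_means(ds), "IVF", pseudocount=0.01)
        fm2 = fm_ratios(group_means(ds2), "IVF", pseudocount=0.01)
        assert np.allclose(fm1["log2_fm"], -fm2["log2_fm"])


class TestXaRatios:
    def test_uniform_expression_gives_unity(self, tiny_dataset):
        ds = tiny_dataset
        flat = ds.matrix.copy()
        flat.loc[:, :] = 3.0
        ds2 = validate_dataset(ds.annotation, flat, ds.samples)
        xa = xa_ratios(ds2)
        assert np.allclose(xa["xa_ratio"], 1.0)

    def test_hand_arithmetic(self, tiny_dataset):
        # female sample 1: X expressed {50, 4} -> 27; A {10, 4} -> 7
        xa = xa_ratios(tiny_dataset, expressed_min_fpkm=0.1)
        assert xa.loc["IVF_f_1", "xa_ratio"] == pytest.approx(27.0 / 7.0)
        # male sample 1: X expressed {2} (XIST 0); A {10, 4} -> 7
        assert xa.loc["IVF_m_1", "xa_ratio"] == pytest.approx(2.0 / 7.0)

    def test_scale_invariance_per_sample(self, tiny_dataset):
        ds = tiny_dataset
        scaled = ds.matrix.copy()
        scaled["IVF_f_1"] *= 17.0
        ds2 = validate_dataset(ds.annotation, scaled, ds.samples)
        a = xa_ratios(ds)
        b = xa_ratios(ds2)
        assert b.loc["IVF_f_1", "xa_ratio"] == pytest.approx(
            a.loc["IVF_f_1", "xa_ratio"])


class TestFmHistogram:
    def test_hand_binning(self):
        fm = pd.DataFrame({"female_mean": [1.0] * 3, "male_mean": [1.0] * 3,
                           "log2_fm": [-0.1, 0.1, 0.3],
                           "passes_min_fpkm": [True] * 3})
        hist = fm_histogram(fm)
        lookup = dict(zip(hist["bin_left"].round(6), hist["count"]))
        assert lookup == {-0.2: 1, 0.0: 1, 0.2: 1}

    def test_all_zero_ratios_fall_in_first_nonnegative_bin(self):
        fm = pd.DataFrame({"female_mean": [1.0] * 4, "male_mean": [1.0] * 4,
                           "log2_fm": [0.0] * 4,
                           "passes_min_fpkm": [True] * 4})
        hist = fm_histogram(fm)
        assert len(hist) == 1
        assert hist.loc[0, "bin_left"] == 0.0
        assert hist.loc[0, "count"] == 4

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.lists(st.floats(-8, 8, allow_nan=False), min_size=1,
                    max_size=200))
    def test_counts_conserve_defined_ratios(self, values):
        fm = pd.DataFrame({"female_mean": 1.0, "male_mean": 1.0,
                           "log2_fm": values,
                           "passes_min_fpkm": True},
                          index=range(len(values)))
        assert fm_histogram(fm)["count"].sum() == len(values)


class TestCompareDistributions:
    def test_identical_lists_have_zero_ks_statistic(self):
        res = compare_distributions([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.ks_statistic == 0.0

    def test_separated_lists_match_enumeration_oracle(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        res = compare_distributions(a, b)
        assert res.mw_statistic == 0.0
        assert res.mw_p == pytest.approx(0.1)        # 2 / C(6,3)
        assert res.mw_p == pytest.approx(exact_mw_two_sided_p(a, b))
        assert res.ks_p == pytest.approx(exact_ks_p(a, b))

    def test_random_small_samples_match_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            a = rng.normal(size=5)
            b = rng.normal(0.8, size=6)
            res = compare_distributions(a, b)
            assert res.mw_p == pytest.approx(exact_mw_two_sided_p(a, b))
            assert res.ks_p == pytest.approx(exact_ks_p(a, b))

    def test_degenerate_ties_return_p_one_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = compare_distributions([2.0] * 5, [2.0] * 5)
        assert res.mw_p == 1.0


class TestSexedXaTest:
    def make_xa(self, female, male):
        vals = list(female) + list(male)
        idx = [f"f{i}" for i in range(len(female))] + \
              [f"m{i}" for i in range(len(male))]
        xa = pd.DataFrame({"xa_ratio": vals}, index=idx)
        samples = pd.DataFrame({
            "sex": ["female"] * len(female) + ["male"] * len(male),
            "group": "IVF"}, index=idx)
        return xa, samples

    def test_identical_lists_give_p_one(self):
        xa, samples = self.make_xa([0.5, 0.6, 0.7], [0.7, 0.5, 0.6])
        assert sexed_xa_test(xa, samples, "IVF") == 1.0

    def test_fully_separated_lists_reject(self):
        xa, samples = self.make_xa([0.9, 1.1, 0.95, 1.05, 0.92, 1.08],
                                   [0.4, 0.5, 0.45, 0.42, 0.52, 0.48])
        p = sexed_xa_test(xa, samples, "IVF")
        assert p < 0.01
        f = [0.9, 1.1, 0.95, 1.05, 0.92, 1.08]
        m = [0.4, 0.5, 0.45, 0.42, 0.52, 0.48]
        assert p == pytest.approx(exact_mw_two_sided_p(f, m))

    def test_too_few_samples_error(self):
        xa, samples = self.make_xa([1.0], [0.5, 0.6])
        with pytest.raises(DataError):
            sexed_xa_test(xa, samples, "IVF")


class TestExpressedCounts:
    def make_means(self, male, female):
        means = pd.DataFrame({("male", "IVF"): male, ("female", "IVF"): female},
                             index=[f"g{i}" for i in range(len(male))])
        means.columns = pd.MultiIndex.from_tuples(means.columns,
                                                  names=["sex", "group"])
        ann = pd.DataFrame({"chrom_class": "x_linked"}, index=means.index)
        return means, ann

    def test_hand_count_pooling_sexes_by_max(self):
        means, ann = self.make_means([0.0, 0.05, 0.2, 3.0],
                                     [0.0, 0.05, 0.05, 0.0])
        assert expressed_counts(means, ann, threshold=0.1) == {"IVF": 2}

    def test_count_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        vals = rng.exponential(1.0, 50)
        means, ann = self.make_means(vals, vals[::-1])
        counts = [expressed_counts(means, ann, threshold=t)["IVF"]
                  for t in (0.0, 0.1, 0.5, 1.0, 5.0)]
        assert counts == sorted(counts, reverse=True)


class TestFmExceedProportions:
    def test_ratios_exactly_one_never_exceed(self):
        fm = pd.DataFrame({"female_mean": [2.0] * 3, "male_mean": [2.0] * 3,
                           "log2_fm": [0.0] * 3, "passes_min_fpkm": True})
        assert fm_exceed_proportions(fm)[1.0] == 0.0

    def test_hand_proportions(self):
        f = np.array([0.5, 1.5, 2.5, 3.0])
        fm = pd.DataFrame({"female_mean": f, "male_mean": np.ones(4),
                           "log2_fm": np.log2(f), "passes_min_fpkm": True})
        props = fm_exceed_proportions(fm)
        assert props[1.0] == pytest.approx(0.75)
        assert props[2.0] == pytest.approx(0.50)
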