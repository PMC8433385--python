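import numpy as np
import pytest
from scipy import stats as sps

from acoustocalib.errors import ValidationError
from acoustocalib.stats import one_way_anova, scheffe_posthoc, viability_test


def gaussian_groups(rng, means, n=20, sd=1.0):
    return {f"g{i}": rng.normal(m, sd, n) for i, m in enumerate(means)}


class TestAnova:
    def test_equal_means_give_f_zero_p_one(self):
        g = {"a": [1.0, 2.0, 3.0], "b": [3.0, 2.0, 1.0]}
        res = one_way_anova(g)
        assert res.F == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_within_variance_guarded(self):
        res = one_way_anova({"a": [0.0, 0.0], "b": [1.0, 1.0]})
        assert np.isinf(res.F)
        assert res.p_value == 0.0

    def test_all_identical_rejected(self):
        with pytest.raises(ValidationError):
            one_way_anova({"a": [1.0, 1.0], "b": [1.0, 1.0]})

    def test_matches_textbook_formula_and_scipy(self):
        rng = np.random.default_rng(5)
        g = gaussian_groups(rng, [0.0, 0.3, 0.6])
        res = one_way_anova(g)
        # independent oracle 1: direct textbook computation
        data = [np.asarray(v) for v in g.values()]
        grand = np.concatenate(data).mean()
        ssb = sum(len(x) * (x.mean() - grand) ** 2 for x in data)
        ssw = sum(((x - x.mean()) ** 2).sum() for x in data)
        F_oracle = (ssb / 2) / (ssw / (sum(map(len, data)) - 3))
        assert res.F == pytest.approx(F_oracle, abs=1e-9)
        # independent oracle 2: scipy's implementation
        F_sp, p_sp = sps.f_oneway(*data)
        assert res.F == pytest.approx(F_sp, rel=1e-9)
        assert res.p_value == pytest.approx(p_sp, rel=1e-9)

    def test_sum_of_squares_identity(self):
        rng = np.random.default_rng(6)
        g = gaussian_groups(rng, [0.0, 0.5, 1.0, 1.5], n=13)
        res = one_way_anova(g)
        all_values = np.concatenate(list(g.values()))
        ss_total = ((all_values - all_values.mean()) ** 2).sum()
        assert res.ss_between + res.ss_within == pytest.approx(ss_total, abs=1e-9)

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError, match=">=2"):
            one_way_anova({"a": [1.0], "b": [1.0, 2.0]})


class TestScheffe:
    def test_identical_pair_means_not_significant(self):
        g = {"a": [1.0, 2.0, 3.0], "b": [3.0, 2.0, 1.0], "c": [0.0, 2.0, 4.0]}
        res = one_way_anova(g)
        pairs = scheffe_posthoc(g, res)
        ab = next(p for p in pairs if set(p.labels) == {"a", "b"})
        assert ab.p_value == pytest.approx(1.0)
        assert not ab.significant

    def test_never_more_liberal_than_omnibus(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            g = gaussian_groups(rng, rng.normal(0, 0.3, 3), n=8)
            res = one_way_anova(g)
            pairs = scheffe_posthoc(g, res)
            assert all(p.p_value >= res.p_value - 1e-12 for p in pairs)
            if res.p_value > 0.05:
                assert not any(p.significant for p in pairs)

    def test_pairwise_p_not_below_unadjusted_contrast(self):
        # the unadjusted single-contrast test uses the same omnibus MSE and
        # refers F_ij to F(1, N−k); Scheffé divides by k−1, so its p can
        # never be smaller
        rng = np.random.default_rng(9)
        for _ in range(25):
            g = gaussian_groups(rng, rng.normal(0, 0.4, 3), n=10)
            res = one_way_anova(g)
            for pair in scheffe_posthoc(g, res):
                p_unadjusted = sps.f.sf(pair.F_scheffe, 1, res.df_within)
                assert pair.p_value >= p_unadjusted - 1e-12

    def test_mismatched_groups_rejected(self):
        g = {"a": [1.0, 2.0], "b": [3.0, 4.0]}
        res = one_way_anova(g)
        with pytest.raises(ValidationError, match="match"):
            scheffe_posthoc({"a": [1.0, 2.0], "c": [3.0, 4.0]}, res)

    def test_unequal_n_supported(self):
        rng = np.random.default_rng(10)
        g = {"a": rng.normal(0, 1, 5), "b": rng.normal(2, 1, 12), "c": rng.normal(0, 1, 8)}
        res = one_way_anova(g)
        pairs = scheffe_posthoc(g, res)
        assert len(pairs) == 3
        assert all(0 <= p.p_value <= 1 for p in pairs)

    def test_permutation_p_agrees_on_small_instance(self):
        # brute-force permutation null for the omnibus F, 2 groups of 5
        rng = np.random.default_rng(12)
        a, b = rng.normal(0, 1, 5), rng.normal(1.0, 1, 5)
        res = one_way_anova({"a": a, "b": b})
        pooled = np.concatenate([a, b])
        count = 0
        n_perm = 4000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            f = one_way_anova({"a": perm[:5], "b": perm[5:]}).F
            count += f >= res.F
        p_perm = count / n_perm
        assert p_perm == pytest.approx(res.p_value, abs=0.05)


class TestViability:
    def test_identical_arms(self):
        x = [1.0, 1.1, 0.9, 1.05]
        res = viability_test(x, x)
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.normalized_mean == pytest.approx(np.mean(x) / np.mean(x))

    def test_doubled_fluorescence_detected(self):
        before = np.array([0.9, 1.0, 1.1, 1.05, 0.95])
        res = viability_test(before, 2 * before)
        assert res.normalized_mean == pytest.approx(2.0, rel=1e-9)
        assert res.p_value < 1e-4
        assert res.significant

    def test_non_positive_baseline_rejected(self):
        with pytest.raises(ValidationError):
            viability_test([-1.0, 1.0], [1.0, 1.0])

    def test_welch_flag_runs(self):
        rng = np.random.default_rng(13)
        res = viability_test(rng.normal(1, 0.04, 20), rng.normal(1, 0.08, 20), welch=True)
        assert 0 <= res.p_value <= 1
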