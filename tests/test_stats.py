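"""Statistics tests: textbook-formula oracles, ROUT behaviour, simulation calibration."""

import math
import warnings

import numpy as np
import pytest

import turnoverlab as tl
from turnoverlab.stats import compare_groups, mean_sem


def hand_paired_t(x, y):
    """Textbook paired t: t = mean(d) / (sd(d)/sqrt(n)), two-tailed p from t(n-1)."""
    from scipy.stats import t as tdist
    d = np.asarray(x) - np.asarray(y)
    n = d.size
    t = d.mean() / (d.std(ddof=1) / math.sqrt(n))
    p = 2 * tdist.sf(abs(t), df=n - 1)
    return t, p


def hand_pearson(x, y):
    """Textbook Pearson r and its t-based two-tailed p."""
    from scipy.stats import t as tdist
    x, y = np.asarray(x), np.asarray(y)
    r = np.sum((x - x.mean()) * (y - y.mean())) / math.sqrt(
        np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
    n = x.size
    t = r * math.sqrt((n - 2) / (1 - r * r))
    return r, 2 * tdist.sf(abs(t), df=n - 2)


class TestAgainstTextbookFormulas:
    def test_paired_t_matches_hand_formula(self, rng):
        for _ in range(20):
            n = rng.integers(5, 30)
            x = rng.normal(1.0, 0.5, n)
            y = x + rng.normal(0.2, 0.3, n)
            t, p = tl.paired_t(x, y)
            t0, p0 = hand_paired_t(x, y)
            assert t == pytest.approx(t0, rel=1e-10)
            assert p == pytest.approx(p0, rel=1e-10)

    def test_pearson_matches_hand_formula(self, rng):
        for _ in range(20):
            n = rng.integers(5, 30)
            x = rng.normal(0.0, 1.0, n)
            y = 0.5 * x + rng.normal(0.0, 1.0, n)
            r, p = tl.pearson_r(x, y)
            r0, p0 = hand_pearson(x, y)
            assert r == pytest.approx(r0, rel=1e-10)
            assert p == pytest.approx(p0, rel=1e-10)

    def test_sem_on_three_point_fixture(self):
        mean, sem = mean_sem([1.0, 2.0, 3.0])
        assert mean == 2.0
        assert sem == pytest.approx(1.0 / math.sqrt(3), rel=1e-12)


class TestPairedTDegenerate:
    def test_identical_samples_convention(self):
        with pytest.warns(UserWarning, match="identical"):
            t, p = tl.paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_constant_nonzero_shift_signalled(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            t, p = tl.paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert math.isinf(t) and t > 0 and p == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tl.paired_t([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_shifted_pairs_detected(self):
        # n=14 pairs, unit shift, difference sd 0.5: overwhelmingly significant
        hits = 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            x = r.normal(0.0, 1.0, 14)
            y = x + 1.0 + r.normal(0.0, 0.5, 14)
            _, p = tl.paired_t(y, x)
            hits += p < 0.001
        assert hits >= 48  # >= 95 % of seeds


class TestNormalityScreen:
    def test_null_rarely_rejected(self):
        ok = sum(
            tl.ks_normality(np.random.default_rng(s).normal(0, 1, 1000)) > 0.05
            for s in range(100))
        assert ok >= 90

    def test_gross_violation_rejected(self):
        p = tl.ks_normality(np.random.default_rng(3).exponential(1.0, 1000))
        assert p < 0.05

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValueError):
            tl.ks_normality([1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            tl.ks_normality([1.0, 2.0])


class TestPearsonBehaviour:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        r, p = tl.pearson_r(x, 2 * x + 3)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_independent_samples_near_zero(self, rng):
        x, y = rng.normal(0, 1, 5000), rng.normal(0, 1, 5000)
        r, _ = tl.pearson_r(x, y)
        assert abs(r) < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            tl.pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_recovers_coupling_at_study_size(self):
        # RNA fraction new coupled to synthesis (true rho 0.85) at n = 14:
        # estimated r lands in a credible band around the truth
        rs = []
        for seed in range(40):
            r = np.random.default_rng(seed)
            latent = r.normal(0, 1, 14)
            x = latent + r.normal(0, math.sqrt(1 / 0.85**2 - 1), 14)
            rs.append(tl.pearson_r(x, latent)[0])
        assert 0.7 <= np.median(rs) <= 0.95


class TestRout:
    def test_gross_outlier_flagged_small_sample(self):
        keep = tl.rout_outliers([1.0, 1.1, 0.9, 1.05, 12.0], q=1.0)
        np.testing.assert_array_equal(keep, [True, True, True, True, False])

    def test_hand_computed_reference_procedure(self):
        # median 1.05; abs residuals (0.05, 0.05, 0.15, 0, 10.95);
        # RSDR = 68.27th pct * n/(n-1) = 0.12308 * 1.25; only 12.0 survives BH at Q=1 %
        x = np.array([1.0, 1.1, 0.9, 1.05, 12.0])
        resid = np.abs(x - np.median(x))
        rsdr = np.percentile(resid, 68.27) * 5 / 4
        assert rsdr == pytest.approx(0.15385, abs=1e-4)
        keep = tl.rout_outliers(x, q=1.0)
        assert list(np.flatnonzero(~keep)) == [4]

    def test_clean_sample_all_kept(self, rng):
        keep = tl.rout_outliers(rng.normal(1.0, 0.1, 12), q=1.0)
        assert keep.all()

    def test_symmetric_about_median(self, rng):
        x = rng.normal(0.0, 1.0, 15)
        x[3] = 9.0
        mirrored = 2 * np.median(x) - x
        np.testing.assert_array_equal(
            tl.rout_outliers(x, 1.0), tl.rout_outliers(mirrored, 1.0))

    def test_null_false_outlier_rate(self):
        # outlier-free normal data: flags at most ceil(Q% n)+1 points nearly always
        n, bound, bad = 20, math.ceil(0.01 * 20) + 1, 0
        for seed in range(200):
            x = np.random.default_rng(seed).normal(0, 1, n)
            bad += (~tl.rout_outliers(x, q=1.0)).sum() > bound
        assert bad <= 2  # >= 99 % of seeds within bound

    def test_preconditions(self):
        with pytest.raises(ValueError):
            tl.rout_outliers([1.0, 2.0, 3.0], q=1.0)
        with pytest.raises(ValueError):
            tl.rout_outliers([1.0, 2.0, 3.0, 4.0], q=0.0)


class TestCompareGroups:
    def test_paired_outlier_removes_the_pair(self):
        a = np.array([1.0, 1.1, 0.9, 1.05, 30.0, 1.02])
        b = np.array([1.2, 1.3, 1.1, 1.25, 1.22, 1.18])
        ids = [f"s{i}" for i in range(6)]
        gc = compare_groups("k", "collagen", "denervated", a, "sham", b,
                            paired=True, subject_ids_a=ids, rout_q=1.0)
        assert gc.outliers_removed == ("s4",)
        assert gc.n_a == gc.n_b == 5

    def test_unpaired_and_percent_difference(self):
        gc = compare_groups("fsr", "myofibrillar", "denervated", [1.4, 1.5, 1.6],
                            "nonsurgical", [2.2, 2.3, 2.4], paired=False)
        assert gc.mean_a == pytest.approx(1.5)
        assert gc.pct_difference == pytest.approx(100 * (2.3 - 1.5) / 2.3)
        assert gc.p < 0.01
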