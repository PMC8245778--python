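import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from endocorr import km_estimate, logrank_test, median_split
from endocorr.ce_association import CE_HIGH, CE_LOW
from endocorr.errors import ConfigError, DataError, FitError
from endocorr.survival import (
    age_subgroup_analysis,
    compare_groups,
    compare_ratio_by_subtype,
    cox_fit,
    cox_score_test,
)


def _features(ratios, ids=None):
    ids = ids or [f"S{i:03d}" for i in range(len(ratios))]
    return pd.DataFrame(
        {"ratio": ratios}, index=pd.Index(ids, name="sample_id")
    )


def _clinical(times, events, ages=None, subtypes=None, ids=None):
    n = len(times)
    ids = ids or [f"S{i:03d}" for i in range(n)]
    return pd.DataFrame(
        {
            "os_time": times,
            "os_event": events,
            "age": ages if ages is not None else [55.0] * n,
            "subtype": subtypes if subtypes is not None else ["unknown"] * n,
        },
        index=pd.Index(ids, name="sample_id"),
    )


class TestMedianSplit:
    def test_clean_even_split(self):
        ga = median_split(_features([0.1, 0.2, 0.8, 0.9]))
        assert ga.samples(CE_LOW) == ["S000", "S001"]
        assert ga.samples(CE_HIGH) == ["S002", "S003"]

    def test_median_tie_assigned_low(self):
        ga = median_split(_features([0.1, 0.5, 0.9]))
        assert "S001" in ga.samples(CE_LOW)

    def test_all_identical_rejected(self):
        with pytest.raises(DataError, match="identical"):
            median_split(_features([0.5, 0.5, 0.5]))

    def test_matches_bruteforce_comparison_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 40))
            ratios = rng.choice([0.1, 0.3, 0.5, 0.7], size=n)
            if len(set(ratios)) == 1:
                continue
            feats = _features(ratios)
            ga = median_split(feats)
            med = float(np.median(ratios))
            for sid, r in feats["ratio"].items():
                expected = CE_HIGH if r > med else CE_LOW
                assert ga.groups[sid] == expected
            n_tied = int(np.sum(ratios == med))
            sizes = ga.groups.value_counts()
            # |#below - #above| <= ties, plus the tied block itself goes low
            assert (
                abs(sizes.get(CE_HIGH, 0) - sizes.get(CE_LOW, 0))
                <= max(1, 2 * n_tied)
            )


class TestKaplanMeier:
    def test_no_censoring_empirical_survival(self):
        km = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])

    def test_all_censored_is_flat_one(self):
        km = km_estimate([5.0, 7.0, 9.0], [0, 0, 0])
        assert km.times.size == 0
        assert km.n_subjects == 3

    def test_hand_product_limit_worked_example(self):
        # subjects: 1 (event), 2 (censored), 3 (event), 4 (event)
        km = km_estimate([1.0, 2.0, 3.0, 4.0], [1, 0, 1, 1])
        np.testing.assert_allclose(km.times, [1.0, 3.0, 4.0])
        np.testing.assert_allclose(km.survival, [3 / 4, 3 / 8, 0.0])
        np.testing.assert_array_equal(km.n_risk, [4, 2, 1])

    def test_nonpositive_time_rejected(self):
        with pytest.raises(DataError, match="positive"):
            km_estimate([0.0, 1.0], [1, 1])

    def test_monotone_in_unit_interval_and_median(self, rng):
        t = rng.exponential(10, size=60)
        e = rng.integers(0, 2, size=60)
        if e.sum() == 0:
            e[0] = 1
        km = km_estimate(t, e)
        assert np.all(np.diff(km.survival) <= 1e-15)
        assert np.all((km.survival >= 0) & (km.survival <= 1))
        if not math.isnan(km.median_time):
            assert km.survival[km.times == km.median_time][0] <= 0.5


def oracle_logrank(ta, ea, tb, eb):
    """Definitional hypergeometric sum over distinct event times."""
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    grp = np.concatenate([np.zeros(len(ta)), np.ones(len(tb))])
    O = E = V = 0.0
    for u in sorted(set(t[e == 1])):
        n = np.sum(t >= u)
        n1 = np.sum((t >= u) & (grp == 0))
        d = np.sum((t == u) & (e == 1))
        d1 = np.sum((t == u) & (e == 1) & (grp == 0))
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = (O - E) ** 2 / V
    return chi2, stats.chi2.sf(chi2, 1)


class TestLogrank:
    def test_identical_groups(self):
        t, e = [1.0, 2.0, 3.0], [1, 0, 1]
        res = logrank_test(t, e, t, e)
        assert res.chi2 == 0.0
        assert res.p == 1.0

    def test_six_subject_bruteforce_oracle(self):
        ta, ea = np.array([1.0, 4.0, 6.0]), np.array([1, 1, 0])
        tb, eb = np.array([2.0, 3.0, 5.0]), np.array([1, 0, 1])
        res = logrank_test(ta, ea, tb, eb)
        chi2, p = oracle_logrank(ta, ea, tb, eb)
        assert abs(res.chi2 - chi2) < 1e-12
        assert abs(res.p - p) < 1e-12

    def test_random_data_matches_oracle(self, rng):
        for _ in range(20):
            ta = rng.exponential(5, size=15).round(1) + 0.1
            tb = rng.exponential(8, size=12).round(1) + 0.1
            ea = rng.integers(0, 2, size=15)
            eb = rng.integers(0, 2, size=12)
            if ea.sum() + eb.sum() == 0:
                continue
            res = logrank_test(ta, ea, tb, eb)
            chi2, _ = oracle_logrank(ta, ea, tb, eb)
            assert abs(res.chi2 - chi2) < 1e-10

    def test_symmetry(self, rng):
        ta = rng.exponential(5, size=20)
        tb = rng.exponential(5, size=20)
        ea = np.ones(20, int)
        eb = np.ones(20, int)
        r1 = logrank_test(ta, ea, tb, eb)
        r2 = logrank_test(tb, eb, ta, ea)
        assert abs(r1.chi2 - r2.chi2) < 1e-12
        assert abs(r1.p - r2.p) < 1e-12

    def test_no_events_reported_missing(self):
        res = logrank_test([1.0, 2.0], [0, 0], [3.0], [0])
        assert not res.defined


class TestCox:
    def test_constant_covariate_rejected(self):
        with pytest.raises(ConfigError, match="constant"):
            cox_fit([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1], [1.0, 1.0, 1.0, 1.0])

    def test_score_test_equals_logrank_on_tiefree_data(self, rng):
        for _ in range(10):
            n = 40
            x = rng.integers(0, 2, size=n).astype(float)
            if x.std() == 0:
                continue
            t = rng.exponential(10 * np.exp(-0.5 * x))
            t = t + rng.uniform(0, 1e-6, size=n)  # guarantee no ties
            e = (rng.uniform(size=n) > 0.2).astype(int)
            if e.sum() < 2:
                continue
            chi2, _ = cox_score_test(t, e, x)
            lr = logrank_test(t[x == 1], e[x == 1], t[x == 0], e[x == 0])
            assert abs(chi2 - lr.chi2) < 1e-9

    def test_recovers_true_hazard_ratio(self):
        g = np.random.default_rng(2024)
        n = 500
        x = g.integers(0, 2, size=n).astype(float)
        t = g.exponential(1.0 / (0.1 * 2.0**x))
        c = g.exponential(1.0 / (0.1 * 2.0**x) / 0.45)  # ~30% censoring
        times = np.minimum(t, c)
        events = (t <= c).astype(int)
        res = cox_fit(times, events, x, names=["grp"])
        hr = res.hr[0]
        assert res.ci_low[0] <= 2.0 <= res.ci_high[0]
        assert 1.6 <= hr <= 2.5

    def test_matches_lifelines_on_tied_data(self, rng):
        lifelines = pytest.importorskip("lifelines")
        n = 120
        x1 = rng.integers(0, 2, size=n).astype(float)
        x2 = rng.normal(60, 10, size=n)
        t = np.ceil(rng.exponential(20 * np.exp(-0.4 * x1), size=n))  # ties
        e = (rng.uniform(size=n) > 0.3).astype(int)
        res = cox_fit(t, e, np.column_stack([x1, x2]), names=["x1", "x2"])
        df = pd.DataFrame({"t": t, "e": e, "x1": x1, "x2": x2})
        cph = lifelines.CoxPHFitter()
        cph.fit(df, duration_col="t", event_col="e")
        np.testing.assert_allclose(
            res.coef, cph.params_[["x1", "x2"]].to_numpy(), atol=1e-6
        )
        np.testing.assert_allclose(
            res.se,
            cph.standard_errors_[["x1", "x2"]].to_numpy(),
            atol=1e-5,
        )

    def test_perfect_separation_raises_fit_error(self):
        # group 0 all fails early, group 1 all later: monotone likelihood
        t = np.concatenate([np.arange(1, 11), np.arange(100, 110)]).astype(float)
        e = np.ones(20, int)
        x = np.concatenate([np.ones(10), np.zeros(10)])
        with pytest.raises(FitError):
            cox_fit(t, e, x)

    def test_null_ci_coverage(self):
        # Wald 95% CI covers beta=0 between 92% and 97% of null replicates
        g = np.random.default_rng(99)
        cover = 0
        n_rep = 2000
        for _ in range(n_rep):
            n = 60
            x = g.integers(0, 2, size=n).astype(float)
            te = g.exponential(10.0, size=n)
            c = g.exponential(40.0, size=n)
            times = np.minimum(te, c)
            events = (te <= c).astype(int)
            try:
                res = cox_fit(times, events, x)
            except FitError:
                continue
            if res.ci_low[0] <= 1.0 <= res.ci_high[0]:
                cover += 1
        assert 0.92 <= cover / n_rep <= 0.97

    def test_coefficient_sign_matches_km_ordering(self, rng):
        n = 100
        x = rng.integers(0, 2, size=n).astype(float)
        t = rng.exponential(1.0 / (0.05 * 3.0**x)) + rng.uniform(
            0, 1e-9, size=n
        )
        e = np.ones(n, int)
        res = cox_fit(t, e, x)
        km1 = km_estimate(t[x == 1], e[x == 1])
        km0 = km_estimate(t[x == 0], e[x == 0])
        assert res.coef[0] > 0  # x=1 has higher hazard
        assert km1.median_time < km0.median_time


class TestCohortComparisons:
    def test_compare_groups_smoke(self, rng):
        n = 60
        feats = _features(rng.uniform(size=n))
        clin = _clinical(
            rng.exponential(300, size=n) + 1.0,
            rng.integers(0, 2, size=n),
            ages=rng.normal(60, 8, size=n),
        )
        comp = compare_groups(median_split(feats), clin)
        assert set(comp.km_curves) == {CE_HIGH, CE_LOW}
        assert comp.logrank.defined
        assert comp.cox is not None and comp.cox.names == ["ce_high", "age"]

    def test_age_subgroup_all_young_marks_older_not_evaluable(self, rng):
        n = 30
        feats = _features(rng.uniform(size=n))
        clin = _clinical(
            rng.exponential(300, size=n) + 1.0,
            np.ones(n, int),
            ages=np.full(n, 45.0),
        )
        out = age_subgroup_analysis(feats, clin, cutoff=60)
        assert out["younger"].evaluable
        assert not out["older"].evaluable

    def test_age_subgroups_identical_data_identical_stats(self, rng):
        n = 40
        ratios = rng.uniform(size=n)
        times = rng.exponential(300, size=n) + 1.0
        events = rng.integers(0, 2, size=n)
        events[0] = 1
        young = _clinical(times, events, ages=np.full(n, 40.0))
        old = _clinical(
            times, events, ages=np.full(n, 70.0),
            ids=[f"T{i:03d}" for i in range(n)],
        )
        feats = pd.concat(
            [_features(ratios), _features(ratios, ids=list(old.index))]
        )
        out = age_subgroup_analysis(feats, pd.concat([young, old]), cutoff=60)
        assert abs(out["younger"].logrank.chi2 - out["older"].logrank.chi2) < 1e-12


class TestSubtypeComparison:
    def test_identical_pools(self):
        feats = _features([0.4, 0.4, 0.4, 0.4])
        clin = _clinical(
            [10.0] * 4, [1] * 4,
            subtypes=["mesenchymal", "mesenchymal", "proneural", "neural"],
        )
        res = compare_ratio_by_subtype(feats, clin)
        assert res.t == 0.0 and res.p == 1.0

    def test_degenerate_variance_flagged(self):
        feats = _features([0.0, 0.0, 1.0, 1.0])
        clin = _clinical(
            [10.0] * 4, [1] * 4,
            subtypes=["mesenchymal", "mesenchymal", "proneural", "neural"],
        )
        res = compare_ratio_by_subtype(feats, clin)
        assert res.infinite_separation
        assert math.isnan(res.t)

    def test_small_pool_rejected(self):
        feats = _features([0.1, 0.2, 0.3])
        clin = _clinical(
            [10.0] * 3, [1] * 3,
            subtypes=["mesenchymal", "proneural", "neural"],
        )
        with pytest.raises(DataError):
            compare_ratio_by_subtype(feats, clin)

    def test_matches_formula_oracle(self, rng):
        for _ in range(20):
            na, nb = int(rng.integers(2, 15)), int(rng.integers(2, 15))
            a = rng.uniform(size=na)
            b = rng.uniform(size=nb)
            feats = _features(np.concatenate([a, b]))
            clin = _clinical(
                [10.0] * (na + nb), [1] * (na + nb),
                subtypes=["mesenchymal"] * na + ["classical"] * nb,
            )
            res = compare_ratio_by_subtype(feats, clin)
            t_ref, p_ref = stats.ttest_ind(a, b, equal_var=True)
            assert abs(res.t - t_ref) < 1e-10
            assert abs(res.p - p_ref) < 1e-10
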