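import numpy as np
import pytest

from pathscore.expression_io import BENIGN, TUMOUR, SampleAnnotation
from pathscore.scoring import OutlierCall
from pathscore.survival import (
    GEHAN_BRESLOW,
    MANTEL_COX,
    SurvivalDataset,
    km_estimate,
    logrank_test,
    spearman,
    stratify_by_outlier,
    stratify_by_score_split,
)
from ._oracles import (
    km_survival_brute,
    logrank_permutation_p,
    spearman_rho_brute,
)


def _dataset(times, events, strata):
    ids = tuple(f"s{i}" for i in range(len(times)))
    return SurvivalDataset(ids, np.asarray(times, float), np.asarray(events, bool),
                           tuple(strata))


class TestKM:
    def test_all_events_closed_form(self):
        curves = km_estimate(_dataset([1, 2, 3], [1, 1, 1], ["g"] * 3))
        np.testing.assert_allclose(curves["g"].survival, [2 / 3, 1 / 3, 0.0])

    def test_censored_middle_hand_product(self):
        # events at 1 and 3, censored at 2: S(1) = 2/3, S(3) = (2/3) * 0 = 0
        curves = km_estimate(_dataset([1, 2, 3], [1, 0, 1], ["g"] * 3))
        c = curves["g"]
        np.testing.assert_allclose(c.event_times, [1.0, 3.0])
        np.testing.assert_allclose(c.survival, [2 / 3, 0.0])
        assert c.survival_at(2.5) == pytest.approx(2 / 3)

    def test_no_events_flat_one(self, caplog):
        curves = km_estimate(_dataset([5, 6], [0, 0], ["g"] * 2))
        assert curves["g"].event_times.size == 0
        assert curves["g"].survival_at(100) == 1.0
        assert any("no events" in r.message for r in caplog.records)

    def test_zero_censoring_equals_empirical_survival(self, rng):
        times = rng.exponential(10, size=25)
        curves = km_estimate(_dataset(times, np.ones(25), ["g"] * 25))
        c = curves["g"]
        for t, s in zip(c.event_times, c.survival):
            assert s == pytest.approx((times > t).mean())

    def test_matches_brute_force_with_censoring(self, rng):
        times = np.round(rng.exponential(10, size=30), 1)
        events = rng.random(30) < 0.7
        if not events.any():
            events[0] = True
        curves = km_estimate(_dataset(times, events, ["g"] * 30))
        brute = km_survival_brute(times, events)
        for t, s in zip(curves["g"].event_times, curves["g"].survival):
            assert s == pytest.approx(brute[float(t)])

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        times = np.round(rng.exponential(10, size=40), 1)
        events = rng.random(40) < 0.6
        events[0] = True
        curves = km_estimate(_dataset(times, events, ["g"] * 40))
        kmf = KaplanMeierFitter().fit(times, events)
        for t, s in zip(curves["g"].event_times, curves["g"].survival):
            assert s == pytest.approx(kmf.predict(t), abs=1e-9)

    def test_survival_non_increasing_invariant(self, rng):
        times = rng.exponential(5, size=20)
        events = rng.random(20) < 0.5
        events[0] = True
        c = km_estimate(_dataset(times, events, ["g"] * 20))["g"]
        assert (np.diff(c.survival) <= 1e-12).all()
        assert (np.diff(c.at_risk) < 0).all()

    def test_truncation_horizon(self):
        data = _dataset([10, 70, 80], [1, 1, 0], ["g"] * 3).truncate(60)
        np.testing.assert_allclose(data.times, [10, 60, 60])
        assert list(data.events) == [True, False, False]


class TestLogrank:
    def test_identical_strata_statistic_zero(self):
        data = _dataset([1, 2, 3, 1, 2, 3], [1, 1, 1, 1, 1, 1],
                        ["a", "a", "a", "b", "b", "b"])
        for w in (MANTEL_COX, GEHAN_BRESLOW):
            res = logrank_test(data, w)
            assert res.statistic == pytest.approx(0.0, abs=1e-12)
            assert res.p_value == pytest.approx(1.0)

    def test_complete_separation_toy_vs_permutation_oracle(self):
        data = _dataset([1, 2, 3, 10, 11, 12], [1] * 6, ["a"] * 3 + ["b"] * 3)
        for w in (MANTEL_COX, GEHAN_BRESLOW):
            res = logrank_test(data, w)
            assert res.statistic > 0
            p_perm = logrank_permutation_p(data.times, data.events,
                                           np.array([True] * 3 + [False] * 3), w)
            # C(6,3)=20 labelings; the two complete separations are most extreme
            assert p_perm == pytest.approx(2 / 20)
            # at n=6 the chi-square approximation is anti-conservative
            # relative to the discrete permutation floor of 0.1
            assert res.p_value < p_perm
            assert abs(res.p_value - p_perm) <= 0.1

    def test_time_scaling_invariance(self, rng):
        times = rng.exponential(5, size=12)
        events = rng.random(12) < 0.8
        events[0] = True
        strata = ["a"] * 6 + ["b"] * 6
        for w in (MANTEL_COX, GEHAN_BRESLOW):
            r1 = logrank_test(_dataset(times, events, strata), w)
            r2 = logrank_test(_dataset(times * 7.3, events, strata), w)
            assert r1.statistic == pytest.approx(r2.statistic)

    def test_weights_agree_when_at_risk_constant(self):
        # single event time in each group's support: every table sees the
        # same at-risk count, so constant weights match mantel-cox exactly
        data = _dataset([5, 5, 5, 5], [1, 1, 0, 0], ["a", "b", "a", "b"])
        r1 = logrank_test(data, MANTEL_COX)
        r2 = logrank_test(data, GEHAN_BRESLOW)
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        times = np.round(rng.exponential(8, size=30), 1) + 0.1
        events = rng.random(30) < 0.7
        events[:2] = True
        strata = ["a"] * 15 + ["b"] * 15
        res = logrank_test(_dataset(times, events, strata), MANTEL_COX)
        ref = ll_logrank(times[:15], times[15:], events[:15], events[15:])
        assert res.statistic == pytest.approx(ref.test_statistic, rel=1e-6)
        assert res.p_value == pytest.approx(ref.p_value, rel=1e-6)

    def test_requires_two_strata_and_events(self):
        with pytest.raises(ValueError, match="2 strata"):
            logrank_test(_dataset([1, 2], [1, 1], ["a", "a"]))
        with pytest.raises(ValueError, match="no events"):
            logrank_test(_dataset([1, 2], [0, 0], ["a", "b"]))


def _calls(directions, pathway="p1"):
    return [OutlierCall(sample_id=f"T{i}", pathway=pathway, direction=d,
                        threshold_sd=2.0, score=0.0)
            for i, d in enumerate(directions)]


def _tumour_ann(n, time=10.0, event=True):
    return [SampleAnnotation(sample_id=f"T{i}", group=TUMOUR,
                             time_to_event=time, event=event) for i in range(n)]


class TestStratify:
    def test_partition_sizes(self):
        calls = _calls(["up", "up", "up", "none", "none", "none", "none",
                        "down", "none", "none"])
        data = stratify_by_outlier(calls, "p1", "up", _tumour_ann(10))
        assert sum(s == "outlier" for s in data.strata) == 3
        assert sum(s == "rest" for s in data.strata) == 7

    def test_down_direction(self):
        calls = _calls(["down", "none", "none"])
        data = stratify_by_outlier(calls, "p1", "down", _tumour_ann(3))
        assert sum(s == "outlier" for s in data.strata) == 1

    def test_no_outliers_error(self):
        calls = _calls(["none", "none"])
        with pytest.raises(ValueError, match="empty stratum"):
            stratify_by_outlier(calls, "p1", "up", _tumour_ann(2))

    def test_missing_survival_fields_error(self):
        calls = _calls(["up", "none"])
        ann = [SampleAnnotation(sample_id="T0", group=TUMOUR),
               SampleAnnotation(sample_id="T1", group=TUMOUR)]
        with pytest.raises(ValueError, match="survival fields"):
            stratify_by_outlier(calls, "p1", "up", ann)

    def test_median_split(self):
        import pandas as pd

        scores = pd.Series([0.1, 0.2, 0.9, 1.0], index=[f"T{i}" for i in range(4)])
        data = stratify_by_score_split(scores, _tumour_ann(4), split="median")
        assert sum(s == "high" for s in data.strata) == 2


class TestSpearman:
    def test_perfect_increase(self):
        rho, _ = spearman([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert rho == pytest.approx(1.0)

    def test_perfect_reversal(self):
        rho, _ = spearman([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_tied_example_matches_brute_force(self):
        x = [1.0, 2.0, 2.0, 3.0, 5.0]
        y = [2, 1, 3, 3, 4]
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(spearman_rho_brute(x, y))

    def test_exact_p_matches_scipy_large_n(self, rng):
        from scipy import stats

        x = rng.normal(size=20)
        y = 0.5 * x + rng.normal(size=20)
        rho, p = spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_vector_flagged(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [1, 2, 3])


def test_dataset_invariants():
    with pytest.raises(ValueError, match="non-negative"):
        _dataset([-1, 2], [1, 1], ["a", "b"])
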