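"""Kaplan-Meier, log-rank test, hazard ratios and cutoff stratification,
cross-checked against hand tabulation and lifelines."""

import numpy as np
import pandas as pd
import pytest

from gutnk.survival import (combined_strata, km_estimate, logrank_test,
                            median_survival, stratify_by_cutoff)


def km_oracle(times, events):
    """Naive per-time product-limit loop."""
    distinct = sorted({t for t, e in zip(times, events) if e == 1})
    out = {}
    s = 1.0
    for ti in distinct:
        n_i = sum(1 for t in times if t >= ti)
        d_i = sum(1 for t, e in zip(times, events) if t == ti and e == 1)
        s *= 1 - d_i / n_i
        out[ti] = s
    return out


class TestKM:
    def test_all_censored_stays_at_one(self):
        curve = km_estimate([3, 5, 8], [0, 0, 0])
        assert curve.times.size == 0
        assert curve.survival_at(100) == 1.0

    def test_hand_product_limit(self):
        curve = km_estimate([2, 3, 5, 7], [1, 0, 1, 0])
        assert curve.survival_at(2) == pytest.approx(0.75)
        assert curve.survival_at(5) == pytest.approx(0.375)
        assert curve.survival_at(4.9) == pytest.approx(0.75)

    def test_single_event_among_n(self):
        curve = km_estimate([1, 2, 3, 4, 5], [1, 0, 0, 0, 0])
        assert curve.survival_at(1) == pytest.approx(1 - 1 / 5)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])

    def test_oracle_agreement_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 16))
            times = rng.integers(1, 10, size=n).astype(float)  # forces ties
            events = rng.integers(0, 2, size=n)
            curve = km_estimate(times, events)
            oracle = km_oracle(times.tolist(), events.tolist())
            assert curve.times.tolist() == sorted(oracle)
            for ti, si in zip(curve.times, curve.survival):
                assert si == pytest.approx(oracle[ti], abs=1e-12)

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        times = rng.exponential(10, size=40)
        events = rng.integers(0, 2, size=40)
        if events.sum() == 0:
            events[0] = 1
        curve = km_estimate(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        for ti, si in zip(curve.times, curve.survival):
            assert si == pytest.approx(
                float(kmf.survival_function_at_times(ti).iloc[0]), abs=1e-10)


class TestMedian:
    def test_hand_example(self):
        curve = km_estimate([2, 3, 5, 7], [1, 0, 1, 0])
        assert median_survival(curve) == 5

    def test_all_censored_undefined(self):
        assert median_survival(km_estimate([3, 5], [0, 0])) is None

    def test_exact_half_uses_leq_convention(self):
        # two subjects, one death: S drops to exactly 0.5 at t=4
        curve = km_estimate([4, 9], [1, 0])
        assert median_survival(curve) == 4


def logrank_oracle(ta, ea, tb, eb):
    """Hand-tabulated 2x2 table per distinct event time."""
    pooled = [(t, e, "a") for t, e in zip(ta, ea)] + \
             [(t, e, "b") for t, e in zip(tb, eb)]
    event_times = sorted({t for t, e, _ in pooled if e == 1})
    o = e_exp = v = 0.0
    for ti in event_times:
        at_risk = [(t, e, g) for t, e, g in pooled if t >= ti]
        n = len(at_risk)
        n_a = sum(1 for *_, g in at_risk if g == "a")
        d = sum(1 for t, e, _ in pooled if t == ti and e == 1)
        d_a = sum(1 for t, e, g in pooled if t == ti and e == 1 and g == "a")
        o += d_a
        e_exp += d * n_a / n
        if n > 1:
            v += d * (n_a / n) * ((n - n_a) / n) * (n - d) / (n - 1)
    return o, e_exp, (o - e_exp) ** 2 / v


class TestLogRank:
    def test_identical_groups(self):
        t = [2.0, 4.0, 6.0, 8.0]
        e = [1, 0, 1, 0]
        res = logrank_test(t, e, t, e)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.hazard_ratio == pytest.approx(1.0)

    def test_hand_tabulated_toy_instance(self):
        ta, ea = [1.0, 3.0, 5.0], [1, 1, 0]
        tb, eb = [2.0, 4.0, 6.0], [0, 1, 0]
        res = logrank_test(ta, ea, tb, eb)
        o, e, chi2 = logrank_oracle(ta, ea, tb, eb)
        assert res.observed[0] == pytest.approx(o)
        assert res.expected[0] == pytest.approx(e)
        assert res.chi_square == pytest.approx(chi2, abs=1e-12)

    def test_oracle_agreement_random_instances(self, rng):
        for _ in range(100):
            na, nb = int(rng.integers(3, 12)), int(rng.integers(3, 12))
            ta = rng.integers(1, 10, size=na).astype(float)
            tb = rng.integers(1, 10, size=nb).astype(float)
            ea = rng.integers(0, 2, size=na)
            eb = rng.integers(0, 2, size=nb)
            if ea.sum() + eb.sum() == 0:
                ea[0] = 1
            try:
                res = logrank_test(ta, ea, tb, eb)
            except ValueError:
                continue  # zero-variance degenerate draw
            o, e, chi2 = logrank_oracle(ta.tolist(), ea.tolist(),
                                        tb.tolist(), eb.tolist())
            assert res.chi_square == pytest.approx(chi2, abs=1e-12)

    def test_matches_lifelines_statistic(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        ta = rng.exponential(10, size=30)
        tb = rng.exponential(20, size=30)
        ea = rng.integers(0, 2, size=30)
        eb = rng.integers(0, 2, size=30)
        res = logrank_test(ta, ea, tb, eb)
        ref = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert res.chi_square == pytest.approx(ref.test_statistic, abs=1e-8)
        assert res.p_value == pytest.approx(ref.p_value, abs=1e-10)

    def test_label_swap_inverts_hr_keeps_p(self, rng):
        ta = rng.exponential(5, size=25)
        tb = rng.exponential(15, size=25)
        ea = np.ones(25, dtype=int)
        eb = rng.integers(0, 2, size=25)
        ab = logrank_test(ta, ea, tb, eb)
        ba = logrank_test(tb, eb, ta, ea)
        assert ab.p_value == pytest.approx(ba.p_value, abs=1e-12)
        assert ab.hazard_ratio == pytest.approx(1 / ba.hazard_ratio, rel=1e-9)

    def test_late_censoring_time_is_irrelevant(self):
        """Where exactly a record is censored beyond the last event does not
        affect the statistic (risk sets at event times are identical)."""
        ta, ea = [1.0, 3.0, 5.0], [1, 1, 0]
        tb, eb = [2.0, 4.0, 6.0], [0, 1, 0]
        base = logrank_test(ta, ea, tb, eb)
        moved = logrank_test([1.0, 3.0, 50.0], ea, tb, eb)
        assert moved.chi_square == pytest.approx(base.chi_square, abs=1e-12)
        km_a = km_estimate([1.0, 3.0, 5.0], ea)
        km_b = km_estimate([1.0, 3.0, 50.0], ea)
        assert km_a.survival.tolist() == km_b.survival.tolist()

    def test_hazard_ratio_recovery(self, rng):
        """Exponential groups with true HR 3 at n=1000/group recover the
        ratio within 15 percent."""
        n = 1000
        ta = rng.exponential(1.0 / 3.0, size=n)   # hazard 3
        tb = rng.exponential(1.0, size=n)         # hazard 1
        horizon = 0.4  # moderate censoring: O/E estimator nearly unbiased
        ea = (ta <= horizon).astype(int)
        eb = (tb <= horizon).astype(int)
        res = logrank_test(np.minimum(ta, horizon), ea,
                           np.minimum(tb, horizon), eb)
        assert res.hazard_ratio == pytest.approx(3.0, rel=0.15)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1.0, 2.0], [0, 0], [3.0], [0])

    def test_mantel_haenszel_variant(self, rng):
        ta = rng.exponential(3, size=30)
        tb = rng.exponential(9, size=30)
        res = logrank_test(ta, np.ones(30, int), tb, np.ones(30, int),
                           hr_variant="mantel-haenszel")
        assert res.variant == "mantel-haenszel"
        assert res.hazard_ratio > 1
        assert res.ci_lower < res.hazard_ratio < res.ci_upper


class TestStratification:
    def test_perfectly_prognostic_marker(self):
        values = pd.Series([1, 2, 3, 10, 11, 12],
                           index=[f"s{i}" for i in range(6)])
        labels = [0, 0, 0, 1, 1, 1]
        strata, cutoff = stratify_by_cutoff(values, labels)
        assert (strata == ["low"] * 3 + ["high"] * 3).all()
        assert 3 < cutoff < 10

    def test_deterministic_on_rerun(self, rng):
        values = pd.Series(rng.normal(size=23))
        labels = rng.integers(0, 2, size=23)
        if len(set(labels.tolist())) < 2:
            labels[0] = 1 - labels[0]
        s1, c1 = stratify_by_cutoff(values, labels)
        s2, c2 = stratify_by_cutoff(values, labels)
        assert c1 == c2 and (s1 == s2).all()

    def test_planted_hazard_marker_concentrates_events(self):
        """High stratum captures more deaths than low in nearly all
        replicates of a 23-subject prognostic-marker design."""
        import gutnk

        wins = 0
        n_rep = 50
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            sev = rng.standard_normal(23)
            marker = sev + rng.normal(0, 0.5, 23)
            t = rng.exponential(1 / (0.05 * np.exp(1.2 * sev)))
            event = (t <= 15).astype(int)
            if len(set(event.tolist())) < 2:
                continue
            strata, _ = stratify_by_cutoff(pd.Series(marker), event)
            hi = event[(strata == "high").to_numpy()]
            lo = event[(strata == "low").to_numpy()]
            wins += hi.sum() >= lo.sum()
        assert wins / n_rep >= 0.95

    def test_combined_identical_markers_keep_everyone(self):
        s = pd.Series(["high", "low", "high"], index=list("abc"))
        joint = combined_strata(s, s.copy())
        assert len(joint) == 3
        assert set(joint) == {"high/high", "low/low"}

    def test_combined_discordant_excluded(self):
        s1 = pd.Series(["high", "low"], index=list("ab"))
        s2 = pd.Series(["low", "low"], index=list("ab"))
        joint = combined_strata(s1, s2)
        assert list(joint.index) == ["b"]
        assert joint.loc["b"] == "low/low"

    def test_independent_markers_exclude_about_half(self, rng):
        n = 100
        s1 = pd.Series(np.where(rng.random(n) < 0.5, "high", "low"))
        s2 = pd.Series(np.where(rng.random(n) < 0.5, "high", "low"))
        joint = combined_strata(s1, s2)
        # binomial(100, 1/2): 3 sigma is 15
        assert abs(len(joint) - 50) <= 15
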