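"""Spearman correlation, printed and refit logistic risk models, ROC
utilities."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from gutnk.association import (PRINTED_MODELS, evaluate_risk, fit_logistic,
                               odds_ratio_from_coef, roc_auc,
                               spearman_correlation, youden_cutoff)


class TestSpearman:
    def test_perfect_agreement(self):
        rho, _ = spearman_correlation([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)

    def test_perfect_reversal(self):
        rho, _ = spearman_correlation([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_hand_derived_value(self):
        rho, p = spearman_correlation([1, 2, 3], [2, 1, 3])
        assert rho == pytest.approx(0.5)
        assert 0 < p <= 1

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_correlation([1, 1, 1], [1, 2, 3])

    def test_small_sample_p_is_exact_permutation(self):
        """For n <= 10 the p-value equals the exhaustive permutation tail."""
        x = [3, 1, 4, 1.5, 9]
        y = [2, 7, 1, 8, 2.8]
        rho, p = spearman_correlation(x, y)
        from scipy.stats import rankdata
        rx, ry = rankdata(x), rankdata(y)
        hits = total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, perm)[0, 1]
            total += 1
            hits += abs(r) >= abs(rho) - 1e-12
        assert p == pytest.approx(hits / total)

    def test_large_sample_matches_scipy(self, rng):
        from scipy.stats import spearmanr
        x = rng.normal(size=50)
        y = x + rng.normal(size=50)
        rho, p = spearman_correlation(x, y)
        ref = spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


class TestRiskModels:
    def test_printed_cc_model_at_zero(self):
        model = PRINTED_MODELS["cc_risk_2var"]
        p = evaluate_risk(model, {"PD-1|CD56bright": 0.0,
                                  "Escherichia/Ruminococcus": 0.0})
        assert p == pytest.approx(1 / (1 + math.exp(3.3919)), abs=1e-6)
        assert p == pytest.approx(0.0326, abs=5e-4)

    def test_logit_zero_gives_half(self):
        model = PRINTED_MODELS["cc_risk_2var"]
        # choose the ratio to cancel the intercept with PD-1 at zero
        ratio = 3.3919 / 2.6358
        p = evaluate_risk(model, {"PD-1|CD56bright": 0.0,
                                  "Escherichia/Ruminococcus": ratio})
        assert p == pytest.approx(0.5, abs=1e-9)

    def test_monotone_in_positive_coefficient(self):
        model = PRINTED_MODELS["cc_risk_2var"]
        probs = [evaluate_risk(model, {"PD-1|CD56bright": 5.0,
                                       "Escherichia/Ruminococcus": r})
                 for r in (-1.0, 0.0, 1.0, 2.0)]
        assert all(a < b for a, b in zip(probs, probs[1:]))

    def test_missing_feature_named(self):
        with pytest.raises(KeyError, match="Escherichia/Ruminococcus"):
            evaluate_risk(PRINTED_MODELS["cc_risk_2var"],
                          {"PD-1|CD56bright": 1.0})

    def test_odds_ratio_identities(self):
        assert odds_ratio_from_coef(0.0) == 1.0
        for x in (0.3, 1.0, 7.5):
            assert odds_ratio_from_coef(math.log(x)) == pytest.approx(x)

    def test_printed_coefficients_reproduce_printed_odds_ratios(self):
        assert odds_ratio_from_coef(0.5938) == pytest.approx(1.81, abs=0.005)
        assert odds_ratio_from_coef(2.6358) == pytest.approx(14.0, abs=0.05)
        assert odds_ratio_from_coef(0.208) == pytest.approx(1.23, abs=0.005)


class TestFitLogistic:
    def test_null_simulation_keeps_coefficients_small(self, rng):
        """Labels independent of features: most Wald tests stay null."""
        insignificant = 0
        for _ in range(20):
            X = pd.DataFrame({"x": rng.normal(size=1000)})
            y = rng.integers(0, 2, size=1000)
            m = fit_logistic(X, y)
            assert abs(m.coefficients["x"]) < 0.5
            z = m.coefficients["x"] / m.standard_errors["x"]
            insignificant += abs(z) < 1.96
        assert insignificant >= 18  # >= 90 percent of replicates

    def test_parameter_recovery(self, rng):
        beta0, beta1 = -1.0, 0.8
        x = rng.normal(size=5000)
        p = 1 / (1 + np.exp(-(beta0 + beta1 * x)))
        y = (rng.random(5000) < p).astype(int)
        m = fit_logistic(pd.DataFrame({"x": x}), y)
        assert m.converged
        assert m.coefficients["x"] == pytest.approx(beta1, rel=0.10)
        assert m.intercept == pytest.approx(beta0, rel=0.10)

    def test_binary_feature_equals_log_cross_product_ratio(self):
        # 2x2 contingency: exposed 30/10, unexposed 10/30
        x = [1] * 40 + [0] * 40
        y = [1] * 30 + [0] * 10 + [1] * 10 + [0] * 30
        m = fit_logistic(pd.DataFrame({"x": x}), y)
        assert m.coefficients["x"] == pytest.approx(math.log(9.0), abs=1e-4)

    def test_perfect_separation_flagged(self):
        x = np.concatenate([np.linspace(-2, -1, 10), np.linspace(1, 2, 10)])
        y = np.array([0] * 10 + [1] * 10)
        m = fit_logistic(pd.DataFrame({"x": x}), y)
        assert not m.converged

    def test_constant_feature_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(pd.DataFrame({"x": [1.0] * 10}), [0, 1] * 5)


def auc_oracle(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = hits = 0.0
    for sp in pos:
        for sn in neg:
            total += 1
            hits += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return hits / total


def youden_oracle(scores, labels):
    uniq = sorted(set(scores))
    best = None
    for c in [(a + b) / 2 for a, b in zip(uniq, uniq[1:])]:
        tp = sum(1 for s, l in zip(scores, labels) if l == 1 and s > c)
        fn = sum(1 for s, l in zip(scores, labels) if l == 1 and s <= c)
        tn = sum(1 for s, l in zip(scores, labels) if l == 0 and s <= c)
        fp = sum(1 for s, l in zip(scores, labels) if l == 0 and s > c)
        j = tp / (tp + fn) + tn / (tn + fp) - 1
        if best is None or j > best[0] + 1e-12:
            best = (j, c)
    return best[1]


class TestRoc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 9, 10], [0, 0, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_hand_counted_pairs(self):
        assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])

    def test_monotone_transform_invariance(self, rng):
        s = rng.normal(size=60)
        y = rng.integers(0, 2, size=60)
        if len(set(y.tolist())) < 2:
            y[0] = 1 - y[0]
        assert roc_auc(np.exp(s), y) == pytest.approx(roc_auc(s, y), abs=1e-12)

    def test_oracle_agreement_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 30))
            s = np.round(rng.normal(size=n), 1)  # rounding forces ties
            y = rng.integers(0, 2, size=n)
            if len(set(y.tolist())) < 2:
                y[0] = 1 - y[0]
            assert roc_auc(s, y) == pytest.approx(auc_oracle(s, y), abs=1e-12)


class TestYouden:
    def test_clean_split(self):
        cutoff, sens, spec = youden_cutoff([1, 2, 3, 4], [0, 0, 1, 1])
        assert cutoff == pytest.approx(2.5)
        assert sens == 1.0 and spec == 1.0

    def test_anti_informative_scores_report_low_j(self):
        cutoff, sens, spec = youden_cutoff([4, 3, 2, 1], [0, 0, 1, 1])
        assert sens + spec - 1 <= 0

    def test_oracle_agreement_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(8, 50))
            s = rng.normal(size=n)
            y = rng.integers(0, 2, size=n)
            if len(set(y.tolist())) < 2:
                y[0] = 1 - y[0]
            cutoff, _, _ = youden_cutoff(s, y)
            assert cutoff == pytest.approx(youden_oracle(s.tolist(), y.tolist()),
                                           abs=1e-12)
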