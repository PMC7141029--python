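import itertools
import json

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import promoterfoot as pf
from promoterfoot.classifier import ConfigurationError


def _brute_force_cutoff(values, labels):
    """Exhaustive search over all candidates and both directions."""
    values = np.asarray(values, float)
    y = np.asarray(labels).astype(bool)
    uniq = np.unique(values)
    candidates = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2, [uniq[-1] + 1.0]])
    best = (None, -1.0)
    for c in candidates:
        ind = values > c
        sens = (ind & y).sum() / y.sum()
        spec = (~ind & ~y).sum() / (~y).sum()
        ba = (sens + spec) / 2
        score = max(ba, 1 - ba)
        if score > best[1] + 1e-12:
            best = (c, score)
    return best


def _brute_force_auc(probs, labels):
    y = np.asarray(labels).astype(bool)
    cases = np.asarray(probs)[y]
    controls = np.asarray(probs)[~y]
    u = sum(
        1.0 if c > k else 0.5 if c == k else 0.0
        for c in cases
        for k in controls
    )
    return u / (len(cases) * len(controls))


class TestOptimalCutoff:
    def test_separated_groups(self):
        cutoff, score = pf.optimal_cutoff([5, 6, 1, 2], [1, 1, 0, 0])
        assert (cutoff, score) == (3.5, 1.0)

    def test_all_identical_values_uninformative(self):
        cutoff, score = pf.optimal_cutoff([2.0, 2.0, 2.0, 2.0], [1, 0, 1, 0])
        assert score == 0.5
        assert cutoff < 2.0

    def test_tie_broken_to_smallest_candidate(self):
        cutoff, score = pf.optimal_cutoff([1, 3, 2, 4], [1, 1, 0, 0])
        assert (cutoff, score) == (1.5, 0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            pf.optimal_cutoff([1, 2], [1, 1])

    def test_matches_exhaustive_search(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 50))
            values = rng.choice([0.5, 1.5, 2.5, 3.5, 4.5], size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            assert pf.optimal_cutoff(values, labels) == _brute_force_cutoff(values, labels)


class TestBinarize:
    def test_value_at_cutoff_is_zero(self):
        frame = pd.DataFrame({"g": [1.0, 1.0 + 1e-9, 0.5]})
        out = pf.binarize(frame, {"g": 1.0})
        assert out["g"].tolist() == [0.0, 1.0, 0.0]

    def test_idempotent_on_binary_matrix(self, rng):
        frame = pd.DataFrame(rng.integers(0, 2, size=(6, 3)).astype(float),
                             columns=list("abc"))
        once = pf.binarize(frame, {c: 0.5 for c in "abc"})
        assert once.equals(pf.binarize(once, {c: 0.5 for c in "abc"}))

    def test_missing_rule_rejected(self):
        with pytest.raises(ConfigurationError, match="b"):
            pf.binarize(pd.DataFrame({"a": [1.0], "b": [2.0]}), {"a": 0.0})


class TestFitLogistic:
    def test_saturated_closed_form_single_binary_feature(self):
        x = np.array([0, 0, 0, 0, 1, 1, 1, 1.0])[:, None]
        y = np.array([0, 0, 0, 1, 0, 1, 1, 1.0])
        fit = pf.fit_logistic(x, y)
        assert fit.intercept == pytest.approx(logit(0.25), abs=1e-4)
        assert fit.coefficients[0] == pytest.approx(logit(0.75) - logit(0.25), abs=1e-4)
        assert fit.converged and not fit.separation

    def test_random_saturated_designs_match_closed_form(self, rng):
        for _ in range(20):
            n0, n1 = rng.integers(6, 20, size=2)
            x = np.concatenate([np.zeros(n0), np.ones(n1)])
            y = np.concatenate([
                rng.random(n0) < 0.4, rng.random(n1) < 0.7
            ]).astype(float)
            p0, p1 = y[x == 0].mean(), y[x == 1].mean()
            if p0 in (0, 1) or p1 in (0, 1):
                continue
            fit = pf.fit_logistic(x[:, None], y)
            assert fit.intercept == pytest.approx(logit(p0), abs=1e-4)
            assert fit.coefficients[0] == pytest.approx(logit(p1) - logit(p0), abs=1e-4)

    def test_no_features_gives_prevalence_intercept(self):
        y = np.array([0, 0, 0, 1.0])
        fit = pf.fit_logistic(np.empty((4, 0)), y)
        assert fit.intercept == pytest.approx(logit(0.25), abs=1e-6)

    def test_perfect_separation_flagged_and_capped(self, caplog):
        x = np.array([0, 0, 0, 1, 1, 1.0])[:, None]
        y = np.array([0, 0, 0, 1, 1, 1.0])
        with caplog.at_level("WARNING", logger="promoterfoot"):
            fit = pf.fit_logistic(x, y)
        assert fit.separation
        assert np.abs(fit.coefficients).max() <= 15.0 + 1e-9

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            pf.fit_logistic(np.ones((3, 1)), np.ones(3))

    def test_agrees_with_statsmodels(self, rng):
        import statsmodels.api as sm

        x = rng.integers(0, 2, size=(40, 3)).astype(float)
        y = (rng.random(40) < expit(-0.5 + x @ np.array([1.0, -0.8, 0.3]))).astype(float)
        fit = pf.fit_logistic(x, y)
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert fit.intercept == pytest.approx(ref.params[0], abs=1e-5)
        assert fit.coefficients == pytest.approx(ref.params[1:], abs=1e-5)


class TestStepwise:
    def test_label_identical_feature_selected_first(self, rng):
        y = rng.integers(0, 2, size=40)
        design = pd.DataFrame(
            rng.integers(0, 2, size=(40, 10)).astype(float),
            columns=[f"n{i}" for i in range(10)],
        )
        design["signal"] = y.astype(float)
        subset = pf.stepwise_select(design, y, max_features=5)
        assert subset[0] == "signal"

    def test_pure_noise_selects_few_features(self):
        # AIC admits a noise feature when its LR statistic exceeds 2, which a
        # chi^2_1 variate does with probability ~0.157, so of 20 noise
        # features roughly 3 enter on average; the penalty keeps the model
        # far below the 15-feature cap on every seed
        counts = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = np.repeat([0, 1], 30)
            design = rng.integers(0, 2, size=(60, 20)).astype(float)
            counts.append(len(pf.stepwise_select(design, y, max_features=15)))
        assert max(counts) < 10
        assert np.mean(counts) <= 6

    def test_max_features_zero_returns_empty(self, rng):
        design = rng.integers(0, 2, size=(10, 3)).astype(float)
        assert pf.stepwise_select(design, np.repeat([0, 1], 5), max_features=0) == []

    def test_respects_max_features_cap(self, rng):
        y = rng.integers(0, 2, size=50)
        design = pd.DataFrame(rng.integers(0, 2, size=(50, 12)).astype(float))
        design[0] = y * 1.0  # strong feature to force selection
        subset = pf.stepwise_select(design, y, max_features=1)
        assert len(subset) <= 1


class TestLoocv:
    def test_perfect_feature_predicts_every_fold(self, rng):
        y = np.repeat([0, 1], 10)
        design = pd.DataFrame({"f": y.astype(float)})
        probs = pf.loocv_probabilities(design, y, ["f"])
        assert np.all((probs > 0.5) == (y == 1))

    def test_null_features_give_chance_auc(self):
        rng = np.random.default_rng(9)
        y = np.repeat([0, 1], 20)
        design = pd.DataFrame(
            rng.integers(0, 2, size=(40, 5)).astype(float),
            columns=[f"f{i}" for i in range(5)],
        )
        probs = pf.loocv_probabilities(design, y, list(design.columns))
        auc = _brute_force_auc(probs, y)
        assert 0.3 <= auc <= 0.7

    def test_permuting_samples_permutes_probabilities(self, rng):
        y = np.repeat([0, 1], 8)
        design = pd.DataFrame(rng.integers(0, 2, size=(16, 3)).astype(float))
        probs = pf.loocv_probabilities(design, y, list(design.columns))
        perm = rng.permutation(16)
        probs_perm = pf.loocv_probabilities(design.iloc[perm], y[perm], list(design.columns))
        assert probs_perm == pytest.approx(probs[perm])

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            pf.loocv_probabilities(pd.DataFrame({"f": [0.0, 1.0]}), [0, 1], ["f"])


class TestRoc:
    def test_perfect_separation(self):
        roc = pf.roc_analysis([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert roc.auc == 1.0
        assert roc.sensitivity == 1.0 and roc.specificity == 1.0

    def test_crossed_pairs_give_half(self):
        roc = pf.roc_analysis([0.9, 0.1, 0.8, 0.2], [1, 1, 0, 0])
        assert roc.auc == pytest.approx(0.5)

    def test_auc_invariant_under_monotone_transform(self, rng):
        probs = rng.random(30)
        y = rng.integers(0, 2, size=30)
        y[:2] = [0, 1]
        a = pf.roc_analysis(probs, y).auc
        b = pf.roc_analysis(np.exp(3 * probs), y).auc
        assert a == pytest.approx(b)

    def test_auc_matches_brute_force_u_statistic(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 30))
            probs = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            roc = pf.roc_analysis(probs, y)
            assert roc.auc == pytest.approx(_brute_force_auc(probs, y))
            assert roc.auc_ci_low <= roc.auc <= roc.auc_ci_high

    def test_confusion_matrix_consistent_at_threshold(self, rng):
        probs = rng.random(40)
        y = rng.integers(0, 2, size=40)
        y[:2] = [0, 1]
        roc = pf.roc_analysis(probs, y)
        pred = probs > roc.threshold
        yb = y.astype(bool)
        assert roc.sensitivity == pytest.approx((pred & yb).sum() / yb.sum())
        assert roc.specificity == pytest.approx((~pred & ~yb).sum() / (~yb).sum())
        assert roc.accuracy == pytest.approx((pred == yb).mean())


class TestCompareAuc:
    def test_identical_probabilities_give_p_one(self, rng):
        probs = rng.random(20)
        y = np.repeat([0, 1], 10)
        p = pf.compare_auc(pf.roc_analysis(probs, y), pf.roc_analysis(probs, y))
        assert p == pytest.approx(1.0)

    def test_symmetric_in_arguments(self, rng):
        y = np.repeat([0, 1], 15)
        ra = pf.roc_analysis(rng.random(30), y)
        rb = pf.roc_analysis(rng.random(30), y)
        assert pf.compare_auc(ra, rb) == pytest.approx(pf.compare_auc(rb, ra))

    def test_perfect_vs_chance_is_significant(self, rng):
        y = np.repeat([0, 1], 50)
        perfect = pf.roc_analysis(y + rng.normal(0, 1e-3, 100), y)
        chance = pf.roc_analysis(rng.random(100), y)
        assert pf.compare_auc(perfect, chance) < 0.01

    def test_mismatched_samples_rejected(self, rng):
        ra = pf.roc_analysis(rng.random(10), np.repeat([0, 1], 5))
        rb = pf.roc_analysis(rng.random(8), np.repeat([0, 1], 4))
        with pytest.raises(ValueError):
            pf.compare_auc(ra, rb)


class TestPublishedClassifier:
    def test_all_zero_indicators_give_intercept(self):
        model = pf.published_ma_classifier()
        eta, prob, call = pf.predict(model, {g: 0 for g in model.features})
        assert eta == pytest.approx(2.180)
        assert prob == pytest.approx(expit(2.180))
        assert call  # probability > 0.5 at the default threshold

    def test_all_one_indicators_sum_coefficients(self):
        model = pf.published_ma_classifier()
        eta, _, _ = pf.predict(model, {g: 1 for g in model.features})
        assert eta == pytest.approx(-3.426, abs=1e-3)

    def test_single_smc3_indicator(self):
        model = pf.published_ma_classifier()
        values = {g: 0 for g in model.features}
        values["SMC3"] = 1
        eta, _, _ = pf.predict(model, values)
        assert eta == pytest.approx(2.785)

    def test_feature_count_and_named_coefficient(self):
        model = pf.published_ma_classifier()
        assert len(model.features) == 12
        assert model.coefficients["TMEM184A"] == pytest.approx(-1.652)
        assert model.coefficients["NIPBL"] == pytest.approx(-0.057)

    def test_json_round_trip_lossless(self, tmp_path):
        model = pf.published_ma_classifier(cutoffs={"SMC3": 12.5})
        path = tmp_path / "model.json"
        model.to_json(path)
        back = pf.PromoterClassifier.from_json(path)
        assert back == model

    def test_missing_feature_named_in_error(self):
        model = pf.published_ma_classifier()
        values = {g: 0 for g in model.features if g != "MASTL"}
        with pytest.raises(ConfigurationError, match="MASTL"):
            pf.predict(model, values)

    def test_cutoffs_applied_before_linear_predictor(self):
        model = pf.published_ma_classifier(cutoffs={"SMC3": 10.0})
        values = {g: 0 for g in model.features}
        values["SMC3"] = 11.0  # above cutoff -> indicator 1
        eta, _, _ = pf.predict(model, values)
        assert eta == pytest.approx(2.785)
        values["SMC3"] = 10.0  # at cutoff -> strict comparison gives 0
        eta, _, _ = pf.predict(model, values)
        assert eta == pytest.approx(2.180)
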