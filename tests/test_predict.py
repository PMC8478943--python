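"""AUC statistic, stratified holdout, Bayesian logistic fits and the
five-model experiment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trimtrack import (SamplerSettings, ValidationError, auc,
                       build_wide_matrix, fit_bayes_logistic, holdout_split,
                       model_features, run_prediction_experiment,
                       simulate_cohort)
from trimtrack.simulate import MEASURES, SimulationConfig
from trimtrack._mcmc import LogisticPosterior, sample_mwg


def brute_force_auc(scores, labels):
    scores = np.asarray(scores, float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestAuc:
    def test_half_concordant_example(self):
        assert auc([0.9, 0.8, 0.3], [1, 0, 1]) == 0.5

    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_is_half(self):
        assert auc([0.4] * 10, [1, 0] * 5) == 0.5

    def test_single_class_errors(self):
        with pytest.raises(ValidationError):
            auc([0.1, 0.2], [1, 1])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_rank_formula_equals_pairwise_enumeration(self, data):
        n = data.draw(st.integers(2, 12))
        # coarse grid of scores forces frequent ties
        scores = data.draw(st.lists(st.integers(0, 4), min_size=n, max_size=n))
        labels = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        if len(set(labels)) < 2:
            labels[0], labels[1] = 0, 1
        assert auc(np.asarray(scores) / 4.0, labels) == pytest.approx(
            brute_force_auc(np.asarray(scores) / 4.0, labels), abs=1e-12)


def outcome_wide(seed=3, n=700, gamma=None):
    cfg = SimulationConfig(
        n_women=n, seed=seed,
        gamma_path=gamma if gamma is not None else {})
    wide = build_wide_matrix(simulate_cohort(cfg))
    return wide.dropna(subset=["pph"]).reset_index(drop=True)


class TestHoldoutSplit:
    def test_exact_stratified_counts(self):
        wide = outcome_wide(n=1012)
        n_ev = int(wide.pph.sum())
        train, test = holdout_split(wide, n_hold=200, n_events=25, seed=4)
        assert len(test) == 200 and test.pph.sum() == 25
        assert len(train) == len(wide) - 200
        assert train.pph.sum() == n_ev - 25
        assert set(train.woman_id).isdisjoint(test.woman_id)

    def test_deterministic(self):
        wide = outcome_wide(n=1012)
        a = holdout_split(wide, seed=9)
        b = holdout_split(wide, seed=9)
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_insufficient_events_error(self):
        wide = outcome_wide(n=300)
        wide["pph"] = 0.0
        wide.loc[:19, "pph"] = 1.0  # only 20 events
        with pytest.raises(ValidationError, match="20 events"):
            holdout_split(wide, n_hold=200, n_events=25, seed=1)


FAST = SamplerSettings(chains=3, burnin=200, total_iter=700)


class TestBayesLogistic:
    def test_posterior_matches_penalized_mle_oracle(self, rng):
        """Single binary feature with true OR 2: posterior mean within 3
        posterior SDs of the ridge-penalized MLE under the same prior."""
        from scipy.optimize import minimize
        n = 3000
        x = rng.integers(0, 2, n).astype(float)
        eta = -1.5 + np.log(2.0) * x
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        X = pd.DataFrame({"x": x})
        fit = fit_bayes_logistic(X, y, prior_var=2.0, settings=FAST, seed=2)
        sd_x = x.std()

        def neg_log_post(b):
            lin = b[0] + b[1] * ((x - x.mean()) / sd_x)
            return -(y @ lin - np.logaddexp(0, lin).sum()) + (b @ b) / 4.0

        mle = minimize(neg_log_post, np.zeros(2)).x
        d = fit.draws[:, :, 1].ravel()
        assert abs(d.mean() - mle[1]) < 3 * d.std()

    def test_zero_information_coefficient_reverts_to_prior(self, rng):
        """A predictor column of zeros contributes nothing to the likelihood,
        so its posterior is the Normal(0, 2) prior."""
        n = 400
        y = rng.integers(0, 2, n).astype(float)
        X = np.column_stack([np.ones(n), np.zeros(n)])
        post = LogisticPosterior(X, y, prior_var=2.0)
        res = sample_mwg(post, 1500, 500, 3, seed=8)
        d = res.draws[:, :, 1].ravel()
        assert abs(d.mean()) < 3 * np.sqrt(2.0 / len(d)) * 10
        assert d.var() == pytest.approx(2.0, rel=0.15)

    def test_constant_feature_dropped_with_warning(self, rng, caplog):
        import logging
        y = rng.integers(0, 2, 100).astype(float)
        X = pd.DataFrame({"a": rng.normal(size=100), "b": np.ones(100)})
        with caplog.at_level(logging.WARNING, logger="trimtrack.predict"):
            fit = fit_bayes_logistic(X, y, settings=FAST, seed=1)
        assert fit.dropped == ["b"] and fit.feature_names == ["a"]
        assert "constant" in caplog.text

    def test_single_class_outcome_errors(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=60)})
        with pytest.raises(ValidationError, match="both classes"):
            fit_bayes_logistic(X, np.zeros(60), settings=FAST, seed=1)

    def test_standardization_uses_train_statistics_only(self, rng):
        y = rng.integers(0, 2, 200).astype(float)
        X = pd.DataFrame({"a": rng.normal(5.0, 2.0, 200)})
        fit = fit_bayes_logistic(X, y, settings=FAST, seed=3)
        assert fit.center[0] == pytest.approx(X["a"].mean())
        assert fit.scale[0] == pytest.approx(X["a"].std(ddof=0))
        # poisoned held-out rows never touch the fit
        X_test = pd.DataFrame({"a": [np.nan, 1.0]})
        fit2 = fit_bayes_logistic(X, y, settings=FAST, seed=3)
        np.testing.assert_array_equal(fit.draws, fit2.draws)
        p = fit.predict_proba(X_test.fillna(0.0))
        assert ((p > 0) & (p < 1)).all()


def test_model_features_enumeration():
    assert model_features("baseline") == ["age"]
    assert len(model_features("tri2")) == 15
    assert all(c.endswith("_t2") for c in model_features("tri2")[1:])
    assert len(model_features("tracking")) == 1 + 42
    with pytest.raises(ValidationError):
        model_features("tri9")


class TestExperiment:
    def test_paired_design_and_replicate_counts(self):
        wide = outcome_wide(n=600, seed=17)
        per, summ = run_prediction_experiment(
            wide, replicates=2, n_hold=80, n_events=10, seed=3, settings=FAST)
        assert len(per) == 2 * 5
        assert set(per.model_id) == {"baseline", "tri1", "tri2", "tri3", "tracking"}
        assert (per.groupby("model_id").replicate
                .apply(lambda s: sorted(s) == [1, 2])).all()
        assert set(summ.columns) == {"model_id", "mean_auc", "se_auc"}
        assert (summ.se_auc >= 0).all()

    def test_null_cohort_auc_near_half(self):
        wide = outcome_wide(n=900, seed=19, gamma={})
        per, summ = run_prediction_experiment(
            wide, replicates=3, n_hold=100, n_events=12, seed=5, settings=FAST)
        # 3 SEs of a null AUC with 12/88 split, averaged over 3 replicates
        assert (abs(summ.mean_auc - 0.5) < 0.20).all()

    def test_deterministic_under_seed(self):
        wide = outcome_wide(n=600, seed=17)
        a = run_prediction_experiment(wide, replicates=1, n_hold=80,
                                      n_events=10, seed=11, settings=FAST)
        b = run_prediction_experiment(wide, replicates=1, n_hold=80,
                                      n_events=10, seed=11, settings=FAST)
        pd.testing.assert_frame_equal(a[0], b[0])
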