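import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone
from sklearn.naive_bayes import CategoricalNB

from icpforecast import (
    ICPForecaster,
    fit,
    posterior,
    posterior_with_missing,
    predict_enhanced,
    predict_map,
)
from icpforecast.model import CategoricalLagNB, decide_enhanced, enhanced_scores

from conftest import manual_forecaster_d1_1, windows_from_arrays


def bruteforce_posterior(X, y, history):
    """Independent oracle: Bayes' rule on raw contingency counts.

    P(y=c | x) = #(y=c, X=x) / #(X=x), the empirical conditional frequency —
    what the joint-mode lambda=0 model must reproduce for any seen history.
    """
    X = np.asarray(X, dtype=int)
    y = np.asarray(y, dtype=int)
    match = (X == np.asarray(history, dtype=int)).all(axis=1)
    assert match.any(), "oracle only defined for seen histories"
    return np.array([(y[match] == 1).mean(), (y[match] == 2).mean()])


class TestFit:
    def test_degenerate_counts(self):
        ws = windows_from_arrays([(3, 3)] * 4 + [(1, 2)] * 4, [2] * 4 + [1] * 4)
        m = fit(ws, smoothing=0.0)
        est = m.estimators_[1]
        assert np.allclose(est.feature_prob_[1, :, 2], 1.0)  # P(level 3 | y=2) per lag

    def test_smoothing_fills_empty_cells(self):
        ws = windows_from_arrays([(1, 1)] * 3, [1] * 3)
        est = CategoricalLagNB(smoothing=1.0).fit(
            ws.frame[["x1", "x2"]].to_numpy(), ws.frame["y"].to_numpy()
        )
        assert (est.feature_prob_ > 0).all()
        assert (est.class_prior_ > 0).all()
        assert np.allclose(est.feature_prob_.sum(axis=2), 1.0)

    def test_hand_counted_tables(self, hand_windows_d1_2):
        m = fit(hand_windows_d1_2, smoothing=0.0)
        est = m.estimators_[1]
        assert np.allclose(est.class_prior_, [0.5, 0.5])
        expect_c1 = np.array([[0.75, 0.25, 0.0], [0.75, 0.25, 0.0]])
        expect_c2 = np.array([[0.0, 0.25, 0.75], [0.0, 0.25, 0.75]])
        assert np.allclose(est.feature_prob_[0], expect_c1)
        assert np.allclose(est.feature_prob_[1], expect_c2)

    def test_hand_counted_joint(self, hand_windows_d1_2):
        m = fit(hand_windows_d1_2, mode="joint", smoothing=0.0)
        jp = m.estimators_[1].joint_prob_
        assert jp[0][0, 0] == pytest.approx(0.5)   # P((1,1) | y=1) = 2/4
        assert jp[1][2, 2] == pytest.approx(0.5)   # P((3,3) | y=2) = 2/4
        assert np.allclose(jp.sum(axis=(1, 2)), 1.0)

    def test_errors(self, hand_windows_d1_2):
        X = hand_windows_d1_2.frame[["x1", "x2"]].to_numpy()
        y = hand_windows_d1_2.frame["y"].to_numpy()
        with pytest.raises(ValueError, match="lambda"):
            CategoricalLagNB(smoothing=-1).fit(X, y)
        with pytest.raises(ValueError, match="empty"):
            CategoricalLagNB().fit(X[:0], y[:0])
        with pytest.raises(ValueError, match="levels"):
            CategoricalLagNB().fit(X + 3, y)
        with pytest.raises(ValueError, match="horizon k = 2"):
            ICPForecaster(d1=2, m=2).fit(hand_windows_d1_2)  # no k=2 rows


class TestPosterior:
    def test_symmetric_model_gives_half(self):
        m = manual_forecaster_d1_1(cond1=(0.2, 0.3, 0.5), cond2=(0.2, 0.3, 0.5))
        for lvl in (1, 2, 3):
            assert np.allclose(posterior(m, [lvl], 1), [0.5, 0.5])

    def test_hand_bayes_per_lag(self, hand_windows_d1_2):
        m = fit(hand_windows_d1_2, smoothing=0.0)
        assert np.allclose(posterior(m, [1, 1], 1), [1.0, 0.0])
        # (2,2): numerators .5*.25*.25 for both classes
        assert np.allclose(posterior(m, [2, 2], 1), [0.5, 0.5])

    def test_joint_matches_bruteforce_oracle(self, hand_windows_d1_2):
        X = hand_windows_d1_2.frame[["x1", "x2"]].to_numpy()
        y = hand_windows_d1_2.frame["y"].to_numpy()
        m = fit(hand_windows_d1_2, mode="joint", smoothing=0.0)
        for hist in {tuple(r) for r in X.astype(int)}:
            assert np.allclose(
                posterior(m, hist, 1), bruteforce_posterior(X, y, hist), atol=1e-12
            )

    def test_bad_level_rejected(self, hand_windows_d1_2):
        m = fit(hand_windows_d1_2)
        with pytest.raises(ValueError, match="levels"):
            posterior(m, [1, 4], 1)
        with pytest.raises(ValueError, match="horizon"):
            posterior(m, [1, 1], 99)

    @given(
        st.integers(min_value=0, max_value=2**31 - 1),
        st.sampled_from(["per_lag", "joint"]),
        st.floats(min_value=0.0, max_value=5.0),
    )
    @settings(deadline=None, max_examples=60)
    def test_normalization_property(self, seed, mode, lam):
        rng = np.random.default_rng(seed)
        n, d1 = 40, 3
        X = rng.integers(1, 4, size=(n, d1))
        y = rng.integers(1, 3, size=n)
        if len(set(y)) < 2:
            y[0], y[1] = 1, 2
        est = CategoricalLagNB(mode=mode, smoothing=lam).fit(X, y)
        proba = est.predict_proba(rng.integers(1, 4, size=(20, d1)))
        assert np.all(proba >= 0) and np.all(proba <= 1)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-12)


class TestMissing:
    def test_fully_observed_identity(self, hand_windows_d1_2):
        m = fit(hand_windows_d1_2, smoothing=1.0)
        p, flag = posterior_with_missing(m, [1.0, 2.0], 1)
        assert not flag
        assert np.allclose(p, posterior(m, [1, 2], 1))

    @pytest.mark.parametrize("mode", ["per_lag", "joint"])
    def test_one_missing_equals_completion_sum(self, hand_windows_d1_2, mode):
        """Marginalization must equal explicit summation over the 3 completions
        of the missing lag, weighted by their class-conditional probability."""
        m = fit(hand_windows_d1_2, mode=mode, smoothing=1.0)
        est = m.estimators_[1]
        p, _ = posterior_with_missing(m, [np.nan, 3.0], 1)
        num = np.zeros(2)
        for ci in range(2):
            for lvl in (1, 2, 3):
                if mode == "per_lag":
                    lik = est.feature_prob_[ci, 0, lvl - 1] * est.feature_prob_[ci, 1, 2]
                else:
                    lik = est.joint_prob_[ci][lvl - 1, 2]
                num[ci] += est.class_prior_[ci] * lik
        assert np.allclose(p, num / num.sum(), atol=1e-12)

    def test_per_lag_missing_equals_reduced_model(self, hand_windows_d1_2):
        """Dropping a lag's factor is the same as querying a model that never
        saw that lag at all."""
        m2 = fit(hand_windows_d1_2, smoothing=1.0)
        ws1 = windows_from_arrays(
            hand_windows_d1_2.frame[["x2"]].to_numpy(),
            hand_windows_d1_2.frame["y"].to_numpy(),
        )
        m1 = fit(ws1, smoothing=1.0)
        for lvl in (1.0, 2.0, 3.0):
            p2, _ = posterior_with_missing(m2, [np.nan, lvl], 1)
            assert np.allclose(p2, posterior(m1, [lvl], 1), atol=1e-12)

    def test_all_missing_returns_prior(self, hand_windows_d1_2):
        m = fit(hand_windows_d1_2, smoothing=1.0)
        p, flag = posterior_with_missing(m, [np.nan, np.nan], 1)
        assert flag
        assert np.allclose(p, m.estimators_[1].class_prior_)


class TestDecisionRules:
    def test_map_argmax_and_tie(self):
        m = manual_forecaster_d1_1()
        assert predict_map(m, [1], 1) == 1     # (0.6, 0.4)
        assert predict_map(m, [2], 1) == 2     # (0.5, 0.5): tie -> alert class
        assert predict_map(m, [3], 1) == 2     # (0.25, 0.75)

    def test_enhancement_worked_example(self):
        # alpha = 0.65 on posterior (0.6, 0.4): 0.65 * 0.6 = 0.39 < 0.40 -> class 2
        scores = enhanced_scores([[0.6, 0.4]], 0.65)[0]
        assert scores[0] == pytest.approx(0.39)
        assert decide_enhanced([[0.6, 0.4]], 0.65)[0] == 2
        m = manual_forecaster_d1_1()  # history 1 has posterior (0.6, 0.4)
        assert predict_enhanced(m, [1], 1, alpha=0.65) == 2

    def test_alpha_point_six_keeps_confident_normal(self):
        assert decide_enhanced([[0.9, 0.1]], 0.6)[0] == 1  # 0.54 > 0.10

    def test_alpha_one_is_map(self, hand_windows_d1_2):
        m = fit(hand_windows_d1_2, smoothing=1.0)
        rng = np.random.default_rng(0)
        X = rng.integers(1, 4, size=(50, 2)).astype(float)
        assert np.array_equal(
            m.predict_enhanced(X, 1, alpha=1.0), m.predict_map(X, 1)
        )

    @pytest.mark.parametrize("alpha", [0.0, -0.2, 1.5])
    def test_alpha_domain(self, alpha):
        with pytest.raises(ValueError, match="alpha"):
            decide_enhanced([[0.5, 0.5]], alpha)


class TestSklearnInterop:
    def test_clone_and_params(self):
        est = CategoricalLagNB(mode="joint", smoothing=0.5, alpha=0.7)
        params = est.get_params()
        assert params == {"mode": "joint", "smoothing": 0.5, "alpha": 0.7}
        c = clone(est)
        assert c.get_params() == params

    def test_posterior_cross_check_against_sklearn(self):
        """Independent route: sklearn's CategoricalNB with the same smoothing
        and our (smoothed) prior must produce identical posteriors on fully
        observed per-lag data."""
        rng = np.random.default_rng(3)
        X = rng.integers(1, 4, size=(300, 4))
        logits = (X == 3).sum(axis=1) - 1.0
        y = np.where(rng.random(300) < 1 / (1 + np.exp(-logits)), 2, 1)
        ours = CategoricalLagNB(mode="per_lag", smoothing=1.0).fit(X, y)
        ref = CategoricalNB(
            alpha=1.0, min_categories=3, class_prior=ours.class_prior_
        ).fit(X - 1, y)
        assert np.allclose(
            ours.predict_proba(X), ref.predict_proba(X - 1), atol=1e-12
        )


class TestSerialization:
    @pytest.mark.parametrize("mode", ["per_lag", "joint"])
    def test_json_round_trip(self, hand_windows_d1_2, tmp_path, mode):
        m = fit(hand_windows_d1_2, mode=mode, smoothing=1.0, alpha=0.6)
        path = tmp_path / "model.json"
        m.to_json(path)
        m2 = ICPForecaster.from_json(path)
        assert m2.get_params() == m.get_params()
        X = np.array([[1.0, 3.0], [2.0, 2.0], [np.nan, 3.0]])
        p1, _ = m.posterior_with_missing(X, 1)
        p2, _ = m2.posterior_with_missing(X, 1)
        assert np.allclose(p1, p2, atol=0)
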