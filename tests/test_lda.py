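"""Count-weighted LDA: estimator identities, posterior math, validation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import multivariate_normal

from xylemae.ingest import LabeledWindow
from xylemae.lda import (
    LDAModel,
    fit_weighted_lda,
    loo_crossvalidate,
    posterior,
    predict_window_count,
    roc_lda,
)


def _windows_from_blocks(blocks, counts):
    """Stack feature blocks into one matrix with one window per block."""
    features = np.vstack(blocks)
    windows, offset = [], 0
    for i, (b, c) in enumerate(zip(blocks, counts)):
        windows.append(
            LabeledWindow(
                index=i, start=float(offset), end=float(offset + len(b)), kind="scan",
                embolism_count=int(c), signal_indices=np.arange(offset, offset + len(b)),
            )
        )
        offset += len(b)
    return windows, features


def _random_model(rng, p=6):
    a = rng.normal(size=(p, p))
    sigma = a @ a.T + p * np.eye(p)
    return LDAModel(
        mu0=rng.normal(size=p),
        mu1=rng.normal(size=p),
        sigma=sigma,
        prior1=float(rng.uniform(0.05, 0.95)),
    )


class TestFit:
    def test_hand_computed_weighted_means(self):
        """Two windows, sizes (4, 6), counts (2, 3): means match Σn·x̄/Σn by hand."""
        w1 = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0], [7.0, 8.0]])
        w2 = np.array([[2.0, 1.0], [4.0, 3.0], [6.0, 5.0], [8.0, 7.0], [10.0, 9.0], [12.0, 11.0]])
        windows, features = _windows_from_blocks([w1, w2], [2, 3])
        model = fit_weighted_lda(windows, features)
        xbar1, xbar2 = w1.mean(axis=0), w2.mean(axis=0)  # (4,5), (7,6)
        np.testing.assert_allclose(model.mu1, (2 * xbar1 + 3 * xbar2) / 5)
        np.testing.assert_allclose(model.mu0, (2 * xbar1 + 3 * xbar2) / 5)  # n0 = (2, 3) too
        s1 = (w1 - xbar1).T @ (w1 - xbar1)
        s2 = (w2 - xbar2).T @ (w2 - xbar2)
        np.testing.assert_allclose(model.sigma, (s1 + s2) / 10, atol=1e-9)
        assert model.prior1 == pytest.approx(0.5)

    def test_pure_windows_reduce_to_supervised_lda(self, rng):
        """Degenerate weak supervision equals pooled-label LDA exactly."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        x0 = rng.normal(size=(80, 6))
        x1 = rng.normal(size=(50, 6)) + 1.5
        windows, features = _windows_from_blocks([x0, x1], [0, 50])
        model = fit_weighted_lda(windows, features)

        sk = LinearDiscriminantAnalysis(solver="lsqr", store_covariance=True)
        labels = np.r_[np.zeros(80), np.ones(50)]
        sk.fit(features, labels)
        np.testing.assert_allclose(model.mu0, sk.means_[0], rtol=1e-12)
        np.testing.assert_allclose(model.mu1, sk.means_[1], rtol=1e-12)
        np.testing.assert_allclose(model.sigma, sk.covariance_, rtol=1e-9)
        np.testing.assert_allclose(
            posterior(model, features), sk.predict_proba(features)[:, 1], atol=1e-10
        )

    def test_recovery_error_shrinks_with_sample_size(self, rng):
        """Median ‖µ̂1 − µ1‖ over replicates decreases across n ∈ {1e3, 1e4, 1e5}."""
        from xylemae.simulate import DEFAULT_MU0, DEFAULT_MU1, DEFAULT_SIGMA

        chol = np.linalg.cholesky(DEFAULT_SIGMA)
        errors = {n: [] for n in (1_000, 10_000, 100_000)}
        for rep in range(20):
            for n in errors:
                n1 = n // 10
                x1 = DEFAULT_MU1 + rng.standard_normal((n1, 6)) @ chol.T
                x0 = DEFAULT_MU0 + rng.standard_normal((n - n1, 6)) @ chol.T
                blocks = [x0[: (n - n1) // 2], x0[(n - n1) // 2 :], x1[: n1 // 2], x1[n1 // 2 :]]
                windows, features = _windows_from_blocks(
                    blocks, [0, 0, len(blocks[2]), len(blocks[3])]
                )
                model = fit_weighted_lda(windows, features)
                errors[n].append(np.linalg.norm(model.mu1 - DEFAULT_MU1))
        med = [np.median(errors[n]) for n in sorted(errors)]
        assert med[0] > med[1] > med[2]

    def test_moment_corrected_variant_removes_mixing_bias(self, rng):
        """On heavily mixed windows the corrected fit lands nearer the truth."""
        mu0, mu1 = np.zeros(2), np.array([4.0, 2.0])
        blocks, counts = [], []
        for pi in (0.1, 0.3, 0.5):
            n = 4000
            k = int(pi * n)
            blocks.append(np.vstack([rng.normal(size=(n - k, 2)), mu1 + rng.normal(size=(k, 2))]))
            counts.append(k)
        windows, features = _windows_from_blocks(blocks, counts)
        plain = fit_weighted_lda(windows, features)
        corrected = fit_weighted_lda(windows, features, moment_corrected=True)
        assert np.linalg.norm(corrected.mu1 - mu1) < np.linalg.norm(plain.mu1 - mu1)
        assert np.linalg.norm(corrected.mu0 - mu0) < np.linalg.norm(plain.mu0 - mu0)

    def test_degenerate_supervision_rejected(self, rng):
        blocks = [rng.normal(size=(10, 6)), rng.normal(size=(12, 6))]
        windows, features = _windows_from_blocks(blocks, [0, 0])
        with pytest.raises(ValueError, match="zero"):
            fit_weighted_lda(windows, features)
        windows, features = _windows_from_blocks(blocks, [0, 13])
        with pytest.raises(ValueError, match="exceeds"):
            fit_weighted_lda(windows, features)


class TestPosterior:
    def test_equal_means_give_prior(self, rng):
        model = LDAModel(mu0=np.ones(6), mu1=np.ones(6), sigma=np.eye(6), prior1=0.3)
        x = rng.normal(size=(20, 6))
        np.testing.assert_allclose(posterior(model, x), 0.3)

    def test_midpoint_is_half_under_flat_prior(self, rng):
        model = _random_model(rng)
        model.prior1 = 0.5
        assert posterior(model, (model.mu0 + model.mu1) / 2) == pytest.approx(0.5, abs=1e-12)

    def test_matches_explicit_density_evaluation(self, rng):
        """Brute-force Bayes' rule with explicit normal pdfs, 1000 random pairs."""
        for _ in range(50):
            model = _random_model(rng)
            x = rng.normal(size=(20, 6)) * 3
            f1 = multivariate_normal.pdf(x, mean=model.mu1, cov=model.sigma)
            f0 = multivariate_normal.pdf(x, mean=model.mu0, cov=model.sigma)
            expected = model.prior1 * f1 / (model.prior1 * f1 + (1 - model.prior1) * f0)
            np.testing.assert_allclose(posterior(model, x), expected, rtol=1e-10)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_normalized_and_affine_in_x(self, seed):
        rng = np.random.default_rng(seed)
        model = _random_model(rng)
        x, y = rng.normal(size=6), rng.normal(size=6)
        lam = rng.uniform()
        p = posterior(model, x)
        assert 0.0 <= p <= 1.0
        # log-odds is affine: odds(λx + (1−λ)y) = λ·odds(x) + (1−λ)·odds(y)
        ox = model.log_odds(x)[0]
        oy = model.log_odds(y)[0]
        om = model.log_odds(lam * x + (1 - lam) * y)[0]
        assert om == pytest.approx(lam * ox + (1 - lam) * oy, rel=1e-9, abs=1e-9)

    def test_extreme_inputs_stay_finite(self, rng):
        model = _random_model(rng)
        p = posterior(model, np.array([1e6] * 6))
        assert np.isfinite(p) and 0.0 <= p <= 1.0


class TestWindowCounts:
    def test_constant_posterior_gives_prior_times_size(self, rng):
        model = LDAModel(mu0=np.zeros(6), mu1=np.zeros(6), sigma=np.eye(6), prior1=0.2)
        x = rng.normal(size=(15, 6))
        w = LabeledWindow(index=0, start=0, end=1, kind="scan", embolism_count=0,
                          signal_indices=np.arange(15))
        assert predict_window_count(model, w, x) == pytest.approx(0.2 * 15)

    def test_empty_window_predicts_zero(self, rng):
        model = _random_model(rng)
        w = LabeledWindow(index=0, start=0, end=1, kind="break", embolism_count=0)
        assert predict_window_count(model, w, np.empty((0, 6))) == 0.0

    def test_bounded_by_window_size(self, rng):
        model = _random_model(rng)
        x = rng.normal(size=(30, 6))
        w = LabeledWindow(index=0, start=0, end=1, kind="scan", embolism_count=0,
                          signal_indices=np.arange(30))
        assert 0.0 <= predict_window_count(model, w, x) <= 30.0

    def test_prediction_within_poisson_binomial_band(self, rng):
        """Well-separated classes: Σ posteriors ≈ hidden count, within ~2σ."""
        mu0, mu1 = np.zeros(6), np.full(6, 4.0)
        model = LDAModel(mu0=mu0, mu1=mu1, sigma=np.eye(6), prior1=0.2)
        n, k = 200, 40
        x = np.vstack([rng.normal(size=(n - k, 6)), mu1 + rng.normal(size=(k, 6))])
        w = LabeledWindow(index=0, start=0, end=1, kind="scan", embolism_count=k,
                          signal_indices=np.arange(n))
        p = np.asarray(posterior(model, x))
        sigma_pb = np.sqrt(np.sum(p * (1 - p)))
        assert abs(predict_window_count(model, w, x) - k) < 2.5 * sigma_pb + 1.0


class TestLeaveOneOut:
    def _exchangeable(self, rng, n_windows=8, size=300, k=60):
        blocks, counts = [], []
        mu1 = np.full(6, 3.0)
        for _ in range(n_windows):
            blocks.append(np.vstack([rng.normal(size=(size - k, 6)), mu1 + rng.normal(size=(k, 6))]))
            counts.append(k)
        return _windows_from_blocks(blocks, counts)

    def test_identically_distributed_windows_predict_their_counts(self, rng):
        windows, features = self._exchangeable(rng)
        res = loo_crossvalidate(windows, features)
        rel = np.abs(res.table["predicted"] - res.table["observed"]) / res.table["observed"]
        assert rel.max() < 0.25
        assert res.predicted_total == pytest.approx(res.table["predicted"].sum())

    def test_pure_background_window_predicts_near_zero(self, rng):
        # pure training windows give a well-separated fitted model; the
        # held-out window is pure noise and should collect ~no posterior mass
        mu1 = np.full(6, 4.0)
        blocks = [
            rng.normal(size=(300, 6)),
            mu1 + rng.normal(size=(300, 6)),
            rng.normal(size=(300, 6)),
            mu1 + rng.normal(size=(300, 6)),
            rng.normal(size=(200, 6)),  # held-out window of interest
        ]
        counts = [0, 300, 0, 300, 0]
        windows, features = _windows_from_blocks(blocks, counts)
        res = loo_crossvalidate(windows, features)
        held_out = res.table.iloc[-1]
        assert held_out["predicted"] < 0.05 * held_out["size"]

    def test_zero_positive_training_fold_flagged(self, rng):
        # only one window carries counts: its fold has no positives left
        blocks = [rng.normal(size=(40, 6)) for _ in range(3)]
        blocks[0] += np.where(np.arange(40)[:, None] < 10, 4.0, 0.0)
        windows, features = _windows_from_blocks(blocks, [10, 0, 0])
        res = loo_crossvalidate(windows, features)
        assert bool(res.table.loc[0, "flagged"])
        prior = 10 / 120
        assert res.table.loc[0, "predicted"] == pytest.approx(prior * 40)

    def test_requires_three_windows(self, rng):
        windows, features = _windows_from_blocks([rng.normal(size=(10, 6))] * 2, [2, 1])
        with pytest.raises(ValueError, match="three"):
            loo_crossvalidate(windows, features)


class TestROCLDA:
    def test_oracle_posteriors_reach_corner(self, rng):
        blocks, counts, labels = [], [], []
        for _ in range(4):
            k = 5
            blocks.append(rng.normal(size=(30, 6)))
            counts.append(k)
            labels.append(np.r_[np.ones(k), np.zeros(25)])
        windows, _ = _windows_from_blocks(blocks, counts)
        oracle = np.concatenate(labels)
        curve = roc_lda(windows, oracle)
        at_tpr1 = curve.fpr[np.flatnonzero(curve.tpr >= 1.0 - 1e-12)]
        assert at_tpr1.min() == 0.0

    def test_constant_posteriors_jump_along_diagonal(self, rng):
        windows, _ = _windows_from_blocks([rng.normal(size=(20, 6))] * 3, [2, 0, 1])
        curve = roc_lda(windows, np.full(60, 0.25))
        # one threshold at 0.25 retains everything: curve is (0,0) then (1,1)
        assert curve.tpr[-1] == pytest.approx(1.0)
        assert curve.fpr[-1] == pytest.approx(1.0)
        assert len(curve.thresholds) == 2

    def test_lda_dominates_single_parameters(self, small_experiment):
        """Posterior-based ROC beats every raw-parameter ROC in area."""
        from xylemae.explore import roc_parameter
        from xylemae.ingest import FEATURE_COLUMNS, extract_features, filter_noise, link_windows

        exp = small_experiment
        retained = filter_noise(exp.signals)
        windows, _ = link_windows(retained, exp.schedule)
        features = extract_features(retained)
        model = fit_weighted_lda(windows, features)
        from xylemae.lda import posterior as post

        curve = roc_lda(windows, post(model, features))
        for param in FEATURE_COLUMNS:
            assert curve.auc > roc_parameter(retained, windows, param).auc
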