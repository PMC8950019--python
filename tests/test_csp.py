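import numpy as np
import pytest
from scipy import linalg

from mitransfer.csp import (
    CSP,
    class_mean_covariance,
    extract_features,
    featurize_trialset,
    fit_csp,
    project,
)
from mitransfer.trials import CLASS1, CLASS2, Trial, TrialSet


def _labeled_set(rng, n_per_class=10, m=6, ns=80, scales=(1.0, 1.0)):
    """Random two-class set; per-class channel scaling makes classes differ."""
    trials = []
    for label, scale in zip((CLASS1, CLASS2), scales):
        g = np.ones(m)
        g[0] = scale  # class-dependent power on channel 0
        for _ in range(n_per_class):
            trials.append(Trial(data=g[:, None] * rng.standard_normal((m, ns)),
                                label=label))
    return TrialSet(trials=trials)


class TestClassMeanCovariance:
    def test_unit_trace(self, rng):
        ts = _labeled_set(rng)
        for label in (CLASS1, CLASS2):
            c = class_mean_covariance(ts, label)
            assert abs(np.trace(c) - 1.0) < 1e-12

    def test_hand_computed_two_trial_mean(self):
        # trial A: X = [[2,0],[0,0]] -> XX^T = [[4,0],[0,0]], trace 4
        #   -> normalized [[1,0],[0,0]]
        # trial B: X = [[0,0],[0,1]] -> normalized [[0,0],[0,1]]
        # mean = [[.5,0],[0,.5]]
        a = Trial(data=np.array([[2.0, 0.0], [0.0, 0.0]]), label=CLASS1)
        b = Trial(data=np.array([[0.0, 0.0], [0.0, 1.0]]), label=CLASS1)
        c = class_mean_covariance(TrialSet(trials=[a, b]), CLASS1)
        np.testing.assert_allclose(c, 0.5 * np.eye(2))

    def test_scale_invariance_per_trial(self, rng):
        # trace normalization makes each trial's contribution scale-free
        x = rng.standard_normal((4, 50))
        ts1 = TrialSet(trials=[Trial(data=x, label=CLASS1)])
        ts2 = TrialSet(trials=[Trial(data=7.0 * x, label=CLASS1)])
        np.testing.assert_allclose(class_mean_covariance(ts1, CLASS1),
                                   class_mean_covariance(ts2, CLASS1),
                                   rtol=1e-12)

    def test_missing_class_rejected(self, rng):
        ts = TrialSet(trials=[Trial(data=rng.standard_normal((3, 20)),
                                    label=CLASS1)])
        with pytest.raises(ValueError, match="no trials"):
            class_mean_covariance(ts, CLASS2)

    def test_zero_power_trial_rejected(self):
        ts = TrialSet(trials=[Trial(data=np.zeros((3, 20)), label=CLASS1)])
        with pytest.raises(ValueError, match="zero power"):
            class_mean_covariance(ts, CLASS1)


class TestDecompositionInvariants:
    def test_whitening_and_shared_eigenvectors(self, rng):
        ts = _labeled_set(rng, scales=(3.0, 0.5))
        bank, dec = fit_csp(ts, m_pairs=2)
        m = dec.C1.shape[0]
        # P whitens the composite covariance
        np.testing.assert_allclose(dec.P @ dec.Cc @ dec.P.T, np.eye(m),
                                   atol=1e-8)
        # whitened class covariances share eigenvectors; eigenvalues sum to I
        np.testing.assert_allclose(dec.lambda1 + dec.lambda2, np.eye(m),
                                   atol=1e-8)
        # B diagonalizes both S1 and S2
        np.testing.assert_allclose(dec.B.T @ dec.S1 @ dec.B, dec.lambda1,
                                   atol=1e-8)
        np.testing.assert_allclose(dec.B.T @ dec.S2 @ dec.B, dec.lambda2,
                                   atol=1e-8)
        # W simultaneously diagonalizes C1 and C2, diagonals summing to one
        d1 = dec.W_full @ dec.C1 @ dec.W_full.T
        d2 = dec.W_full @ dec.C2 @ dec.W_full.T
        np.testing.assert_allclose(d1, np.diag(np.diag(d1)), atol=1e-8)
        np.testing.assert_allclose(d1 + d2, np.eye(m), atol=1e-8)

    def test_matches_generalized_eigensolver_oracle(self, rng):
        # C1 w = lambda (C1 + C2) w: scipy's generalized eigensolver gives the
        # same eigenvalues as the whitening construction
        ts = _labeled_set(rng, m=5, scales=(2.0, 0.7))
        bank, dec = fit_csp(ts, m_pairs=2)
        w_oracle = linalg.eigh(dec.C1, dec.Cc, eigvals_only=True)[::-1]
        np.testing.assert_allclose(np.diag(dec.lambda1), w_oracle, atol=1e-8)
        # retained rows are the extreme eigenvalues
        np.testing.assert_allclose(
            bank.eigvals_class1,
            np.concatenate([w_oracle[:2], w_oracle[-2:]]), atol=1e-8)

    def test_eigenvalues_sorted_descending_and_in_unit_interval(self, rng):
        ts = _labeled_set(rng, m=8, scales=(4.0, 1.0))
        _, dec = fit_csp(ts, m_pairs=3)
        w1 = np.diag(dec.lambda1)
        assert (np.diff(w1) <= 1e-12).all()
        assert (w1 >= -1e-10).all() and (w1 <= 1 + 1e-10).all()

    def test_filters_discriminate_power_in_expected_direction(self, rng):
        # class 1 has extra power on channel 0: the top filter should give
        # higher projected variance for class 1 than class 2, and vice versa
        # for the bottom filter
        ts = _labeled_set(rng, n_per_class=40, scales=(3.0, 1.0))
        bank, _ = fit_csp(ts, m_pairs=1)
        v = {CLASS1: [], CLASS2: []}
        for t in ts.trials:
            z = project(bank, t)
            v[t.label].append(z.var(axis=1) / t.data.var())
        v1 = np.mean(v[CLASS1], axis=0)
        v2 = np.mean(v[CLASS2], axis=0)
        assert v1[0] > v2[0]   # first row favors class 1
        assert v1[-1] < v2[-1]  # last row favors class 2

    def test_too_many_pairs_rejected(self, rng):
        ts = _labeled_set(rng, m=4)
        with pytest.raises(ValueError, match="exceeds"):
            fit_csp(ts, m_pairs=3)

    def test_single_class_rejected(self, rng):
        ts = TrialSet(trials=[Trial(data=rng.standard_normal((3, 20)),
                                    label=CLASS1) for _ in range(4)])
        with pytest.raises(ValueError, match="both classes"):
            fit_csp(ts, m_pairs=1)


class TestFeatures:
    def test_exp_features_sum_to_one(self, rng):
        ts = _labeled_set(rng, m=6, scales=(2.0, 1.0))
        bank, _ = fit_csp(ts, m_pairs=3)
        for t in ts.trials:
            x = extract_features(bank, t)
            assert x.shape == (6,)
            assert abs(np.exp(x).sum() - 1.0) < 1e-10
            assert (x < 0).all()  # each normalized variance < 1

    def test_hand_computed_feature_values(self):
        # identity "filters" on a 2-channel trial with known variances:
        # rows [1,-1,1,-1] (var 1, about mean 0) and [3,3,-3,-3]? use
        # explicit rows var 3 and 1 -> features log(3/4), log(1/4)
        from mitransfer.csp import SpatialFilterBank

        bank = SpatialFilterBank(W=np.eye(2), m_pairs=1,
                                 eigvals_class1=np.array([1.0, 0.0]),
                                 n_channels=2)
        # row 0: values (-3,1,1,1): mean 0, population var 3
        # row 1: values (1,-1,1,-1): mean 0, population var 1
        x = np.array([[-3.0, 1.0, 1.0, 1.0], [1.0, -1.0, 1.0, -1.0]])
        feats = extract_features(bank, x)
        np.testing.assert_allclose(feats, [np.log(0.75), np.log(0.25)],
                                   atol=1e-12)

    def test_zero_variance_row_raises(self):
        from mitransfer.csp import SpatialFilterBank

        bank = SpatialFilterBank(W=np.eye(2), m_pairs=1,
                                 eigvals_class1=np.array([1.0, 0.0]),
                                 n_channels=2)
        x = np.array([[1.0, -1.0, 1.0], [5.0, 5.0, 5.0]])  # row 1 constant
        with pytest.raises(FloatingPointError, match="zero variance"):
            extract_features(bank, x)

    def test_features_invariant_to_trial_scale(self, rng):
        ts = _labeled_set(rng, scales=(2.0, 1.0))
        bank, _ = fit_csp(ts, m_pairs=2)
        t = ts.trials[0]
        np.testing.assert_allclose(extract_features(bank, t),
                                   extract_features(bank, 10.0 * t.data),
                                   atol=1e-10)

    def test_featurize_trialset_shapes_and_error_annotation(self, rng):
        ts = _labeled_set(rng, n_per_class=5, m=6)
        bank, _ = fit_csp(ts, m_pairs=2)
        feats, labels = featurize_trialset(bank, ts)
        assert feats.shape == (10, 4)
        assert labels.shape == (10,)
        bad = TrialSet(trials=[Trial(data=np.vstack([np.ones((1, 20)),
                                                     np.zeros((5, 20))]))])
        with pytest.raises(FloatingPointError, match="trial 0"):
            featurize_trialset(bank, bad)


class TestSklearnEstimator:
    def test_matches_functional_path(self, rng):
        ts = _labeled_set(rng, m=6, scales=(2.5, 0.8))
        X, y = ts.as_array(), ts.labels
        est = CSP(m_pairs=2).fit(X, y)
        bank, _ = fit_csp(ts, m_pairs=2)
        np.testing.assert_allclose(np.abs(est.filters_), np.abs(bank.W),
                                   atol=1e-8)
        feats, _ = featurize_trialset(bank, ts)
        np.testing.assert_allclose(est.transform(X), feats, atol=1e-8)

    def test_transform_feature_normalization(self, rng):
        ts = _labeled_set(rng, m=6, scales=(2.0, 1.0))
        out = CSP(m_pairs=3).fit_transform(ts.as_array(), ts.labels)
        np.testing.assert_allclose(np.exp(out).sum(axis=1), 1.0, atol=1e-10)

    def test_non_binary_labels_rejected(self, rng):
        X = rng.standard_normal((6, 4, 30))
        with pytest.raises(ValueError, match="two-class"):
            CSP(m_pairs=1).fit(X, np.array([0, 1, 2, 0, 1, 2]))

    def test_fit_on_separable_fixture_orders_eigenvalues_extremely(
            self, separable_benchmark):
        # on a strongly separable synthetic set the extreme eigenvalues are
        # far from 0.5 (chance level)
        src, _ = separable_benchmark
        bank, _ = fit_csp(src, m_pairs=2)
        assert bank.eigvals_class1[0] > 0.6
        assert bank.eigvals_class1[-1] < 0.4
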