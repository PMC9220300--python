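"""Fusion and classifier tests: PCA reduction, weighted fusion, MLP behavior."""

import numpy as np
import pandas as pd
import pytest

from edafuse import (FusionMLPClassifier, build_classifier, fuse,
                     mlp_parameter_count, reduce_dim)


def two_loop_fuse_oracle(S, G, P):
    n, d = S.shape
    T = np.zeros((n, d))
    for i in range(n):
        for j in range(d):
            T[i, j] = sum(P[j, k] * G[i, k] for k in range(d))
    return S * T


class TestReduceDim:
    def test_full_rank_lossless(self):
        rng = np.random.default_rng(0)
        G = pd.DataFrame(rng.normal(size=(10, 3)), index=[f"s{i}" for i in range(10)])
        out = reduce_dim(G, d=3)
        # distances are preserved under a rotation
        from scipy.spatial.distance import pdist
        np.testing.assert_allclose(pdist(out.to_numpy()), pdist(G.to_numpy()),
                                   atol=1e-8)

    def test_rank1_single_component_explains_everything(self):
        u = np.linspace(-1, 1, 8)
        G = pd.DataFrame(np.outer(u, [1.0, 2.0, -1.0]),
                         index=[f"s{i}" for i in range(8)])
        out = reduce_dim(G, d=1)
        # all variance lies along the single component
        assert np.var(out.to_numpy()) == pytest.approx(np.var(G.to_numpy(), axis=0).sum())

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(1)
        G = pd.DataFrame(rng.normal(size=(20, 50)), index=[f"s{i}" for i in range(20)])
        fit_rows = [f"s{i}" for i in range(15)]
        out = reduce_dim(G, d=11, fit_rows=fit_rows).to_numpy()
        X = G.loc[fit_rows].to_numpy()
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc / (len(fit_rows) - 1)
        w, V = np.linalg.eigh(cov)
        V = V[:, np.argsort(w)[::-1][:11]]
        want = (G.to_numpy() - X.mean(axis=0)) @ V
        for j in range(11):  # sign per component is arbitrary
            col, ref = out[:, j], want[:, j]
            assert (np.allclose(col, ref, atol=1e-8)
                    or np.allclose(col, -ref, atol=1e-8))

    def test_fit_rows_have_zero_mean(self):
        rng = np.random.default_rng(2)
        G = pd.DataFrame(rng.normal(size=(12, 6)), index=[f"s{i}" for i in range(12)])
        fit_rows = [f"s{i}" for i in range(9)]
        out = reduce_dim(G, d=4, fit_rows=fit_rows)
        np.testing.assert_allclose(out.loc[fit_rows].mean(axis=0), 0.0, atol=1e-8)

    def test_d_too_large_raises(self):
        G = pd.DataFrame(np.eye(3), index=list("abc"))
        with pytest.raises(ValueError):
            reduce_dim(G, d=5)


class TestFuse:
    def test_identity_weights_return_S(self):
        rng = np.random.default_rng(3)
        S = rng.normal(size=(4, 3))
        np.testing.assert_array_equal(fuse(S, np.ones((4, 3)), np.eye(3)), S)

    def test_zero_embedding_annihilates(self):
        S = np.ones((5, 2))
        assert not fuse(S, np.zeros((5, 2)), np.eye(2)).any()

    def test_matches_two_loop_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            S = rng.normal(size=(4, 3))
            G = rng.normal(size=(4, 3))
            P = rng.normal(size=(3, 3))
            np.testing.assert_allclose(fuse(S, G, P),
                                       two_loop_fuse_oracle(S, G, P), atol=1e-10)

    def test_shape_mismatch_names_shapes(self):
        with pytest.raises(ValueError, match=r"\(4, 3\)"):
            fuse(np.zeros((4, 3)), np.zeros((4, 2)), np.eye(3))


class TestClassifierConstruction:
    def test_parameter_count_closed_form(self):
        d = 11
        want = (d * 64 + 64) + (64 * 128 + 128) + (128 * 64 + 64) + (64 * 2 + 2) \
            + 2 * (64 + 128 + 64) + d * d
        clf = build_classifier(d)
        assert clf.n_parameters_ == want == mlp_parameter_count(d)

    def test_same_seed_same_initial_parameters(self):
        a, b = build_classifier(7, seed=5), build_classifier(7, seed=5)
        for wa, wb in zip(a._W, b._W):
            np.testing.assert_array_equal(wa, wb)
        np.testing.assert_array_equal(a.P_, b.P_)
        assert np.array_equal(a.P_, np.eye(7))

    def test_inference_is_deterministic_despite_dropout(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 8))
        y = (X[:, 0] > 0).astype(int)
        clf = FusionMLPClassifier(fusion=False, epochs=30, seed=0).fit(X, y)
        p1, p2 = clf.predict_proba(X), clf.predict_proba(X)
        np.testing.assert_array_equal(p1, p2)


class TestTrainPredict:
    def test_separable_data_high_training_accuracy(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(200, 6))
        y = (X[:, 0] + X[:, 1] > 0).astype(int)
        clf = FusionMLPClassifier(fusion=False, epochs=200, seed=0).fit(X, y)
        assert (clf.predict(X) == y).mean() >= 0.95
        assert clf.loss_history_[-1] < clf.loss_history_[0]

    def test_null_data_held_out_accuracy_near_chance(self):
        accs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(160, 5))
            y = rng.integers(0, 2, size=160)
            clf = FusionMLPClassifier(fusion=False, epochs=60, seed=seed)
            clf.fit(X[:100], y[:100])
            accs.append((clf.predict(X[100:]) == y[100:]).mean())
        n = 60 * 10
        assert abs(np.mean(accs) - 0.5) <= 3 * np.sqrt(0.25 / n)

    def test_same_seed_identical_trained_parameters(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 6))
        y = (X[:, 0] > 0).astype(int)
        a = FusionMLPClassifier(fusion=False, epochs=40, seed=2).fit(X, y)
        b = FusionMLPClassifier(fusion=False, epochs=40, seed=2).fit(X, y)
        for wa, wb in zip(a._W, b._W):
            np.testing.assert_array_equal(wa, wb)

    def test_probabilities_sum_to_one_and_duplicates_match(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(50, 4))
        y = (X[:, 0] > 0).astype(int)
        clf = FusionMLPClassifier(fusion=False, epochs=30, seed=0).fit(X, y)
        X2 = np.vstack([X[:5], X[:5]])
        p = clf.predict_proba(X2)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_array_equal(p[:5], p[5:])

    def test_untrained_model_raises(self):
        clf = FusionMLPClassifier(fusion=False)
        with pytest.raises(Exception):
            clf.predict(np.zeros((3, 4)))

    def test_one_class_training_rejected(self):
        clf = FusionMLPClassifier(fusion=False, epochs=5)
        with pytest.raises(ValueError):
            clf.fit(np.zeros((10, 3)), np.zeros(10))

    def test_frozen_identity_P_with_unit_embedding_equals_sf_only(self):
        """Ablation consistency: all-ones embedding rows and frozen P reduce the
        fusion model exactly to the SF-only classifier."""
        rng = np.random.default_rng(10)
        S = rng.normal(size=(60, 5))
        y = (S[:, 0] > 0).astype(int)
        ones = np.ones_like(S)
        fused = FusionMLPClassifier(fusion=True, learn_transform=False,
                                    epochs=50, seed=1).fit(np.hstack([S, ones]), y)
        sf = FusionMLPClassifier(fusion=False, epochs=50, seed=1).fit(S, y)
        np.testing.assert_array_equal(
            fused.predict_proba(np.hstack([S, ones])), sf.predict_proba(S))
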