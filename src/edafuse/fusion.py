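"""Weighted fusion of statistical features with graph embeddings, and the MLP.

The participant embedding matrix G (real parts of the complex graph
embeddings) is PCA-reduced to the statistical-feature dimension d, each trial
inherits its subject's reduced row ĝ, and the fused per-trial feature is

    F = S ⊗ (P ĝ),

an elementwise product in which the linearly transformed embedding acts as a
learnable per-feature weight on the statistical features. The transformation
matrix P (initialized to the identity) is trained jointly with a small
feed-forward network: three hidden layers of widths 64, 128 and 64, each
followed by batch normalization, ReLU and dropout 0.2, then a 2-unit softmax
output trained with the mean-squared-error criterion against one-hot targets
using the Adam optimizer (cross-entropy available behind a flag).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

__all__ = ["reduce_dim", "fuse", "FusionMLPClassifier", "mlp_parameter_count",
           "build_classifier"]


def reduce_dim(G: pd.DataFrame, d: int, fit_rows: Sequence[str] | None = None) -> pd.DataFrame:
    """PCA-reduce the embedding matrix G to d columns.

    The PCA (with centering) is fitted on ``fit_rows`` only — pass the
    training-fold subjects to keep test subjects out of the fit — and then
    applied to every row of G.
    """
    if fit_rows is None:
        fit_rows = list(G.index)
    fit = G.loc[list(fit_rows)]
    max_d = min(G.shape[1], len(fit))
    if d > max_d:
        raise ValueError(
            f"d={d} too large for PCA fitted on {len(fit)} rows of width {G.shape[1]}"
        )
    pca = PCA(n_components=d, svd_solver="full")
    pca.fit(fit.to_numpy())
    out = pca.transform(G.to_numpy())
    return pd.DataFrame(out, index=G.index, columns=[f"pc{k}" for k in range(d)])


def fuse(S: np.ndarray, G_rows: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Elementwise weighted fusion F = S ⊗ (G_rows Pᵀ).

    ``S`` and ``G_rows`` are (n_trials, d) with matching shapes; each row of
    ``G_rows`` is transformed by the d×d matrix ``P`` and multiplied
    elementwise into the corresponding row of ``S``.
    """
    S = np.asarray(S, dtype=float)
    G_rows = np.asarray(G_rows, dtype=float)
    P = np.asarray(P, dtype=float)
    if S.shape != G_rows.shape:
        raise ValueError(f"shape mismatch: S {S.shape} vs embedding rows {G_rows.shape}")
    if P.shape != (S.shape[1], S.shape[1]):
        raise ValueError(f"P must be {S.shape[1]}×{S.shape[1]}, got {P.shape}")
    return S * (G_rows @ P.T)


def mlp_parameter_count(d: int, hidden: tuple[int, ...] = (64, 128, 64),
                        n_out: int = 2, with_transform: bool = True) -> int:
    """Closed-form trainable-parameter count of the fusion network.

    Sums dense weights and biases, batch-norm scale/shift pairs per hidden
    layer, and (optionally) the d×d transformation matrix P.
    """
    sizes = (d, *hidden, n_out)
    n = sum(a * b + b for a, b in zip(sizes[:-1], sizes[1:]))
    n += sum(2 * h for h in hidden)  # batch-norm gamma/beta
    if with_transform:
        n += d * d
    return n


def _softmax_rows(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class FusionMLPClassifier(BaseEstimator, ClassifierMixin):
    """MLP over fused statistical + embedding features, trained with MSE on softmax.

    Parameters
    ----------
    fusion : bool, default True
        If True, ``X`` must be ``(n, 2d)``: the first d columns are the
        statistical features S and the last d the subject's PCA-reduced
        embedding row; the model learns P and classifies F = S ⊗ (P ĝ).
        If False, ``X`` is ``(n, d)`` and used directly (SF-only mode).
    hidden : tuple of int, default (64, 128, 64)
        Hidden-layer widths; batch norm, ReLU and dropout follow each.
    dropout : float, default 0.2
    epochs : int, default 700
    lr : float, default 1e-3
        Adam learning rate.
    loss : {"mse", "ce"}, default "mse"
        MSE between softmax outputs and one-hot targets, or cross-entropy.
    class_weight : None or "balanced", default None
        "balanced" weights samples inversely to their class frequency in the
        training set, so the fitted model does not inherit training-fold
        class imbalance.
    learn_transform : bool, default True
        If False, P stays frozen at the identity.
    seed : int, default 0

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
    P_ : ndarray of shape (d, d)
        Learned transformation matrix (fusion mode).
    loss_history_ : list of float
        Training loss per epoch; strictly computed in training mode.
    n_parameters_ : int
    """

    def __init__(self, fusion: bool = True, hidden: tuple[int, ...] = (64, 128, 64),
                 dropout: float = 0.2, epochs: int = 700, lr: float = 1e-3,
                 loss: str = "mse", class_weight: str | None = None,
                 learn_transform: bool = True, seed: int = 0):
        self.fusion = fusion
        self.hidden = hidden
        self.dropout = dropout
        self.epochs = epochs
        self.lr = lr
        self.loss = loss
        self.class_weight = class_weight
        self.learn_transform = learn_transform
        self.seed = seed

    # ------------------------------------------------------------------ setup

    def _split_X(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.fusion:
            if X.shape[1] % 2 != 0:
                raise ValueError(
                    f"fusion mode expects (n, 2d) input, got {X.shape[1]} columns"
                )
            d = X.shape[1] // 2
            return X[:, :d], X[:, d:]
        return X, None

    def _init_params(self, d: int, rng: np.random.Generator) -> None:
        sizes = (d, *self.hidden, 2)
        self._W = [rng.normal(0, np.sqrt(2.0 / a), (a, b))
                   for a, b in zip(sizes[:-1], sizes[1:])]
        self._b = [np.zeros(b) for b in sizes[1:]]
        self._gamma = [np.ones(h) for h in self.hidden]
        self._beta = [np.zeros(h) for h in self.hidden]
        self._run_mean = [np.zeros(h) for h in self.hidden]
        self._run_var = [np.ones(h) for h in self.hidden]
        self.P_ = np.eye(d)

    def _params_list(self) -> list[np.ndarray]:
        ps = [*self._W, *self._b, *self._gamma, *self._beta]
        if self.fusion and self.learn_transform:
            ps.append(self.P_)
        return ps

    # ---------------------------------------------------------------- forward

    def _forward(self, F: np.ndarray, training: bool,
                 rng: np.random.Generator | None = None):
        """Forward pass on fused features F; returns probs and a tape for backprop."""
        eps = 1e-5
        a = F
        tape = []
        n_hidden = len(self.hidden)
        for l in range(n_hidden):
            z = a @ self._W[l] + self._b[l]
            if training:
                mu = z.mean(axis=0)
                var = z.var(axis=0)
                self._run_mean[l] = 0.9 * self._run_mean[l] + 0.1 * mu
                self._run_var[l] = 0.9 * self._run_var[l] + 0.1 * var
            else:
                mu, var = self._run_mean[l], self._run_var[l]
            inv_std = 1.0 / np.sqrt(var + eps)
            zhat = (z - mu) * inv_std
            bn = self._gamma[l] * zhat + self._beta[l]
            relu = np.maximum(bn, 0.0)
            if training and self.dropout > 0:
                keep = 1.0 - self.dropout
                mask = (rng.random(relu.shape) < keep) / keep
            else:
                mask = np.ones_like(relu)
            out = relu * mask
            tape.append((a, z, zhat, inv_std, bn, mask))
            a = out
        z_out = a @ self._W[-1] + self._b[-1]
        p = _softmax_rows(z_out)
        tape.append((a, z_out))
        return p, tape

    def _backward(self, p: np.ndarray, Y: np.ndarray, tape, S=None, G=None,
                  w: np.ndarray | None = None):
        """Analytic gradients of the configured loss w.r.t. every parameter."""
        n = p.shape[0]
        w_col = np.ones((n, 1)) if w is None else w[:, None]
        if self.loss == "mse":
            g = w_col * 2.0 * (p - Y) / p.size
            dz = p * (g - (g * p).sum(axis=1, keepdims=True))
        else:  # cross-entropy + softmax
            dz = w_col * (p - Y) / n
        gW = [np.zeros_like(w) for w in self._W]
        gb = [np.zeros_like(b) for b in self._b]
        gGamma = [np.zeros_like(gm) for gm in self._gamma]
        gBeta = [np.zeros_like(bt) for bt in self._beta]

        a_last, _ = tape[-1]
        gW[-1] = a_last.T @ dz
        gb[-1] = dz.sum(axis=0)
        da = dz @ self._W[-1].T
        for l in range(len(self.hidden) - 1, -1, -1):
            a_in, z, zhat, inv_std, bn, mask = tape[l]
            d_relu = da * mask
            d_bn = d_relu * (bn > 0)
            gGamma[l] = (d_bn * zhat).sum(axis=0)
            gBeta[l] = d_bn.sum(axis=0)
            d_zhat = d_bn * self._gamma[l]
            m = z.shape[0]
            dz_l = inv_std * (
                d_zhat - d_zhat.mean(axis=0) - zhat * (d_zhat * zhat).mean(axis=0)
            )
            gW[l] = a_in.T @ dz_l
            gb[l] = dz_l.sum(axis=0)
            da = dz_l @ self._W[l].T

        grads = [*gW, *gb, *gGamma, *gBeta]
        if self.fusion and self.learn_transform:
            # F = S ∘ (G Pᵀ): dL/dP = (dL/dF ∘ S)ᵀ G
            dF = da
            grads.append((dF * S).T @ G)
        return grads

    # -------------------------------------------------------------------- fit

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FusionMLPClassifier":
        S, G = self._split_X(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError(
                f"expected exactly 2 classes in y, got {self.classes_.size}"
            )
        Y = np.zeros((len(y), 2))
        cls_idx = np.searchsorted(self.classes_, y)
        Y[np.arange(len(y)), cls_idx] = 1.0
        if self.loss not in ("mse", "ce"):
            raise ValueError(f"loss must be 'mse' or 'ce', got {self.loss!r}")
        if self.class_weight is None:
            w = None
        elif self.class_weight == "balanced":
            counts = np.bincount(cls_idx, minlength=2)
            w = (len(y) / (2.0 * counts))[cls_idx]
        else:
            raise ValueError(f"class_weight must be None or 'balanced', got {self.class_weight!r}")

        d = S.shape[1]
        rng = np.random.default_rng(self.seed)
        self._init_params(d, rng)
        params = self._params_list()
        m_adam = [np.zeros_like(p) for p in params]
        v_adam = [np.zeros_like(p) for p in params]
        b1, b2, eps = 0.9, 0.999, 1e-8
        self.loss_history_: list[float] = []

        for t in range(1, self.epochs + 1):
            F = fuse(S, G, self.P_) if self.fusion else S
            p, tape = self._forward(F, training=True, rng=rng)
            wv = np.ones(len(y)) if w is None else w
            if self.loss == "mse":
                loss = float(np.mean(wv[:, None] * (p - Y) ** 2))
            else:
                loss = float(np.mean(
                    -wv * np.log(np.clip(p[np.arange(len(y)), cls_idx], 1e-12, None))
                ))
            if not np.isfinite(loss):
                raise FloatingPointError("non-finite training loss")
            self.loss_history_.append(loss)
            grads = self._backward(p, Y, tape, S=S, G=G, w=w)
            params = self._params_list()
            for i, (prm, grd) in enumerate(zip(params, grads)):
                m_adam[i] = b1 * m_adam[i] + (1 - b1) * grd
                v_adam[i] = b2 * v_adam[i] + (1 - b2) * grd**2
                mhat = m_adam[i] / (1 - b1**t)
                vhat = v_adam[i] / (1 - b2**t)
                prm -= self.lr * mhat / (np.sqrt(vhat) + eps)

        self.n_parameters_ = mlp_parameter_count(
            d, tuple(self.hidden), 2, with_transform=self.fusion
        )
        self.n_features_in_ = X.shape[1]
        return self

    # -------------------------------------------------------------- inference

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "classes_")
        S, G = self._split_X(X)
        F = fuse(S, G, self.P_) if self.fusion else S
        p, _ = self._forward(F, training=False)
        return p

    def predict(self, X: np.ndarray) -> np.ndarray:
        p = self.predict_proba(X)
        return self.classes_[np.argmax(p, axis=1)]  # argmax ties -> first class

    # ----------------------------------------------------------- persistence

    def save(self, path) -> None:
        """Checkpoint layer shapes, weights, batch-norm state and P as JSON."""
        import json

        check_is_fitted(self, "classes_")
        payload = {
            "hidden": list(self.hidden),
            "fusion": self.fusion,
            "classes": self.classes_.tolist(),
            "W": [w.tolist() for w in self._W],
            "b": [b.tolist() for b in self._b],
            "gamma": [g.tolist() for g in self._gamma],
            "beta": [b.tolist() for b in self._beta],
            "run_mean": [m.tolist() for m in self._run_mean],
            "run_var": [v.tolist() for v in self._run_var],
            "P": self.P_.tolist(),
            "loss_history": self.loss_history_,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "FusionMLPClassifier":
        """Restore a checkpoint written by :meth:`save`."""
        import json

        with open(path) as fh:
            d = json.load(fh)
        clf = cls(fusion=d["fusion"], hidden=tuple(d["hidden"]))
        clf.classes_ = np.asarray(d["classes"])
        clf._W = [np.asarray(w) for w in d["W"]]
        clf._b = [np.asarray(b) for b in d["b"]]
        clf._gamma = [np.asarray(g) for g in d["gamma"]]
        clf._beta = [np.asarray(b) for b in d["beta"]]
        clf._run_mean = [np.asarray(m) for m in d["run_mean"]]
        clf._run_var = [np.asarray(v) for v in d["run_var"]]
        clf.P_ = np.asarray(d["P"])
        clf.loss_history_ = list(d["loss_history"])
        return clf


def build_classifier(d: int, seed: int = 0, **kwargs) -> FusionMLPClassifier:
    """Construct an untrained fusion network with initialized parameters.

    Weights are He-initialized from ``seed``; P starts at the identity so the
    embedding initially passes through unchanged. The returned estimator is
    ready for :meth:`FusionMLPClassifier.fit`.
    """
    clf = FusionMLPClassifier(seed=seed, **kwargs)
    rng = np.random.default_rng(seed)
    clf._init_params(d, rng)
    clf.n_parameters_ = mlp_parameter_count(d, tuple(clf.hidden), 2,
                                            with_transform=clf.fusion)
    return clf
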