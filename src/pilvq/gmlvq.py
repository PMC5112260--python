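"""Generalized Matrix Learning Vector Quantization (GMLVQ).

A prototype-based classifier with an adaptive full metric tensor.  Each
class is represented by a prototype w_q in feature space; the distance of
an input x to a prototype is the quadratic form

    d_Lambda(x, w) = (x - w)^T Lambda (x - w),      Lambda = Omega^T Omega,

so Lambda is positive semi-definite by construction and, beyond per-feature
scaling, accounts for pairwise feature interplay.  Training minimizes the
cost  sum_i phi(mu(x_i))  with the relative distance difference

    mu(x) = (d+ - d-) / (d+ + d-),

where d+ (d-) is the distance to the closest prototype of the correct
(a wrong) class, by per-example steepest descent on both the prototypes
and Omega.  Lambda is renormalized to unit trace after every learning
step, which fixes the otherwise arbitrary global scale of the metric.
Classification is winner-takes-all over prototypes.

The diagonal of the learned Lambda ranks feature relevance; off-diagonal
elements expose discriminative feature interplay (see
:mod:`pilvq.relevance`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "GMLVQClassifier",
    "TrainConfig",
    "gmlvq_distance",
    "compute_mu",
    "gmlvq_train",
    "gmlvq_predict",
    "normalize_metric_tensor",
]


def gmlvq_distance(x: np.ndarray, w: np.ndarray, lam: np.ndarray) -> float:
    """Quadratic-form distance (x - w)^T Lambda (x - w)."""
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if x.shape != w.shape or lam.shape != (x.size, x.size):
        raise ValueError(
            f"dimension mismatch: x{x.shape}, w{w.shape}, Lambda{lam.shape}"
        )
    e = x - w
    return float(e @ lam @ e)


def compute_mu(d_plus: float, d_minus: float) -> float:
    """Relative distance difference in [-1, 1]; negative = correct side."""
    if d_plus < 0 or d_minus < 0:
        raise ValueError("distances must be nonnegative")
    s = d_plus + d_minus
    if s == 0:
        warnings.warn("both prototype distances are zero; mu defined as 0")
        return 0.0
    return (d_plus - d_minus) / s


def normalize_metric_tensor(lam: np.ndarray) -> np.ndarray:
    """Rescale a PSD metric tensor so its eigenvalues sum to one.

    Same eigenvectors, eigenvalues divided by their sum — equivalently
    Lambda / trace(Lambda), reconstructed through the eigendecomposition.
    """
    lam = np.asarray(lam, dtype=float)
    if lam.ndim != 2 or lam.shape[0] != lam.shape[1]:
        raise ValueError("Lambda must be square")
    if not np.allclose(lam, lam.T, atol=1e-10):
        raise ValueError("Lambda must be symmetric")
    vals, vecs = np.linalg.eigh(lam)
    total = vals.sum()
    if total <= 0:
        raise ValueError("metric tensor has nonpositive trace")
    vals = vals / total
    return (vecs * vals) @ vecs.T


@dataclass
class TrainConfig:
    """Optimizer constants for online GMLVQ training."""

    lr_prototype: float = 0.01
    lr_omega: float = 0.001
    epochs: int = 300
    final_lr_fraction: float = 0.1
    prototype_init_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.lr_omega > self.lr_prototype:
            warnings.warn("lr_omega > lr_prototype (unconventional)")


def _mu_gradients(x, wp, wm, omega):
    """Analytic gradients of mu w.r.t. w+, w-, Omega (before trace renorm)."""
    lam = omega.T @ omega
    ep = x - wp
    em = x - wm
    dp = float(ep @ lam @ ep)
    dm = float(em @ lam @ em)
    s = dp + dm
    if s == 0:
        z = np.zeros_like
        return z(wp), z(wm), np.zeros_like(omega), dp, dm
    gp = 2.0 * dm / s**2   # dmu/dd+
    gm = -2.0 * dp / s**2  # dmu/dd-
    grad_wp = gp * (-2.0 * lam @ ep)
    grad_wm = gm * (-2.0 * lam @ em)
    grad_omega = 2.0 * omega @ (gp * np.outer(ep, ep) + gm * np.outer(em, em))
    return grad_wp, grad_wm, grad_omega, dp, dm


class GMLVQClassifier(BaseEstimator, ClassifierMixin):
    """GMLVQ with one prototype per class and an adaptive full metric.

    Parameters
    ----------
    lr_prototype, lr_omega : float
        Initial learning rates for the prototype and metric updates; both
        decay linearly to ``final_lr_fraction`` of their start value.
    epochs : int
        Passes over the (shuffled) training data.
    prototype_init_fraction : float in (0, 1]
        Prototypes are initialized as the mean of a random subset of this
        fraction of the class's training points.
    scale : bool
        Z-score features with training statistics inside the model
        (recommended for heterogeneous units such as dots vs. ms).
    train_metric : bool
        If False, Lambda stays fixed at ``initial_lambda`` and only the
        prototypes are trained (used when an externally learned metric is
        imposed).
    initial_lambda : ndarray or None
        Starting metric; default identity / m (unit trace).
    random_state : int or None
        Seed for prototype initialization and example shuffling.

    Attributes
    ----------
    prototypes_ : ndarray (n_classes, m), in the scaled space
    prototype_labels_ : ndarray (n_classes,)
    omega_, lambda_ : ndarray (m, m); trace(lambda_) == 1
    cost_trace_ : per-epoch mean of mu
    """

    def __init__(
        self,
        lr_prototype: float = 0.01,
        lr_omega: float = 0.001,
        epochs: int = 300,
        final_lr_fraction: float = 0.1,
        prototype_init_fraction: float = 0.5,
        scale: bool = True,
        train_metric: bool = True,
        initial_lambda: np.ndarray | None = None,
        random_state: int | None = None,
    ):
        self.lr_prototype = lr_prototype
        self.lr_omega = lr_omega
        self.epochs = epochs
        self.final_lr_fraction = final_lr_fraction
        self.prototype_init_fraction = prototype_init_fraction
        self.scale = scale
        self.train_metric = train_metric
        self.initial_lambda = initial_lambda
        self.random_state = random_state

    # -- helpers ----------------------------------------------------------

    def _apply_scaler(self, X):
        return (X - self.scaler_mean_) / self.scaler_scale_

    def _init_prototypes(self, Xs, y, rng):
        protos = []
        for c in self.classes_:
            Xc = Xs[y == c]
            n_sub = max(1, int(round(self.prototype_init_fraction * len(Xc))))
            idx = rng.choice(len(Xc), size=n_sub, replace=False)
            protos.append(Xc[idx].mean(axis=0))
        return np.array(protos)

    def _winner_indices(self, e_all_dists, yi_class_idx):
        """Closest correct and closest wrong prototype indices."""
        same = self.prototype_labels_idx_ == yi_class_idx
        dp_idx = np.flatnonzero(same)[np.argmin(e_all_dists[same])]
        dm_idx = np.flatnonzero(~same)[np.argmin(e_all_dists[~same])]
        return dp_idx, dm_idx

    # -- sklearn API ------------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if np.isnan(X).any():
            raise ValueError("NaN in input")
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("need at least 2 classes present in y")
        n, m = X.shape
        rng = np.random.default_rng(self.random_state)

        if self.scale:
            self.scaler_mean_ = X.mean(axis=0)
            sd = X.std(axis=0)
            self.scaler_scale_ = np.where(sd > 0, sd, 1.0)
        else:
            self.scaler_mean_ = np.zeros(m)
            self.scaler_scale_ = np.ones(m)
        Xs = self._apply_scaler(X)

        self.prototype_labels_ = self.classes_.copy()
        class_index = {c: i for i, c in enumerate(self.classes_)}
        self.prototype_labels_idx_ = np.arange(self.classes_.size)
        y_idx = np.array([class_index[c] for c in y])
        W = self._init_prototypes(Xs, y, rng)

        if self.initial_lambda is not None:
            lam0 = np.asarray(self.initial_lambda, dtype=float)
            lam0 = lam0 / np.trace(lam0)
            # Omega = principal square root (symmetric), for completeness
            vals, vecs = np.linalg.eigh(lam0)
            vals = np.clip(vals, 0.0, None)
            omega = (vecs * np.sqrt(vals)) @ vecs.T
        else:
            omega = np.eye(m) / np.sqrt(m)
        lam = omega.T @ omega
        lam /= np.trace(lam)

        cost_trace = []
        for epoch in range(self.epochs):
            frac = epoch / max(1, self.epochs - 1)
            decay = 1.0 + frac * (self.final_lr_fraction - 1.0)
            lr_w = self.lr_prototype * decay
            lr_om = self.lr_omega * decay
            order = rng.permutation(n)
            mu_sum = 0.0
            for i in order:
                x = Xs[i]
                diffs = x - W
                dists = np.einsum("ij,jk,ik->i", diffs, lam, diffs)
                p_idx, m_idx = self._winner_indices(dists, y_idx[i])
                wp, wm = W[p_idx], W[m_idx]
                grad_wp, grad_wm, grad_om, dp, dm = _mu_gradients(x, wp, wm, omega)
                mu_sum += compute_mu(dp, dm) if dp + dm > 0 else 0.0
                W[p_idx] = wp - lr_w * grad_wp
                W[m_idx] = wm - lr_w * grad_wm
                if self.train_metric:
                    omega = omega - lr_om * grad_om
                    lam = omega.T @ omega
                    tr = np.trace(lam)
                    if tr <= 0:
                        raise FloatingPointError("metric collapsed during training")
                    omega = omega / np.sqrt(tr)
                    lam = lam / tr
            cost_trace.append(mu_sum / n)

        self.prototypes_ = W
        self.omega_ = omega
        self.lambda_ = 0.5 * (lam + lam.T)
        self.cost_trace_ = cost_trace
        self.n_features_in_ = m
        return self

    def _distances(self, X):
        Xs = self._apply_scaler(np.asarray(X, dtype=float))
        if Xs.ndim == 1:
            Xs = Xs[None]
        if Xs.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {Xs.shape[1]}"
            )
        diffs = Xs[:, None, :] - self.prototypes_[None, :, :]
        return np.einsum("npj,jk,npk->np", diffs, self.lambda_, diffs)

    def predict(self, X):
        labels, _ = self.predict_with_distance(X)
        return labels

    def predict_with_distance(self, X):
        """Winner-takes-all labels plus the winning prototype distance.

        Exact distance ties are broken toward the smallest class label
        (deterministic), with a warning.
        """
        D = self._distances(X)
        labels = np.empty(D.shape[0], dtype=self.classes_.dtype)
        winner = np.empty(D.shape[0])
        for i, row in enumerate(D):
            best = row.min()
            cand = np.flatnonzero(row == best)
            if cand.size > 1 and np.unique(self.prototype_labels_[cand]).size > 1:
                warnings.warn("equidistant prototypes; tie broken to lowest class label")
            labels[i] = min(self.prototype_labels_[cand].tolist())
            winner[i] = best
        return labels, winner

    def class_winner_distance(self, X, label, lam_override: np.ndarray | None = None):
        """Distance to the closest prototype of a given class.

        ``lam_override`` substitutes a (e.g. eigenvalue-normalized) metric
        tensor for cross-classifier confidence comparison.
        """
        Xs = self._apply_scaler(np.asarray(X, dtype=float))
        if Xs.ndim == 1:
            Xs = Xs[None]
        lam = self.lambda_ if lam_override is None else lam_override
        mask = self.prototype_labels_ == label
        if not mask.any():
            raise ValueError(f"no prototype with label {label!r}")
        diffs = Xs[:, None, :] - self.prototypes_[None, mask, :]
        d = np.einsum("npj,jk,npk->np", diffs, lam, diffs)
        return d.min(axis=1)

    def cost(self, X, y):
        """Mean mu over a labelled sample (the phi=identity cost / n)."""
        D = self._distances(X)
        y = np.asarray(y)
        total = 0.0
        for i in range(D.shape[0]):
            same = self.prototype_labels_ == y[i]
            dp = D[i][same].min()
            dm = D[i][~same].min()
            total += compute_mu(dp, dm) if dp + dm > 0 else 0.0
        return total / D.shape[0]


def gmlvq_train(X, y, config: TrainConfig | None = None, **kwargs) -> GMLVQClassifier:
    cfg = config or TrainConfig()
    model = GMLVQClassifier(
        lr_prototype=cfg.lr_prototype,
        lr_omega=cfg.lr_omega,
        epochs=cfg.epochs,
        final_lr_fraction=cfg.final_lr_fraction,
        prototype_init_fraction=cfg.prototype_init_fraction,
        random_state=cfg.seed,
        **kwargs,
    )
    return model.fit(X, y)


def gmlvq_predict(model: GMLVQClassifier, x):
    labels, dists = model.predict_with_distance(np.atleast_2d(x))
    return labels[0], float(dists[0])
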