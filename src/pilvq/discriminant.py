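"""Fisher discriminants for vectors (LDA) and symmetric matrices (2D-LDA).

Both extractors project onto a one-dimensional discriminative space.
Standard LDA finds ``w`` maximizing the Fisher ratio
``J(w) = (w^T S_B w) / (w^T S_W w)``.  2D-LDA operates on matrix-valued
observations X (here: reduced connectivity graphs) through a bilinear form
``f = a^T X b`` and maximizes the ratio of squared between-class to summed
squared within-class bilinear forms by alternating exact one-dimensional
generalized Rayleigh-quotient steps in ``a`` and ``b``.

The edge-importance matrix ``I = (a b^T + b a^T) / 2`` turns a fitted
bilinear projection into symmetric per-edge discriminative weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "LDAProjection",
    "TwoDLDAProjection",
    "FisherLDA",
    "TwoDLDA",
    "fit_lda",
    "fit_2dlda",
    "project_graphs",
    "compute_importance_matrix",
]


@dataclass
class LDAProjection:
    w_opt: np.ndarray
    fisher_J: float


@dataclass
class TwoDLDAProjection:
    a_opt: np.ndarray
    b_opt: np.ndarray
    J_trace: list[float]
    converged: bool


def _regularize(S: np.ndarray, eps_scale: float = 1e-6) -> np.ndarray:
    d = S.shape[0]
    tr = np.trace(S)
    eps = eps_scale * (tr / d if tr > 0 else 1.0)
    return S + eps * np.eye(d)


def _two_class_split(X, y):
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.size}")
    return classes, X[y == classes[0]], X[y == classes[1]]


class FisherLDA(BaseEstimator, TransformerMixin):
    """One-dimensional Fisher discriminant with scatter regularization.

    Fitted attributes: ``w_`` (unit-norm direction), ``fisher_j_``
    (achieved ratio), ``classes_``.
    """

    def __init__(self, reg: float = 1e-6):
        self.reg = reg

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        classes, X1, X2 = _two_class_split(X, y)
        m1, m2 = X1.mean(axis=0), X2.mean(axis=0)
        dm = m2 - m1
        Sw = np.zeros((X.shape[1],) * 2)
        for Xc, mc in ((X1, m1), (X2, m2)):
            D = Xc - mc
            Sw += D.T @ D
        Sw = _regularize(Sw, self.reg)
        try:
            w = scipy.linalg.solve(Sw, dm, assume_a="pos")
        except scipy.linalg.LinAlgError as exc:
            raise ValueError("within-class scatter singular after regularization") from exc
        norm = np.linalg.norm(w)
        if norm == 0:
            w = np.zeros_like(dm)
            w[0] = 1.0
        else:
            w = w / norm
        Sb = np.outer(dm, dm)
        denom = float(w @ Sw @ w)
        self.classes_ = classes
        self.w_ = w
        self.fisher_j_ = float(w @ Sb @ w) / denom if denom > 0 else 0.0
        return self

    def transform(self, X):
        return np.asarray(X, dtype=float) @ self.w_


def fit_lda(vectors, labels, reg: float = 1e-6) -> LDAProjection:
    m = FisherLDA(reg=reg).fit(np.asarray(vectors), labels)
    return LDAProjection(w_opt=m.w_, fisher_J=m.fisher_j_)


class TwoDLDA(BaseEstimator, TransformerMixin):
    """Bilinear (rank-one) discriminant for symmetric matrix observations.

    Parameters
    ----------
    tol : float
        Relative change in J below which alternation stops.
    max_iter : int
        Maximum number of (a, b) alternation rounds.
    reg : float
        Scale of the ridge added to within-class quadratic forms.
    positive_label :
        Class whose mean projected feature is made the larger one by the
        joint sign convention on (a, b); default: the lexically larger
        class label.

    Fitted attributes: ``a_``, ``b_`` (unit norm), ``j_trace_`` (monotone
    non-decreasing), ``converged_``, ``classes_``.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 100,
                 reg: float = 1e-6, positive_label=None):
        self.tol = tol
        self.max_iter = max_iter
        self.reg = reg
        self.positive_label = positive_label

    def _j_value(self, a, b, dM, centered) -> float:
        between = float(a @ dM @ b) ** 2
        within = float(np.sum((np.einsum("i,nij,j->n", a, centered, b)) ** 2))
        if within <= 0:
            raise ValueError("degenerate within-class variation (identical matrices?)")
        return between / within

    @staticmethod
    def _best_direction(dM_vec, U):
        """Maximize (x^T v)^2 / sum_n (x^T u_n)^2 — a generalized eigenproblem."""
        B = np.outer(dM_vec, dM_vec)
        W = U.T @ U
        W = _regularize(W)
        vals, vecs = scipy.linalg.eigh(B, W)
        x = vecs[:, -1]
        return x / np.linalg.norm(x)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[1] != X.shape[2]:
            raise ValueError("X must be (n_samples, d, d)")
        if not np.allclose(X, np.swapaxes(X, 1, 2), atol=1e-10):
            raise ValueError("input matrices must be symmetric")
        classes, X1, X2 = _two_class_split(X, y)
        M1, M2 = X1.mean(axis=0), X2.mean(axis=0)
        dM = M2 - M1
        centered = np.concatenate([X1 - M1, X2 - M2], axis=0)
        d = X.shape[1]

        b = np.full(d, 1.0 / np.sqrt(d))
        a = self._best_direction(dM @ b, centered @ b)
        j = self._j_value(a, b, dM, centered)
        trace = [j]
        converged = False
        for _ in range(self.max_iter):
            b_new = self._best_direction(dM.T @ a, centered.transpose(0, 2, 1) @ a)
            a_new = self._best_direction(dM @ b_new, centered @ b_new)
            j_new = self._j_value(a_new, b_new, dM, centered)
            if j_new < j:  # numerical stall: keep the better iterate
                converged = True
                break
            a, b = a_new, b_new
            rel = (j_new - j) / j if j > 0 else np.inf
            j = j_new
            trace.append(j)
            if rel < self.tol:
                converged = True
                break

        # sign convention: the bilinear feature is invariant under a joint
        # flip of (a, b); the observable ambiguity is their relative sign.
        # Flip b alone so the positive class mean feature >= the other's.
        y_arr = np.asarray(y)
        pos = self.positive_label if self.positive_label is not None else classes[-1]
        f = np.einsum("i,nij,j->n", a, X, b)
        if f[y_arr == pos].mean() < f[y_arr != pos].mean():
            b = -b
        self.classes_ = classes
        self.a_ = a
        self.b_ = b
        self.j_trace_ = trace
        self.converged_ = converged
        self.n_iter_ = len(trace) - 1
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        if X.shape[1] != self.a_.size or X.shape[2] != self.b_.size:
            raise ValueError(
                f"matrices of shape {X.shape[1:]} incompatible with "
                f"projection of size {self.a_.size}"
            )
        return np.einsum("i,nij,j->n", self.a_, X, self.b_)

    @property
    def importance_matrix_(self) -> np.ndarray:
        return 0.5 * (np.outer(self.a_, self.b_) + np.outer(self.b_, self.a_))


def fit_2dlda(matrices, labels, tol: float = 1e-8, max_iter: int = 100,
              positive_label=None) -> TwoDLDAProjection:
    m = TwoDLDA(tol=tol, max_iter=max_iter, positive_label=positive_label)
    m.fit(np.asarray(matrices), labels)
    return TwoDLDAProjection(
        a_opt=m.a_, b_opt=m.b_, J_trace=m.j_trace_, converged=m.converged_
    )


def project_graphs(proj: TwoDLDAProjection, matrices) -> np.ndarray:
    """Bilinear features a^T X b for a list/stack of matrices."""
    X = np.asarray(matrices, dtype=float)
    if X.ndim == 2:
        X = X[None]
    if X.shape[1] != proj.a_opt.size or X.shape[2] != proj.b_opt.size:
        raise ValueError("dimension mismatch between projection and matrices")
    return np.einsum("i,nij,j->n", proj.a_opt, X, proj.b_opt)


def compute_importance_matrix(proj: TwoDLDAProjection) -> np.ndarray:
    """Symmetric edge-importance matrix I = (a b^T + b a^T) / 2."""
    a, b = proj.a_opt, proj.b_opt
    return 0.5 * (np.outer(a, b) + np.outer(b, a))
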