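"""Privileged-information guided metric learning for GMLVQ.

Privileged data (here: fMRI-derived features) exist only at training time.
Their influence is transferred to the original feature space (cognitive
scores) by metric learning:

1. train a GMLVQ in the privileged space to obtain a discriminative
   metric Lambda*;
2. train a baseline GMLVQ in the original space (metric Lambda,
   prototypes);
3. tag subject pairs as *similar* (privileged distance below the a*-th
   percentile and same class label) or *dissimilar* (above the b*-th
   percentile and different labels);
4. learn Lambda_new in the original space by Information-Theoretic Metric
   Learning (ITML): minimize the LogDet divergence to the prior Lambda
   subject to the tagged pairs being closer than l / farther than u,
   where l and u are the a-th / b-th percentiles of original-space
   pairwise distances under Lambda (slack-relaxed Bregman projections);
5. freeze Lambda_new (trace-normalized) and retrain the prototypes only.

The resulting classifier predicts from the original features alone.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold

from .gmlvq import GMLVQClassifier, normalize_metric_tensor

__all__ = [
    "PairConstraintSets",
    "PIMetricConfig",
    "build_pair_sets",
    "itml_fit",
    "PrivilegedGMLVQClassifier",
    "train_pi_gmlvq",
    "tune_percentile_bounds",
]


@dataclass
class PairConstraintSets:
    s_plus: list[tuple[int, int]]
    s_minus: list[tuple[int, int]]
    l_star: float
    u_star: float
    a_star: float
    b_star: float


@dataclass
class PIMetricConfig:
    """Percentile bounds and ITML constants.

    ``a_star``/``b_star`` are lower/upper percentiles (in percent, e.g. 10
    and 90) of the privileged-space pairwise distance distribution that
    set the similar/dissimilar thresholds l*, u*; ``a``/``b`` play the
    same role for the original-space ITML targets l, u.  ``slack`` is the
    ITML gamma (soft-constraint trade-off); sweeps stop when the largest
    dual update falls below ``tol``.
    """

    a_star: float = 10.0
    b_star: float = 90.0
    a: float = 10.0
    b: float = 90.0
    slack: float = 1.0
    max_sweeps: int = 1000
    tol: float = 1e-3

    def __post_init__(self):
        for lo, hi, names in ((self.a_star, self.b_star, "a*/b*"),
                              (self.a, self.b, "a/b")):
            if not 0 < lo < hi < 100:
                raise ValueError(f"percentiles {names} must satisfy 0 < a < b < 100")


def _pairwise_sq_distances(X: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Condensed upper-triangle (i < j) quadratic-form distances."""
    n = X.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    diffs = X[iu] - X[ju]
    return np.einsum("pj,jk,pk->p", diffs, lam, diffs), iu, ju


def build_pair_sets(privileged_vectors, labels, lambda_star, config: PIMetricConfig
                    ) -> PairConstraintSets:
    """Tag index pairs as similar / dissimilar from privileged distances.

    A pair (i, j), i < j, enters S+ when its privileged distance is at
    most the a*-percentile l* *and* the labels agree; it enters S- when
    the distance is at least the b*-percentile u* *and* the labels
    differ.  Pairs meeting neither conjunction are unconstrained.
    """
    X = np.asarray(privileged_vectors, dtype=float)
    y = np.asarray(labels)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 subjects with privileged data")
    d, iu, ju = _pairwise_sq_distances(X, np.asarray(lambda_star, dtype=float))
    l_star = float(np.percentile(d, config.a_star))
    u_star = float(np.percentile(d, config.b_star))
    degenerate = np.ptp(d) == 0  # all pairs equally distant: thresholds coincide
    if u_star <= l_star and not degenerate:
        raise ValueError(
            f"u* = {u_star:.3g} <= l* = {l_star:.3g}; "
            "choose different percentile bounds"
        )
    s_plus, s_minus = [], []
    for k in range(d.size):
        i, j = int(iu[k]), int(ju[k])
        if d[k] <= l_star and y[i] == y[j]:
            s_plus.append((i, j))
        elif d[k] >= u_star and y[i] != y[j]:
            s_minus.append((i, j))
    return PairConstraintSets(
        s_plus=s_plus, s_minus=s_minus, l_star=l_star, u_star=u_star,
        a_star=config.a_star, b_star=config.b_star,
    )


def itml_fit(original_vectors, constraints: PairConstraintSets,
             prior_lambda, l: float, u: float,
             config: PIMetricConfig | None = None) -> np.ndarray:
    """Information-theoretic metric learning by cyclic Bregman projections.

    Finds the PSD matrix closest (LogDet divergence) to ``prior_lambda``
    such that similar pairs have distance <= l and dissimilar pairs have
    distance >= u, softened by the slack parameter gamma.  Rank-one
    Bregman updates keep every iterate positive semi-definite.  With no
    constraints the prior is returned unchanged.
    """
    cfg = config or PIMetricConfig()
    X = np.asarray(original_vectors, dtype=float)
    A0 = np.asarray(prior_lambda, dtype=float)
    vals = np.linalg.eigvalsh(0.5 * (A0 + A0.T))
    if vals.min() < -1e-10:
        raise ValueError("prior metric is not PSD")
    if l >= u:
        raise ValueError(f"need l < u, got l={l}, u={u}")
    cons = [(i, j, +1.0, l) for i, j in constraints.s_plus]
    cons += [(i, j, -1.0, u) for i, j in constraints.s_minus]
    A = A0.copy()
    if not cons:
        return A
    gamma = cfg.slack
    lambdas = np.zeros(len(cons))
    xi = np.array([b for (_, _, _, b) in cons], dtype=float)
    converged = False
    for _ in range(cfg.max_sweeps):
        max_change = 0.0
        for c, (i, j, delta, _) in enumerate(cons):
            v = X[i] - X[j]
            Av = A @ v
            p = float(v @ Av)
            if p < 1e-15 or xi[c] < 1e-15:
                continue
            alpha = min(lambdas[c], 0.5 * delta * (1.0 / p - gamma / xi[c]))
            beta = delta * alpha / (1.0 - delta * alpha * p)
            xi[c] = gamma * xi[c] / (gamma + delta * alpha * xi[c])
            lambdas[c] -= alpha
            A += beta * np.outer(Av, Av)
            max_change = max(max_change, abs(alpha))
        if max_change < cfg.tol:
            converged = True
            break
    if not converged:
        warnings.warn("ITML did not converge within max_sweeps; returning best iterate")
    return 0.5 * (A + A.T)


class PrivilegedGMLVQClassifier(BaseEstimator, ClassifierMixin):
    """GMLVQ over original features with an ITML metric shaped by privileged data.

    ``fit`` takes the original feature matrix plus a privileged matrix for
    (a subset of) the same subjects; ``predict`` uses original features
    only.  GMLVQ optimizer settings apply to all three internal trainings.

    Attributes (after fit): ``lambda_star_`` (privileged-space metric),
    ``lambda_baseline_``, ``lambda_new_`` (fused, unit trace),
    ``constraints_``, ``model_`` (the final prototype classifier).
    """

    def __init__(
        self,
        a: float = 10.0,
        b: float = 90.0,
        a_star: float = 10.0,
        b_star: float = 90.0,
        slack: float = 1.0,
        max_sweeps: int = 1000,
        lr_prototype: float = 0.01,
        lr_omega: float = 0.001,
        epochs: int = 300,
        prototype_init_fraction: float = 0.5,
        random_state: int | None = None,
    ):
        self.a = a
        self.b = b
        self.a_star = a_star
        self.b_star = b_star
        self.slack = slack
        self.max_sweeps = max_sweeps
        self.lr_prototype = lr_prototype
        self.lr_omega = lr_omega
        self.epochs = epochs
        self.prototype_init_fraction = prototype_init_fraction
        self.random_state = random_state

    def _gmlvq(self, seed_offset: int, **overrides) -> GMLVQClassifier:
        rs = None if self.random_state is None else self.random_state + seed_offset
        params = dict(
            lr_prototype=self.lr_prototype,
            lr_omega=self.lr_omega,
            epochs=self.epochs,
            prototype_init_fraction=self.prototype_init_fraction,
            random_state=rs,
        )
        params.update(overrides)
        return GMLVQClassifier(**params)

    def fit(self, X, y, X_privileged=None, privileged_rows=None):
        """Five-stage PI fusion (see module docstring).

        Parameters
        ----------
        X, y : original features and labels for all training subjects.
        X_privileged : privileged features, one row per privileged subject.
        privileged_rows : indices into X matching the rows of
            ``X_privileged`` (default: all rows, requiring equal lengths).
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X_privileged is None:
            raise ValueError("X_privileged is required to fit a PI-guided model")
        Xp = np.asarray(X_privileged, dtype=float)
        rows = (np.arange(X.shape[0]) if privileged_rows is None
                else np.asarray(privileged_rows, dtype=int))
        if Xp.shape[0] != rows.size:
            raise ValueError("X_privileged rows must align with privileged_rows")
        if rows.size == 0:
            raise ValueError("no subject has both modalities")
        yp = y[rows]
        if np.unique(yp).size < 2:
            raise ValueError("privileged subset must contain both classes")
        cfg = PIMetricConfig(
            a_star=self.a_star, b_star=self.b_star, a=self.a, b=self.b,
            slack=self.slack, max_sweeps=self.max_sweeps,
        )

        # stage 1: metric in the privileged space
        priv_model = self._gmlvq(1).fit(Xp, yp)
        self.lambda_star_ = priv_model.lambda_

        # stage 2: baseline model in the original space
        base_model = self._gmlvq(2).fit(X, y)
        self.lambda_baseline_ = base_model.lambda_

        # stage 3: pair constraints from privileged closeness
        Xp_s = priv_model._apply_scaler(Xp)
        self.constraints_ = build_pair_sets(Xp_s, yp, self.lambda_star_, cfg)
        # pair indices refer to the privileged subset; map onto X rows
        mapped = PairConstraintSets(
            s_plus=[(int(rows[i]), int(rows[j])) for i, j in self.constraints_.s_plus],
            s_minus=[(int(rows[i]), int(rows[j])) for i, j in self.constraints_.s_minus],
            l_star=self.constraints_.l_star, u_star=self.constraints_.u_star,
            a_star=cfg.a_star, b_star=cfg.b_star,
        )

        # stage 4: ITML in the original (scaled) space
        Xs = base_model._apply_scaler(X)
        d, _, _ = _pairwise_sq_distances(Xs, self.lambda_baseline_)
        l = float(np.percentile(d, cfg.a))
        u = float(np.percentile(d, cfg.b))
        if l >= u:
            raise ValueError("degenerate original-space percentile bounds (l >= u)")
        lam_new = itml_fit(Xs, mapped, self.lambda_baseline_, l, u, cfg)
        self.lambda_new_ = normalize_metric_tensor(lam_new)
        self.itml_bounds_ = (l, u)

        # stage 5: prototypes only, under the fused metric
        self.model_ = self._gmlvq(
            3, train_metric=False, initial_lambda=self.lambda_new_
        ).fit(X, y)
        self.classes_ = self.model_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    # prediction path is pure original-space GMLVQ
    def predict(self, X):
        return self.model_.predict(X)

    def predict_with_distance(self, X):
        return self.model_.predict_with_distance(X)

    def class_winner_distance(self, X, label, lam_override=None):
        return self.model_.class_winner_distance(X, label, lam_override)

    @property
    def lambda_(self):
        return self.model_.lambda_

    @property
    def prototype_labels_(self):
        return self.model_.prototype_labels_


def train_pi_gmlvq(X, y, X_privileged, privileged_rows=None,
                   config: PIMetricConfig | None = None,
                   **gmlvq_params) -> PrivilegedGMLVQClassifier:
    cfg = config or PIMetricConfig()
    model = PrivilegedGMLVQClassifier(
        a=cfg.a, b=cfg.b, a_star=cfg.a_star, b_star=cfg.b_star,
        slack=cfg.slack, max_sweeps=cfg.max_sweeps, **gmlvq_params,
    )
    return model.fit(X, y, X_privileged=X_privileged, privileged_rows=privileged_rows)


def tune_percentile_bounds(
    X, y, X_privileged, privileged_rows=None,
    lower_grid=(5.0, 10.0, 15.0), upper_grid=(85.0, 90.0, 95.0),
    n_folds: int = 3, random_state: int = 0, **gmlvq_params,
):
    """Grid-search the four percentile bounds by cross-validated MMAE.

    Evaluates (a = a*, b = b*) pairs over the standard tuning grids on a
    stratified K-fold of the given training set and returns the bounds of
    the lowest mean macroaveraged error (ties: first in grid order).
    Intended to be run on the first data split only, then frozen.
    """
    from .evaluation import macro_mae

    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rows = (np.arange(X.shape[0]) if privileged_rows is None
            else np.asarray(privileged_rows, dtype=int))
    Xp = np.asarray(X_privileged, dtype=float)
    best = None
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=random_state)
    folds = list(skf.split(X, y))
    for lo, hi in itertools.product(lower_grid, upper_grid):
        errs = []
        for tr, te in folds:
            in_priv = np.isin(rows, tr)
            tr_rows = rows[in_priv]
            pos = {r: k for k, r in enumerate(tr)}
            member_rows = np.array([pos[r] for r in tr_rows], dtype=int)
            if np.unique(y[tr_rows]).size < 2:
                continue
            model = PrivilegedGMLVQClassifier(
                a=lo, b=hi, a_star=lo, b_star=hi,
                random_state=random_state, **gmlvq_params,
            ).fit(X[tr], y[tr], X_privileged=Xp[in_priv],
                  privileged_rows=member_rows)
            errs.append(macro_mae(y[te], model.predict(X[te])))
        score = float(np.mean(errs)) if errs else np.inf
        if best is None or score < best[0]:
            best = (score, lo, hi)
    _, lo, hi = best
    return {"a": lo, "b": hi, "a_star": lo, "b_star": hi}
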