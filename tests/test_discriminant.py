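"""Fisher LDA, 2D-LDA alternating optimization, importance matrices."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from conftest import fisher_j
from pilvq.discriminant import (
    FisherLDA,
    TwoDLDA,
    compute_importance_matrix,
    fit_2dlda,
    fit_lda,
    project_graphs,
)


def symmetric_noise(rng, d, scale=1.0):
    N = rng.normal(0, scale, (d, d))
    return 0.5 * (N + N.T)


class TestFisherLDA:
    def test_matches_brute_force_maximizer_2d(self, rng):
        """Grid/golden-section maximizer of the Fisher ratio over angles."""
        X = np.vstack([
            rng.normal([0, 0], [1.0, 0.6], (30, 2)),
            rng.normal([2.0, 0.7], [1.0, 0.6], (30, 2)),
        ])
        y = np.repeat([0, 1], 30)
        proj = fit_lda(X, y)

        def neg_j(theta):
            w = np.array([np.cos(theta), np.sin(theta)])
            return -fisher_j(X, y, w)

        best = np.inf
        for start in np.linspace(0, np.pi, 16, endpoint=False):
            r = minimize_scalar(neg_j, bracket=(start, start + 0.1),
                                method="brent")
            best = min(best, r.fun)
        assert proj.fisher_J == pytest.approx(-best, abs=1e-6)

    def test_informative_axis_dominates(self, rng):
        X = rng.normal(size=(400, 4))
        y = np.repeat([0, 1], 200)
        X[y == 1, 0] += 10.0
        proj = fit_lda(X, y)
        assert abs(proj.w_opt[0]) > 0.99

    def test_equal_means_zero_between_class(self):
        # mirror-symmetric classes: identical means, J = 0 for any direction
        A = np.array([[1.0, 0], [-1, 0], [0, 1], [0, -1]])
        proj = fit_lda(np.vstack([A, A * 0.5]), np.repeat([0, 1], 4))
        assert proj.fisher_J == pytest.approx(0.0, abs=1e-12)

    def test_scalar_case(self):
        x = np.array([[0.0], [1.0], [4.0], [5.0]])
        y = np.array([0, 0, 1, 1])
        proj = fit_lda(x, y)
        assert abs(proj.w_opt[0]) == pytest.approx(1.0)
        # (m2 - m1)^2 / S_W = 16 / 1 (regularized denominator, loose tol)
        assert proj.fisher_J == pytest.approx(16.0, rel=1e-3)

    def test_unit_norm(self, rng):
        X = rng.normal(size=(20, 5))
        y = np.repeat([0, 1], 10)
        assert np.linalg.norm(fit_lda(X, y).w_opt) == pytest.approx(1.0)


class TestTwoDLDA:
    def _planted_dataset(self, rng, d=5, n=40, strength=6.0, noise=0.2):
        E = np.zeros((d, d))
        E[0, 1] = E[1, 0] = 1.0
        X, y = [], []
        for k in range(n):
            cls = k % 2
            X.append(cls * strength * E + symmetric_noise(rng, d, noise))
            y.append(cls)
        return np.array(X), np.array(y)

    def test_monotone_j_trace(self, rng):
        X, y = self._planted_dataset(rng)
        proj = fit_2dlda(X, y)
        t = np.array(proj.J_trace)
        assert (np.diff(t) >= -1e-9).all()
        assert t[-1] >= t[0]

    def test_recovers_planted_edge(self, rng):
        X, y = self._planted_dataset(rng, strength=6.0, noise=0.2)
        proj = fit_2dlda(X, y)
        I = compute_importance_matrix(proj)
        off = np.abs(I - np.diag(np.diag(I)))
        assert np.unravel_index(off.argmax(), off.shape) in [(0, 1), (1, 0)]

    def test_beats_coordinate_pair_oracle(self, rng):
        """The fitted J is at least the best coordinate-pair projection J."""
        X, y = self._planted_dataset(rng, d=4)
        model = TwoDLDA().fit(X, y)
        classes = np.unique(y)
        M1, M2 = X[y == classes[0]].mean(0), X[y == classes[1]].mean(0)
        centered = np.concatenate([X[y == classes[0]] - M1, X[y == classes[1]] - M2])
        d = X.shape[1]
        best = 0.0
        for i in range(d):
            for j in range(d):
                a = np.eye(d)[i]
                b = np.eye(d)[j]
                num = float(a @ (M2 - M1) @ b) ** 2
                den = float(np.sum(np.einsum("i,nij,j->n", a, centered, b) ** 2))
                if den > 0:
                    best = max(best, num / den)
        assert model.j_trace_[-1] >= best * (1 - 1e-9)

    def test_parameter_count_is_2d(self, rng):
        X, y = self._planted_dataset(rng, d=6)
        proj = fit_2dlda(X, y)
        assert proj.a_opt.size + proj.b_opt.size == 2 * 6

    def test_nonsymmetric_rejected(self, rng):
        X = rng.normal(size=(6, 3, 3))
        with pytest.raises(ValueError, match="symmetric"):
            fit_2dlda(X, np.repeat([0, 1], 3))

    def test_identical_matrices_degenerate(self):
        X = np.tile(np.eye(3), (8, 1, 1))
        with pytest.raises(ValueError, match="degenerate"):
            fit_2dlda(X, np.repeat([0, 1], 4))

    def test_sign_convention_deterministic(self, rng):
        X, y = self._planted_dataset(rng)
        p1 = fit_2dlda(X, y, positive_label=1)
        p2 = fit_2dlda(X, y, positive_label=1)
        assert np.array_equal(p1.a_opt, p2.a_opt)
        f = project_graphs(p1, X)
        assert f[y == 1].mean() >= f[y == 0].mean()


class TestProjection:
    def test_identity_matrix_unit_vectors(self):
        from pilvq.discriminant import TwoDLDAProjection

        p = TwoDLDAProjection(np.array([1.0, 0]), np.array([1.0, 0]), [1.0], True)
        assert project_graphs(p, np.eye(2))[0] == pytest.approx(1.0)

    def test_cross_term(self):
        from pilvq.discriminant import TwoDLDAProjection

        p = TwoDLDAProjection(np.array([1.0, 0]), np.array([0.0, 1]), [1.0], True)
        X = np.array([[0.0, 1], [1, 0]])
        assert project_graphs(p, X)[0] == pytest.approx(1.0)

    def test_bilinearity_in_scale(self, rng):
        from pilvq.discriminant import TwoDLDAProjection

        a = rng.normal(size=3)
        b = rng.normal(size=3)
        p = TwoDLDAProjection(a, b, [1.0], True)
        X = symmetric_noise(rng, 3)
        assert project_graphs(p, 2.5 * X)[0] == pytest.approx(
            2.5 * project_graphs(p, X)[0]
        )

    def test_dimension_mismatch(self):
        from pilvq.discriminant import TwoDLDAProjection

        p = TwoDLDAProjection(np.ones(3), np.ones(3), [1.0], True)
        with pytest.raises(ValueError):
            project_graphs(p, np.eye(4))


class TestImportanceMatrix:
    def test_hand_example(self):
        from pilvq.discriminant import TwoDLDAProjection

        p = TwoDLDAProjection(np.array([1.0, 0]), np.array([0.0, 1]), [1.0], True)
        I = compute_importance_matrix(p)
        assert np.allclose(I, [[0, 0.5], [0.5, 0]])

    def test_equal_vectors_outer_product(self, rng):
        from pilvq.discriminant import TwoDLDAProjection

        a = rng.normal(size=4)
        p = TwoDLDAProjection(a, a.copy(), [1.0], True)
        assert np.allclose(compute_importance_matrix(p), np.outer(a, a))

    def test_always_symmetric(self, rng):
        from pilvq.discriminant import TwoDLDAProjection

        p = TwoDLDAProjection(rng.normal(size=5), rng.normal(size=5), [1.0], True)
        I = compute_importance_matrix(p)
        assert np.array_equal(I, I.T)

    def test_invariant_to_joint_sign_flip(self, rng):
        from pilvq.discriminant import TwoDLDAProjection

        a, b = rng.normal(size=4), rng.normal(size=4)
        p1 = TwoDLDAProjection(a, b, [1.0], True)
        p2 = TwoDLDAProjection(-a, -b, [1.0], True)
        assert np.allclose(compute_importance_matrix(p1),
                           compute_importance_matrix(p2))
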