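import numpy as np
import pytest

from pilvq.simulate import default_config, simulate_cohort


@pytest.fixture(scope="session")
def study_cohort():
    """The standard 13/47 cohort with 34 imaged subjects (seeded)."""
    return simulate_cohort(default_config(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(7)


def brute_force_pearson(Y):
    """Double-loop Pearson correlation oracle (population normalization)."""
    V, n = Y.shape
    G = np.empty((V, V))
    for i in range(V):
        for j in range(V):
            yi, yj = Y[i], Y[j]
            mi, mj = yi.mean(), yj.mean()
            si = np.sqrt(np.mean((yi - mi) ** 2))
            sj = np.sqrt(np.mean((yj - mj) ** 2))
            G[i, j] = np.mean((yi - mi) * (yj - mj)) / (si * sj)
    return G


def exact_signed_rank_p(x, alternative):
    """Exact one-sided signed-rank p-value by full sign enumeration (n <= 12).

    Assumes no zeros and no tied absolute values.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    assert n <= 12 and np.all(x != 0)
    ranks = np.argsort(np.argsort(np.abs(x))) + 1
    w_obs = ranks[x > 0].sum()
    total = 0
    count = 0
    for mask in range(2 ** n):
        w = sum(ranks[k] for k in range(n) if (mask >> k) & 1)
        total += 1
        if alternative == "greater" and w >= w_obs:
            count += 1
        elif alternative == "less" and w <= w_obs:
            count += 1
    return count / total


def fisher_j(X, y, w):
    """Fisher criterion value for a direction (oracle helper)."""
    classes = np.unique(y)
    X1, X2 = X[y == classes[0]], X[y == classes[1]]
    m1, m2 = X1.mean(axis=0), X2.mean(axis=0)
    dm = m2 - m1
    num = float(w @ np.outer(dm, dm) @ w)
    Sw = np.zeros((X.shape[1],) * 2)
    for Xc, mc in ((X1, m1), (X2, m2)):
        D = Xc - mc
        Sw += D.T @ D
    den = float(w @ Sw @ w)
    return num / den
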