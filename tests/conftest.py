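import numpy as np
import pytest
from hypothesis import settings

from connpredict.atlas import Roi, RoiSet, load_pool198, load_table1

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def pool198():
    return load_pool198()


def make_small_pool(n_a: int = 12, n_b: int = 8) -> RoiSet:
    """A compact two-network pool for fast end-to-end simulations."""
    rois = []
    for i in range(n_a):
        rois.append(Roi(f"A{i}", 100 + i, "netA", -60.0 + 20.0 * i, 10.0, 20.0))
    for i in range(n_b):
        rois.append(Roi(f"B{i}", 200 + i, "netB", -60.0 + 20.0 * i, -40.0, 0.0))
    return RoiSet(rois)


@pytest.fixture(scope="session")
def small_pool():
    return make_small_pool()


# ---------------------------------------------------------------------------
# independent oracles (kept free of the implementation paths they check)
# ---------------------------------------------------------------------------

def soft_threshold(z: float, t: float) -> float:
    return np.sign(z) * max(abs(z) - t, 0.0)


def cd_lasso_oracle(X, y, lam, n_iter=20_000, tol=1e-14):
    """Cyclic coordinate descent for (1/(2n))||y - b0 - Xb||^2 + lam||b||_1."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, m = X.shape
    xbar = X.mean(axis=0)
    Xc = X - xbar
    ybar = y.mean()
    yc = y - ybar
    col_sq = (Xc**2).sum(axis=0) / n
    b = np.zeros(m)
    resid = yc.copy()
    for _ in range(n_iter):
        delta = 0.0
        for j in range(m):
            if col_sq[j] == 0:
                continue
            old = b[j]
            rho = Xc[:, j] @ resid / n + col_sq[j] * old
            new = soft_threshold(rho, lam) / col_sq[j]
            if new != old:
                resid -= Xc[:, j] * (new - old)
                delta = max(delta, abs(new - old))
            b[j] = new
        if delta < tol:
            break
    b0 = ybar - xbar @ b
    return b0, b


def lasso_objective(X, y, b0, b, lam):
    n = len(y)
    r = y - b0 - X @ b
    return 0.5 / n * r @ r + lam * np.abs(b).sum()


def kkt_residual(X, y, b0, b, lam):
    """Max violation of the LASSO stationarity conditions (with intercept)."""
    X = np.asarray(X, float)
    n = len(y)
    r = y - b0 - X @ b
    g = X.T @ r / n
    res = abs(r.mean())
    for j in range(X.shape[1]):
        if b[j] != 0:
            res = max(res, abs(g[j] - lam * np.sign(b[j])))
        else:
            res = max(res, max(abs(g[j]) - lam, 0.0))
    return res


def bh_oracle(p):
    """Step-up BH adjustment: p_(i) * m / i with a reverse cumulative min."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out
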