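import numpy as np
import pandas as pd
import pytest

from glycadecomp import synth


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic mid-size synthetic cohort shared across tests."""
    cfg = synth.GeneratorConfig(n_samples=800, seed=42, detection_limit_quantile=0.01)
    return cfg, synth.generate_cohort(cfg)


@pytest.fixture(scope="session")
def sparse_regression_fixture():
    """Sparse linear-model data with known truth: 3 of 20 active features."""
    rng = np.random.default_rng(7)
    n, p = 600, 20
    X = rng.standard_normal((n, p))
    true_support = [0, 5, 12]
    beta = np.zeros(p)
    beta[true_support] = [1.0, -0.8, 0.6]
    signal = X @ beta
    noise_sd = np.std(signal) / np.sqrt(5)  # SNR 5
    y = signal + noise_sd * rng.standard_normal(n)
    Xf = pd.DataFrame(X, columns=[f"f{i}" for i in range(p)])
    ys = pd.Series((y - y.mean()) / y.std(ddof=1))
    return Xf, ys, true_support


def lasso_cd_oracle(X, y, lam, tol=1e-13, max_iter=200000):
    """Independent cyclical coordinate descent for the lasso.

    Minimises (1/2n)||y − b0 − Xb||² + λ||b||₁ with the intercept handled
    by centring. Deliberately naive: plain Python loop over coordinates.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    xm, ym = X.mean(axis=0), y.mean()
    Xc, yc = X - xm, y - ym
    col_ss = (Xc**2).sum(axis=0)
    b = np.zeros(p)
    r = yc.copy()
    for _ in range(max_iter):
        max_delta = 0.0
        for j in range(p):
            if col_ss[j] == 0:
                continue
            rho = Xc[:, j] @ r + col_ss[j] * b[j]
            bj = np.sign(rho) * max(abs(rho) / n - lam, 0.0) / (col_ss[j] / n)
            delta = bj - b[j]
            if delta != 0.0:
                r -= Xc[:, j] * delta
                b[j] = bj
                max_delta = max(max_delta, abs(delta))
        if max_delta < tol:
            break
    b0 = ym - xm @ b
    return b0, b
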