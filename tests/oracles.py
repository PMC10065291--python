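"""Independent oracles shared by the test modules.

These deliberately avoid the package's own likelihood code paths: the
conditional-logistic oracle enumerates each matched set's likelihood
directly, differentiates it by complex step (machine precision) and
optimizes with scipy; the covariance comes from a central finite-difference
Hessian of that enumerated likelihood.
"""

import numpy as np
from scipy import optimize


def enum_loglik(X, y, strata, beta):
    beta = np.asarray(beta)
    total = 0.0 + 0.0j if np.iscomplexobj(beta) else 0.0
    for s in np.unique(strata):
        rows = strata == s
        eta = X[rows] @ beta
        shift = np.max(eta.real)
        lse = np.log(np.sum(np.exp(eta - shift))) + shift
        total = total + eta[y[rows]][0] - lse
    return total


def enum_grad(X, y, strata, beta):
    h = 1e-200
    g = np.empty(len(beta))
    for j in range(len(beta)):
        b = beta.astype(complex)
        b[j] += 1j * h
        g[j] = enum_loglik(X, y, strata, b).imag / h
    return g


def enum_fit(X, y, strata, p):
    """(beta_hat, loglik, covariance) by enumeration + scipy optimization."""
    res = optimize.minimize(
        lambda b: -enum_loglik(X, y, strata, b),
        np.zeros(p),
        jac=lambda b: -enum_grad(X, y, strata, b),
        method="BFGS",
        options={"gtol": 1e-12, "maxiter": 500},
    )
    h = 1e-6
    H = np.zeros((p, p))
    for j in range(p):
        e = np.zeros(p)
        e[j] = h
        H[:, j] = (
            enum_grad(X, y, strata, res.x + e)
            - enum_grad(X, y, strata, res.x - e)
        ) / (2 * h)
    H = (H + H.T) / 2
    return res.x, -res.fun, np.linalg.inv(-H)


def random_matched_sets(rng, n_strata=50, max_size=4, p=3):
    """Random strata of 2..max_size days, one case each, p columns
    (the first column binary)."""
    X_list, y_list, s_list = [], [], []
    for s in range(n_strata):
        m = rng.integers(2, max_size + 1)
        Xs = rng.normal(0, 1, (m, p))
        Xs[:, 0] = rng.integers(0, 2, m)
        ys = np.zeros(m, bool)
        ys[rng.integers(m)] = True
        X_list.append(Xs)
        y_list.append(ys)
        s_list.append(np.full(m, s))
    return np.vstack(X_list), np.concatenate(y_list), np.concatenate(s_list)
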