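"""Conditional logistic regression for matched sets (Newton-Raphson).

For matched sets with exactly one case each, the conditional likelihood of a
stratum s with rows j and design rows x_j is

    exp(x_case' beta) / sum_j exp(x_j' beta)

— the same partial-likelihood kernel as stratified Cox regression with one
event per stratum. The fit maximizes the sum of stratum log-likelihoods by
Newton-Raphson on the analytic score and observed information, with
step-halving whenever a full step would decrease the likelihood. Strata with
no within-stratum variation in a column contribute zero score for it; a
column constant within *every* stratum carries no information and makes the
information matrix singular (an error — drop such columns upstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FitResult", "clogit_fit", "clogit_loglik", "SeparationError"]


class SeparationError(RuntimeError):
    """Monotone likelihood: some coefficient diverges."""


@dataclass
class FitResult:
    """Coefficients, covariance and diagnostics of a conditional-logit fit."""

    beta: np.ndarray
    cov: np.ndarray
    converged: bool
    loglik: float
    n_strata: int
    n_iter: int
    column_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        p = self.beta.size
        if self.cov.shape != (p, p):
            raise ValueError("covariance shape must match beta")
        if not np.allclose(self.cov, self.cov.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def _prepare(X, y, strata):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    strata = np.asarray(strata)
    order = np.argsort(strata, kind="stable")
    X, y, strata = X[order], y[order], strata[order]
    _, starts, counts = np.unique(strata, return_index=True, return_counts=True)
    case_per = np.add.reduceat(y.astype(int), starts)
    if not np.all(case_per == 1):
        raise ValueError("every stratum must contain exactly one case")
    return X, y, starts, counts


def _ll_score_hess(X, y, starts, beta):
    eta = X @ beta
    m = np.maximum.reduceat(eta, starts)
    expu = np.exp(eta - np.repeat(m, np.diff(np.append(starts, len(eta)))))
    denom = np.add.reduceat(expu, starts)
    ll = float(eta[y].sum() - (np.log(denom) + m).sum())
    p = expu / np.repeat(denom, np.diff(np.append(starts, len(eta))))
    Xp = X * p[:, None]
    mu = np.add.reduceat(Xp, starts, axis=0)  # per-stratum expected x
    score = X[y].sum(axis=0) - mu.sum(axis=0)
    hess = -(Xp.T @ X - mu.T @ mu)
    return ll, score, hess


def clogit_loglik(X, y, strata, beta) -> float:
    """Conditional log-likelihood at ``beta`` (one case per stratum)."""
    Xs, ys, starts, _ = _prepare(X, y, strata)
    return _ll_score_hess(Xs, ys, starts, np.asarray(beta, dtype=float))[0]


def clogit_fit(
    X: np.ndarray,
    y: np.ndarray,
    strata: np.ndarray,
    column_names: list[str] | None = None,
    max_iter: int = 100,
    score_tol: float = 1e-8,
    step_tol: float = 1e-10,
) -> FitResult:
    """Maximize the conditional likelihood by Newton-Raphson.

    Parameters
    ----------
    X : (n_rows, p) design matrix
    y : boolean case indicator (one True per stratum)
    strata : stratum label per row
    column_names : labels used in error diagnostics

    Convergence when max |score| < ``score_tol`` or the Newton step is
    shorter than ``step_tol``. The covariance is the inverse observed
    information at the optimum. Raises :class:`SeparationError` when the
    likelihood is monotone in some direction (coefficients diverge) and
    ``np.linalg.LinAlgError`` when the information matrix is singular.
    """
    Xs, ys, starts, counts = _prepare(X, y, strata)
    n, p = Xs.shape
    names = column_names or [f"x{j}" for j in range(p)]
    if len(names) != p:
        raise ValueError("column_names length must match design columns")
    beta = np.zeros(p)
    ll, score, hess = _ll_score_hess(Xs, ys, starts, beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(score)) < score_tol:
            converged = True
            break
        info = -hess
        try:
            if np.linalg.cond(info) > 1e12:
                raise np.linalg.LinAlgError("ill-conditioned information")
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as err:
            bad = int(np.argmin(np.abs(np.diag(info))))
            raise np.linalg.LinAlgError(
                f"singular information matrix (no within-stratum variation "
                f"in column {names[bad]!r}?)"
            ) from err
        # step-halving on likelihood decrease
        scale = 1.0
        for _ in range(40):
            cand = beta + scale * step
            ll_new, score_new, hess_new = _ll_score_hess(Xs, ys, starts, cand)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        if np.linalg.norm(scale * step) < step_tol:
            beta = cand
            ll, score, hess = ll_new, score_new, hess_new
            converged = True
            break
        beta, ll, score, hess = cand, ll_new, score_new, hess_new
        # |log OR| beyond ~15 (OR > 3e6) only arises under separation
        if np.max(np.abs(beta)) > 15:
            bad = int(np.argmax(np.abs(beta)))
            raise SeparationError(
                f"monotone likelihood: coefficient for {names[bad]!r} "
                "diverges (complete or quasi-complete separation)"
            )
    else:
        if np.max(np.abs(score)) < 1e-4:
            converged = True  # flat tail; accept with loose score
    cov = np.linalg.inv(-hess)
    cov = (cov + cov.T) / 2.0
    return FitResult(
        beta=beta,
        cov=cov,
        converged=converged,
        loglik=ll,
        n_strata=len(starts),
        n_iter=it,
        column_names=list(names),
    )
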