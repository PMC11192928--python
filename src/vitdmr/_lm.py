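"""Low-level linear and logistic fitting routines.

These are deliberately self-contained (plain normal equations / IRLS) so the
higher-level modules can be cross-checked against independent oracles in the
test suite, and so that tight simulation loops stay fast.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import expit

from .errors import DegenerateInputError, SeparationError, ValidationError

Z95 = 1.959963984540054  # two-sided 95% normal quantile


def add_intercept(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return np.column_stack([np.ones(len(X)), X])


def drop_collinear(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Greedily keep a maximal linearly independent set of columns."""
    kept_idx: list[int] = []
    dropped: list[str] = []
    rank = 0
    for j in range(X.shape[1]):
        cand = X[:, kept_idx + [j]]
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            kept_idx.append(j)
            rank = r
        else:
            dropped.append(names[j])
    return X[:, kept_idx], [names[i] for i in kept_idx], dropped


def ols(y: np.ndarray, X: np.ndarray) -> dict:
    """Ordinary least squares with Wald (normal) inference.

    ``X`` must already contain the intercept column and be full rank.
    Returns beta, se, cov, r2, resid, dof.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValidationError(f"n={n} too small for {p} parameters")
    XtX = X.T @ X
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded upstream
        raise DegenerateInputError("design matrix is singular") from exc
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    dof = n - p
    sigma2 = float(resid @ resid) / dof
    cov = XtX_inv * sigma2
    se = np.sqrt(np.diag(cov))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 0.0
    return {
        "beta": beta,
        "se": se,
        "cov": cov,
        "r2": r2,
        "resid": resid,
        "dof": dof,
        "sigma2": sigma2,
        "n": n,
    }


def wls(y: np.ndarray, X: np.ndarray, w: np.ndarray) -> dict:
    """Weighted least squares; returns beta and the unscaled (X'WX)^-1."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    w = np.asarray(w, dtype=float)
    Xw = X * w[:, None]
    XtWX_inv = np.linalg.inv(X.T @ Xw)
    beta = XtWX_inv @ (Xw.T @ y)
    resid = y - X @ beta
    rss_w = float(w @ resid**2)
    return {"beta": beta, "cov_unscaled": XtWX_inv, "resid": resid, "rss_w": rss_w}


def logistic_irls(
    y: np.ndarray,
    X: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> dict:
    """Logistic regression by iteratively reweighted least squares.

    Convergence criterion: |change in deviance| < ``tol``. Raises
    :class:`SeparationError` when coefficients diverge (complete or
    quasi-complete separation).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    classes = np.unique(y)
    if not np.all(np.isin(classes, [0.0, 1.0])):
        raise ValidationError("binary outcome must be coded 0/1")
    if classes.size < 2:
        raise ValidationError("both outcome classes must be present")
    beta = np.zeros(p)
    prev_dev = np.inf
    dev = np.inf
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        try:
            beta = np.linalg.solve(X.T @ Xw, Xw.T @ z)
        except np.linalg.LinAlgError as exc:
            raise DegenerateInputError("singular information matrix in IRLS") from exc
        mu = np.clip(expit(X @ beta), 1e-12, 1 - 1e-12)
        dev = -2.0 * float(y @ np.log(mu) + (1 - y) @ np.log(1 - mu))
        if np.max(np.abs(beta)) > 1e2:
            raise SeparationError(
                "coefficients diverging (|beta| > 100): separation detected"
            )
        if abs(dev - prev_dev) < tol:
            break
        prev_dev = dev
    else:
        if np.max(np.abs(beta)) > 15:
            raise SeparationError("IRLS failed to converge; separation suspected")
    eta = X @ beta
    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    se = np.sqrt(np.diag(cov))
    return {"beta": beta, "se": se, "cov": cov, "deviance": dev, "n": n}


def wald_p(beta: float | np.ndarray, se: float | np.ndarray) -> np.ndarray:
    se = np.asarray(se, dtype=float)
    z = np.divide(beta, se, out=np.zeros_like(se), where=se > 0)
    return 2.0 * stats.norm.sf(np.abs(z))
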