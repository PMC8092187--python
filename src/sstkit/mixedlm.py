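"""Random-intercept linear mixed model fit by profiled REML.

For the single-random-intercept model ``y = X b + u[g] + e`` the
covariance of each subject block is ``sigma2 * (I + theta * J)`` with
``theta = var(u) / sigma2``.  Both ``b`` and ``sigma2`` profile out of the
REML criterion, leaving a one-dimensional optimization over ``theta``,
which Brent's method solves to high precision.  This keeps fits fast and
bit-reproducible for the simulation studies in this package.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize


@dataclass(frozen=True)
class RandomInterceptFit:
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: float          # residual variance
    tau2: float            # random-intercept variance
    theta: float           # tau2 / sigma2
    n_obs: int
    n_groups: int
    reml_criterion: float  # -2 * restricted log-likelihood, up to a constant


def _group_index(groups: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    _, inv = np.unique(groups, return_inverse=True)
    counts = np.bincount(inv)
    return inv, counts, counts.size


def _profile(theta: float, X: np.ndarray, y: np.ndarray, inv: np.ndarray,
             counts: np.ndarray):
    """REML criterion with beta and sigma2 profiled out, at fixed theta."""
    n, p = X.shape
    shrink = theta / (1.0 + counts * theta)  # per group

    def W(mat: np.ndarray) -> np.ndarray:
        # (I + theta J)^-1 applied blockwise: v - shrink_g * sum_g(v)
        sums = np.zeros((counts.size,) + mat.shape[1:])
        np.add.at(sums, inv, mat)
        return mat - (shrink[inv, None] if mat.ndim == 2 else shrink[inv]) * sums[inv]

    WX = W(X)
    Wy = W(y)
    XtWX = X.T @ WX
    beta = np.linalg.solve(XtWX, X.T @ Wy)
    resid = y - X @ beta
    rss = float(resid @ W(resid))
    crit = ((n - p) * np.log(rss)
            + float(np.sum(np.log1p(counts * theta)))
            + float(np.linalg.slogdet(XtWX)[1]))
    return crit, beta, XtWX, rss


def fit_random_intercept(X: np.ndarray, y: np.ndarray, groups: np.ndarray
                         ) -> RandomInterceptFit:
    """REML fit; ``groups`` is any label array aligned with the rows."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than parameters ({p})")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    inv, counts, n_groups = _group_index(np.asarray(groups))

    def objective(log_theta: float) -> float:
        return _profile(np.exp(log_theta), X, y, inv, counts)[0]

    res = optimize.minimize_scalar(objective, bounds=(-25.0, 25.0),
                                   method="bounded",
                                   options={"xatol": 1e-12})
    theta = float(np.exp(res.x))
    crit, beta, XtWX, rss = _profile(theta, X, y, inv, counts)
    # boundary check: a zero random-intercept variance may beat the interior
    crit0, beta0, XtWX0, rss0 = _profile(0.0, X, y, inv, counts)
    if crit0 < crit:
        theta, crit, beta, XtWX, rss = 0.0, crit0, beta0, XtWX0, rss0
    sigma2 = rss / (n - p)
    cov_beta = sigma2 * np.linalg.inv(XtWX)
    return RandomInterceptFit(beta=beta, cov_beta=cov_beta, sigma2=sigma2,
                              tau2=theta * sigma2, theta=theta, n_obs=n,
                              n_groups=n_groups, reml_criterion=crit)
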