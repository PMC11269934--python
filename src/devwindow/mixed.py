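"""Gaussian linear mixed model with a single random intercept.

The marginal model is ``y = X beta + Z u + e`` with one intercept per
grouping level (animal), ``u ~ N(0, sd_animal^2)``, ``e ~ N(0,
sd_resid^2)``.  Estimation profiles the variance ratio ``lambda =
sd_animal^2 / sd_resid^2``: at each ratio the fixed effects come from
generalized least squares in closed form (group-wise Woodbury identity),
and the ratio itself is found by 1-D likelihood optimization.  Maximum
likelihood is the default; REML is available via a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class MixedLMResult:
    params: np.ndarray
    se: np.ndarray
    tvalues: np.ndarray
    sd_animal: float
    sd_resid: float
    loglik: float
    deviance: float
    df_resid: int
    names: list[str]
    method: str  # 'ML' or 'REML'

    def param(self, name: str) -> float:
        return float(self.params[self.names.index(name)])


def _check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    scale = diag.max() if diag.size else 0.0
    bad = [names[i] for i in range(X.shape[1]) if diag[i] < 1e-10 * max(scale, 1.0)]
    if bad:
        raise ValueError(f"design is singular; collinear column(s): {', '.join(bad)}")


def _group_blocks(groups: np.ndarray) -> list[np.ndarray]:
    _, codes = np.unique(groups, return_inverse=True)
    return [np.flatnonzero(codes == k) for k in range(codes.max() + 1)]


def _precompute(X: np.ndarray, y: np.ndarray, blocks: list[np.ndarray]) -> dict:
    """Sufficient statistics that do not depend on the variance ratio."""
    return dict(
        XtX=X.T @ X,
        Xty=X.T @ y,
        yty=float(y @ y),
        S=np.vstack([X[idx].sum(axis=0) for idx in blocks]),  # group column sums
        Sy=np.array([y[idx].sum() for idx in blocks]),
        ng=np.array([idx.size for idx in blocks], dtype=float),
        n=y.size,
        p=X.shape[1],
    )


def _profile(lam: float, pre: dict, reml: bool):
    """Profiled log-likelihood and GLS estimates at variance ratio ``lam``.

    Uses the group-wise Woodbury identity: H^-1 = I - c J per group with
    c = lam / (1 + lam n_g), so everything reduces to the precomputed
    group sums — O(groups x p) per evaluation.
    """
    n, p = pre["n"], pre["p"]
    c = lam / (1.0 + lam * pre["ng"])
    A = pre["XtX"] - (pre["S"].T * c) @ pre["S"]
    b = pre["Xty"] - pre["S"].T @ (c * pre["Sy"])
    beta = np.linalg.solve(A, b)
    y_h_y = pre["yty"] - float(c * pre["Sy"] @ pre["Sy"])
    rss = y_h_y - 2.0 * float(beta @ b) + float(beta @ A @ beta)
    rss = max(rss, 1e-300)
    logdet_h = float(np.sum(np.log1p(lam * pre["ng"])))
    if reml:
        sigma2 = rss / (n - p)
        ll = (
            -0.5 * (n - p) * (_LOG2PI + np.log(sigma2) + 1.0)
            - 0.5 * logdet_h
            - 0.5 * np.linalg.slogdet(A)[1]
        )
    else:
        sigma2 = rss / n
        ll = -0.5 * n * (_LOG2PI + np.log(sigma2) + 1.0) - 0.5 * logdet_h
    return ll, beta, sigma2, A


def fit_random_intercept_lm(
    X,
    y,
    groups: Optional[Sequence] = None,
    reml: bool = False,
    names: Optional[Sequence[str]] = None,
) -> MixedLMResult:
    """Fit the random-intercept model by profiled-ratio likelihood.

    Parameters
    ----------
    X : (n, p) design matrix of fixed effects (include the intercept).
    y : (n,) response.
    groups : (n,) animal labels; ``None`` reduces to ordinary least squares.
    reml : use restricted rather than full maximum likelihood.
    names : column names for reporting (default x0, x1, ...).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and np.asarray(y).size == X.shape[1]:
        X = X.T
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    names = list(names) if names is not None else [f"x{i}" for i in range(p)]
    _check_full_rank(X, names)
    if groups is None:
        lam_hat = 0.0
        pre = _precompute(X, y, [np.arange(n)])
        ll, beta, sigma2, A = _profile(0.0, pre, reml)
    else:
        groups = np.asarray(groups)
        if len(np.unique(groups)) < 2:
            raise ValueError("need >= 2 grouping levels (animals)")
        pre = _precompute(X, y, _group_blocks(groups))

        def neg(theta: float) -> float:
            return -_profile(np.exp(theta), pre, reml)[0]

        res = optimize.minimize_scalar(
            neg, bounds=(-14.0, 14.0), method="bounded", options={"xatol": 1e-10}
        )
        lam_hat = float(np.exp(res.x))
        ll, beta, sigma2, A = _profile(lam_hat, pre, reml)
        ll0, beta0, sigma20, A0 = _profile(0.0, pre, reml)
        if ll0 >= ll:  # boundary solution: no animal-level variance
            lam_hat, ll, beta, sigma2, A = 0.0, ll0, beta0, sigma20, A0
    cov = sigma2 * np.linalg.inv(A)
    se = np.sqrt(np.diag(cov))
    return MixedLMResult(
        params=beta,
        se=se,
        tvalues=beta / se,
        sd_animal=float(np.sqrt(lam_hat * sigma2)),
        sd_resid=float(np.sqrt(sigma2)),
        loglik=float(ll),
        deviance=float(-2.0 * ll),
        df_resid=n - p,
        names=names,
        method="REML" if reml else "ML",
    )


def marginal_loglik(X, y, groups, beta, sd_animal: float, sd_resid: float) -> float:
    """Log-likelihood by direct assembly of the marginal covariance.

    Builds the dense n x n covariance ``sd_resid^2 I + sd_animal^2 Z Z'``
    and evaluates the multivariate-normal log density — an independent
    route used to verify the profiled engine on small instances.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    groups = np.asarray(groups)
    n = y.size
    same = groups[:, None] == groups[None, :]
    V = sd_resid**2 * np.eye(n) + sd_animal**2 * same
    r = y - X @ np.asarray(beta, dtype=float)
    sign, logdet = np.linalg.slogdet(V)
    return float(-0.5 * (n * _LOG2PI + logdet + r @ np.linalg.solve(V, r)))
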