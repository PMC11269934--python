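"""Developmental curve fits: Gaussian window, linear-plateau, quadratic.

Estimators follow the scikit-learn protocol (``fit`` / ``predict``,
``get_params``; fitted attributes carry a trailing underscore) so they
compose with sklearn model selection.  Grouped fits delegate to the
random-intercept engine in :mod:`devwindow.mixed`; the thin functions at
the bottom accept tidy study tables and return frozen report dataclasses.

Relative gene expression uses the 2^-ddCt convention against a reference
gene and reference group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .core import FitFailureError, validate_study_table
from .mixed import MixedLMResult, fit_random_intercept_lm, marginal_loglik  # noqa: F401

logger = logging.getLogger(__name__)


def _as_1d(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return X.ravel() if X.ndim > 1 else X


# ---------------------------------------------------------------------------
# Gaussian developmental window


def gaussian_window_curve(pd_day, kappa, mu, sigma):
    pd_day = np.asarray(pd_day, dtype=float)
    return kappa * np.exp(-((pd_day - mu) ** 2) / (2.0 * sigma**2))


@dataclass
class GaussianWindowFit:
    kappa: float  # peak responsiveness ratio
    mu: float  # peak postnatal day
    sigma: float  # window half-width (days)
    se: dict
    tvalues: dict
    n: int
    residual_ss: float


class GaussianWindowRegressor(BaseEstimator, RegressorMixin):
    """Bell-curve fit of responsiveness ratio against postnatal day.

    Model: ``RR(PD) = kappa * exp(-(PD - mu)^2 / (2 sigma^2))``, fit by
    nonlinear least squares with multi-start initialization (``mu`` at
    the empirical argmax +/- 2 days, ``sigma`` in {1, 3}).  Standard
    errors come from the Jacobian at the optimum; t = estimate / SE.
    """

    def __init__(self, min_distinct_days: int = 6):
        self.min_distinct_days = min_distinct_days

    def fit(self, X, y):
        x = _as_1d(X)
        y = np.asarray(y, dtype=float).ravel()
        if len(np.unique(x)) < self.min_distinct_days:
            raise ValueError(f"need >= {self.min_distinct_days} distinct postnatal days")
        mu_peak = float(x[np.argmax(y)])
        kappa0 = max(float(y.max()), 1e-3)
        span = float(x.max() - x.min())
        best, best_cov, best_sse = None, None, np.inf
        for dmu in (-2.0, 0.0, 2.0):
            for sigma0 in (1.0, 3.0):
                try:
                    popt, pcov = optimize.curve_fit(
                        gaussian_window_curve,
                        x,
                        y,
                        p0=[kappa0, mu_peak + dmu, sigma0],
                        bounds=([0.0, x.min() - 5.0, 1e-3], [max(1.0, 2 * kappa0), x.max() + 5.0, 2 * span]),
                        maxfev=10000,
                    )
                except RuntimeError:
                    continue
                sse = float(np.sum((y - gaussian_window_curve(x, *popt)) ** 2))
                if sse < best_sse:
                    best, best_cov, best_sse = popt, pcov, sse
        if best is None:
            raise FitFailureError("Gaussian window fit failed from every start")
        self.kappa_, self.mu_, self.sigma_ = (float(v) for v in best)
        se = np.sqrt(np.diag(best_cov))
        self.se_ = dict(zip(("kappa", "mu", "sigma"), (float(s) for s in se)))
        with np.errstate(divide="ignore", invalid="ignore"):
            self.tvalues_ = {k: float(v / self.se_[k]) if self.se_[k] > 0 else np.inf
                             for k, v in zip(("kappa", "mu", "sigma"), best)}
        self.n_ = int(x.size)
        self.residual_ss_ = best_sse
        return self

    def predict(self, X):
        check_is_fitted(self, "kappa_")
        return gaussian_window_curve(_as_1d(X), self.kappa_, self.mu_, self.sigma_)

    def result_(self) -> GaussianWindowFit:
        check_is_fitted(self, "kappa_")
        return GaussianWindowFit(
            self.kappa_, self.mu_, self.sigma_, self.se_, self.tvalues_, self.n_, self.residual_ss_
        )


def fit_gaussian_window(pd_days, rr, group=None) -> GaussianWindowFit:
    """Fit the Gaussian responsiveness window to per-slice RR observations."""
    return GaussianWindowRegressor().fit(pd_days, rr).result_()


# ---------------------------------------------------------------------------
# Linear-plateau (segmented) regression with profiled junction point


@dataclass
class PlateauFit:
    a: float  # intercept
    b: float  # pre-junction slope
    jp: float  # junction point, days
    se: dict
    tvalues: dict
    sd_animal: float
    sd_resid: float
    plateau: float  # a + b * jp
    deviance: float
    n: int
    linear_fallback: bool


class LinearPlateauRegressor(BaseEstimator, RegressorMixin):
    """Piecewise mean: ``a + b x`` below the junction ``jp``, constant above.

    The junction point is profiled over a grid (coarse pass, then 0.05-day
    refinement); at each candidate the conditional model is fit by the
    random-intercept engine (or OLS without groups) and ``jp`` minimizes
    the deviance.  Its SE comes from the numerical curvature of the
    profile deviance.  Flat data (unidentifiable junction) fall back to a
    plain linear fit, flagged via ``linear_fallback_``.
    """

    def __init__(self, random_intercept: bool = True, grid_step: float = 0.05, reml: bool = False):
        self.random_intercept = random_intercept
        self.grid_step = grid_step
        self.reml = reml

    def _fit_at(self, x, y, groups, jp):
        X = np.column_stack([np.ones_like(x), np.minimum(x, jp)])
        return fit_random_intercept_lm(X, y, groups=groups, reml=self.reml, names=["a", "b"])

    def fit(self, X, y, groups=None):
        x = _as_1d(X)
        y = np.asarray(y, dtype=float).ravel()
        if not (self.random_intercept and groups is not None):
            groups = None
        distinct = np.unique(x)
        if distinct.size < 4:
            raise ValueError("need at least 4 distinct x values to profile a junction")
        lo, hi = distinct[2], distinct[-2]  # >= 3 below, >= 2 at/above the candidate
        if hi <= lo:
            raise ValueError("x range too narrow to place a junction")

        linear = fit_random_intercept_lm(
            np.column_stack([np.ones_like(x), x]), y, groups=groups, reml=self.reml, names=["a", "b"]
        )
        if np.std(y) < 1e-12 or abs(linear.param("b")) < 1e-10 * max(1.0, np.std(y) / max(np.std(x), 1e-12)):
            logger.warning("flat data: junction unidentifiable; returning linear fit")
            return self._set_linear(linear, x)

        coarse = np.arange(lo, hi + 1e-9, max(self.grid_step, 0.25))
        dev_c = np.array([self._fit_at(x, y, groups, jp).deviance for jp in coarse])
        jc = coarse[int(np.argmin(dev_c))]
        fine = np.arange(max(lo, jc - 0.5), min(hi, jc + 0.5) + 1e-9, self.grid_step)
        fits = [self._fit_at(x, y, groups, jp) for jp in fine]
        dev = np.array([f.deviance for f in fits])
        k = int(np.argmin(dev))
        if dev.max() - dev.min() < 1e-9:
            logger.warning("deviance profile flat: junction unidentifiable; returning linear fit")
            return self._set_linear(linear, x)
        best = fits[k]
        self.jp_ = float(fine[k])
        self.a_, self.b_ = best.params
        se_jp = np.nan
        if 0 < k < dev.size - 1:
            h = self.grid_step
            curv = (dev[k - 1] - 2 * dev[k] + dev[k + 1]) / h**2
            if curv > 0:
                se_jp = float(np.sqrt(2.0 / curv))
        self.se_ = {"a": float(best.se[0]), "b": float(best.se[1]), "jp": se_jp}
        self.tvalues_ = {
            "a": float(best.tvalues[0]),
            "b": float(best.tvalues[1]),
            "jp": float(self.jp_ / se_jp) if se_jp and np.isfinite(se_jp) else np.nan,
        }
        self.sd_animal_ = best.sd_animal
        self.sd_resid_ = best.sd_resid
        self.plateau_ = float(self.a_ + self.b_ * self.jp_)
        self.deviance_ = best.deviance
        self.profile_ = pd.DataFrame({"jp": fine, "deviance": dev})
        self.linear_fallback_ = False
        self.n_ = int(x.size)
        return self

    def _set_linear(self, linear: MixedLMResult, x: np.ndarray):
        self.a_, self.b_ = linear.params
        self.jp_ = np.nan
        self.se_ = {"a": float(linear.se[0]), "b": float(linear.se[1]), "jp": np.nan}
        self.tvalues_ = {"a": float(linear.tvalues[0]), "b": float(linear.tvalues[1]), "jp": np.nan}
        self.sd_animal_ = linear.sd_animal
        self.sd_resid_ = linear.sd_resid
        self.plateau_ = np.nan
        self.deviance_ = linear.deviance
        self.profile_ = pd.DataFrame({"jp": [], "deviance": []})
        self.linear_fallback_ = True
        self.n_ = int(x.size)
        return self

    def predict(self, X):
        check_is_fitted(self, "a_")
        x = _as_1d(X)
        if self.linear_fallback_:
            return self.a_ + self.b_ * x
        return self.a_ + self.b_ * np.minimum(x, self.jp_)

    def result_(self) -> PlateauFit:
        check_is_fitted(self, "a_")
        return PlateauFit(
            a=float(self.a_), b=float(self.b_), jp=float(self.jp_), se=self.se_,
            tvalues=self.tvalues_, sd_animal=self.sd_animal_, sd_resid=self.sd_resid_,
            plateau=self.plateau_, deviance=self.deviance_, n=self.n_,
            linear_fallback=self.linear_fallback_,
        )


# ---------------------------------------------------------------------------
# Quadratic developmental trajectory


@dataclass
class QuadFit:
    a: float
    b: float
    c: float
    se: dict
    tvalues: dict
    sd_animal: float
    sd_resid: float
    vertex: float  # -b / (2c)
    vertex_value: float  # a - b^2 / (4c)
    vertex_is_minimum: Optional[bool]
    n: int


class QuadraticRegressor(BaseEstimator, RegressorMixin):
    """Quadratic mean ``a + b x + c x^2`` with optional animal intercepts.

    The vertex (developmental extremum) is reported at ``-b/(2c)`` with
    value ``a - b^2/(4c)``; a vanishing curvature leaves it undefined.
    """

    def __init__(self, random_intercept: bool = True, reml: bool = False):
        self.random_intercept = random_intercept
        self.reml = reml

    def fit(self, X, y, groups=None):
        x = _as_1d(X)
        y = np.asarray(y, dtype=float).ravel()
        if len(np.unique(x)) < 3:
            raise ValueError("need >= 3 distinct x values")
        if not (self.random_intercept and groups is not None):
            groups = None
        design = np.column_stack([np.ones_like(x), x, x**2])
        res = fit_random_intercept_lm(design, y, groups=groups, reml=self.reml, names=["a", "b", "c"])
        self.a_, self.b_, self.c_ = res.params
        self.se_ = dict(zip(res.names, (float(s) for s in res.se)))
        self.tvalues_ = dict(zip(res.names, (float(t) for t in res.tvalues)))
        self.sd_animal_ = res.sd_animal
        self.sd_resid_ = res.sd_resid
        if abs(self.c_) < 1e-12:
            logger.warning("curvature ~ 0: vertex undefined")
            self.vertex_, self.vertex_value_, self.vertex_is_minimum_ = np.nan, np.nan, None
        else:
            self.vertex_ = float(-self.b_ / (2.0 * self.c_))
            self.vertex_value_ = float(self.a_ - self.b_**2 / (4.0 * self.c_))
            self.vertex_is_minimum_ = bool(self.c_ > 0)
        self.deviance_ = res.deviance
        self.n_ = int(x.size)
        return self

    def predict(self, X):
        check_is_fitted(self, "a_")
        x = _as_1d(X)
        return self.a_ + self.b_ * x + self.c_ * x**2

    def result_(self) -> QuadFit:
        check_is_fitted(self, "a_")
        return QuadFit(
            a=float(self.a_), b=float(self.b_), c=float(self.c_), se=self.se_,
            tvalues=self.tvalues_, sd_animal=self.sd_animal_, sd_resid=self.sd_resid_,
            vertex=self.vertex_, vertex_value=self.vertex_value_,
            vertex_is_minimum=self.vertex_is_minimum_, n=self.n_,
        )


# ---------------------------------------------------------------------------
# Study-table wrappers


def _table_xyg(table: pd.DataFrame, variable: Optional[str]):
    validate_study_table(table)
    if variable is not None:
        table = table[table["variable"] == variable]
    if table.empty:
        raise ValueError("no rows for the requested variable")
    return (
        table["pd"].to_numpy(dtype=float),
        table["value"].to_numpy(dtype=float),
        table["animal_id"].to_numpy(),
    )


def fit_linear_plateau(table: pd.DataFrame, random_intercept: bool = True,
                       variable: Optional[str] = None, grid_step: float = 0.05) -> PlateauFit:
    x, y, g = _table_xyg(table, variable)
    reg = LinearPlateauRegressor(random_intercept=random_intercept, grid_step=grid_step)
    return reg.fit(x, y, groups=g if random_intercept else None).result_()


def fit_quadratic(table: pd.DataFrame, random_intercept: bool = True,
                  variable: Optional[str] = None) -> QuadFit:
    x, y, g = _table_xyg(table, variable)
    reg = QuadraticRegressor(random_intercept=random_intercept)
    return reg.fit(x, y, groups=g if random_intercept else None).result_()


# ---------------------------------------------------------------------------
# Relative expression (2^-ddCt)


@dataclass
class RQResult:
    samples: pd.DataFrame  # sample_id, group, dct, ddct, rq
    reference_group: object
    group_summary: pd.DataFrame  # group, rq_geomean, n
    n_excluded: int


def compute_rq(ct_target, ct_reference_gene, groups, reference_group) -> RQResult:
    """Relative expression by the 2^-ddCt method.

    dCt = Ct(target) - Ct(reference gene) per sample; ddCt subtracts the
    mean dCt of the reference group; RQ = 2^-ddCt.  Samples missing
    either Ct are excluded (logged).  The geometric mean RQ of the
    reference group is 1 by construction.
    """
    ct_t = np.asarray(ct_target, dtype=float)
    ct_r = np.asarray(ct_reference_gene, dtype=float)
    groups = np.asarray(groups)
    ok = ~(np.isnan(ct_t) | np.isnan(ct_r))
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("excluding %d samples missing a Ct value", n_excluded)
    ct_t, ct_r, groups = ct_t[ok], ct_r[ok], groups[ok]
    ref_mask = groups == reference_group
    if not ref_mask.any():
        raise ValueError(f"reference group {reference_group!r} not present")
    dct = ct_t - ct_r
    ddct = dct - dct[ref_mask].mean()
    rq = 2.0 ** (-ddct)
    samples = pd.DataFrame({"sample_id": np.arange(rq.size), "group": groups,
                            "dct": dct, "ddct": ddct, "rq": rq})
    summary = (
        samples.groupby("group", sort=True)["rq"]
        .agg(rq_geomean=lambda v: float(np.exp(np.mean(np.log(v)))), n="size")
        .reset_index()
    )
    return RQResult(samples=samples, reference_group=reference_group,
                    group_summary=summary, n_excluded=n_excluded)
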