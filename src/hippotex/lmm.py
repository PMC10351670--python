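"""Exact profiled ML/REML fitting of the single-random-intercept linear mixed model.

The model is ``y = X beta + b_g + e`` with one random intercept per group,
``b_g ~ N(0, tau2)`` and ``e ~ N(0, sigma2)``.  For this special covariance
structure the likelihood can be profiled down to a one-dimensional search over
the variance ratio ``lambda = tau2 / sigma2``: per-group cross-products are
assembled once and every candidate ``lambda`` costs a single p x p solve.
This makes the repeated fits of BIC model scans and simulation calibrations
cheap; the general-purpose engine for richer models remains
``statsmodels.MixedLM`` (against which this solver is cross-checked in the
test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = ["RandomInterceptLM", "RandomInterceptLMResults"]

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class RandomInterceptLMResults:
    """Estimates from a random-intercept LMM fit.

    Attributes
    ----------
    params : ndarray
        Fixed-effect coefficients.
    bse : ndarray
        Their standard errors from the GLS covariance.
    sigma2, tau2 : float
        Residual and random-intercept variances.
    llf : float
        Maximised log-likelihood (ML) or restricted log-likelihood (REML).
    bic : float
        ``-2 llf + k log(n)`` with ``k`` = fixed effects + 2 variance
        parameters and ``n`` the number of observations (ML fits only).
    """

    params: np.ndarray
    bse: np.ndarray
    cov_params: np.ndarray
    sigma2: float
    tau2: float
    llf: float
    method: str
    nobs: int
    k_fe: int
    group_labels: list = field(repr=False, default_factory=list)
    blups: np.ndarray = field(repr=False, default=None)

    @property
    def bic(self) -> float:
        k = self.k_fe + 2
        return -2.0 * self.llf + k * np.log(self.nobs)

    def blup_series(self) -> pd.Series:
        return pd.Series(self.blups, index=self.group_labels, name="blup")


class RandomInterceptLM:
    """``y = X beta + b_group + e`` fitted by profiled ML or REML.

    Parameters
    ----------
    endog : array-like, shape (n,)
    exog : array-like, shape (n, p)
        Design matrix; include an intercept column if one is wanted.
    groups : array-like, shape (n,)
        Group labels for the random intercept.
    """

    def __init__(self, endog, exog, groups):
        y = np.asarray(endog, dtype=float).ravel()
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if y.shape[0] != X.shape[0]:
            raise ValueError("endog and exog have different lengths")
        codes, labels = pd.factorize(np.asarray(groups))
        if codes.shape[0] != y.shape[0]:
            raise ValueError("groups length mismatch")
        self.nobs, self.k_fe = X.shape
        self.group_labels = list(labels)
        n_g = np.bincount(codes)
        # per-group sufficient statistics
        p = self.k_fe
        G = len(labels)
        sx = np.zeros((G, p))
        sy = np.zeros(G)
        np.add.at(sx, codes, X)
        np.add.at(sy, codes, y)
        self._XtX = X.T @ X
        self._Xty = X.T @ y
        self._yty = float(y @ y)
        self._sx, self._sy, self._ng = sx, sy, n_g.astype(float)
        self._y, self._X, self._codes = y, X, codes

    # ------------------------------------------------------------------
    def _profile(self, lam: float, reml: bool):
        """GLS solve and profiled -2 log-likelihood at variance ratio lam."""
        c = lam / (1.0 + self._ng * lam)          # per group
        XtViX = self._XtX - (self._sx * c[:, None]).T @ self._sx
        XtViy = self._Xty - self._sx.T @ (c * self._sy)
        yViy = self._yty - float(c @ (self._sy**2))
        try:
            beta = np.linalg.solve(XtViX, XtViy)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(XtViX, XtViy, rcond=None)[0]
        rss = yViy - float(beta @ XtViy)
        rss = max(rss, 1e-300)
        logdetV = float(np.sum(np.log1p(self._ng * lam)))
        n, p = self.nobs, self.k_fe
        if reml:
            dof = n - p
            sigma2 = rss / dof
            sign, logdetXVX = np.linalg.slogdet(XtViX)
            m2ll = dof * (_LOG_2PI + np.log(sigma2)) + logdetV + logdetXVX + dof
        else:
            sigma2 = rss / n
            m2ll = n * (_LOG_2PI + np.log(sigma2)) + logdetV + n
        return m2ll, beta, sigma2, XtViX

    def fit(self, reml: bool = False) -> RandomInterceptLMResults:
        obj = lambda t: self._profile(np.exp(t), reml)[0]
        res = minimize_scalar(obj, bounds=(-14.0, 10.0), method="bounded",
                              options={"xatol": 1e-8})
        lam = float(np.exp(res.x))
        # allow the boundary tau2 = 0
        m2ll0 = self._profile(0.0, reml)[0]
        if m2ll0 <= res.fun:
            lam = 0.0
        m2ll, beta, sigma2, XtViX = self._profile(lam, reml)
        tau2 = lam * sigma2
        cov = sigma2 * np.linalg.inv(XtViX)
        resid_sum = self._sy - self._sx @ beta
        c = lam / (1.0 + self._ng * lam)
        blups = c * resid_sum
        return RandomInterceptLMResults(
            params=beta, bse=np.sqrt(np.clip(np.diag(cov), 0.0, None)),
            cov_params=cov,
            sigma2=float(sigma2), tau2=float(tau2), llf=float(-0.5 * m2ll),
            method="reml" if reml else "ml", nobs=self.nobs, k_fe=self.k_fe,
            group_labels=self.group_labels, blups=blups,
        )
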