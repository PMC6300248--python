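"""Modified-Gompertz growth curves on absorbance-peak proxies.

Daily absorbance peaks (650 nm for Synechococcus, 680 nm for
Prochlorococcus) proxy pigment and hence cell content.  The Zwietering
modified Gompertz form with an added baseline (absorbance blanks are not
zero) is

    y(t) = baseline + K * exp(-exp(mu * e / K * (lag - t) + 1)),

with lag (d), maximum specific growth rate mu (AU d-1, the steepest tangent
slope) and carrying capacity K (AU above baseline).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import NotFittedError
from scipy.optimize import least_squares

__all__ = ["gompertz_predict", "GompertzGrowthFitter", "fit_growth"]

_E = np.e
_TOL = 1e-15


def gompertz_predict(t, lag_d: float, rate: float, capacity: float,
                     baseline: float = 0.0):
    """Absorbance at time ``t`` (days) under the modified Gompertz model."""
    t_arr = np.asarray(t, dtype=float)
    if capacity <= 0:
        out = np.full(t_arr.shape, float(baseline))
        return float(out) if np.ndim(t) == 0 else out
    out = baseline + capacity * np.exp(
        -np.exp(rate * _E / capacity * (lag_d - t_arr) + 1.0))
    return float(out) if np.ndim(t) == 0 else out


class GompertzGrowthFitter(RegressorMixin, BaseEstimator):
    """Least-squares fit of the modified Gompertz growth model.

    Initialisation: baseline = min, capacity = range, rate from the steepest
    observed slope, lag from the tangent intercept with the baseline.  A
    series with no increasing trend is flagged unconverged rather than
    raising.  Fitted attributes: ``lag_d_``, ``rate_``, ``capacity_``,
    ``baseline_``, ``converged_``, ``flags_``, ``exponential_window_``.
    """

    def __init__(self, tol: float = _TOL, max_iter: int = 5000):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).ravel()
        yv = np.asarray(y, dtype=float)
        if t.size < 5:
            raise ValueError("need at least 5 growth points")
        self.flags_: tuple[str, ...] = ()

        baseline0 = float(np.min(yv))
        capacity0 = max(float(np.ptp(yv)), 1e-9)
        dy = np.diff(yv) / np.diff(t)
        i_max = int(np.argmax(dy)) if dy.size else 0
        rate0 = max(float(dy[i_max]), 1e-6) if dy.size else 1e-6
        t_steep = 0.5 * (t[i_max] + t[i_max + 1]) if dy.size else t[0]
        lag0 = float(t_steep - (yv[i_max] - baseline0) / rate0)

        trend = np.polyfit(t, yv, 1)[0] if np.ptp(yv) > 0 else 0.0
        if trend <= 0:
            # flat or declining series: no growth to fit
            self.lag_d_, self.rate_ = lag0, 0.0
            self.capacity_, self.baseline_ = capacity0, baseline0
            self.converged_ = False
            self.flags_ = ("no_growth",)
            self.residual_ss_ = float(np.sum((yv - np.mean(yv)) ** 2))
            self.exponential_window_ = (np.nan, np.nan)
            return self

        def resid(th):
            lag, rate, cap, base = th
            return gompertz_predict(t, lag, rate, cap, base) - yv

        res = least_squares(
            resid, x0=[lag0, rate0, capacity0, baseline0],
            bounds=([-np.inf, 1e-12, 1e-12, -np.inf],
                    [np.inf, np.inf, np.inf, np.inf]),
            method="trf", xtol=self.tol, ftol=self.tol, gtol=self.tol,
            max_nfev=self.max_iter)
        self.lag_d_, self.rate_, self.capacity_, self.baseline_ = (
            float(v) for v in res.x)
        self.converged_ = bool(res.success)
        self.residual_ss_ = float(2.0 * res.cost)
        # exponential-phase window: lag to the time reaching 95% of capacity
        u95 = np.log(-np.log(0.95))
        t95 = self.lag_d_ - (u95 - 1.0) * self.capacity_ / (self.rate_ * _E)
        self.exponential_window_ = (self.lag_d_, float(t95))
        return self

    def predict(self, X):
        if not hasattr(self, "rate_"):
            raise NotFittedError("fit before predict")
        return gompertz_predict(np.asarray(X, float).ravel(), self.lag_d_,
                                self.rate_, self.capacity_, self.baseline_)


def fit_growth(days, absorbance) -> GompertzGrowthFitter:
    """Convenience wrapper returning a fitted :class:`GompertzGrowthFitter`."""
    return GompertzGrowthFitter().fit(days, absorbance)
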