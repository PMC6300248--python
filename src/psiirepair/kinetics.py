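"""Two-state kinetics of Photosystem II photoinactivation and repair.

The active-PSII pool (tracked through F_V'/F_M' as a proxy) obeys

    dA/dt = -k_PI * A + k_REC * (A0 - A),

a first-order exchange between an active pool A and an inactivated pool
A0 - A of fixed total A0.  Photoinactivation (k_PI) is light-driven loss of
activity; repair (k_REC) is functional restoration through protein turnover
and is blocked by the ribosome inhibitor lincomycin.  The closed form is

    A(t) = A0 * (k_REC + k_PI * exp(-(k_PI + k_REC) t)) / (k_PI + k_REC),

which reduces to the pure exponential A0 * exp(-k_PI t) when k_REC = 0.

The measurement design is a paired lincomycin chase: k_PI is fit from the
+lincomycin decay (repair blocked), then k_REC is fit from the same
replicate's -lincomycin series with k_PI held fixed, on the assumption that
photoinactivation proceeds identically in both cuvettes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import NotFittedError

__all__ = [
    "predict_active",
    "PhotoinactivationFitter",
    "RepairFitter",
    "FluorDecaySeries",
    "KineticFit",
    "fit_photoinactivation",
    "fit_repair",
    "pair_and_fit",
    "PairedFitResult",
]

_TOL = 1e-15


def predict_active(a0: float, k_pi: float, k_rec: float, t):
    """Active-PSII proxy at time ``t`` (s) under damage and repair.

    Total function of finite inputs; when ``k_pi + k_rec == 0`` the pool is
    stationary at ``a0``.  Accepts scalar or array ``t``.
    """
    t_arr = np.asarray(t, dtype=float)
    k_tot = k_pi + k_rec
    if k_tot == 0.0:
        out = np.full(t_arr.shape, float(a0))
    elif k_rec == 0.0:
        # repair-free limit: identical to the single-phase exponential
        out = a0 * np.exp(-k_pi * t_arr)
    else:
        out = a0 * (k_rec + k_pi * np.exp(-k_tot * t_arr)) / k_tot
    return float(out) if np.ndim(t) == 0 else out


def _as_times(X) -> np.ndarray:
    t = np.asarray(X, dtype=float)
    if t.ndim == 2 and t.shape[1] == 1:
        t = t[:, 0]
    if t.ndim != 1:
        raise ValueError("expected a 1-d time array or a single-column matrix")
    return t


def _param_se(jac: np.ndarray, residual_ss: float, n: int, p: int) -> np.ndarray:
    """Standard errors from the least-squares Jacobian at the solution."""
    dof = n - p
    if dof <= 0:
        return np.full(p, np.nan)
    try:
        cov = np.linalg.pinv(jac.T @ jac) * residual_ss / dof
        return np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:  # pragma: no cover - degenerate geometry
        return np.full(p, np.nan)


class PhotoinactivationFitter(RegressorMixin, BaseEstimator):
    """Single-phase exponential decay fit, ``A(t) = A0 exp(-k_PI t)``.

    Used on +lincomycin F_V'/F_M' series, where repair is blocked and pure
    photoinactivation remains.  ``k_PI`` is initialised from a log-linear
    regression of the positive observations; negative estimates (rising
    signal) are reported, never clipped.

    Attributes (after ``fit``): ``a0_``, ``k_pi_``, ``se_a0_``, ``se_k_pi_``,
    ``residual_ss_``, ``converged_``, ``flags_``, ``n_obs_``.
    """

    def __init__(self, tol: float = _TOL, max_iter: int = 2000):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        t = _as_times(X)
        y = np.asarray(y, dtype=float)
        if t.shape != y.shape:
            raise ValueError("times and values must have matching length")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite values in decay series")
        if t.size < 3:
            raise ValueError("need at least 3 time points")
        self.n_obs_ = int(t.size)
        self.flags_: tuple[str, ...] = ()

        scale = max(1.0, float(np.max(np.abs(y))))
        if np.ptp(y) <= 1e-12 * scale:
            # perfectly flat series: no measurable decay
            self.a0_, self.k_pi_ = float(y[0]), 0.0
            self.se_a0_ = self.se_k_pi_ = 0.0
            self.residual_ss_ = float(np.sum((y - y.mean()) ** 2))
            self.converged_ = True
            self.flags_ = ("no_decay",)
            return self

        a0_init = float(y[0]) if y[0] != 0 else float(np.mean(y))
        mask = y > 0
        k_init = 1e-4
        if mask.sum() >= 2 and np.ptp(t[mask]) > 0:
            slope, icpt = np.polyfit(t[mask], np.log(y[mask]), 1)
            k_init = -float(slope)
            a0_init = float(np.exp(icpt))

        res = least_squares(
            lambda th: th[0] * np.exp(-th[1] * t) - y,
            x0=[a0_init, k_init],
            method="lm",
            xtol=self.tol, ftol=self.tol, gtol=self.tol,
            max_nfev=self.max_iter,
        )
        self.a0_, self.k_pi_ = (float(v) for v in res.x)
        self.converged_ = bool(res.success)
        self.residual_ss_ = float(2.0 * res.cost)
        self.se_a0_, self.se_k_pi_ = _param_se(res.jac, self.residual_ss_, t.size, 2)
        return self

    def predict(self, X):
        if not hasattr(self, "k_pi_"):
            raise NotFittedError("fit before predict")
        return self.a0_ * np.exp(-self.k_pi_ * _as_times(X))


class RepairFitter(RegressorMixin, BaseEstimator):
    """One-parameter repair fit with ``k_PI`` frozen at its paired estimate.

    Fits ``k_REC`` in :func:`predict_active` to a -lincomycin series.  ``a0``
    defaults to the first observation (F_V'/F_M' at t0 as the proxy's initial
    value); set ``co_fit_a0=True`` to estimate it jointly.  Negative k_REC is
    permitted and flagged; a fit that runs to the saturation bound (a series
    that never decays although k_PI > 0) is flagged ``repair_saturated``.
    """

    #: bound on |k_REC| (s-1); five orders above the fastest observed repair
    K_REC_BOUND = 10.0

    def __init__(self, k_pi: float, a0: float | None = None,
                 co_fit_a0: bool = False, tol: float = _TOL,
                 max_iter: int = 2000, saturation_k: float = 1.0):
        self.k_pi = k_pi
        self.a0 = a0
        self.co_fit_a0 = co_fit_a0
        self.tol = tol
        self.max_iter = max_iter
        self.saturation_k = saturation_k

    def fit(self, X, y):
        if not np.isfinite(self.k_pi):
            raise ValueError("k_pi must be finite")
        t = _as_times(X)
        y = np.asarray(y, dtype=float)
        if t.shape != y.shape:
            raise ValueError("times and values must have matching length")
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite values in decay series")
        if t.size < 3:
            raise ValueError("need at least 3 time points")
        self.n_obs_ = int(t.size)
        self.flags_: tuple[str, ...] = ()

        a0 = float(self.a0) if self.a0 is not None else float(y[np.argmin(t)])

        # initialise from the apparent plateau fraction k_REC/(k_PI + k_REC)
        plateau = float(np.mean(y[-3:])) / a0 if a0 != 0 else 0.5
        plateau = min(max(plateau, 1e-6), 1 - 1e-6)
        k_init = self.k_pi * plateau / (1 - plateau) if self.k_pi > 0 else 1e-4
        k_init = float(np.clip(k_init, -self.K_REC_BOUND * 0.99,
                               self.K_REC_BOUND * 0.99))

        if self.co_fit_a0:
            def resid(th):
                return predict_active(th[1], self.k_pi, th[0], t) - y
            x0 = [k_init, a0]
            bounds = ([-self.K_REC_BOUND, 1e-12], [self.K_REC_BOUND, np.inf])
        else:
            def resid(th):
                return predict_active(a0, self.k_pi, th[0], t) - y
            x0 = [k_init]
            bounds = ([-self.K_REC_BOUND], [self.K_REC_BOUND])

        res = least_squares(resid, x0=x0, bounds=bounds, method="trf",
                            xtol=self.tol, ftol=self.tol, gtol=self.tol,
                            max_nfev=self.max_iter)
        self.k_rec_ = float(res.x[0])
        self.a0_ = float(res.x[1]) if self.co_fit_a0 else a0
        self.converged_ = bool(res.success)
        self.residual_ss_ = float(2.0 * res.cost)
        ses = _param_se(res.jac, self.residual_ss_, t.size, len(x0))
        self.se_k_rec_ = float(ses[0])
        self.se_a0_ = float(ses[1]) if self.co_fit_a0 else 0.0

        flags = []
        if self.k_rec_ < 0:
            flags.append("negative_k_rec")
        if self.k_rec_ >= self.saturation_k:
            flags.append("repair_saturated")
        self.flags_ = tuple(flags)
        return self

    def predict(self, X):
        if not hasattr(self, "k_rec_"):
            raise NotFittedError("fit before predict")
        return predict_active(self.a0_, self.k_pi, self.k_rec_, _as_times(X))


@dataclass
class FluorDecaySeries:
    """F_V'/F_M' versus elapsed treatment-light time for one replicate."""

    replicate_id: str
    strain_id: str
    growth_light: float
    lincomycin: bool
    times: np.ndarray
    fvfm: np.ndarray
    measurement_state: str = "post_actinic"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.fvfm = np.asarray(self.fvfm, dtype=float)
        if np.any(self.times < 0):
            raise ValueError("times must be non-negative")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be non-decreasing")
        if not np.all(np.isfinite(self.fvfm)):
            raise ValueError("fvfm values must be finite")

    @property
    def initial_value(self) -> float:
        return float(self.fvfm[0])


@dataclass
class KineticFit:
    """Estimated rate constants with uncertainties and fit diagnostics."""

    k_pi: float
    a0: float
    se_k_pi: float
    residual_ss: float
    converged: bool
    flags: tuple = ()
    k_rec: float | None = None
    se_k_rec: float | None = None
    paired_replicate_id: str | None = None


def _series_arrays(series) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(series, FluorDecaySeries):
        return series.times, series.fvfm
    times, values = series
    return np.asarray(times, float), np.asarray(values, float)


def fit_photoinactivation(series) -> KineticFit:
    """Fit ``A0 exp(-k_PI t)`` to a +lincomycin decay series.

    ``series`` is a :class:`FluorDecaySeries` (must carry lincomycin=True) or
    a ``(times, values)`` pair.
    """
    if isinstance(series, FluorDecaySeries) and not series.lincomycin:
        raise ValueError("photoinactivation fits require a +lincomycin series")
    t, y = _series_arrays(series)
    est = PhotoinactivationFitter().fit(t, y)
    return KineticFit(
        k_pi=est.k_pi_, a0=est.a0_, se_k_pi=float(est.se_k_pi_),
        residual_ss=est.residual_ss_, converged=est.converged_,
        flags=est.flags_,
    )


def fit_repair(series, k_pi_fixed: float, co_fit_a0: bool = False,
               paired_replicate_id: str | None = None) -> KineticFit:
    """Fit ``k_REC`` with ``k_PI`` frozen, on a -lincomycin series."""
    if isinstance(series, FluorDecaySeries) and series.lincomycin:
        raise ValueError("repair fits require a -lincomycin series")
    t, y = _series_arrays(series)
    est = RepairFitter(k_pi=k_pi_fixed, co_fit_a0=co_fit_a0).fit(t, y)
    return KineticFit(
        k_pi=k_pi_fixed, a0=est.a0_, se_k_pi=0.0,
        residual_ss=est.residual_ss_, converged=est.converged_,
        flags=est.flags_, k_rec=est.k_rec_, se_k_rec=est.se_k_rec_,
        paired_replicate_id=paired_replicate_id,
    )


@dataclass
class PairedFitResult:
    """Per-replicate paired fits plus the group summary and rejects table."""

    fits: pd.DataFrame
    summary: pd.DataFrame
    rejects: pd.DataFrame


_DECAY_COLUMNS = ["replicate_id", "strain_id", "growth_light",
                  "lincomycin", "time_s", "fvfm"]


def pair_and_fit(decay: pd.DataFrame, co_fit_a0: bool = False) -> PairedFitResult:
    """Run the paired lincomycin-chase fits over a long-format decay table.

    For every (strain, growth light, replicate): fit k_PI on the +lincomycin
    series, then k_REC on the paired -lincomycin series with k_PI frozen.
    Unpaired series are reported in the rejects table, never silently dropped.
    """
    missing = [c for c in _DECAY_COLUMNS if c not in decay.columns]
    if missing:
        raise ValueError(f"decay table missing columns: {missing}")

    fit_rows, reject_rows = [], []
    grouped = decay.groupby(["strain_id", "growth_light", "replicate_id"],
                            sort=True)
    for (strain, light, rep), grp in grouped:
        plus = grp[grp["lincomycin"].astype(bool)].sort_values("time_s")
        minus = grp[~grp["lincomycin"].astype(bool)].sort_values("time_s")
        if plus.empty or minus.empty:
            missing_arm = "+lincomycin" if plus.empty else "-lincomycin"
            reject_rows.append({
                "strain_id": strain, "growth_light": light,
                "replicate_id": rep, "n_rows": len(grp),
                "reason": f"unpaired series: no {missing_arm} partner",
            })
            continue
        f_pi = fit_photoinactivation(
            (plus["time_s"].to_numpy(), plus["fvfm"].to_numpy()))
        f_rec = fit_repair(
            (minus["time_s"].to_numpy(), minus["fvfm"].to_numpy()),
            k_pi_fixed=f_pi.k_pi, co_fit_a0=co_fit_a0,
            paired_replicate_id=str(rep))
        fit_rows.append({
            "strain_id": strain, "growth_light": light, "replicate_id": rep,
            "k_pi": f_pi.k_pi, "se_k_pi": f_pi.se_k_pi, "a0_plus": f_pi.a0,
            "k_rec": f_rec.k_rec, "se_k_rec": f_rec.se_k_rec,
            "a0_minus": f_rec.a0,
            "converged": f_pi.converged and f_rec.converged,
            "flags": ";".join(f_pi.flags + f_rec.flags),
        })

    fits = pd.DataFrame(fit_rows, columns=[
        "strain_id", "growth_light", "replicate_id", "k_pi", "se_k_pi",
        "a0_plus", "k_rec", "se_k_rec", "a0_minus", "converged", "flags"])
    rejects = pd.DataFrame(reject_rows, columns=[
        "strain_id", "growth_light", "replicate_id", "n_rows", "reason"])

    if fits.empty:
        summary = pd.DataFrame(columns=[
            "strain_id", "growth_light", "k_pi_mean", "k_pi_sem",
            "k_rec_mean", "k_rec_sem", "n"])
    else:
        def sem(x):
            x = np.asarray(x, float)
            return float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else np.nan

        summary = (fits.groupby(["strain_id", "growth_light"])
                   .agg(k_pi_mean=("k_pi", "mean"), k_pi_sem=("k_pi", sem),
                        k_rec_mean=("k_rec", "mean"), k_rec_sem=("k_rec", sem),
                        n=("k_pi", "size"))
                   .reset_index())
    return PairedFitResult(fits=fits, summary=summary, rejects=rejects)
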