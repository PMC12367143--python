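"""Estimators turning simulated assay output into kinetic observables.

* :func:`woolf_hanes_fit` -- kcat and Km from initial-velocity points via
  the Woolf-Hanes linearisation ([S]/v against [S]; slope = 1/kcat,
  intercept = Km/kcat), with delta-method standard errors.
* :func:`fit_exponential` -- A(1 - exp(-B t)) fits for single-turnover
  time courses (B = k_tran or k_chem).
* :func:`detect_burst` -- pre-steady-state burst amplitude by
  extrapolating the late linear phase of a product time course back to
  t = 0; a burst traps roughly one product per catalytic site, so the
  flag fires at an amplitude of 0.5 per site or more.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["MMFit", "ExpFit", "BurstResult", "EstimatorError",
           "woolf_hanes_fit", "fit_exponential", "detect_burst"]


class EstimatorError(RuntimeError):
    """Raised when an estimator cannot produce a valid fit."""


@dataclass
class MMFit:
    """Michaelis-Menten parameters from a Woolf-Hanes linear fit."""

    kcat: float                # s^-1
    km: float                  # uM
    kcat_se: float
    km_se: float
    r_squared: float
    valid: bool = True
    diagnostics: str = ""


@dataclass
class ExpFit:
    """Parameters of y(t) = A (1 - exp(-B t))."""

    amplitude: float           # molecules (or uM)
    rate: float                # s^-1
    residual_norm: float


@dataclass
class BurstResult:
    amplitude: float           # product molecules extrapolated to t = 0
    amplitude_per_site: float
    burst: bool
    steady_rate: float         # s^-1 per enzyme


def _as_sv(points):
    """Extract (concentration, velocity) arrays from VelocityPoints or pairs."""
    s, v = [], []
    for p in points:
        if hasattr(p, "concentration"):
            s.append(p.concentration)
            v.append(float(p.velocity))
        else:
            s.append(p[0])
            v.append(float(p[1]))
    return np.asarray(s, float), np.asarray(v, float)


def woolf_hanes_fit(points) -> MMFit:
    """Ordinary least squares on ([S], [S]/v); kcat = 1/slope, Km =
    intercept/slope.

    Exact on noiseless Michaelis-Menten data.  Standard errors come from
    the regression covariance by the delta method.  A non-positive fitted
    slope or intercept marks the fit invalid (Km/kcat unidentifiable from
    the supplied grid).
    """
    s, v = _as_sv(points)
    keep = v > 0
    s, v = s[keep], v[keep]
    if len(s) < 3:
        raise EstimatorError("need at least 3 points with positive velocity")
    x = s
    y = s / v
    X = np.column_stack([x, np.ones_like(x)])
    beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    m, b = beta
    yhat = X @ beta
    rss = float(np.sum((y - yhat) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    # velocity noise is roughly multiplicative, so the Hanes residuals are
    # heteroscedastic; use the HC3 sandwich covariance for honest errors
    xtx_inv = np.linalg.inv(X.T @ X)
    h = np.einsum("ij,jk,ik->i", X, xtx_inv, X)
    u = (y - yhat) / np.clip(1.0 - h, 1e-3, None)
    cov = xtx_inv @ (X.T * u ** 2) @ X @ xtx_inv
    var_m, var_b, cov_mb = cov[0, 0], cov[1, 1], cov[0, 1]
    if m <= 0 or b < 0:
        return MMFit(np.nan, np.nan, np.nan, np.nan, r2, valid=False,
                     diagnostics=f"non-positive Hanes slope/intercept: m={m:.3g}, b={b:.3g}")
    kcat = 1.0 / m
    km = b / m
    kcat_se = np.sqrt(var_m) / m ** 2
    km_var = (var_b / m ** 2 + (b ** 2 / m ** 4) * var_m
              - 2.0 * (b / m ** 3) * cov_mb)
    km_se = np.sqrt(max(km_var, 0.0))
    return MMFit(float(kcat), float(km), float(kcat_se), float(km_se), float(r2))


def fit_exponential(times, values) -> ExpFit:
    """Nonlinear least squares for y(t) = A (1 - exp(-B t)).

    The start point is derived deterministically from the data: A0 is 5%
    above the maximum and B0 comes from the slope of -log(1 - y/A0).
    Bounded restarts perturb the start point if the first fit fails.
    """
    t = np.asarray(times, float)
    y = np.asarray(values, float)
    if len(t) < 5:
        raise EstimatorError("need at least 5 time points")
    ymax = float(y.max())
    if ymax <= 0:
        raise EstimatorError("degenerate input: no signal to fit")
    a0 = 1.05 * ymax
    frac = np.clip(y / a0, 0.0, 1.0 - 1e-12)
    mask = (t > 0) & (frac > 0)
    if mask.sum() >= 2:
        b0 = max(float(np.polyfit(t[mask], -np.log1p(-frac[mask]), 1)[0]), 1e-6)
    else:
        b0 = 1.0 / max(t[-1], 1e-9)

    def model(tt, a, b):
        return a * (1.0 - np.exp(-b * tt))

    last_err = None
    for fa, fb in ((1.0, 1.0), (1.0, 0.3), (1.0, 3.0), (1.5, 1.0)):
        try:
            popt, _ = curve_fit(model, t, y, p0=(a0 * fa, b0 * fb),
                                bounds=([0.0, 0.0], [np.inf, np.inf]),
                                maxfev=20000)
            a, b = popt
            if a > 0 and b > 0:
                resid = float(np.linalg.norm(y - model(t, a, b)))
                return ExpFit(float(a), float(b), resid)
        except Exception as exc:  # noqa: BLE001 - retried with new start
            last_err = exc
    raise EstimatorError(f"exponential fit did not converge: {last_err}")


def detect_burst(traj, enzyme_copies: int, sites: int = 1,
                 threshold: float = 0.5, tail: float = 0.5,
                 stability_tol: float = 0.1) -> BurstResult:
    """Burst amplitude from the late linear phase of a product trace.

    The final ``tail`` fraction of the samples must be in the steady
    linear phase: it is split into three windows whose slopes must agree
    to ``stability_tol`` relative (allowing for counting noise via the
    per-window slope standard error).  The burst amplitude is the t = 0
    intercept of the line fitted to that phase.
    """
    if hasattr(traj, "product"):
        t = np.asarray(traj.times, float)
        y = np.asarray(traj.product, float)
    else:
        t, y = (np.asarray(a, float) for a in traj)
    n = len(t)
    lo = int((1.0 - tail) * n)
    tw, yw = t[lo:], y[lo:]
    if len(tw) < 9:
        raise EstimatorError("too few samples in the candidate steady phase")
    thirds = np.array_split(np.arange(len(tw)), 3)
    slopes, ses = [], []
    for ix in thirds:
        coef = np.polyfit(tw[ix], yw[ix], 1)
        slopes.append(coef[0])
        # cumulative event counts have random-walk residuals, so the OLS
        # slope variance is meaningless; use the counting (Poisson) error
        # of the window increment instead
        dy = abs(yw[ix[-1]] - yw[ix[0]])
        dt = tw[ix[-1]] - tw[ix[0]]
        ses.append(np.sqrt(max(dy, 1.0)) / max(dt, 1e-12))
    slopes = np.asarray(slopes)
    mean_slope = slopes.mean()
    if mean_slope > 0:
        dev = np.abs(slopes - mean_slope)
        tol = np.maximum(stability_tol * abs(mean_slope), 3.0 * np.asarray(ses))
        if np.any(dev > tol):
            raise EstimatorError(
                f"steady phase not detected: late slopes {slopes} not stationary")
    slope, intercept = np.polyfit(tw, yw, 1)
    amplitude = max(float(intercept), 0.0)
    per_site = amplitude / (max(enzyme_copies, 1) * max(sites, 1))
    return BurstResult(amplitude, per_site, per_site >= threshold,
                       float(slope / max(enzyme_copies, 1)))
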