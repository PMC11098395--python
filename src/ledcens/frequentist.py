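"""Maximum-likelihood fitting and asymptotic intervals for the LED.

Point estimation maximizes the censored (or complete) log-likelihood by
damped Newton iteration on the unconstrained scale theta = (log nu,
log eta), using the analytic score and Hessian, with a small profile
grid for the starting point and a derivative-free simplex fallback.

Interval estimation follows standard large-sample theory: the inverse of
the observed information at the MLE estimates the covariance of
(nu_hat, eta_hat), parameter intervals are estimate +/- z * se, and
intervals for the survival and hazard functions S(t), h(t) propagate
that covariance through the delta method.  Following the convention of
the reference tables, intervals are not truncated to natural ranges
unless requested (an S(t) upper bound may exceed 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .distribution import LEDParams, led_hrf, led_sf, log_psi
from .likelihood import (CaseQuantities, _as_quantities, hessian_logscale,
                         log_likelihood, loglik_logscale, observed_information,
                         score, score_logscale)

__all__ = [
    "FitResult",
    "IntervalEstimate",
    "fit_mle",
    "plugin_reliability",
    "aci_params",
    "delta_ci_reliability",
    "reliability_gradients",
]


@dataclass(frozen=True)
class IntervalEstimate:
    """A two-sided interval estimate with its construction label."""

    lower: float
    upper: float
    level: float
    method: str

    def __post_init__(self) -> None:
        if not (0 < self.level < 1):
            raise ValueError("level must lie in (0, 1)")
        if self.lower > self.upper:
            raise ValueError("lower must not exceed upper")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit of the LED to one (possibly censored) sample."""

    estimates: LEDParams
    loglik: float
    info: np.ndarray          # observed information at the MLE
    vcov: np.ndarray          # its inverse
    se: np.ndarray            # sqrt of vcov diagonal: (se_nu, se_eta)
    converged: bool
    iterations: int
    score_norm: float
    n_obs: int

    def to_dict(self) -> dict:
        return {
            "nu": self.estimates.nu, "eta": self.estimates.eta,
            "loglik": self.loglik, "se_nu": float(self.se[0]),
            "se_eta": float(self.se[1]), "converged": self.converged,
            "iterations": self.iterations,
        }


class FitError(RuntimeError):
    """Raised when no optimizer start converges to a proper maximum."""


def _start_points(q: CaseQuantities) -> list[np.ndarray]:
    """Crude profile-grid starts on the (log nu, log eta) scale."""
    x = q.x
    med = float(np.median(x))
    nu0 = np.log(np.log(2.0) / med)  # matches the model median ln2/nu at eta = 1
    starts = [np.array([nu0, 0.0])]
    for log_eta in (-1.0, 1.0):
        starts.append(np.array([nu0, log_eta]))
    starts.append(np.array([np.log(1.0 / max(np.mean(x), 1e-12)), 0.0]))
    return starts


def _newton(theta0: np.ndarray, q: CaseQuantities, tol: float, max_iter: int):
    """Damped Newton ascent on the log-parameter scale."""
    theta = theta0.copy()
    ll = loglik_logscale(theta, q)
    if not np.isfinite(ll):
        return theta, ll, False, 0
    it = 0
    for it in range(1, max_iter + 1):
        g = score_logscale(theta, q)
        if np.max(np.abs(g)) < tol * (1.0 + abs(ll)):
            return theta, ll, True, it
        H = hessian_logscale(theta, q)
        try:
            step = np.linalg.solve(H, -g)
        except np.linalg.LinAlgError:
            step = g  # gradient ascent fallback
        if not np.all(np.isfinite(step)):
            step = g
        # ensure ascent direction; fall back to the gradient if not
        if np.dot(step, g) <= 0:
            step = g
        # cap the log-scale step so the line search stays in range
        norm = np.max(np.abs(step))
        if norm > 5.0:
            step = step * (5.0 / norm)
        lam = 1.0
        for _ in range(40):
            cand = theta + lam * step
            ll_new = loglik_logscale(cand, q)
            if np.isfinite(ll_new) and ll_new > ll - 1e-12:
                theta, ll = cand, ll_new
                break
            lam *= 0.5
        else:
            return theta, ll, False, it
    g = score_logscale(theta, q)
    return theta, ll, bool(np.max(np.abs(g)) < tol * (1.0 + abs(ll))), it


def fit_mle(sample, tol: float = 1e-8, max_iter: int = 200) -> FitResult:
    """Fit the LED to an IAT-II PCS sample or a complete data vector.

    Raises :class:`FitError` if no start (Newton, then Nelder-Mead
    refinement) reaches a point with small score and positive-definite
    observed information.
    """
    q = _as_quantities(sample)
    if len(np.unique(q.x)) < 2:
        raise FitError("need at least 2 distinct failure times")

    best = None
    total_iter = 0
    for theta0 in _start_points(q):
        theta, ll, ok, it = _newton(theta0, q, tol, max_iter)
        total_iter += it
        if np.isfinite(ll) and (best is None or ll > best[1] + 1e-12 or
                                (ok and not best[2] and ll >= best[1] - 1e-9)):
            best = (theta, ll, ok)
    theta, ll, ok = best
    if not ok:
        # simplex fallback from the best point found, then a final Newton polish
        res = optimize.minimize(lambda t: -loglik_logscale(t, q), theta,
                                method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 4000})
        total_iter += res.nit
        theta2, ll2, ok, it = _newton(res.x, q, tol, max_iter)
        total_iter += it
        if ll2 >= ll:
            theta, ll = theta2, ll2

    params = LEDParams(*np.exp(theta))
    g = score(params, q)
    info = observed_information(params, q)
    score_norm = float(np.max(np.abs(g)))
    converged = bool(ok and np.all(np.linalg.eigvalsh(info) > 0))
    if not converged:
        raise FitError(
            f"optimization failed: score_norm={score_norm:.3g}, "
            f"information eigenvalues={np.linalg.eigvalsh(info)}")
    vcov = np.linalg.inv(info)
    return FitResult(estimates=params, loglik=float(ll), info=info, vcov=vcov,
                     se=np.sqrt(np.diag(vcov)), converged=converged,
                     iterations=total_iter, score_norm=score_norm, n_obs=q.E2)


def plugin_reliability(fit: FitResult, t: float) -> tuple[float, float]:
    """Plug-in ML estimates (S_hat(t), h_hat(t)) by MLE invariance."""
    if not fit.converged:
        raise ValueError("fit did not converge")
    if t <= 0:
        raise ValueError("t must be > 0")
    return float(led_sf(t, fit.estimates)), float(led_hrf(t, fit.estimates))


def aci_params(fit: FitResult, level: float = 0.95,
               truncate: bool = False) -> tuple[IntervalEstimate, IntervalEstimate]:
    """Normal-theory confidence intervals for (nu, eta).

    Symmetric about the MLE; lower bounds may be negative unless
    ``truncate`` clips them at zero.
    """
    if not fit.converged:
        raise ValueError("fit did not converge")
    z = stats.norm.ppf(0.5 + level / 2.0)
    out = []
    for est, se in zip(fit.estimates.as_tuple(), fit.se):
        lo, hi = est - z * se, est + z * se
        if truncate:
            lo = max(lo, 0.0)
        out.append(IntervalEstimate(float(lo), float(hi), level, "ACI"))
    return tuple(out)


def reliability_gradients(params, t: float) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of S(t) and h(t) in (nu, eta), evaluated analytically.

    Used by the delta method; both are exact derivatives of the survival
    and hazard formulas (verified against numerical differentiation in
    the test suite).
    """
    p = params if isinstance(params, LEDParams) else LEDParams(*params)
    nu, eta = p.nu, p.eta
    lp = float(log_psi(t, nu))
    la = float(np.logaddexp(0.0, eta * lp))
    u = np.exp(eta * lp - la)          # Psi^eta/(1+Psi^eta)
    ela = np.exp(-la)                  # = S(t)
    g = t / (-np.expm1(-nu * t))       # t e^{nu t}/Psi
    dS_dnu = -ela * eta * u * g
    dS_deta = -ela * u * lp
    h = float(led_hrf(t, p))
    dh_dnu = h * (1.0 / nu + t + (eta - 1.0) * g - eta * u * g)
    dh_deta = h * (1.0 / eta + lp * ela)
    return np.array([dS_dnu, dS_deta]), np.array([dh_dnu, dh_deta])


def delta_ci_reliability(fit: FitResult, t: float, level: float = 0.95,
                         truncate: bool = False
                         ) -> tuple[IntervalEstimate, IntervalEstimate]:
    """Delta-method confidence intervals for S(t) and h(t).

    var(S_hat) = G1' V G1 and var(h_hat) = G2' V G2 with V the inverse
    observed information and G1, G2 the reliability gradients at the MLE.
    """
    if not fit.converged:
        raise ValueError("fit did not converge")
    if t <= 0:
        raise ValueError("t must be > 0")
    z = stats.norm.ppf(0.5 + level / 2.0)
    S_hat, h_hat = plugin_reliability(fit, t)
    G1, G2 = reliability_gradients(fit.estimates, t)
    sd_S = float(np.sqrt(G1 @ fit.vcov @ G1))
    sd_h = float(np.sqrt(G2 @ fit.vcov @ G2))
    lo_S, hi_S = S_hat - z * sd_S, S_hat + z * sd_S
    lo_h, hi_h = h_hat - z * sd_h, h_hat + z * sd_h
    if truncate:
        lo_S, hi_S = max(lo_S, 0.0), min(hi_S, 1.0)
        lo_h = max(lo_h, 0.0)
    return (IntervalEstimate(float(lo_S), float(hi_S), level, "delta-ACI"),
            IntervalEstimate(float(lo_h), float(hi_h), level, "delta-ACI"))


def reliability_se(fit: FitResult, t: float) -> tuple[float, float]:
    """Delta-method standard errors of (S_hat(t), h_hat(t))."""
    G1, G2 = reliability_gradients(fit.estimates, t)
    return (float(np.sqrt(G1 @ fit.vcov @ G1)),
            float(np.sqrt(G2 @ fit.vcov @ G2)))
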