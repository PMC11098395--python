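"""Log-likelihood, score and observed information for the LED under IAT-II PCS.

With Psi_i = e^{nu x_i} - 1 the log-likelihood of an observed sample
(dropping the parameter-free combinatorial constant) is

    l(nu, eta) = E2 log(nu eta)
               + sum_{i<=E2} [(eta-1) log Psi_i + nu x_i - 2 log(1+Psi_i^eta)]
               - sum_i R_i log(1+Psi_i^eta)            (executed removals)
               - B log(1+Psi_{T*}^eta),                (terminal withdrawal)

where the last term covers all three cases at once: B = 0 in case I, the
anchor T* is the m-th failure in case II and the hard-stop time T2 in
case III.  The score and the (negated) Hessian are implemented from the
closed-form derivatives of this expression; every power of Psi goes
through the same log-space kernel as the distribution code.

A log-parameter variant (theta = (log nu, log eta)) with chain-rule
gradient and Hessian is provided for unconstrained optimization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .censoring import IATIIPCSSample
from .distribution import LEDParams, log_psi

__all__ = [
    "CaseQuantities",
    "log_likelihood",
    "score",
    "observed_information",
    "loglik_logscale",
    "score_logscale",
    "hessian_logscale",
]


@dataclass(frozen=True)
class CaseQuantities:
    """Extracted view of a censored sample, as the likelihood consumes it.

    ``removals`` aligns with ``x`` (zeros after the adaptation point);
    ``anchor`` is the stopping time T* carrying the terminal-withdrawal
    survival weight ``B``.
    """

    x: np.ndarray
    removals: np.ndarray
    B: int
    anchor: float
    E1: int
    case: str

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        rem = np.asarray(self.removals, dtype=float)
        if len(x) == 0:
            raise ValueError("empty sample")
        if len(rem) != len(x):
            raise ValueError("removals must align with x")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "removals", rem)

    @property
    def E2(self) -> int:
        return len(self.x)

    @classmethod
    def from_sample(cls, sample: IATIIPCSSample) -> "CaseQuantities":
        return cls(x=sample.x, removals=sample.applied_removals, B=sample.B,
                   anchor=float(sample.Tstar), E1=sample.E1, case=sample.case)

    @classmethod
    def from_complete(cls, data) -> "CaseQuantities":
        """Complete i.i.d. data: no removals, no terminal withdrawal."""
        x = np.sort(np.asarray(data, dtype=float))
        return cls(x=x, removals=np.zeros(len(x)), B=0, anchor=float(x[-1]),
                   E1=len(x), case="I")


def _as_quantities(sample) -> CaseQuantities:
    if isinstance(sample, CaseQuantities):
        return sample
    if isinstance(sample, IATIIPCSSample):
        return CaseQuantities.from_sample(sample)
    return CaseQuantities.from_complete(np.asarray(sample, dtype=float))


def _params(params) -> tuple[float, float]:
    if isinstance(params, LEDParams):
        return params.nu, params.eta
    nu, eta = float(params[0]), float(params[1])
    if nu <= 0 or eta <= 0 or not np.isfinite(nu) or not np.isfinite(eta):
        raise ValueError("parameters must be finite and positive")
    return nu, eta


def _kernel(nu: float, eta: float, q: CaseQuantities):
    """Shared per-point quantities for loglik/score/information.

    Returns arrays over the E2 observed failures plus the anchor point
    appended last, with the weight vector (2 + R_i for observations,
    B for the anchor) used by the censoring terms.
    """
    x = np.append(q.x, q.anchor)
    lp = log_psi(x, nu)                    # log Psi
    la = np.logaddexp(0.0, eta * lp)       # log(1 + Psi^eta)
    u = np.exp(eta * lp - la)              # Psi^eta / (1 + Psi^eta)
    # g = x e^{nu x} / Psi  (d/dnu of log Psi), stable for nu*x small/large
    g = x / (-np.expm1(-nu * x))
    return x, lp, la, u, g


def log_likelihood(params, sample) -> float:
    """IAT-II PCS log-likelihood of the LED, additive constant omitted."""
    nu, eta = _params(params)
    q = _as_quantities(sample)
    x, lp, la, u, g = _kernel(nu, eta, q)
    obs = slice(0, q.E2)
    ll = q.E2 * np.log(nu * eta)
    ll += np.sum((eta - 1.0) * lp[obs] + nu * x[obs] - 2.0 * la[obs])
    ll -= np.sum(q.removals * la[obs])
    ll -= q.B * la[-1]
    return float(ll)


def score(params, sample) -> np.ndarray:
    """Gradient (d/dnu, d/deta) of the log-likelihood."""
    nu, eta = _params(params)
    q = _as_quantities(sample)
    x, lp, la, u, g = _kernel(nu, eta, q)
    w = np.append(2.0 + q.removals, float(q.B))  # survival-term weights
    obs = slice(0, q.E2)
    d_nu = (q.E2 / nu
            + (eta - 1.0) * np.sum(g[obs])
            + np.sum(x[obs])
            - eta * np.sum(w * u * g))
    d_eta = (q.E2 / eta
             + np.sum(lp[obs])
             - np.sum(w * u * lp))
    return np.array([d_nu, d_eta])


def observed_information(params, sample) -> np.ndarray:
    """Negated Hessian of the log-likelihood (symmetric 2x2)."""
    nu, eta = _params(params)
    q = _as_quantities(sample)
    x, lp, la, u, g = _kernel(nu, eta, q)
    w = np.append(2.0 + q.removals, float(q.B))
    obs = slice(0, q.E2)
    enx = np.exp(-nu * x)          # e^{-nu x}
    ela = np.exp(-la)              # 1/(1 + Psi^eta)
    # z = d/dnu [ u g ] = g^2 u (eta/(1+Psi^eta) - e^{-nu x}); every factor bounded
    z = g * g * u * (eta * ela - enx)
    d2_nunu = (-q.E2 / nu ** 2
               - (eta - 1.0) * np.sum(g[obs] ** 2 * enx[obs])
               - eta * np.sum(w * z))
    # d/deta [ eta u g ] = g u (1 + eta lp / (1+Psi^eta))
    d2_nueta = np.sum(g[obs]) - np.sum(w * g * u * (1.0 + eta * lp * ela))
    d2_etaeta = (-q.E2 / eta ** 2
                 - np.sum(w * u * ela * lp ** 2))
    H = np.array([[d2_nunu, d2_nueta], [d2_nueta, d2_etaeta]])
    return -H


# -- log-parameter scale (unconstrained optimization) ----------------------

def loglik_logscale(theta, sample) -> float:
    """Log-likelihood at theta = (log nu, log eta); -inf off the usable range."""
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)) or np.any(np.abs(theta) > 300):
        return -np.inf
    return log_likelihood(np.exp(theta), sample)


def score_logscale(theta, sample) -> np.ndarray:
    p = np.exp(np.asarray(theta, dtype=float))
    return score(p, sample) * p


def hessian_logscale(theta, sample) -> np.ndarray:
    """Hessian of the log-likelihood in theta = (log nu, log eta)."""
    p = np.exp(np.asarray(theta, dtype=float))
    s = score(p, sample)
    H = -observed_information(p, sample)
    return H * np.outer(p, p) + np.diag(s * p)
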