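"""The logistic-exponential lifetime distribution.

A positive random variable X follows the logistic-exponential law
LED(nu, eta) when

    S(x) = P(X > x) = 1 / (1 + (e^{nu x} - 1)^eta),   x >= 0,

with rate parameter ``nu > 0`` (per unit time) and dimensionless shape
``eta > 0``.  The family reduces to the exponential law with rate ``nu``
at ``eta = 1`` and, depending on ``eta`` and ``nu``, exhibits constant,
increasing, decreasing, bathtub and upside-down-bathtub hazard rates,
which makes it a convenient model for repairable-equipment failure
intervals and similar reliability data.

All evaluations route powers of ``Psi(x) = e^{nu x} - 1`` through
log-space, ``log Psi = nu x + log1p(-e^{-nu x})``, so that densities and
hazards stay finite up to ``nu x`` of several hundred and remain accurate
for ``nu x`` near zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LEDParams",
    "led_pdf",
    "led_logpdf",
    "led_cdf",
    "led_sf",
    "led_hrf",
    "led_quantile",
    "led_rng",
]


@dataclass(frozen=True)
class LEDParams:
    """Parameter pair of the logistic-exponential distribution.

    Attributes
    ----------
    nu : float
        Rate-like parameter, per unit time; strictly positive.
    eta : float
        Dimensionless shape parameter; strictly positive.
    """

    nu: float
    eta: float

    def __post_init__(self) -> None:
        nu, eta = float(self.nu), float(self.eta)
        if not (np.isfinite(nu) and nu > 0):
            raise ValueError(f"nu must be finite and > 0, got {self.nu!r}")
        if not (np.isfinite(eta) and eta > 0):
            raise ValueError(f"eta must be finite and > 0, got {self.eta!r}")
        object.__setattr__(self, "nu", nu)
        object.__setattr__(self, "eta", eta)

    def as_tuple(self) -> tuple[float, float]:
        return (self.nu, self.eta)


def _params(params) -> tuple[float, float]:
    if isinstance(params, LEDParams):
        return params.nu, params.eta
    nu, eta = params
    return LEDParams(nu, eta).as_tuple()


def log_psi(x, nu: float):
    """log(e^{nu x} - 1), computed without overflow or cancellation.

    Written as nu x + log(1 - e^{-nu x}); the inner factor goes through
    expm1 so the result stays accurate down to nu x ~ 1e-300.
    """
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        return nu * x + np.log(-np.expm1(-nu * x))


def led_logpdf(x, params):
    """Log-density of LED(nu, eta); -inf where the density vanishes."""
    nu, eta = _params(params)
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be >= 0")
    lp = log_psi(x, nu)
    # log(1 + Psi^eta), stable for Psi^eta large or tiny
    la = np.logaddexp(0.0, eta * lp)
    with np.errstate(invalid="ignore"):
        out = np.log(nu * eta) + nu * x + (eta - 1.0) * lp - 2.0 * la
    # x == 0 limits: 0 for eta > 1, nu for eta == 1, +inf for eta < 1
    if np.any(x == 0):
        if eta > 1:
            lim = -np.inf
        elif eta == 1:
            lim = np.log(nu)
        else:
            lim = np.inf
        out = np.where(x == 0, lim, out)
    return out[()] if out.ndim == 0 else out


def led_pdf(x, params):
    """Density of LED(nu, eta) at x >= 0 (per unit time)."""
    return np.exp(led_logpdf(x, params))


def led_cdf(x, params):
    """Distribution function P(X <= x); 0 at x = 0."""
    nu, eta = _params(params)
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be >= 0")
    la = np.logaddexp(0.0, eta * log_psi(x, nu))
    out = -np.expm1(-la)
    out = np.where(x == 0, 0.0, out)
    return out[()] if out.ndim == 0 else out


def led_sf(x, params):
    """Survival function P(X > x) = 1/(1 + Psi^eta); 1 at x = 0."""
    nu, eta = _params(params)
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be >= 0")
    la = np.logaddexp(0.0, eta * log_psi(x, nu))
    out = np.where(x == 0, 1.0, np.exp(-la))
    return out[()] if out.ndim == 0 else out


def led_hrf(t, params):
    """Hazard rate h(t) = f(t)/S(t) = nu eta e^{nu t} Psi^{eta-1}/(1 + Psi^eta).

    At t = 0 the limit is 0 for eta > 1, nu for eta = 1 and +inf for
    eta < 1 (the density formula is stated for t > 0 only).
    """
    nu, eta = _params(params)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    lp = log_psi(t, nu)
    la = np.logaddexp(0.0, eta * lp)
    with np.errstate(invalid="ignore"):
        out = np.exp(np.log(nu * eta) + nu * t + (eta - 1.0) * lp - la)
    if np.any(t == 0):
        lim = 0.0 if eta > 1 else (nu if eta == 1 else np.inf)
        out = np.where(t == 0, lim, out)
    return out[()] if out.ndim == 0 else out


def led_quantile(u, params):
    """Inverse CDF: x(u) = (1/nu) log(1 + (u/(1-u))^{1/eta}) for u in (0,1)."""
    nu, eta = _params(params)
    u = np.asarray(u, dtype=float)
    if np.any((u <= 0) | (u >= 1)):
        raise ValueError("u must lie strictly inside (0, 1)")
    # (u/(1-u))^{1/eta} through logs; log(u/(1-u)) = log(u) - log1p(-u)
    lodds = np.log(u) - np.log1p(-u)
    out = np.log1p(np.exp(lodds / eta)) / nu
    return out[()] if out.ndim == 0 else out


def led_rng(n: int, params, seed=None):
    """Draw ``n`` i.i.d. LED(nu, eta) lifetimes by inverse-transform sampling.

    ``seed`` may be an int, a Generator or None; results are reproducible
    for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.random(int(n))
    # guard the (measure-zero) endpoints of the uniform draw
    u = np.clip(u, np.finfo(float).tiny, 1.0 - np.finfo(float).epsneg)
    return led_quantile(u, params)
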