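"""Bayesian inference for the LED under IAT-II PCS via Metropolis-Hastings.

Independent gamma priors nu ~ Gamma(a1, b1), eta ~ Gamma(a2, b2) (shape/
rate) multiply the censored likelihood; the posterior is explored by a
componentwise random-walk Metropolis-Hastings sampler: each coordinate
is proposed from a normal centred at its current value (default proposal
standard deviations taken from the asymptotic covariance of the MLE,
which also supplies the initial point), and accepted with probability
min(1, posterior ratio).  Proposals outside the positive support are
rejected outright.  The acceptance ratio always uses the full joint
posterior, which is the mathematically correct target and subsumes the
single-coordinate conditionals.

Point estimation supports squared-error loss (posterior mean) and the
asymmetric LINEX loss with parameter p, whose Bayes estimator is
-(1/p) log E[exp(-p theta)]; credible intervals are equal-tailed
percentile intervals of the sorted post-burn-in draws or, alternatively,
the shortest window containing the required fraction of ordered draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .distribution import LEDParams
from .frequentist import FitError, FitResult, IntervalEstimate, fit_mle
from .likelihood import _as_quantities, log_likelihood

__all__ = [
    "PriorSpec",
    "MCMCConfig",
    "LossSpec",
    "PosteriorDraws",
    "log_posterior",
    "run_mh",
    "bayes_point_estimates",
    "credible_interval",
    "posterior_summary",
]

QUANTITIES = ("nu", "eta", "S", "h")


@dataclass(frozen=True)
class PriorSpec:
    """Gamma shape/rate hyperparameters for the two LED parameters."""

    a1: float = 0.001
    b1: float = 0.001
    a2: float = 0.001
    b2: float = 0.001

    def __post_init__(self) -> None:
        if min(self.a1, self.b1, self.a2, self.b2) <= 0:
            raise ValueError("all hyperparameters must be > 0")

    @classmethod
    def diffuse(cls) -> "PriorSpec":
        return cls(0.001, 0.001, 0.001, 0.001)

    @classmethod
    def from_mean_var(cls, mean_nu: float, mean_eta: float,
                      var: float = 0.5) -> "PriorSpec":
        """Gamma priors with the given means and common variance."""
        return cls(a1=mean_nu ** 2 / var, b1=mean_nu / var,
                   a2=mean_eta ** 2 / var, b2=mean_eta / var)


@dataclass(frozen=True)
class MCMCConfig:
    """Chain length P, burn-in Q, seed, proposal scales and S/h time point."""

    P: int = 10_000
    Q: int = 1_000
    seed: int | None = None
    proposal_sd: tuple[float, float] | None = None
    t_eval: float = 0.25

    def __post_init__(self) -> None:
        if not (0 <= self.Q < self.P):
            raise ValueError("need 0 <= Q < P")
        if self.t_eval <= 0:
            raise ValueError("t_eval must be > 0")


@dataclass(frozen=True)
class LossSpec:
    """SELF (squared error) or LINEX loss with asymmetry p != 0."""

    kind: str = "SELF"
    p: float = 0.0

    def __post_init__(self) -> None:
        kind = self.kind.upper()
        object.__setattr__(self, "kind", kind)
        if kind not in ("SELF", "LINEX"):
            raise ValueError("kind must be SELF or LINEX")
        if kind == "LINEX" and self.p == 0:
            raise ValueError("LINEX requires p != 0")


@dataclass
class PosteriorDraws:
    """MCMC chains for (nu, eta) and the induced S(t), h(t) at t_eval."""

    nu: np.ndarray
    eta: np.ndarray
    S: np.ndarray
    h: np.ndarray
    Q: int
    t_eval: float
    accept_rate: tuple[float, float] = field(default=(np.nan, np.nan))

    def post_burn(self, name: str) -> np.ndarray:
        return getattr(self, name)[self.Q:]

    @property
    def P(self) -> int:
        return len(self.nu)


def log_posterior(params, sample, prior: PriorSpec) -> float:
    """Unnormalized log posterior: censored log-likelihood + gamma log-priors."""
    p = params if isinstance(params, LEDParams) else LEDParams(*params)
    ll = log_likelihood(p, sample)
    lp = ((prior.a1 - 1.0) * np.log(p.nu) - prior.b1 * p.nu
          + (prior.a2 - 1.0) * np.log(p.eta) - prior.b2 * p.eta)
    return float(ll + lp)


def reliability_chains(nu: np.ndarray, eta: np.ndarray, t: float):
    """Vectorized S(t), h(t) along parameter chains (same math as led_sf/led_hrf)."""
    lp = nu * t + np.log(-np.expm1(-nu * t))
    la = np.logaddexp(0.0, eta * lp)
    S = np.exp(-la)
    h = np.exp(np.log(nu * eta) + nu * t + (eta - 1.0) * lp - la)
    return S, h


def _log_posterior_raw(nu: float, eta: float, sample, prior: PriorSpec) -> float:
    if nu <= 0 or eta <= 0:
        return -np.inf
    return log_posterior((nu, eta), sample, prior)


def run_mh(sample, prior: PriorSpec | None = None,
           config: MCMCConfig | None = None,
           fit: FitResult | None = None) -> PosteriorDraws:
    """Componentwise random-walk Metropolis-Hastings on the joint posterior.

    The MLE fit (computed here unless supplied) provides the initial
    point and, through its standard errors, the default proposal scales.
    If the fit fails the chain starts from the prior means with unit
    proposal scales, with a warning.
    """
    prior = prior or PriorSpec.diffuse()
    config = config or MCMCConfig()
    q = _as_quantities(sample)
    if fit is None:
        try:
            fit = fit_mle(q)
        except FitError as exc:
            warnings.warn(f"MLE unavailable ({exc}); starting from prior means")
            fit = None
    if fit is not None:
        cur = np.array(fit.estimates.as_tuple())
        prop_sd = np.asarray(config.proposal_sd or fit.se, dtype=float)
    else:
        cur = np.array([prior.a1 / prior.b1, prior.a2 / prior.b2])
        prop_sd = np.asarray(config.proposal_sd or (1.0, 1.0), dtype=float)

    rng = np.random.default_rng(config.seed)
    P = config.P
    chain = np.empty((P, 2))
    lp_cur = _log_posterior_raw(cur[0], cur[1], q, prior)
    accepted = np.zeros(2, dtype=int)
    for k in range(P):
        # fixed interleaved order: nu move then eta move, one uniform each
        for c in range(2):
            prop = cur.copy()
            prop[c] = rng.normal(cur[c], prop_sd[c])
            # off-support proposals have posterior zero and are auto-rejected
            lp_prop = _log_posterior_raw(prop[0], prop[1], q, prior)
            if np.log(rng.random()) <= lp_prop - lp_cur:
                cur, lp_cur = prop, lp_prop
                accepted[c] += 1
        chain[k] = cur
    nu_c, eta_c = chain[:, 0], chain[:, 1]
    t = config.t_eval
    # S and h chains are deterministic transforms of the parameter draws
    S_c, h_c = reliability_chains(nu_c, eta_c, t)
    return PosteriorDraws(nu=nu_c, eta=eta_c, S=S_c, h=h_c, Q=config.Q,
                          t_eval=t, accept_rate=tuple(accepted / P))


def _point_estimate(draws: np.ndarray, loss: LossSpec) -> float:
    if draws.std() == 0 and len(draws) > 1:
        # degenerate chain: both losses return the constant
        return float(draws[0])
    if loss.kind == "SELF":
        return float(draws.mean())
    p = loss.p
    # -(1/p) log mean exp(-p theta), evaluated via a shifted log-sum-exp
    a = -p * draws
    amax = a.max()
    return float(-(amax + np.log(np.mean(np.exp(a - amax)))) / p)


def bayes_point_estimates(draws: PosteriorDraws,
                          loss: LossSpec = LossSpec("SELF")) -> dict:
    """Bayes point estimates of nu, eta, S(t), h(t) under the given loss."""
    if draws.P - draws.Q < 100:
        raise ValueError("need at least 100 post-burn-in draws")
    out = {}
    for name in QUANTITIES:
        chain = draws.post_burn(name)
        if np.ptp(chain) == 0:
            warnings.warn(f"degenerate {name} chain (zero variance)")
        out[name] = _point_estimate(chain, loss)
    return out


def credible_interval(draws: PosteriorDraws, level: float = 0.95,
                      method: str = "percentile") -> dict:
    """Equal-tailed percentile or shortest credible interval per quantity.

    The percentile construction orders the post-burn-in draws and reads
    off the xi/2 and 1 - xi/2 order statistics; the shortest construction
    scans for the minimal-width window containing a fraction (1 - xi) of
    consecutive ordered draws.  Both contain the posterior median.
    """
    if not (0 < level < 1):
        raise ValueError("level must lie in (0, 1)")
    if method not in ("percentile", "shortest"):
        raise ValueError("method must be 'percentile' or 'shortest'")
    xi = 1.0 - level
    out = {}
    for name in QUANTITIES:
        srt = np.sort(draws.post_burn(name))
        N = len(srt)
        if method == "percentile":
            lo_idx = min(max(int(np.floor(N * xi / 2.0)), 0), N - 1)
            hi_idx = min(max(int(np.ceil(N * (1.0 - xi / 2.0))) - 1, 0), N - 1)
            lo, hi = srt[lo_idx], srt[hi_idx]
            label = "percentile-credible"
        else:
            k = max(int(np.ceil((1.0 - xi) * N)), 1)
            widths = srt[k - 1:] - srt[:N - k + 1]
            j = int(np.argmin(widths))
            lo, hi = srt[j], srt[j + k - 1]
            label = "shortest-credible"
        out[name] = IntervalEstimate(float(lo), float(hi), level, label)
    return out


def posterior_summary(draws: PosteriorDraws, linex_p: float = 0.5,
                      level: float = 0.95) -> dict:
    """Point estimates (SELF and LINEX), posterior sds and intervals."""
    self_est = bayes_point_estimates(draws, LossSpec("SELF"))
    linex_est = bayes_point_estimates(draws, LossSpec("LINEX", linex_p))
    intervals = credible_interval(draws, level, "percentile")
    sds = {name: float(draws.post_burn(name).std(ddof=1)) for name in QUANTITIES}
    return {
        "self": self_est, "linex": linex_est, "posterior_sd": sds,
        "intervals": {k: (v.lower, v.upper) for k, v in intervals.items()},
        "accept_rate": draws.accept_rate,
    }
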