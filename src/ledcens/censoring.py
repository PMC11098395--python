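"""Improved adaptive Type-II progressive censoring (IAT-II PCS).

A life test starts with ``n`` units, a target failure count ``m`` and a
removal plan ``R = (R_1, ..., R_m)`` with ``sum(R) = n - m``: at the i-th
observed failure, ``R_i`` surviving units are withdrawn.  Two thresholds
``T1 < T2`` make the design adaptive:

* once ``T1`` has passed, intermediate withdrawals are suspended (so the
  target of ``m`` failures is reached faster);
* the test hard-stops at ``T2``.

Writing ``X_m`` for the m-th failure time, an experiment ends in one of
three observable cases:

* **Case I** (``X_m < T1``): an ordinary progressive Type-II sample; all
  planned removals executed, nothing left to withdraw at the end.
* **Case II** (``T1 < X_m < T2``): removals executed only at failures
  before ``T1``; the ``B`` survivors remaining at ``X_m`` are withdrawn
  then.
* **Case III** (``X_m > T2``): the test stops at ``T2`` having observed
  only ``k2 < m`` failures; the ``B`` survivors are withdrawn at ``T2``.

The bookkeeping quantities are ``E1``/``E2`` (failures strictly before
``T1`` / before the stopping time), ``B`` (terminal withdrawal count) and
``Tstar`` (stopping time, ``min(X_m, T2)``), and every sample satisfies
the accounting identity ``E2 + sum(applied removals) + B = n``.

Failure counts relative to a threshold use strict inequality: a failure
time exactly equal to ``T1`` or ``T2`` counts as NOT before it (ties have
probability zero under a continuous law).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .distribution import LEDParams, led_quantile, led_sf

__all__ = [
    "CensoringScheme",
    "IATIIPCSSample",
    "make_scheme_I",
    "make_scheme_II",
    "make_scheme_III",
    "parse_removals",
    "format_removals",
    "classify_sample",
    "simulate_iatii",
    "censor_complete_data",
    "complete_scheme",
]


def parse_removals(spec, m: int | None = None) -> tuple[int, ...]:
    """Parse a removal plan given as a sequence or run-length shorthand.

    The shorthand ``"4*2, 0*10, 4*2"`` means "4 repeated twice, 0
    repeated ten times, 4 repeated twice".  A bare integer token counts
    once.
    """
    if isinstance(spec, str):
        out: list[int] = []
        for token in re.split(r"[,\s]+", spec.strip()):
            if not token:
                continue
            if "*" in token:
                value, count = token.split("*")
                out.extend([int(value)] * int(count))
            else:
                out.append(int(token))
        R = tuple(out)
    else:
        R = tuple(int(r) for r in spec)
    if m is not None and len(R) != m:
        raise ValueError(f"removal plan has length {len(R)}, expected m={m}")
    return R


def format_removals(R) -> str:
    """Run-length shorthand for a removal plan (inverse of parse_removals)."""
    parts = []
    R = list(R)
    i = 0
    while i < len(R):
        j = i
        while j < len(R) and R[j] == R[i]:
            j += 1
        parts.append(f"{R[i]}*{j - i}" if j - i > 1 else f"{R[i]}")
        i = j
    return ",".join(parts)


@dataclass(frozen=True)
class CensoringScheme:
    """Design of an IAT-II progressively censored experiment."""

    n: int
    m: int
    R: tuple[int, ...]
    T1: float
    T2: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "R", parse_removals(self.R))
        n, m, R = self.n, self.m, self.R
        if not (isinstance(n, (int, np.integer)) and n >= 2):
            raise ValueError("n must be an integer >= 2")
        # m == n (with R identically zero) is the degenerate no-censoring design
        if not (1 <= m <= n):
            raise ValueError("m must satisfy 1 <= m <= n")
        if len(R) != m:
            raise ValueError(f"removal vector must have length m={m}")
        if any(r < 0 for r in R):
            raise ValueError("removals must be non-negative")
        if sum(R) != n - m:
            raise ValueError(f"sum(R)={sum(R)} must equal n-m={n - m}")
        if not (0 < self.T1 < self.T2):
            raise ValueError("thresholds must satisfy 0 < T1 < T2")

    def to_dict(self) -> dict:
        return {
            "n": int(self.n),
            "m": int(self.m),
            "R": format_removals(self.R),
            "T1": float(self.T1),
            "T2": float(self.T2),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CensoringScheme":
        return cls(int(d["n"]), int(d["m"]), parse_removals(d["R"], int(d["m"])),
                   float(d["T1"]), float(d["T2"]))


def make_scheme_I(n: int, m: int, T1: float, T2: float) -> CensoringScheme:
    """All n-m removals at the first failure: R = (n-m, 0, ..., 0)."""
    return CensoringScheme(n, m, (n - m,) + (0,) * (m - 1), T1, T2)


def make_scheme_II(n: int, m: int, T1: float, T2: float) -> CensoringScheme:
    """All n-m removals at the last failure: R = (0, ..., 0, n-m)."""
    return CensoringScheme(n, m, (0,) * (m - 1) + (n - m,), T1, T2)


def make_scheme_III(n: int, m: int, T1: float, T2: float) -> CensoringScheme:
    """All n-m removals at the m/2-th failure (m must be even)."""
    if m % 2:
        raise ValueError("scheme III requires even m")
    R = [0] * m
    R[m // 2 - 1] = n - m
    return CensoringScheme(n, m, tuple(R), T1, T2)


def complete_scheme(n: int) -> CensoringScheme:
    """The degenerate no-censoring design: every unit observed to failure."""
    return CensoringScheme(n, n, (0,) * n, 1e300, 2e300)


@dataclass(frozen=True)
class IATIIPCSSample:
    """An observed IAT-II progressively censored sample.

    ``x`` holds the observed (strictly increasing) failure times,
    ``applied_removals[i]`` the number of survivors actually withdrawn at
    the i-th failure, and ``B`` the units withdrawn when the test stopped
    at ``Tstar``.
    """

    x: np.ndarray
    case: str
    E1: int
    E2: int
    k1: int
    k2: int
    B: int
    Tstar: float
    applied_removals: np.ndarray
    scheme: CensoringScheme
    truncated_removal: bool = field(default=False)

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        applied = np.asarray(self.applied_removals, dtype=int)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "applied_removals", applied)
        if self.case not in ("I", "II", "III"):
            raise ValueError(f"unknown case {self.case!r}")
        if x.ndim != 1 or len(x) != self.E2:
            raise ValueError("len(x) must equal E2")
        # ties are tolerated (rounded real data); strict decreases are not
        if np.any(x <= 0) or np.any(np.diff(x) < 0):
            raise ValueError("x must be non-decreasing and positive")
        if not (self.E1 <= self.E2 <= self.scheme.m):
            raise ValueError("need E1 <= E2 <= m")
        if len(applied) != self.E2:
            raise ValueError("applied_removals must align with x")
        total = self.E2 + int(applied.sum()) + self.B
        if total != self.scheme.n:
            raise ValueError(
                f"accounting failure: E2 + removals + B = {total} != n = {self.scheme.n}")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "index": np.arange(1, self.E2 + 1),
            "time": self.x,
            "removal": self.applied_removals,
        })

    def header(self) -> dict:
        return {
            "case": self.case, "E1": self.E1, "E2": self.E2,
            "k1": self.k1, "k2": self.k2, "B": self.B,
            "Tstar": float(self.Tstar), "scheme": self.scheme.to_dict(),
        }


def classify_sample(times, scheme: CensoringScheme) -> IATIIPCSSample:
    """Classify observed failure times into the case structure of a design.

    ``times`` must be the complete record of an experiment run under
    ``scheme`` (all failures up to the stopping rule).
    """
    x = np.asarray(times, dtype=float)
    if x.ndim != 1:
        raise ValueError("times must be a 1-D array")
    if np.any(x <= 0):
        raise ValueError("failure times must be positive")
    if np.any(np.diff(x) < 0):
        raise ValueError("times must be sorted ascending")
    n, m, R, T1, T2 = scheme.n, scheme.m, scheme.R, scheme.T1, scheme.T2
    E2 = len(x)
    if E2 > m:
        raise ValueError(f"observed {E2} failures, more than m={m}")
    k1 = int(np.sum(x < T1))
    applied = np.zeros(E2, dtype=int)

    if E2 == m and E2 > 0:
        xm = x[-1]
        if xm < T1:
            case, k2, Tstar = "I", m, xm
            applied[:] = R
            B = 0
        elif xm < T2:
            case, k2, Tstar = "II", int(np.sum(x < T2)), xm
            applied[:k1] = R[:k1]
            B = n - m - int(sum(R[:k1]))
        else:
            raise ValueError(
                "m-th failure beyond T2: such a failure cannot be observed under this design")
    else:
        # E2 < m (possibly zero failures): the test must have stopped at T2
        if E2 > 0 and x[-1] >= T2:
            raise ValueError("with fewer than m failures all times must precede T2")
        case, k2, Tstar = "III", E2, T2
        applied[:k1] = R[:k1]
        B = n - E2 - int(sum(R[:k1]))
    if B < 0:
        raise ValueError("negative terminal withdrawal: times inconsistent with scheme")
    return IATIIPCSSample(x=x, case=case, E1=k1, E2=E2, k1=k1, k2=k2, B=B,
                          Tstar=Tstar, applied_removals=applied, scheme=scheme)


def simulate_iatii(params, scheme: CensoringScheme, seed=None,
                   quantile=None, sf=None) -> IATIIPCSSample:
    """Simulate one IAT-II PCS sample from a quantile-invertible law.

    The generation is sequential-conditional: with ``r_i`` units at risk
    after the (i-1)-th failure and its withdrawals, the i-th failure time
    satisfies ``S(X_i)/S(x_{i-1}) = U_i^{1/r_i}`` with ``U_i`` uniform —
    the minimum of ``r_i`` i.i.d. residual lifetimes — and is inverted
    through the quantile function.  Withdrawals follow the adaptive rule:
    ``R_i`` survivors removed after a failure strictly before ``T1``,
    none afterwards; the test stops at the m-th failure or at ``T2``.

    ``params`` may be an :class:`LEDParams` (default LED law) or any pair
    accepted by it; alternatively pass explicit ``quantile``/``sf``
    callables for a different lifetime law.
    """
    if quantile is None:
        p = params if isinstance(params, LEDParams) else LEDParams(*params)
        quantile = lambda u: led_quantile(u, p)  # noqa: E731
        sf = lambda t: led_sf(t, p)  # noqa: E731
    elif sf is None:
        raise ValueError("provide sf together with quantile")
    rng = np.random.default_rng(seed)
    n, m, R, T1, T2 = scheme.n, scheme.m, scheme.R, scheme.T1, scheme.T2

    r = n  # units still on test
    sf_prev = 1.0
    x: list[float] = []
    applied: list[int] = []
    truncated = False
    for i in range(m):
        u = rng.random()
        sf_new = sf_prev * u ** (1.0 / r)
        sf_new = min(max(sf_new, np.finfo(float).tiny), 1.0 - np.finfo(float).epsneg)
        xi = float(quantile(1.0 - sf_new))
        if xi >= T2:
            # hard stop: the would-be i-th failure never happens
            break
        x.append(xi)
        r -= 1
        if xi < T1:
            rem = int(R[i])
            if rem > r:
                rem, truncated = r, True
            applied.append(rem)
            r -= rem
        else:
            applied.append(0)
        sf_prev = float(sf(xi))
        if r == 0:
            break

    x_arr = np.asarray(x)
    E2 = len(x_arr)
    k1 = int(np.sum(x_arr < T1))
    if E2 == m and E2 > 0 and x_arr[-1] < T2:
        case = "I" if x_arr[-1] < T1 else "II"
        k2, Tstar = m, x_arr[-1]
        B = n - E2 - int(np.sum(applied))
    else:
        case, k2, Tstar = "III", E2, T2
        B = n - E2 - int(np.sum(applied))
    return IATIIPCSSample(x=x_arr, case=case, E1=k1, E2=E2, k1=k1, k2=k2, B=B,
                          Tstar=Tstar, applied_removals=np.asarray(applied, dtype=int),
                          scheme=scheme, truncated_removal=truncated)


def censor_complete_data(data, scheme: CensoringScheme, seed=None) -> IATIIPCSSample:
    """Apply an IAT-II PCS design to a complete sample of real lifetimes.

    Withdrawn survivors are chosen uniformly at random (seeded) among the
    units still on test, mirroring how a practitioner would censor an
    already-observed dataset.
    """
    data = np.sort(np.asarray(data, dtype=float))
    if len(data) != scheme.n:
        raise ValueError(f"need exactly n={scheme.n} values, got {len(data)}")
    rng = np.random.default_rng(seed)
    n, m, R, T1, T2 = scheme.n, scheme.m, scheme.R, scheme.T1, scheme.T2

    pool = list(data)
    x: list[float] = []
    applied: list[int] = []
    truncated = False
    for i in range(m):
        if not pool:
            break
        xi = min(pool)
        if xi >= T2:
            break
        pool.remove(xi)
        x.append(xi)
        if xi < T1:
            rem = int(R[i])
            if rem > len(pool):
                rem, truncated = len(pool), True
            for idx in sorted(rng.choice(len(pool), size=rem, replace=False), reverse=True):
                pool.pop(int(idx))
            applied.append(rem)
        else:
            applied.append(0)

    x_arr = np.asarray(x)
    E2 = len(x_arr)
    if E2 == 0:
        raise ValueError("no observed failures before T2 under this scheme")
    k1 = int(np.sum(x_arr < T1))
    if E2 == m and x_arr[-1] < T2:
        case = "I" if x_arr[-1] < T1 else "II"
        k2, Tstar = m, x_arr[-1]
    else:
        case, k2, Tstar = "III", E2, T2
    B = n - E2 - int(np.sum(applied))
    return IATIIPCSSample(x=x_arr, case=case, E1=k1, E2=E2, k1=k1, k2=k2, B=B,
                          Tstar=Tstar, applied_removals=np.asarray(applied, dtype=int),
                          scheme=scheme, truncated_removal=truncated)
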