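"""Demographic parameters of a cohort life table.

Computes the classic female-based cohort parameters from an lx/mx schedule:

* net reproductive rate  ``R0 = Σ_x lx·mx``  (daughters per female per
  generation),
* intrinsic rate of increase ``rm``, the unique real root of the discrete
  Euler-Lotka (renewal) equation ``Σ_x exp(-rm·x)·lx·mx = 1``,
* mean generation time ``T = ln(R0)/rm`` (days),
* finite rate of increase ``λ = exp(rm)`` (per day).

Ages enter the sums exactly as the whole-day grid values by default; the
mid-interval "pivotal age" refinement (x + 0.5) is available as an option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import AnalysisError, NumericalError
from .life_table import LifeTable

#: Canonical parameter names, in reporting order.
PARAMETERS = ("R0", "T", "rm", "lambda")

DEFAULT_TOL = 1e-10


@dataclass(frozen=True)
class DemographicParams:
    """Birch's four cohort parameters for one diet.

    Satisfies ``lam == exp(rm)`` and ``t == ln(r0)/rm`` by construction.
    """

    r0: float
    t: float
    rm: float
    lam: float

    def __getitem__(self, name: str) -> float:
        try:
            return {"R0": self.r0, "T": self.t, "rm": self.rm, "lambda": self.lam}[name]
        except KeyError:
            raise KeyError(f"unknown parameter {name!r}; expected one of {PARAMETERS}")


def _schedule(lt: LifeTable, pivotal_age: bool):
    x = lt.ages + 0.5 if pivotal_age else lt.ages
    return x, lt.lx * lt.mx


def net_reproductive_rate(lt: LifeTable, *, pivotal_age: bool = False) -> float:
    """R0 = Σ lx·mx, expected daughters per newborn female."""
    _, lxmx = _schedule(lt, pivotal_age)
    r0 = float(lxmx.sum())
    if r0 == 0.0:
        raise AnalysisError("all-zero mx schedule: the cohort never reproduces")
    return r0


def euler_lotka_residual(rm: float, lt: LifeTable, *, pivotal_age: bool = False) -> float:
    """Σ exp(-rm·x)·lx·mx − 1 at a candidate rm."""
    x, lxmx = _schedule(lt, pivotal_age)
    return float(np.exp(-rm * x) @ lxmx - 1.0)


def intrinsic_rate(
    lt: LifeTable,
    tol: float = DEFAULT_TOL,
    *,
    pivotal_age: bool = False,
) -> float:
    """Solve the Euler-Lotka equation for the intrinsic rate of increase.

    The left-hand side is strictly decreasing in rm, so the root is unique.
    It is bracketed starting from [-1, 2] per day, doubling the bracket as
    needed up to |rm| = 10/day, then isolated with Brent's method.  The
    returned root satisfies ``|Σ exp(-rm·x)·lx·mx − 1| < tol``.
    """
    if tol <= 0:
        raise AnalysisError("tol must be positive")
    net_reproductive_rate(lt, pivotal_age=pivotal_age)  # rejects all-zero mx
    x, lxmx = _schedule(lt, pivotal_age)

    def f(r: float) -> float:
        return float(np.exp(-r * x) @ lxmx - 1.0)

    lo, hi = -1.0, 2.0
    while f(lo) <= 0:  # need f(lo) > 0 > f(hi)
        lo *= 2.0
        if lo < -10.0:
            raise NumericalError("no Euler-Lotka root with rm > -10 per day")
    while f(hi) >= 0:
        hi *= 2.0
        if hi > 10.0:
            raise NumericalError("no Euler-Lotka root with rm < 10 per day")
    rm = brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)
    if abs(rm) < 1e-13:  # stationary schedule (R0 = 1): report exactly zero
        rm = 0.0
    if abs(f(rm)) >= tol:
        raise NumericalError(
            f"Euler-Lotka residual {abs(f(rm)):.3e} not below tol={tol:.1e}"
        )
    return float(rm)


def mean_generation_time(r0: float, rm: float) -> float:
    """T = ln(R0)/rm, the mean age of mothers at daughter production (days)."""
    if r0 <= 0:
        raise AnalysisError("R0 must be positive")
    if rm == 0.0:
        raise AnalysisError(
            "T = ln(R0)/rm is undefined at rm = 0; only a single-pulse "
            "schedule has a well-defined stationary generation time"
        )
    return math.log(r0) / rm


def finite_rate(rm: float) -> float:
    """λ = exp(rm), the daily population multiplication factor."""
    return math.exp(rm)


def demographic_params(
    lt: LifeTable,
    tol: float = DEFAULT_TOL,
    *,
    pivotal_age: bool = False,
) -> DemographicParams:
    """Compute all four parameters of one life table.

    At rm = 0 with a single reproductive pulse, T is the pulse age (the
    limit of ln(R0)/rm); otherwise rm = 0 leaves T undefined.
    """
    r0 = net_reproductive_rate(lt, pivotal_age=pivotal_age)
    rm = intrinsic_rate(lt, tol, pivotal_age=pivotal_age)
    if rm == 0.0:
        x, lxmx = _schedule(lt, pivotal_age)
        pulse = np.nonzero(lxmx)[0]
        if len(pulse) == 1:
            t = float(x[pulse[0]])
        else:
            raise AnalysisError("T undefined: rm = 0 on a multi-age schedule")
    else:
        t = mean_generation_time(r0, rm)
    return DemographicParams(r0=r0, t=t, rm=rm, lam=finite_rate(rm))
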