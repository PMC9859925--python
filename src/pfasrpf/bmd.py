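"""Benchmark concentrations and relative potency factors.

The benchmark concentration (BMC, a.k.a. CED) at a signed critical effect
size ``ces`` is the concentration at which the response reaches
``a*(1+ces)``; for the exponential model it has the closed form::

    BMC = b * (-ln(1 - ln(1+ces)/ln(c))) ** (1/d)

Under a parallel-curve fit (shared ``c`` and ``d``) the BMC of every
compound is its ``b`` times the same shape factor, so the relative potency
factor ``RPF_i = BMC_index / BMC_i = b_index / b_i`` is independent of the
chosen effect size.

Confidence bounds are profile-likelihood bounds: a parameter of interest is
made explicit by reparameterization, all other parameters are re-maximized
at each fixed value, and the bounds are where the profile log-likelihood
drops by ``chi2(df=1).ppf(level)/2`` (1.35277 for a two-sided 90% interval)
below its maximum, located by bisection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .errors import (
    ConsistencyError,
    DirectionError,
    DomainError,
    PfasRpfError,
    UnreachableEffectError,
)
from .fitting import FitResult, _Packer
from .io_tables import SummaryTable

__all__ = ["BmcEstimate", "RpfEstimate", "bmc_closed_form", "profile_ci_bmc", "rpf_from_fit"]

_PROFILE_REL_TOL = 1e-4
_SEARCH_SPAN = 1e3


@dataclass(frozen=True)
class BmcEstimate:
    """BMC point estimate (CED) with profile bounds (CEDL, CEDU)."""

    compound: str
    ces: float
    ced: float
    cedl: float
    cedu: float
    level: float = 0.90

    def __post_init__(self) -> None:
        if not (self.cedl <= self.ced <= self.cedu):
            raise PfasRpfError(
                f"bounds out of order for {self.compound}: "
                f"{self.cedl} <= {self.ced} <= {self.cedu} fails"
            )


@dataclass(frozen=True)
class RpfEstimate:
    """Relative potency vs the index compound, with profile CI."""

    compound: str
    index: str
    rpf: float
    ci_low: float
    ci_high: float
    level: float = 0.90

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.rpf <= self.ci_high):
            raise PfasRpfError(f"RPF CI out of order for {self.compound}")


def _shape_factor(c: float, d: float, ces: float) -> float:
    """(-ln(1 - ln(1+ces)/ln c))**(1/d); BMC = b * shape_factor."""
    ratio = math.log1p(ces) / math.log(c)
    if ratio >= 1.0:
        raise UnreachableEffectError(
            f"effect size {ces} lies beyond the plateau (c = {c})"
        )
    return (-math.log1p(-ratio)) ** (1.0 / d)


def bmc_closed_form(a: float, b: float, c: float, d: float, ces: float) -> float:
    """Concentration at which the exponential curve reaches ``a*(1+ces)``.

    ``ces`` is a signed fraction (−0.1 = 10% decrease) whose sign must match
    the curve direction (``c<1`` for decreasing).  Doubling ``b`` doubles
    the result; ``a`` does not enter (the effect is relative to background).
    """
    for name, val in (("a", a), ("b", b), ("c", c), ("d", d)):
        if not (val > 0):
            raise DomainError(f"parameter {name} must be positive, got {val}")
    if ces == 0:
        raise DomainError("ces must be nonzero")
    if c == 1.0:
        raise DomainError("c = 1 gives a flat curve; no BMC exists")
    if (ces > 0) != (c > 1):
        raise DirectionError(
            f"sign of ces ({ces}) disagrees with curve direction (c = {c})"
        )
    return b * _shape_factor(c, d, ces)


def _profile_drop(level: float) -> float:
    return float(chi2.ppf(level, df=1)) / 2.0


class _ProfileProblem:
    """Re-maximize the concentrated likelihood with one scalar pinned.

    ``inject(theta_reduced, value) -> theta_full`` places the pinned scalar
    (a CED or an RPF) back into the full parameter vector; warm starts are
    threaded through consecutive evaluations so the bisection stays cheap.
    """

    def __init__(self, packer: _Packer, inject: Callable, theta_reduced0: np.ndarray):
        self.packer = packer
        self.inject = inject
        self.warm = np.asarray(theta_reduced0, dtype=float)

    def loglik_at(self, value: float) -> float:
        def nll(tr: np.ndarray) -> float:
            theta = self.inject(tr, value)
            if theta is None:
                return 1e300
            return self.packer.negloglik_concentrated(theta)

        res = minimize(nll, self.warm, method="L-BFGS-B",
                       options={"maxfun": 2000, "ftol": 1e-13, "gtol": 1e-8})
        if np.isfinite(res.fun):
            self.warm = np.asarray(res.x)
        return -float(res.fun)


def _profile_bound(problem: _ProfileProblem, value_hat: float, ll_max: float,
                   drop: float, side: int) -> tuple[float, bool]:
    """Find where the profile log-likelihood crosses ``ll_max - drop``.

    ``side`` is -1 for the lower bound, +1 for the upper.  Returns
    (bound, hit); ``hit`` is False when the profile never drops within the
    search span (flat likelihood), in which case the span edge is returned.
    """
    target = ll_max - drop
    log_hat = math.log(value_hat)
    log_edge = log_hat + side * math.log(_SEARCH_SPAN)
    # expand geometrically until the profile falls below the target
    lo, hi = log_hat, log_hat  # bracket in log space: ll(lo side) >= target > ll(hi side)
    step = 0.25 * side
    inner = log_hat
    outer = None
    while True:
        cand = inner + step
        if (side > 0 and cand > log_edge) or (side < 0 and cand < log_edge):
            cand = log_edge
        ll = problem.loglik_at(math.exp(cand))
        if ll < target:
            outer = cand
            break
        inner = cand
        if cand == log_edge:
            break
        step *= 2.0
    if outer is None:
        return math.exp(log_edge), False
    # bisect between inner (above target) and outer (below target)
    while abs(outer - inner) > _PROFILE_REL_TOL:
        mid = 0.5 * (inner + outer)
        if problem.loglik_at(math.exp(mid)) >= target:
            inner = mid
        else:
            outer = mid
    return math.exp(0.5 * (inner + outer)), True


def _require_parallel(fit: FitResult) -> None:
    if not fit.spec.is_parallel:
        raise PfasRpfError(
            "parallel curves (b per compound, shared c and d) are required to derive RPFs"
        )


def profile_ci_bmc(table: SummaryTable, fit: FitResult, compound: str,
                   ces: float = -0.1, level: float = 0.90) -> BmcEstimate:
    """Profile-likelihood CI for one compound's BMC at effect size ``ces``.

    The compound's potency ``b`` is replaced by the explicit CED through the
    closed form, all remaining parameters are re-maximized at each candidate
    CED, and the 90% bounds are the 1.35277-drop crossings.
    """
    _require_parallel(fit)
    if compound not in fit.params.b:
        raise ConsistencyError(f"compound {compound!r} not in fit")
    packer = _Packer(fit.spec, table)
    theta_hat = _theta_from_params(packer, fit.params)
    i_b = packer.n_a + list(packer.b_levels).index(compound)
    ced_hat = bmc_closed_form(1.0, fit.params.b[compound], fit.params.c, fit.params.d, ces)

    free_idx = [i for i in range(packer.size) if i != i_b]

    def inject(theta_reduced: np.ndarray, ced: float):
        theta = np.empty(packer.size)
        theta[free_idx] = theta_reduced
        c = math.exp(theta[packer.i_c])
        d = math.exp(theta[packer.i_d])
        if c == 1.0 or (ces > 0) != (c > 1) or math.log1p(ces) / math.log(c) >= 1.0:
            return None
        theta[i_b] = math.log(ced) - math.log(_shape_factor(c, d, ces))
        return theta

    problem = _ProfileProblem(packer, inject, theta_hat[free_idx])
    ll_max = max(fit.loglik, problem.loglik_at(ced_hat))
    drop = _profile_drop(level)
    cedl, hit_l = _profile_bound(problem, ced_hat, ll_max, drop, side=-1)
    problem.warm = theta_hat[free_idx].copy()
    cedu, hit_u = _profile_bound(problem, ced_hat, ll_max, drop, side=+1)
    if not (hit_l and hit_u):
        warnings.warn(
            f"profile likelihood for {compound} did not drop within "
            f"[CED/{_SEARCH_SPAN:g}, CED*{_SEARCH_SPAN:g}]; interval is one-sided",
            stacklevel=2,
        )
    return BmcEstimate(compound=compound, ces=ces, ced=ced_hat,
                       cedl=min(cedl, ced_hat), cedu=max(cedu, ced_hat), level=level)


def _theta_from_params(packer: _Packer, params) -> np.ndarray:
    theta = np.empty(packer.size)
    for j, lvl in enumerate(packer.a_levels):
        key = lvl if lvl in params.a else next(iter(params.a))
        theta[j] = math.log(params.a[key])
    for j, lvl in enumerate(packer.b_levels):
        key = lvl if lvl in params.b else next(iter(params.b))
        theta[packer.n_a + j] = math.log(params.b[key])
    theta[packer.i_c] = math.log(params.c)
    theta[packer.i_d] = math.log(params.d)
    return theta


def rpf_from_fit(table: SummaryTable, fit: FitResult, index: str,
                 level: float = 0.90) -> list[RpfEstimate]:
    """Relative potency factors ``b_index / b_i`` with profile CIs.

    The ratio ``rho_i = b_index / b_i`` is profiled directly (``b_i`` is
    rewritten as ``b_index / rho_i`` with ``b_index`` and everything else
    free), using the same likelihood-drop rule as the BMC bounds.  The index
    compound is returned with RPF exactly 1.
    """
    _require_parallel(fit)
    if index not in fit.params.b:
        raise ConsistencyError(f"index compound {index!r} not in fit")
    packer = _Packer(fit.spec, table)
    theta_hat = _theta_from_params(packer, fit.params)
    i_index = packer.n_a + list(packer.b_levels).index(index)
    out: list[RpfEstimate] = []
    drop = _profile_drop(level)
    for compound in packer.b_levels:
        if compound == index:
            out.append(RpfEstimate(compound=compound, index=index, rpf=1.0,
                                   ci_low=1.0, ci_high=1.0, level=level))
            continue
        i_b = packer.n_a + list(packer.b_levels).index(compound)
        rpf_hat = fit.params.b[index] / fit.params.b[compound]
        free_idx = [i for i in range(packer.size) if i != i_b]

        def inject(theta_reduced: np.ndarray, rho: float, _i_b=i_b, _free=free_idx):
            theta = np.empty(packer.size)
            theta[_free] = theta_reduced
            theta[_i_b] = theta[i_index] - math.log(rho)
            return theta

        problem = _ProfileProblem(packer, inject, theta_hat[free_idx])
        ll_max = max(fit.loglik, problem.loglik_at(rpf_hat))
        lo, hit_l = _profile_bound(problem, rpf_hat, ll_max, drop, side=-1)
        problem.warm = theta_hat[free_idx].copy()
        hi, hit_u = _profile_bound(problem, rpf_hat, ll_max, drop, side=+1)
        if not (hit_l and hit_u):
            warnings.warn(f"RPF profile for {compound} hit the search span; "
                          "interval is one-sided", stacklevel=2)
        out.append(RpfEstimate(compound=compound, index=index, rpf=rpf_hat,
                               ci_low=min(lo, rpf_hat), ci_high=max(hi, rpf_hat),
                               level=level))
    return out
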