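"""Exponential concentration-response model and its lognormal summary likelihood.

The response model is the four-parameter exponential family used throughout
benchmark-dose software for continuous endpoints::

    y(x) = a * c ** (1 - exp(-(x / b) ** d))

with ``a`` the background response at concentration zero (fold-change units,
so typically ~1), ``b`` the potency parameter (µM; the only parameter with
concentration units, so horizontal shifts between parallel curves are pure
``b`` ratios), ``c`` the plateau expressed as a ratio to background
(``c < 1`` for a decreasing endpoint such as RAG1/RAG2 repression), and
``d`` the steepness on the log-concentration scale.

Replicate fold changes are modelled as lognormal with a common log-scale
variance across all groups (homoscedastic on the log scale); the model curve
is the group geometric mean.  Because the input is summary data (arithmetic
mean, SD, n per group), the arithmetic moments are first converted to
log-scale moments by lognormal moment matching, and the likelihood is the
exact normal likelihood of the reconstructed log-scale sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ConsistencyError, DomainError
from .io_tables import SummaryTable

__all__ = [
    "ExpoParams",
    "LogMoments",
    "expo_response",
    "arithmetic_to_log_moments",
    "loglik_summary",
    "conditional_log_var_mle",
]


@dataclass(frozen=True)
class ExpoParams:
    """Parameter set of the exponential model for one fitted configuration.

    ``a`` maps study labels to backgrounds, ``b`` maps compound labels to
    potencies.  A no-effect (null) model is represented by ``c == 1`` (the
    curve is then flat at ``a`` regardless of ``b`` and ``d``).
    ``log_var`` is the shared variance of log-scale residuals.
    """

    a: Mapping[str, float]
    b: Mapping[str, float] = field(default_factory=dict)
    c: float = 1.0
    d: float = 1.0
    log_var: float = 1e-8

    def __post_init__(self) -> None:
        for name, val in (("c", self.c), ("d", self.d), ("log_var", self.log_var)):
            if not (val > 0) or not math.isfinite(val):
                raise DomainError(f"ExpoParams.{name} must be positive and finite, got {val}")
        for label, val in {**dict(self.a), **dict(self.b)}.items():
            if not (val > 0) or not math.isfinite(val):
                raise DomainError(f"parameter for {label!r} must be positive, got {val}")


@dataclass(frozen=True)
class LogMoments:
    """Log-scale mean/variance summary of one replicate group."""

    mu_log: float
    s2_log: float
    n: int

    def __post_init__(self) -> None:
        if self.s2_log < 0:
            raise DomainError(f"s2_log must be >= 0, got {self.s2_log}")
        if self.n < 1:
            raise DomainError(f"n must be >= 1, got {self.n}")


def expo_response(x, a: float, b: float, c: float, d: float):
    """Evaluate ``a * c**(1 - exp(-(x/b)**d))`` at concentration(s) ``x`` (µM).

    Monotone in ``x``: decreasing iff ``c < 1``.  ``x = 0`` returns exactly
    ``a``; as ``x -> inf`` the response approaches the plateau ``a*c``.
    Accepts scalars or arrays.
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0):
        raise DomainError("concentration must be non-negative")
    for name, val in (("a", a), ("b", b), ("c", c), ("d", d)):
        if not (val > 0):
            raise DomainError(f"parameter {name} must be positive, got {val}")
    out = a * c ** (1.0 - np.exp(-((x_arr / b) ** d)))
    return out if out.ndim else float(out)


def arithmetic_to_log_moments(mean: float, sd: float, n: int) -> LogMoments:
    """Convert an arithmetic (mean, sd, n) summary to log-scale moments.

    Uses lognormal moment matching with ``cv = sd/mean``::

        s2_log = ln(1 + cv**2)
        mu_log = ln(mean) - s2_log / 2

    which preserves the first two arithmetic moments exactly.  Scaling mean
    and sd by a common factor shifts ``mu_log`` and leaves ``s2_log`` alone.
    """
    if not (mean > 0):
        raise DomainError(f"mean must be positive for lognormal data, got {mean}")
    if sd < 0:
        raise DomainError(f"sd must be non-negative, got {sd}")
    cv = sd / mean
    s2 = math.log1p(cv * cv)
    mu = math.log(mean) - 0.5 * s2
    return LogMoments(mu_log=mu, s2_log=s2, n=int(n))


def _group_arrays(table: SummaryTable):
    """Vectorize a summary table into per-group arrays of log moments."""
    mu = np.empty(len(table.rows))
    s2 = np.empty(len(table.rows))
    n = np.empty(len(table.rows))
    x = np.empty(len(table.rows))
    compounds = []
    studies = []
    for i, row in enumerate(table.rows):
        lm = arithmetic_to_log_moments(row.mean, row.sd, row.n)
        mu[i], s2[i], n[i], x[i] = lm.mu_log, lm.s2_log, lm.n, row.concentration
        compounds.append(row.compound)
        studies.append(row.study)
    return x, mu, s2, n, compounds, studies


def _predicted_log_means(params: ExpoParams, table: SummaryTable) -> np.ndarray:
    pred = np.empty(len(table.rows))
    for i, row in enumerate(table.rows):
        if row.study not in params.a:
            raise ConsistencyError(f"no background parameter for study {row.study!r}")
        a = params.a[row.study]
        if params.c == 1.0:
            pred[i] = math.log(a)
            continue
        if row.compound not in params.b:
            raise ConsistencyError(f"no potency parameter for compound {row.compound!r}")
        pred[i] = math.log(
            expo_response(row.concentration, a, params.b[row.compound], params.c, params.d)
        )
    return pred


def loglik_summary(params: ExpoParams, table: SummaryTable) -> float:
    """Log-likelihood of the summary table under the lognormal model.

    Each group with log moments ``(m, s2, n)`` and predicted log mean
    ``mu = ln y(x)`` contributes::

        -(n/2) * ln(2*pi*log_var) - [(n-1)*s2 + n*(m - mu)**2] / (2*log_var)

    This equals, up to a data-only constant, the sum of normal log densities
    of any raw log-scale sample with those sufficient statistics.
    """
    _, m, s2, n, _, _ = _group_arrays(table)
    mu = _predicted_log_means(params, table)
    v = params.log_var
    ss = (n - 1.0) * s2 + n * (m - mu) ** 2
    return float(np.sum(-(n / 2.0) * math.log(2.0 * math.pi * v) - ss / (2.0 * v)))


def conditional_log_var_mle(params: ExpoParams, table: SummaryTable) -> float:
    """Closed-form MLE of ``log_var`` given the mean structure.

    ``sigma^2 = sum[(n-1)*s2 + n*(m - mu)**2] / sum(n)`` — the value at which
    the likelihood, profiled over the variance, is maximized.
    """
    _, m, s2, n, _, _ = _group_arrays(table)
    mu = _predicted_log_means(params, table)
    ss = (n - 1.0) * s2 + n * (m - mu) ** 2
    return float(np.sum(ss) / np.sum(n))
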