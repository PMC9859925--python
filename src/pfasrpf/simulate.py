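"""Synthetic concentration-response data with the structure the fit assumes.

The generator emulates the study design behind the RAG1/RAG2 endpoints:
four PFASs sharing curve shape (plateau ``c``, steepness ``d``) and
differing only in potency ``b``; fold-change background ~1 (solvent control
normalized to 1); two independent studies; triplicate wells; two-fold
concentration grids up to 100 µM (33 µM for the most potent compound, PFNA).

Replicate noise is lognormal with constant natural-scale CV, geometric mean
adjusted so the *arithmetic* group mean sits on the model curve — matching
how the fitted model interprets the reported arithmetic summaries.  All
randomness flows through one ``numpy.random.default_rng(seed)``; no global
state is touched, so outputs are reproducible across platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import DomainError
from .io_tables import SummaryRow, SummaryTable
from .model import expo_response
from .qpcr import QpcrRecord

__all__ = ["SimDesign", "simulate_summary_table", "simulate_qpcr_experiment",
           "DEFAULT_COMPOUNDS", "default_grid"]

# Potencies (µM) mirroring the magnitudes of the RAG1 endpoint estimates;
# test-fixture values, not claims about true biology.
DEFAULT_COMPOUNDS: dict[str, float] = {
    "PFOA": 9.8,
    "PFOS": 11.7,
    "PFNA": 6.1,
    "PFHxS": 31.0,
}


def default_grid(top: float, n_nonzero: int = 7) -> tuple[float, ...]:
    """Two-fold dilution series down from ``top``, plus the concentration-0
    solvent control."""
    return (0.0,) + tuple(top / 2.0 ** k for k in reversed(range(n_nonzero)))


def _default_concentrations() -> dict[str, tuple[float, ...]]:
    return {
        compound: default_grid(33.0 if compound == "PFNA" else 100.0)
        for compound in DEFAULT_COMPOUNDS
    }


def _default_a() -> dict[str, float]:
    return {"1": 1.0, "2": 1.0}


@dataclass(frozen=True)
class SimDesign:
    """True parameters and layout of one simulated study pair."""

    compounds: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_COMPOUNDS))
    true_a: Mapping[str, float] = field(default_factory=_default_a)
    true_c: float = 0.2
    true_d: float = 1.5
    cv: float = 0.15
    concentrations: Mapping[str, Sequence[float]] = field(default_factory=_default_concentrations)
    n_replicates: int = 3
    n_studies: int = 2
    seed: int = 0
    endpoint: str = "RAG1"

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise DomainError(f"cv must be >= 0, got {self.cv}")
        if self.n_replicates < 1 or self.n_studies < 1:
            raise DomainError("n_replicates and n_studies must be >= 1")
        if len(self.true_a) < self.n_studies:
            raise DomainError("true_a must cover every study")
        for compound in self.compounds:
            grid = self.concentrations.get(compound)
            if grid is None or 0.0 not in grid:
                raise DomainError(f"concentration grid for {compound!r} must include 0")

    @property
    def studies(self) -> tuple[str, ...]:
        return tuple(list(self.true_a)[: self.n_studies])


def _lognormal_draws(rng, curve_value: float, cv: float, n: int) -> np.ndarray:
    """n lognormal draws whose arithmetic mean is ``curve_value`` at the
    given natural-scale CV (degenerate at cv = 0)."""
    if cv == 0.0:
        return np.full(n, curve_value)
    s2 = math.log1p(cv * cv)
    mu = math.log(curve_value) - 0.5 * s2
    return rng.lognormal(mean=mu, sigma=math.sqrt(s2), size=n)


def simulate_summary_table(design: SimDesign) -> SummaryTable:
    """Draw replicate fold changes per group and return their summary table
    (arithmetic mean, sample SD, n), fully determined by ``design.seed``."""
    rng = np.random.default_rng(design.seed)
    rows = []
    for compound, b in design.compounds.items():
        for study in design.studies:
            a = design.true_a[study]
            for x in design.concentrations[compound]:
                y = expo_response(x, a, b, design.true_c, design.true_d)
                draws = _lognormal_draws(rng, y, design.cv, design.n_replicates)
                n = len(draws)
                sd = float(np.std(draws, ddof=1)) if n > 1 else 0.0
                rows.append(
                    SummaryRow(compound=compound, study=study, concentration=float(x),
                               mean=float(np.mean(draws)), sd=sd, n=n)
                )
    return SummaryTable(endpoint=design.endpoint, rows=tuple(rows))


def simulate_qpcr_experiment(
    design: SimDesign,
    curve_slope: float = -1.0 / math.log10(2.0),
    curve_intercept: float = 25.0,
    reference_level: float = 1.0,
    cq_noise: float = 0.1,
):
    """Simulate a Cq-level experiment: wells for every group plus a 5-point
    2-fold standard-curve dilution series per gene.

    Target-gene template follows the dose-response (lognormal well noise at
    the design CV); the reference gene is constant at ``reference_level``.
    Cq = intercept + slope*log10(quantity) + N(0, cq_noise).  Returns
    ``(records, dilution_series, design_map)`` where ``dilution_series``
    maps gene -> [(relative_dilution, cq), ...] and ``design_map`` maps
    sample label -> (compound, study, concentration) as consumed by
    :func:`pfasrpf.qpcr.summarize_to_table`.  Control wells (concentration
    0) get sample labels starting with ``"SC"``.
    """
    if curve_slope >= 0:
        raise DomainError(f"curve_slope must be negative, got {curve_slope}")
    rng = np.random.default_rng(design.seed)
    target = design.endpoint
    genes = (target, "GAPDH")

    def cq_of(quantity: float) -> float:
        noise = rng.normal(0.0, cq_noise) if cq_noise > 0 else 0.0
        return curve_intercept + curve_slope * math.log10(quantity) + noise

    dilution_series = {
        gene: [(dil, cq_of(dil)) for dil in (1.0, 0.5, 0.25, 0.125, 0.0625)]
        for gene in genes
    }
    records: list[QpcrRecord] = []
    design_map: dict[str, tuple[str, str, float]] = {}
    for compound, b in design.compounds.items():
        for study in design.studies:
            a = design.true_a[study]
            for x in design.concentrations[compound]:
                y = expo_response(x, a, b, design.true_c, design.true_d)
                draws = _lognormal_draws(rng, y, design.cv, design.n_replicates)
                for rep, q_target in enumerate(draws, start=1):
                    if x == 0.0:
                        sample = f"SC:{compound}:s{study}:r{rep}"
                    else:
                        sample = f"{compound}:s{study}:c{x:g}:r{rep}"
                    design_map[sample] = (compound, study, float(x))
                    records.append(QpcrRecord(sample=sample, gene=target, cq=cq_of(q_target)))
                    records.append(QpcrRecord(sample=sample, gene="GAPDH",
                                              cq=cq_of(reference_level)))
    return records, dilution_series, design_map
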