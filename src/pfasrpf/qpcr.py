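"""Standard-curve RT-qPCR quantification and WST-1 viability normalization.

Relative quantities are read off a dilution-series standard curve
(Cq regressed on log10 relative dilution), normalized to a reference gene
(GAPDH in this pipeline), and expressed as fold change against the mean of
the solvent-control group, so the control group averages exactly 1.
Quantities are relative throughout — absolute copy numbers are never
computed, and any per-gene rescaling of the dilution axis cancels in the
fold changes.

Technical-replicate Cq values for the same sample x gene are averaged on
the Cq scale before quantification.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import linregress

from .errors import (
    InsufficientDataError,
    InvalidCurveError,
    NormalizationError,
    PairingError,
    ValidationError,
)
from .io_tables import SummaryRow, SummaryTable

__all__ = [
    "QpcrRecord",
    "StandardCurve",
    "FoldChangeRecord",
    "ViabilityRecord",
    "fit_standard_curve",
    "quantify",
    "viability_percent",
    "summarize_to_table",
]


@dataclass(frozen=True)
class QpcrRecord:
    """One well's quantification cycle for one gene."""

    sample: str
    gene: str
    cq: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.cq):
            raise ValidationError(f"Cq must be finite, got {self.cq}")
        if not (10.0 <= self.cq <= 40.0):
            warnings.warn(
                f"Cq {self.cq} for {self.sample}/{self.gene} outside the usual 10-40 range",
                stacklevel=2,
            )


@dataclass(frozen=True)
class StandardCurve:
    """Fitted dilution-series line: Cq = intercept + slope*log10(dilution).

    ``efficiency`` is the fractional amplification per cycle,
    ``10**(-1/slope) - 1`` (1.0 = a perfect doubling every cycle at
    slope -3.3219).
    """

    gene: str
    slope: float
    intercept: float
    efficiency: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise InvalidCurveError(f"standard curve for {self.gene} has slope {self.slope} >= 0")

    def quantity(self, cq: float) -> float:
        """Relative quantity implied by a Cq (arbitrary dilution units)."""
        return 10.0 ** ((cq - self.intercept) / self.slope)


@dataclass(frozen=True)
class FoldChangeRecord:
    sample: str
    gene: str
    normalized_quantity: float
    fold_change: float


@dataclass(frozen=True)
class ViabilityRecord:
    sample: str
    a450: float
    a630: float
    percent_viability: float


def fit_standard_curve(dilutions: Sequence[tuple[float, float]], gene: str) -> StandardCurve:
    """OLS of Cq on log10(relative dilution) for one gene.

    Needs >= 3 distinct dilutions; a non-negative slope (Cq not decreasing
    with template amount) is rejected as an invalid curve.
    """
    pts = [(float(d), float(cq)) for d, cq in dilutions]
    if len({d for d, _ in pts}) < 3:
        raise InsufficientDataError(
            f"standard curve for {gene} needs >= 3 distinct dilutions, got {len(pts)} points"
        )
    if any(d <= 0 for d, _ in pts):
        raise ValidationError("relative dilutions must be positive")
    logd = np.log10([d for d, _ in pts])
    cqs = np.array([cq for _, cq in pts])
    res = linregress(logd, cqs)
    if res.slope >= 0:
        raise InvalidCurveError(f"standard curve for {gene} has slope {res.slope:.4g} >= 0")
    return StandardCurve(
        gene=gene,
        slope=float(res.slope),
        intercept=float(res.intercept),
        efficiency=10.0 ** (-1.0 / float(res.slope)) - 1.0,
        r_squared=float(res.rvalue) ** 2,
    )


def _mean_cq_by_sample_gene(records: Iterable[QpcrRecord]) -> dict[tuple[str, str], float]:
    acc: dict[tuple[str, str], list[float]] = {}
    for rec in records:
        acc.setdefault((rec.sample, rec.gene), []).append(rec.cq)
    return {key: float(np.mean(v)) for key, v in acc.items()}


def quantify(
    records: Iterable[QpcrRecord],
    curves: Mapping[str, StandardCurve],
    reference_gene: str,
    control_label: str,
) -> list[FoldChangeRecord]:
    """GAPDH-normalized fold changes vs the solvent-control group mean.

    Per sample and target gene: relative quantity from the gene's standard
    curve, divided by the reference-gene quantity of the same sample, then
    divided by the mean normalized quantity over control samples (samples
    whose label starts with ``control_label``).  An identical Cq shift of
    target and reference leaves the normalized quantity unchanged.
    """
    cq_by = _mean_cq_by_sample_gene(records)
    samples: list[str] = []
    genes: list[str] = []
    for sample, gene in cq_by:
        if sample not in samples:
            samples.append(sample)
        if gene != reference_gene and gene not in genes:
            genes.append(gene)
    norm: dict[tuple[str, str], float] = {}
    for sample in samples:
        if (sample, reference_gene) not in cq_by:
            raise PairingError(f"sample {sample!r} has no {reference_gene!r} measurement")
        if reference_gene not in curves:
            raise PairingError(f"no standard curve for reference gene {reference_gene!r}")
        q_ref = curves[reference_gene].quantity(cq_by[(sample, reference_gene)])
        for gene in genes:
            if (sample, gene) not in cq_by:
                continue
            if gene not in curves:
                raise PairingError(f"no standard curve for gene {gene!r}")
            q_tgt = curves[gene].quantity(cq_by[(sample, gene)])
            norm[(sample, gene)] = q_tgt / q_ref
    out: list[FoldChangeRecord] = []
    for gene in genes:
        ctrl = [v for (s, g), v in norm.items() if g == gene and s.startswith(control_label)]
        if not ctrl:
            raise NormalizationError(
                f"no control samples (label prefix {control_label!r}) for gene {gene!r}"
            )
        ctrl_mean = float(np.mean(ctrl))
        for sample in samples:
            if (sample, gene) in norm:
                nq = norm[(sample, gene)]
                out.append(
                    FoldChangeRecord(
                        sample=sample, gene=gene,
                        normalized_quantity=nq, fold_change=nq / ctrl_mean,
                    )
                )
    return out


def viability_percent(
    plate: Iterable[tuple[str, float, float]], control_label: str
) -> list[ViabilityRecord]:
    """WST-1 viability as percent of solvent control.

    Signal is A450 - A630 (630 nm background subtraction); percent is
    100 * signal / mean(control signals).
    """
    wells = [(str(s), float(a450), float(a630)) for s, a450, a630 in plate]
    ctrl = [a450 - a630 for s, a450, a630 in wells if s.startswith(control_label)]
    if not ctrl:
        raise NormalizationError(f"no control wells with label prefix {control_label!r}")
    ctrl_mean = float(np.mean(ctrl))
    if ctrl_mean <= 0:
        raise NormalizationError(f"mean control signal {ctrl_mean} is not positive")
    return [
        ViabilityRecord(sample=s, a450=a450, a630=a630,
                        percent_viability=100.0 * (a450 - a630) / ctrl_mean)
        for s, a450, a630 in wells
    ]


def summarize_to_table(
    folds: Sequence[FoldChangeRecord],
    design: Mapping[str, tuple[str, str, float]],
) -> SummaryTable:
    """Group fold changes by (compound, study, concentration) into the
    summary layout the dose-response fit consumes: arithmetic mean, sample
    SD (n-1 denominator; 0 with a warning for singleton groups), n.

    ``design`` maps each sample label to its (compound, study,
    concentration in µM); the endpoint is the single target gene present.
    """
    genes = {f.gene for f in folds}
    if len(genes) != 1:
        raise ValidationError(f"expected fold changes for one endpoint gene, got {sorted(genes)}")
    endpoint = genes.pop()
    groups: dict[tuple[str, str, float], list[float]] = {}
    for f in folds:
        if f.sample not in design:
            raise ValidationError(f"sample {f.sample!r} missing from the design mapping")
        compound, study, conc = design[f.sample]
        groups.setdefault((compound, str(study), float(conc)), []).append(f.fold_change)
    rows = []
    for (compound, study, conc), vals in groups.items():
        n = len(vals)
        if n == 1:
            warnings.warn(
                f"group ({compound}, {study}, {conc}) has a single replicate; sd set to 0",
                stacklevel=2,
            )
            sd = 0.0
        else:
            sd = float(np.std(vals, ddof=1))
        rows.append(
            SummaryRow(compound=compound, study=study, concentration=conc,
                       mean=float(np.mean(vals)), sd=sd, n=n)
        )
    return SummaryTable(endpoint=endpoint, rows=tuple(rows))
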