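"""Tabular I/O: summary tables (fitting input) and result reports.

All formats are tab-delimited text with a header row, dot decimal separator
and no thousands separators, so that write -> read round-trips are exact.
The summary-table layout carries per-group statistics — compound, study
(independent experiment), concentration (µM), arithmetic mean fold change,
sample SD and replicate count — with the solvent control encoded as
concentration 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .errors import ConsistencyError, FormatError, ValidationError

__all__ = [
    "SummaryRow",
    "SummaryTable",
    "SUMMARY_COLUMNS",
    "read_summary_table",
    "write_summary_table",
    "write_report",
]

SUMMARY_COLUMNS = ("compound", "study", "concentration", "mean", "sd", "n")


@dataclass(frozen=True)
class SummaryRow:
    """One (compound, study, concentration) group of replicate fold changes."""

    compound: str
    study: str
    concentration: float
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if not self.compound:
            raise ValidationError("compound label must be non-empty")
        if not self.study:
            raise ValidationError("study label must be non-empty")
        if not math.isfinite(self.concentration) or self.concentration < 0:
            raise ValidationError(f"concentration must be >= 0, got {self.concentration}")
        if not math.isfinite(self.mean) or self.mean <= 0:
            raise ValidationError(f"mean must be > 0 (fold change), got {self.mean}")
        if not math.isfinite(self.sd) or self.sd < 0:
            raise ValidationError(f"sd must be >= 0, got {self.sd}")
        if self.n < 1:
            raise ValidationError(f"n must be >= 1, got {self.n}")


@dataclass(frozen=True)
class SummaryTable:
    """Ordered collection of summary rows for one endpoint (e.g. RAG1)."""

    endpoint: str
    rows: tuple[SummaryRow, ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValidationError("summary table must be non-empty")
        object.__setattr__(self, "rows", tuple(self.rows))
        seen: set[tuple[str, str, float]] = set()
        for row in self.rows:
            key = (row.compound, row.study, row.concentration)
            if key in seen:
                raise ValidationError(
                    f"duplicate concentration {row.concentration} for "
                    f"compound {row.compound!r} in study {row.study!r}"
                )
            seen.add(key)
        for compound in self.compounds:
            nonzero = {r.concentration for r in self.rows if r.compound == compound and r.concentration > 0}
            if len(nonzero) < 3:
                raise ValidationError(
                    f"compound {compound!r} has only {len(nonzero)} distinct nonzero "
                    "concentrations; at least 3 are needed to identify potency and steepness"
                )

    @property
    def compounds(self) -> tuple[str, ...]:
        out: list[str] = []
        for r in self.rows:
            if r.compound not in out:
                out.append(r.compound)
        return tuple(out)

    @property
    def studies(self) -> tuple[str, ...]:
        out: list[str] = []
        for r in self.rows:
            if r.study not in out:
                out.append(r.study)
        return tuple(out)


def _parse_float(cell: str, column: str, line_no: int) -> float:
    try:
        return float(cell)
    except ValueError:
        raise ValidationError(f"non-numeric value {cell!r} in column {column!r}, row {line_no}") from None


def read_summary_table(path, endpoint: str) -> SummaryTable:
    """Read a tab-delimited summary table and validate it.

    The header must name all of ``compound, study, concentration, mean, sd, n``
    (any order; extra columns are ignored).  Row order is preserved.
    Validation failures report the offending 1-based data row.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    missing = [c for c in SUMMARY_COLUMNS if c not in header]
    if missing:
        raise FormatError(f"{path}: header is missing column(s): {', '.join(missing)}")
    idx = {c: header.index(c) for c in SUMMARY_COLUMNS}
    rows: list[SummaryRow] = []
    for line_no, line in enumerate(lines[1:], start=1):
        cells = line.split("\t")
        if len(cells) < len(header):
            raise FormatError(f"{path}: row {line_no} has {len(cells)} cells, expected {len(header)}")
        n_raw = cells[idx["n"]]
        try:
            n = int(n_raw)
        except ValueError:
            raise ValidationError(f"non-integer n {n_raw!r} in row {line_no}") from None
        try:
            rows.append(
                SummaryRow(
                    compound=cells[idx["compound"]],
                    study=cells[idx["study"]],
                    concentration=_parse_float(cells[idx["concentration"]], "concentration", line_no),
                    mean=_parse_float(cells[idx["mean"]], "mean", line_no),
                    sd=_parse_float(cells[idx["sd"]], "sd", line_no),
                    n=n,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {line_no}: {exc}") from None
    return SummaryTable(endpoint=endpoint, rows=tuple(rows))


def _fmt(value: float) -> str:
    # repr of a Python float is the shortest string that round-trips exactly
    return repr(float(value))


def write_summary_table(table: SummaryTable, path) -> None:
    """Write a summary table as TSV; round-trips exactly through read."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(SUMMARY_COLUMNS) + "\n")
        for r in table.rows:
            fh.write(
                "\t".join(
                    (r.compound, r.study, _fmt(r.concentration), _fmt(r.mean), _fmt(r.sd), str(r.n))
                )
                + "\n"
            )


def write_report(fit, bmcs: Sequence, rpfs: Sequence, path) -> None:
    """Write the per-compound BMC/RPF report (one row per compound).

    BMC point estimate and bounds are printed with 1 decimal, RPFs with 2
    decimals; the index compound's RPF is printed as ``1`` with no interval.
    """
    bmc_by = {b.compound: b for b in bmcs}
    rpf_by = {r.compound: r for r in rpfs}
    if set(bmc_by) != set(rpf_by):
        raise ConsistencyError(
            f"BMC compounds {sorted(bmc_by)} do not match RPF compounds {sorted(rpf_by)}"
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("compound\tbmc10\tbmc10_ci90\trpf\trpf_ci90\n")
        for compound in bmc_by:
            b = bmc_by[compound]
            r = rpf_by[compound]
            if compound == r.index:
                rpf_cell, rpf_ci = "1", "-"
            else:
                rpf_cell = f"{r.rpf:.2f}"
                rpf_ci = f"{r.ci_low:.2f}-{r.ci_high:.2f}"
            fh.write(
                f"{compound}\t{b.ced:.1f}\t{b.cedl:.1f}-{b.cedu:.1f}\t{rpf_cell}\t{rpf_ci}\n"
            )
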