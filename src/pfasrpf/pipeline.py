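"""End-to-end orchestration: quantify -> summarize -> fit -> select -> BMC/RPF.

Pure-Python driver behind the command-line interface; every stage is a
library call so the analysis scripts and tests exercise exactly the same
code paths.  The run log records every candidate's AIC and which one was
selected.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, replace
from pathlib import Path
from . import bmd, fitting, io_tables, qpcr
from .errors import ConfigError, ConsistencyError, PfasRpfError

__all__ = ["PipelineConfig", "AnalysisResult", "analyze_table", "run_bmd_only",
           "run_full", "read_config", "config_defaults_text"]


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis settings shared by all entry points."""

    endpoint: str = "RAG1"
    index: str = "PFOA"
    ces: float = -0.1
    level: float = 0.90
    seed: int = 0
    n_starts: int = 10
    reference_gene: str = "GAPDH"
    control_label: str = "SC"
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.ces == 0:
            raise ConfigError("ces must be nonzero")
        if not (0.0 < self.level < 1.0):
            raise ConfigError(f"confidence level must be in (0, 1), got {self.level}")
        if self.n_starts < 1:
            raise ConfigError("n_starts must be >= 1")


_CONFIG_TYPES = {
    "endpoint": str, "index": str, "ces": float, "level": float,
    "seed": int, "n_starts": int, "reference_gene": str,
    "control_label": str, "out_dir": str,
}


def read_config(path) -> PipelineConfig:
    """Parse a flat ``key = value`` config file ('#' starts a comment)."""
    values = {}
    for line_no, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{line_no}: expected 'key = value', got {raw!r}")
        key, _, val = (p.strip() for p in line.partition("="))
        if key not in _CONFIG_TYPES:
            raise ConfigError(f"{path}:{line_no}: unknown key {key!r}")
        try:
            values[key] = _CONFIG_TYPES[key](val)
        except ValueError:
            raise ConfigError(f"{path}:{line_no}: bad value for {key!r}: {val!r}") from None
    return PipelineConfig(**values)


def config_defaults_text() -> str:
    cfg = PipelineConfig()
    return "".join(f"{k} = {getattr(cfg, k)}\n" for k in _CONFIG_TYPES)


@dataclass(frozen=True)
class AnalysisResult:
    table: io_tables.SummaryTable
    candidates: tuple[fitting.FitResult, ...]
    selected: fitting.FitResult
    bmcs: tuple[bmd.BmcEstimate, ...]
    rpfs: tuple[bmd.RpfEstimate, ...]


def analyze_table(table: io_tables.SummaryTable, config: PipelineConfig,
                  log=None) -> AnalysisResult:
    """Fit the candidate models, select by AIC, and derive BMCs and RPFs
    from the parallel-curve fit."""
    if config.index not in table.compounds:
        raise ConsistencyError(
            f"index compound {config.index!r} not present in table "
            f"(compounds: {', '.join(table.compounds)})"
        )
    log = log or (lambda msg: None)
    fits = []
    for spec in fitting.default_candidates():
        fit = fitting.fit_model(table, spec, seed=config.seed, n_starts=config.n_starts)
        fits.append(fit)
        log(f"candidate a_by={spec.a_by} b_by={spec.b_by} effect={spec.include_effect}: "
            f"loglik={fit.loglik:.4f} k={fit.k} AIC={fit.aic:.4f}")
    selected = fitting.select_model(fits)
    log(f"selected by lowest AIC: a_by={selected.spec.a_by} b_by={selected.spec.b_by} "
        f"effect={selected.spec.include_effect} (AIC={selected.aic:.4f})")
    # BMC/RPF need parallel curves; use the parallel candidate for potency
    # even when a simpler model wins the AIC comparison (and say so).
    parallel = next(f for f in fits if f.spec.is_parallel)
    if selected is not parallel:
        log("note: AIC favored a non-parallel model; RPFs derived from the "
            "parallel-curve candidate as potency requires it")
    bmcs = tuple(
        bmd.profile_ci_bmc(table, parallel, compound, ces=config.ces, level=config.level)
        for compound in table.compounds
    )
    rpfs = tuple(bmd.rpf_from_fit(table, parallel, config.index, level=config.level))
    for est in bmcs:
        log(f"BMC {est.compound}: {est.ced:.3f} µM ({est.cedl:.3f}-{est.cedu:.3f})")
    for est in rpfs:
        log(f"RPF {est.compound}: {est.rpf:.3f} ({est.ci_low:.3f}-{est.ci_high:.3f})")
    return AnalysisResult(table=table, candidates=tuple(fits), selected=selected,
                          bmcs=bmcs, rpfs=rpfs)


def _make_logger(out_dir: Path, stem: str):
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / f"{stem}.log"
    fh = log_path.open("w", encoding="utf-8")

    def log(msg: str) -> None:
        print(msg, file=sys.stderr)
        fh.write(msg + "\n")
        fh.flush()

    return log, fh


def run_bmd_only(config: PipelineConfig, table_path) -> Path:
    """Summary table in, report out (skips the qPCR stages)."""
    table = io_tables.read_summary_table(table_path, endpoint=config.endpoint)
    out_dir = Path(config.out_dir)
    log, fh = _make_logger(out_dir, f"bmd_{config.endpoint}")
    try:
        log(f"seed={config.seed} ces={config.ces} level={config.level} index={config.index}")
        result = analyze_table(table, config, log=log)
        report = out_dir / f"report_{config.endpoint}.tsv"
        io_tables.write_report(result.selected, result.bmcs, result.rpfs, report)
        log(f"report written to {report}")
    finally:
        fh.close()
    return report


def run_full(config: PipelineConfig, cq_path, curve_path, design_path) -> Path:
    """Cq-level input in, report out: standard curves, fold changes, summary
    table, then the BMD/RPF stage.  Studies are quantified separately, each
    against its own solvent controls."""
    import csv

    def read_tsv(path, cols):
        with open(path, encoding="utf-8") as fh:
            rd = csv.DictReader(fh, delimiter="\t")
            missing = [c for c in cols if c not in (rd.fieldnames or [])]
            if missing:
                raise PfasRpfError(f"{path}: missing column(s) {', '.join(missing)}")
            return list(rd)

    curves_rows = read_tsv(curve_path, ("gene", "dilution", "cq"))
    by_gene: dict[str, list[tuple[float, float]]] = {}
    for row in curves_rows:
        by_gene.setdefault(row["gene"], []).append((float(row["dilution"]), float(row["cq"])))
    curves = {gene: qpcr.fit_standard_curve(pts, gene) for gene, pts in by_gene.items()}

    design_rows = read_tsv(design_path, ("sample", "compound", "study", "concentration"))
    design = {r["sample"]: (r["compound"], r["study"], float(r["concentration"]))
              for r in design_rows}
    cq_rows = read_tsv(cq_path, ("sample", "gene", "cq"))
    records = [qpcr.QpcrRecord(r["sample"], r["gene"], float(r["cq"])) for r in cq_rows]

    studies = sorted({study for _, study, _ in design.values()})
    folds = []
    for study in studies:
        in_study = {s for s, (_, st, _) in design.items() if st == study}
        study_records = [r for r in records if r.sample in in_study]
        folds.extend(
            qpcr.quantify(study_records, curves, config.reference_gene, config.control_label)
        )
    table = qpcr.summarize_to_table(folds, design)

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table_path = out_dir / f"summary_{table.endpoint}.tsv"
    io_tables.write_summary_table(table, table_path)
    cfg = replace(config, endpoint=table.endpoint)
    return run_bmd_only(cfg, table_path)
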