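"""Per-trait analysis sequence and comparative reporting.

For one trait the sequence is: fit the base animal model (permanent
environment, additive genetic, year, maternal terms as configured), then
refit adding each requested spatial variant — a column AR1 process, a row
process, both, or the home-range overlap (S) matrix — and compare them by
likelihood-ratio test against the base fit, by AIC, and by the Sum-V
credibility check (a fit whose total variance departs several-fold from
the base model's is flagged as poorly estimated rather than trusted).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .lattice import LatticeIndex
from .matrices import OverlapMatrix, RelationshipMatrix
from .varcomp import (
    FittedModel,
    ModelError,
    ModelSpec,
    VariancePartition,
    animal_term,
    compare_aic,
    lrt,
    maternal_term,
    partition,
    pe_term,
    reml_fit,
    sac_term,
    smatrix_term,
    year_term,
)

SPATIAL_VARIANTS = ("none", "column", "row", "column_and_row", "smatrix")
_SYMBOL_ORDER = [
    "V_PE", "V_A", "V_Year", "V_M",
    "V_Column", "V_Row", "V_Columnandrow", "V_Smatrix", "V_Residual",
]


class WorkflowError(ValueError):
    """Raised for invalid analysis configurations."""


@dataclass
class TraitAnalysisConfig:
    """What to fit for one trait.

    ``random_build_order`` lists the base (non-spatial) random effects;
    ``spatial_variants`` always includes "none" so every spatial fit has
    its nested reference.
    """

    trait: str
    log_transform: bool = False
    fixed_terms: list = field(default_factory=list)
    random_build_order: tuple[str, ...] = (
        "permanent_environment", "animal", "year", "maternal",
    )
    spatial_variants: tuple[str, ...] = SPATIAL_VARIANTS
    baseline_for_sumv: str = "none"
    credibility_factor: float = 3.0

    def __post_init__(self) -> None:
        if "none" not in self.spatial_variants:
            self.spatial_variants = ("none",) + tuple(self.spatial_variants)
        for v in self.spatial_variants:
            if v not in SPATIAL_VARIANTS:
                raise WorkflowError(f"unknown spatial variant {v!r}")


@dataclass
class AnalysisData:
    """Aligned inputs for one trait analysis."""

    phenotypes: pd.DataFrame
    A: RelationshipMatrix
    S: OverlapMatrix | None = None
    lattice: LatticeIndex | None = None


@dataclass
class ComparisonReport:
    config: TraitAnalysisConfig
    fits: dict[str, FittedModel]
    partitions: dict[str, VariancePartition | None]
    lrts: dict[str, tuple[float, int, float]]
    aic_table: pd.DataFrame
    flags: dict[str, dict]
    log: list[str]


def _base_terms(cfg: TraitAnalysisConfig, data: AnalysisData) -> list:
    terms = []
    for name in cfg.random_build_order:
        if name == "permanent_environment":
            terms.append(pe_term())
        elif name == "animal":
            terms.append(animal_term(data.A))
        elif name == "year":
            terms.append(year_term())
        elif name == "maternal":
            terms.append(maternal_term())
        else:
            raise WorkflowError(f"unknown random term {name!r}")
    return terms


def _spatial_terms(variant: str, data: AnalysisData) -> list:
    if variant == "none":
        return []
    if variant == "smatrix":
        if data.S is None:
            raise WorkflowError("smatrix variant requested but no S matrix given")
        return [smatrix_term(data.S)]
    if data.lattice is None:
        raise WorkflowError(f"{variant} variant requested but no lattice given")
    axes = {"column": ("col",), "row": ("row",), "column_and_row": ("row", "col")}
    return [sac_term(data.lattice, axes=axes[variant])]


def run_trait_analysis(
    cfg: TraitAnalysisConfig, data: AnalysisData, **reml_options
) -> ComparisonReport:
    """Fit the base model and every requested spatial variant.

    Non-converged fits stay in the report (flagged) but are excluded from
    the AIC ranking and yield no partition or LRT.
    """
    log: list[str] = []
    fits: dict[str, FittedModel] = {}
    for variant in cfg.spatial_variants:
        spec = ModelSpec(
            response=cfg.trait,
            fixed=list(cfg.fixed_terms),
            random=_base_terms(cfg, data) + _spatial_terms(variant, data),
            log_transform=cfg.log_transform,
        )
        fit = reml_fit(spec, data.phenotypes, **reml_options)
        fits[variant] = fit
        if not fit.converged:
            log.append(f"{variant}: REML did not converge")
        for sym, est in fit.variance_estimates.items():
            if est.bound:
                log.append(f"{variant}: {sym} bound at 0")
        for nm, est in fit.phi_estimates.items():
            if est.bound:
                log.append(f"{variant}: {nm} bound")

    base_fit = fits["none"]
    baseline = cfg.baseline_for_sumv
    baseline_sum_v = (
        fits[baseline].sum_v if fits.get(baseline, base_fit).converged else None
    )
    partitions: dict[str, VariancePartition | None] = {}
    flags: dict[str, dict] = {}
    lrts: dict[str, tuple[float, int, float]] = {}
    for variant, fit in fits.items():
        if fit.converged:
            part = partition(
                fit,
                baseline_sum_v=baseline_sum_v if variant != baseline else None,
                credibility_factor=cfg.credibility_factor,
            )
        else:
            part = None
        partitions[variant] = part
        if part is not None and part.credibility_flag:
            log.append(
                f"{variant}: Sum V {part.sum_v:.4g} departs more than "
                f"{cfg.credibility_factor}x from baseline {baseline_sum_v:.4g}"
            )
        flags[variant] = {
            "converged": fit.converged,
            "bound_components": [
                s for s, e in fit.variance_estimates.items() if e.bound
            ],
            "bound_phis": [s for s, e in fit.phi_estimates.items() if e.bound],
            "sumv_credibility": bool(part.credibility_flag) if part else False,
        }
        if variant != "none" and fit.converged and base_fit.converged:
            lrts[variant] = lrt(base_fit, fit)

    comparable = {v: f for v, f in fits.items() if f.converged}
    aic_table = (
        compare_aic(comparable) if comparable else pd.DataFrame()
    )
    return ComparisonReport(
        config=cfg, fits=fits, partitions=partitions, lrts=lrts,
        aic_table=aic_table, flags=flags, log=log,
    )


def _fmt(value: float, se: float, bound: bool) -> str:
    s = f"{value:.3f} ({se:.3f})"
    return f"*{s}*" if bound else s


def report_table(report: ComparisonReport) -> pd.DataFrame:
    """Wide comparison table: one Var./Prop. column pair per variant.

    Bound estimates are set off with asterisks (the printed-table
    convention for components bound at 0 or 1); phi rows, Sum V and
    h2 (%) close the table.
    """
    variants = list(report.fits)
    symbols = [
        s for s in _SYMBOL_ORDER
        if any(s in f.variance_estimates for f in report.fits.values())
    ]
    rows = {}
    for sym in symbols:
        row = {}
        for v in variants:
            fit = report.fits[v]
            part = report.partitions[v]
            est = fit.variance_estimates.get(sym)
            if est is None:
                row[f"{v}:Var."] = ""
                row[f"{v}:Prop."] = ""
            else:
                row[f"{v}:Var."] = _fmt(est.value, est.se, est.bound)
                if part is not None:
                    p, pse = part.proportions[sym]
                    row[f"{v}:Prop."] = _fmt(p, pse, est.bound)
                else:
                    row[f"{v}:Prop."] = "n/a"
        rows[sym] = row
    for axis, label in (("phi_col", "Column phi"), ("phi_row", "Row phi")):
        row = {}
        any_phi = False
        for v in variants:
            fit = report.fits[v]
            hit = [nm for nm in fit.phi_estimates if nm.endswith(axis)]
            if hit:
                est = fit.phi_estimates[hit[0]]
                row[f"{v}:Var."] = _fmt(est.value, est.se, est.bound)
                any_phi = True
            else:
                row[f"{v}:Var."] = ""
            row[f"{v}:Prop."] = ""
        if any_phi:
            rows[label] = row
    sumv_row = {}
    h2_row = {}
    for v in variants:
        part = report.partitions[v]
        sumv_row[f"{v}:Var."] = (
            f"{part.sum_v:.3f}" if part is not None else "n/a"
        )
        sumv_row[f"{v}:Prop."] = ""
        h2_row[f"{v}:Var."] = f"{part.h2[0]:.3f}" if part is not None else "n/a"
        h2_row[f"{v}:Prop."] = ""
    rows["Sum V"] = sumv_row
    rows["h2 (%)"] = h2_row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "component"
    return table.fillna("")


def render_report(
    report: ComparisonReport,
    outdir: str | Path,
    formats: tuple[str, ...] = ("csv", "text"),
) -> list[Path]:
    """Write the comparison table, LRTs and AICs; byte-stable per input."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    table = report_table(report)
    if "csv" in formats:
        p = outdir / "report.csv"
        table.to_csv(p, lineterminator="\n")
        written.append(p)
        lrt_rows = [
            {"variant": v, "chi2": c, "df": d, "p": pv}
            for v, (c, d, pv) in sorted(report.lrts.items())
        ]
        p = outdir / "lrt.csv"
        pd.DataFrame(
            lrt_rows, columns=["variant", "chi2", "df", "p"]
        ).to_csv(p, index=False, float_format="%.6g", lineterminator="\n")
        written.append(p)
        p = outdir / "aic.csv"
        report.aic_table.to_csv(
            p, index=False, float_format="%.6g", lineterminator="\n"
        )
        written.append(p)
    if "text" in formats:
        p = outdir / "report.txt"
        lines = [f"Trait: {report.config.trait}", "", table.to_string(), ""]
        if report.lrts:
            lines.append("Likelihood-ratio tests vs the no-spatial model:")
            for v, (c, d, pv) in sorted(report.lrts.items()):
                lines.append(f"  {v}: chi2({d}) = {c:.2f}, p = {pv:.3g}")
        if len(report.aic_table):
            lines.append("")
            lines.append("AIC ranking (converged fits):")
            lines.append(report.aic_table.to_string(index=False))
        if report.log:
            lines.append("")
            lines.append("Flags:")
            lines.extend(f"  {msg}" for msg in report.log)
        p.write_text("\n".join(lines) + "\n")
        written.append(p)
    return written
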