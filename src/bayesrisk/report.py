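"""Assembly and rendering of the full analysis report.

``run_report`` drives the whole pipeline — prevalence, per-level confidence
intervals, the Bayes risk table and the top-k summary — and returns a
:class:`ReportBundle` that renders deterministically to Markdown, JSON or
CSV.  Diagnostics (infeasible posteriors, partial population coverage,
prior-calibration dispersion) are collected as warnings, never raised: a
published table can trip them while still being worth rendering.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .bayes_risk import (
    RiskTable,
    build_risk_table,
    calibrate_prior,
    rank_top_factors,
    render_chance,
    total_probability_diagnostic,
)
from .prevalence import (
    EN_DASH,
    IntervalEstimate,
    binomial_interval,
    format_percent,
)
from .tables_io import (
    CaseSeries,
    PopulationReference,
    read_case_table,
    read_population_reference,
    _read_level_value_csv,
)

logger = logging.getLogger("bayesrisk")

__all__ = ["ReportBundle", "run_report", "render_markdown", "render_json"]


@dataclass(frozen=True)
class FactorCIRow:
    factor_name: str
    level_label: str
    count: int
    interval: IntervalEstimate


@dataclass(frozen=True)
class ReportBundle:
    """Everything the report renders, traceable to pipeline operations."""

    disease_label: str
    n_cases: int
    n_screened: int
    prevalence: IntervalEstimate
    factor_rows: tuple[FactorCIRow, ...]
    risk_table: RiskTable
    top: tuple[tuple[str, float], ...]
    warnings: tuple[str, ...] = field(default_factory=tuple)


def run_report(
    cases_path: str | Path,
    population_path: str | Path,
    n_screened: int | None = None,
    *,
    prior: float | str = "auto",
    published_path: str | Path | None = None,
    confidence: float = 0.95,
    ci_method: str = "wald",
    top_k: int = 7,
) -> ReportBundle:
    """Run the full pipeline on a case-series CSV and a population CSV."""
    cases = read_case_table(cases_path, n_screened=n_screened)
    pop = read_population_reference(population_path)
    published = None
    if published_path is not None:
        published = _read_level_value_csv(
            published_path, "posterior", default_units="percent"
        )
    return build_report(
        cases, pop, prior=prior, published_posteriors=published,
        confidence=confidence, ci_method=ci_method, top_k=top_k,
    )


def build_report(
    cases: CaseSeries,
    pop: PopulationReference,
    *,
    prior: float | str = "auto",
    published_posteriors: dict[str, float] | None = None,
    confidence: float = 0.95,
    ci_method: str = "wald",
    top_k: int = 7,
) -> ReportBundle:
    warnings: list[str] = []
    prevalence_ci = binomial_interval(
        cases.n_cases, cases.n_screened, confidence, method=ci_method
    )
    factor_rows = tuple(
        FactorCIRow(
            factor_name=factor.name,
            level_label=lev.level_label,
            count=lev.case_count,
            interval=binomial_interval(
                lev.case_count, cases.n_cases, confidence, method=ci_method
            ),
        )
        for factor in cases.factors
        for lev in factor.levels
    )

    if prior == "auto" and published_posteriors:
        triples = [
            (
                published_posteriors[lev.level_label],
                lev.case_proportion,
                pop.proportion(lev.level_label),
            )
            for lev in cases.iter_levels()
            if lev.level_label in published_posteriors and lev.case_count > 0
        ]
        cal = calibrate_prior(triples)
        if not cal.consistent():
            warnings.append(
                f"calibrated prior dispersion {cal.dispersion:.2e} exceeds 1e-3: "
                "the published posteriors do not share a single prior"
            )
    table = build_risk_table(
        cases, pop, prior=prior, published_posteriors=published_posteriors
    )
    for row in table.infeasible_rows:
        warnings.append(
            f"posterior {row.posterior:.4f} > 1 for level {row.level_label!r}: "
            "inputs are mutually inconsistent"
        )
    for factor in cases.factors:
        if factor.exhaustive:
            check = total_probability_diagnostic(table, factor.name, pop)
            if check.coverage < 0.999:
                warnings.append(
                    f"factor {factor.name!r} covers only "
                    f"{check.coverage:.2%} of the reference population; "
                    "posteriors cannot marginalize back to the prior"
                )
    k = min(top_k, len(table.rows))
    top = tuple(rank_top_factors(table, k))
    for msg in warnings:
        logger.warning(msg)
    return ReportBundle(
        disease_label=cases.disease_label,
        n_cases=cases.n_cases,
        n_screened=cases.n_screened,
        prevalence=prevalence_ci,
        factor_rows=factor_rows,
        risk_table=table,
        top=top,
        warnings=tuple(warnings),
    )


def render_markdown(bundle: ReportBundle) -> str:
    """Deterministic Markdown rendering: identical input, identical bytes."""
    out = io.StringIO()
    w = out.write
    label = bundle.disease_label.capitalize()
    w(f"# {label} risk report\n\n")

    w("## Prevalence\n\n")
    w("| Disease status | No. | % | 95% CI |\n|---|---|---|---|\n")
    p = bundle.prevalence
    w(
        f"| {label} | {bundle.n_cases} | {format_percent(p.point, 1)} "
        f"| {p.render(1)} |\n"
    )
    n_neg = bundle.n_screened - bundle.n_cases
    w(
        f"| No {bundle.disease_label} | {n_neg} "
        f"| {format_percent(n_neg / bundle.n_screened, 1)} | |\n"
    )
    w(f"| Total | {bundle.n_screened} | 100.0% | |\n\n")

    factor_names: list[str] = []
    for row in bundle.factor_rows:
        if row.factor_name not in factor_names:
            factor_names.append(row.factor_name)
    w("## Case distribution by determinant\n\n")
    for name in factor_names:
        w(f"### {name.capitalize()}\n\n")
        w("| Level | No. | % | 95% CI |\n|---|---|---|---|\n")
        for row in bundle.factor_rows:
            if row.factor_name != name:
                continue
            w(
                f"| {row.level_label} | {row.count} "
                f"| {format_percent(row.interval.point, 2)} "
                f"| {row.interval.render(1)} |\n"
            )
        w("\n")

    t = bundle.risk_table
    w("## Posterior risk by determinant (Bayes)\n\n")
    w(
        f"Prior P(D) = {t.prior:.6g} ({t.prior_provenance.replace('_', ' ')})\n\n"
    )
    w(
        "| Factor | Level | No. | % of cases | % of population "
        "| Chance of disease (%) | Feasible |\n|---|---|---|---|---|---|---|\n"
    )
    for row in t.rows:
        w(
            f"| {row.factor_name} | {row.level_label} | {row.case_count} "
            f"| {format_percent(row.case_proportion, 2, trim=True)} "
            f"| {format_percent(row.population_proportion, 2, trim=True)} "
            f"| {render_chance(row.posterior)} "
            f"| {'yes' if row.feasible else 'NO'} |\n"
        )
    w("\n")

    if bundle.top:
        w(f"## Top {len(bundle.top)} determinant levels\n\n")
        w("| Level | Chance of disease (%) |\n|---|---|\n")
        for label_, post in bundle.top:
            w(f"| {label_} | {render_chance(post)} |\n")
        w("\n")

    if bundle.warnings:
        w("## Diagnostics\n\n")
        for msg in bundle.warnings:
            w(f"- {msg}\n")
        w("\n")
    return out.getvalue()


def render_json(bundle: ReportBundle) -> str:
    t = bundle.risk_table
    obj = {
        "disease": bundle.disease_label,
        "n_cases": bundle.n_cases,
        "n_screened": bundle.n_screened,
        "prevalence": {
            "point": bundle.prevalence.point,
            "lower": bundle.prevalence.lower,
            "upper": bundle.prevalence.upper,
            "method": bundle.prevalence.method,
            "confidence": bundle.prevalence.confidence,
        },
        "prior": t.prior,
        "prior_provenance": t.prior_provenance,
        "risk_rows": [
            {
                "factor": r.factor_name,
                "level": r.level_label,
                "count": r.case_count,
                "case_proportion": r.case_proportion,
                "population_proportion": r.population_proportion,
                "posterior": r.posterior,
                "feasible": r.feasible,
            }
            for r in t.rows
        ],
        "top": [
            {"level": label, "posterior": post} for label, post in bundle.top
        ],
        "warnings": list(bundle.warnings),
    }
    return json.dumps(obj, indent=2, ensure_ascii=False) + "\n"


def render_risk_csv(bundle: ReportBundle) -> str:
    frame = bundle.risk_table.to_frame()
    frame.insert(0, "prior", bundle.risk_table.prior)
    return frame.to_csv(index=False)
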