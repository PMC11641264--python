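"""Posterior disease risk per determinant level via Bayes' theorem.

The model: for a determinant level RF and disease D,

    P(D | RF) = P(RF | D) · P(D) / P(RF)

where P(RF | D) is the proportion of cases exhibiting the level (from the
case series), P(RF) the proportion of the general population in that level
(from the reference table) and P(D) the *prior* — the marginal disease
probability.  The prior is an external constant of the model; when a study
publishes posterior tables without stating it, :func:`calibrate_prior`
recovers it by algebraic inversion of every published row and checks that
the rows agree.

Posteriors above 1 are possible when the three inputs are mutually
inconsistent (e.g. a prior far larger than the data support).  Such values
are reported as-is and flagged infeasible — never clamped — because they are
a diagnostic, not a rounding problem.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import pandas as pd

from .errors import DomainError, ValidationError
from .prevalence import format_percent
from .tables_io import CaseSeries, PopulationReference

__all__ = [
    "RiskRow",
    "RiskTable",
    "PriorCalibration",
    "TotalProbabilityCheck",
    "posterior_risk",
    "implied_prior",
    "calibrate_prior",
    "build_risk_table",
    "rank_top_factors",
    "total_probability_diagnostic",
    "render_chance",
]

PriorProvenance = Literal["user_supplied", "calibrated", "observed_prevalence"]


def posterior_risk(
    case_proportion: float, population_proportion: float, prior: float
) -> float:
    """P(D|RF) = P(RF|D) · P(D) / P(RF).

    Returns the raw ratio; values above 1 signal inconsistent inputs and are
    the caller's to flag (see :attr:`RiskRow.feasible`).
    """
    if population_proportion <= 0.0:
        raise DomainError("population proportion must be positive")
    if not 0.0 <= case_proportion <= 1.0:
        raise DomainError(f"case proportion {case_proportion} outside [0, 1]")
    if not 0.0 < prior < 1.0:
        raise DomainError(f"prior {prior} outside (0, 1)")
    return case_proportion * prior / population_proportion


def implied_prior(
    posterior: float, case_proportion: float, population_proportion: float
) -> float:
    """Invert Bayes' rule for the prior: P(D) = P(D|RF) · P(RF) / P(RF|D)."""
    if case_proportion <= 0.0:
        raise DomainError("case proportion must be positive to invert")
    if population_proportion <= 0.0:
        raise DomainError("population proportion must be positive")
    if posterior <= 0.0:
        raise DomainError("posterior must be positive to invert")
    return posterior * population_proportion / case_proportion


@dataclass(frozen=True)
class PriorCalibration:
    """Result of recovering the prior from a published posterior table."""

    prior: float                 # median of the per-row implied priors
    dispersion: float            # max absolute deviation from the median
    implied: tuple[float, ...]   # one implied prior per row

    def consistent(self, tolerance: float = 1e-3) -> bool:
        """Do all rows agree on a common prior within ``tolerance``?"""
        return self.dispersion <= tolerance


def calibrate_prior(
    rows: Iterable[tuple[float, float, float]]
) -> PriorCalibration:
    """Recover the common prior implied by published (posterior, P(RF|D),
    P(RF)) triples.

    Each row yields one implied prior; the calibrated value is their median
    and ``dispersion`` the maximum absolute deviation from it.  A large
    dispersion means the published table was not produced by a single prior
    (or a row is corrupted).
    """
    implied = tuple(
        implied_prior(post, case_p, pop_p) for post, case_p, pop_p in rows
    )
    if len(implied) < 2:
        raise DomainError("calibration needs at least 2 rows")
    prior = statistics.median(implied)
    dispersion = max(abs(v - prior) for v in implied)
    return PriorCalibration(prior=prior, dispersion=dispersion, implied=implied)


@dataclass(frozen=True)
class RiskRow:
    """One determinant level with all Bayes inputs and its posterior."""

    factor_name: str
    level_label: str
    case_count: int
    case_proportion: float        # P(RF | D)
    population_proportion: float  # P(RF)
    posterior: float              # P(D | RF)

    @property
    def feasible(self) -> bool:
        return self.posterior <= 1.0


@dataclass(frozen=True)
class RiskTable:
    """All risk rows computed under one prior."""

    prior: float
    prior_provenance: PriorProvenance
    rows: tuple[RiskRow, ...]

    def row(self, level_label: str) -> RiskRow:
        for r in self.rows:
            if r.level_label == level_label:
                return r
        raise KeyError(level_label)

    @property
    def infeasible_rows(self) -> tuple[RiskRow, ...]:
        return tuple(r for r in self.rows if not r.feasible)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "factor": [r.factor_name for r in self.rows],
                "level": [r.level_label for r in self.rows],
                "count": [r.case_count for r in self.rows],
                "case_proportion": [r.case_proportion for r in self.rows],
                "population_proportion": [
                    r.population_proportion for r in self.rows
                ],
                "posterior": [r.posterior for r in self.rows],
                "feasible": [r.feasible for r in self.rows],
            }
        )


def render_chance(posterior: float) -> str:
    """Render a posterior as the percent chance printed in risk tables:
    two decimals, half-up, trailing zeros trimmed (0.433803 → ``"43.38"``,
    0.154 → ``"15.4"``)."""
    return format_percent(posterior, 2, trim=True).rstrip("%")


def _resolve_prior(
    cases: CaseSeries,
    pop: PopulationReference,
    prior: float | str,
    published_posteriors: dict[str, float] | None,
) -> tuple[float, PriorProvenance]:
    if isinstance(prior, (int, float)):
        p = float(prior)
        if not 0.0 < p < 1.0:
            raise DomainError(f"prior {p} outside (0, 1)")
        return p, "user_supplied"
    if prior == "observed":
        return cases.n_cases / cases.n_screened, "observed_prevalence"
    if prior == "auto":
        if not published_posteriors:
            raise ValidationError(
                "prior='auto' requires a published posterior table to invert"
            )
        triples = []
        for lev in cases.iter_levels():
            if lev.level_label in published_posteriors and lev.case_count > 0:
                triples.append(
                    (
                        published_posteriors[lev.level_label],
                        lev.case_proportion,
                        pop.proportion(lev.level_label),
                    )
                )
        calibration = calibrate_prior(triples)
        return calibration.prior, "calibrated"
    raise DomainError(f"prior must be a float, 'observed' or 'auto'; got {prior!r}")


def build_risk_table(
    cases: CaseSeries,
    pop: PopulationReference,
    prior: float | str = "auto",
    published_posteriors: dict[str, float] | None = None,
) -> RiskTable:
    """Compute the posterior risk for every determinant level.

    ``prior`` is a float in (0, 1), ``"observed"`` (the case series'
    ``n_cases / n_screened``) or ``"auto"`` (calibrated by inverting
    ``published_posteriors``).  Every level with cases must have a population
    entry; levels with zero cases are carried with posterior 0.
    """
    prior_value, provenance = _resolve_prior(cases, pop, prior, published_posteriors)
    rows = []
    for factor in cases.factors:
        for lev in factor.levels:
            if lev.level_label not in pop:
                raise ValidationError(
                    f"no population proportion for level {lev.level_label!r} "
                    f"of factor {factor.name!r}"
                )
            pop_p = pop.proportion(lev.level_label)
            post = (
                posterior_risk(lev.case_proportion, pop_p, prior_value)
                if lev.case_count > 0
                else 0.0
            )
            rows.append(
                RiskRow(
                    factor_name=factor.name,
                    level_label=lev.level_label,
                    case_count=lev.case_count,
                    case_proportion=lev.case_proportion,
                    population_proportion=pop_p,
                    posterior=post,
                )
            )
    return RiskTable(prior=prior_value, prior_provenance=provenance, rows=tuple(rows))


def rank_top_factors(table: RiskTable, k: int) -> list[tuple[str, float]]:
    """The ``k`` levels with the highest posterior risk, descending.

    Ties are broken lexicographically on the level label so the ordering is
    deterministic.
    """
    if k < 0 or k > len(table.rows):
        raise DomainError(f"k={k} outside [0, {len(table.rows)}]")
    ranked = sorted(table.rows, key=lambda r: (-r.posterior, r.level_label))
    return [(r.level_label, r.posterior) for r in ranked[:k]]


@dataclass(frozen=True)
class TotalProbabilityCheck:
    """Law-of-total-probability diagnostic for one exhaustive factor.

    When a factor's levels partition the whole population (coverage 1) and
    its case proportions sum to 1, the population-weighted average of the
    posteriors must reproduce the prior:  Σ P(D|RF_i) P(RF_i) = P(D).
    Coverage below 1 means the reference table describes only part of the
    population (e.g. adults only), and the reconstruction is reported over
    that covered fraction.
    """

    factor_name: str
    coverage: float                    # Σ P(RF_i) over the factor's levels
    case_proportion_sum: float         # Σ P(RF_i | D)
    reconstructed_prior: float | None  # Σ P(D|RF_i) P(RF_i) / coverage


def total_probability_diagnostic(
    table: RiskTable, factor_name: str, pop: PopulationReference
) -> TotalProbabilityCheck:
    """Report (never raise) how well a factor's posteriors marginalize back
    to the prior."""
    rows: Sequence[RiskRow] = [
        r for r in table.rows if r.factor_name == factor_name
    ]
    if not rows:
        raise ValidationError(f"factor {factor_name!r} not present in table")
    coverage = sum(pop.proportion(r.level_label) for r in rows)
    case_sum = sum(r.case_proportion for r in rows)
    reconstructed = None
    if coverage > 0.0 and abs(case_sum - 1.0) < 1e-9:
        reconstructed = (
            sum(r.posterior * pop.proportion(r.level_label) for r in rows)
            / coverage
        )
    return TotalProbabilityCheck(
        factor_name=factor_name,
        coverage=coverage,
        case_proportion_sum=case_sum,
        reconstructed_prior=reconstructed,
    )
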