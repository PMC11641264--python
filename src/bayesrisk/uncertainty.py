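"""Parametric-bootstrap uncertainty for Bayes posterior risks.

Case counts are resampled from the fitted sampling model — a multinomial
over the levels of each exhaustive factor, an independent binomial for each
comorbidity flag — and the posterior is recomputed per replicate.  Intervals
are percentile intervals of the replicate distribution; the point estimate
is always the non-resampled posterior.

The prior is an external constant of the Bayes model and is held fixed by
default.  When it was taken as the observed prevalence of the screened
cohort, ``resample_prior=True`` additionally draws it from the cohort-level
binomial, separating sampling variation of the case-series proportions from
uncertainty in the prevalence itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bayes_risk import build_risk_table
from .errors import ConfigError
from .prevalence import IntervalEstimate
from .tables_io import CaseSeries, PopulationReference

__all__ = ["BootstrapConfig", "bootstrap_posterior", "posterior_samples"]


@dataclass(frozen=True)
class BootstrapConfig:
    replicates: int = 2000
    seed: int = 0
    confidence: float = 0.95
    resample_prior: bool = False
    perturb_population: bool = False
    dirichlet_concentration: float = 1000.0

    def __post_init__(self) -> None:
        if self.replicates < 100:
            raise ConfigError(
                f"replicates={self.replicates} too small for interval output "
                "(minimum 100)"
            )
        if not 0.0 < self.confidence < 1.0:
            raise ConfigError("confidence must be in (0, 1)")
        if self.dirichlet_concentration <= 0.0:
            raise ConfigError("dirichlet_concentration must be positive")


def _resample_population(
    rng: np.random.Generator,
    pop_props: np.ndarray,
    exhaustive: bool,
    concentration: float,
    size: int,
) -> np.ndarray:
    """Draw population proportions around the reference values.

    Exhaustive factors: Dirichlet centred on the level proportions plus the
    uncovered remainder (the reference may describe only part of the
    population); comorbidities: independent Beta per flag.
    """
    if exhaustive:
        remainder = max(1.0 - pop_props.sum(), 0.0)
        alpha = np.append(pop_props, remainder) * concentration
        alpha = np.maximum(alpha, 1e-9)
        draws = rng.dirichlet(alpha, size=size)
        return draws[:, : len(pop_props)]
    a = np.maximum(pop_props * concentration, 1e-9)
    b = np.maximum((1.0 - pop_props) * concentration, 1e-9)
    return rng.beta(a, b, size=(size, len(pop_props)))


def posterior_samples(
    cases: CaseSeries,
    pop: PopulationReference,
    prior: float,
    cfg: BootstrapConfig,
) -> dict[str, np.ndarray]:
    """Replicate posterior draws per level, one array of length
    ``cfg.replicates`` each.  Deterministic under a fixed ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    B = cfg.replicates
    n_cases = cases.n_cases

    if cfg.resample_prior:
        # Prevalence uncertainty from the screened-cohort binomial.
        priors = (
            rng.binomial(cases.n_screened, prior, size=B) / cases.n_screened
        )
    else:
        priors = np.full(B, prior)

    out: dict[str, np.ndarray] = {}
    for factor in cases.factors:
        counts = np.array([lev.case_count for lev in factor.levels])
        labels = [lev.level_label for lev in factor.levels]
        pop_props = np.array([pop.proportion(lab) for lab in labels])
        if factor.exhaustive:
            draws = rng.multinomial(n_cases, counts / n_cases, size=B)
        else:
            draws = rng.binomial(n_cases, counts / n_cases, size=(B, len(counts)))
        props = draws / n_cases
        if cfg.perturb_population:
            pop_b = _resample_population(
                rng, pop_props, factor.exhaustive, cfg.dirichlet_concentration, B
            )
        else:
            pop_b = np.broadcast_to(pop_props, (B, len(pop_props)))
        posteriors = props * priors[:, None] / pop_b
        for j, label in enumerate(labels):
            out[label] = posteriors[:, j]
    return out


def bootstrap_posterior(
    cases: CaseSeries,
    pop: PopulationReference,
    prior: float,
    cfg: BootstrapConfig,
) -> dict[str, IntervalEstimate]:
    """Percentile-bootstrap intervals for every level's posterior risk.

    Returns a map from level label to an :class:`IntervalEstimate` whose
    point is the exact (non-resampled) posterior.  Fully deterministic under
    a fixed ``cfg.seed``.
    """
    table = build_risk_table(cases, pop, prior=prior)
    samples = posterior_samples(cases, pop, prior, cfg)
    alpha = 1.0 - cfg.confidence
    lo_q, hi_q = 100 * alpha / 2.0, 100 * (1.0 - alpha / 2.0)
    out: dict[str, IntervalEstimate] = {}
    for label, draws in samples.items():
        point = table.row(label).posterior
        lower = float(np.percentile(draws, lo_q))
        upper = float(np.percentile(draws, hi_q))
        out[label] = IntervalEstimate(
            point=point,
            lower=min(lower, point),
            upper=max(upper, point),
            method="percentile_bootstrap",
            confidence=cfg.confidence,
        )
    return out
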