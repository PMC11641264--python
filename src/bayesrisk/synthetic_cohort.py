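"""Synthetic cross-sectional cohorts with known conditional disease risks.

The generator emulates an outpatient cross-section of the kind the risk
pipeline analyses: every individual carries one level of each exhaustive
categorical factor (age group, gender, education), independent binary
comorbidity flags, and a disease status drawn with probability

    P(D | individual) = baseline_risk × Π risk_ratio(level or flag)

The multiplicative risk model keeps the generative truth analytically
available: under factor independence the conditional risk of a level is the
baseline times its own ratio times the mean ratio of every other factor
(:func:`true_conditional_risk`), which is what parameter-recovery
experiments compare estimates against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes_risk import build_risk_table, RiskTable
from .errors import ConfigError, ValidationError
from .tables_io import (
    CaseSeries,
    FactorSummary,
    LevelSummary,
    PopulationReference,
)

__all__ = [
    "SyntheticConfig",
    "CohortRecord",
    "generate_cohort",
    "summarize_cohort",
    "true_conditional_risk",
    "expected_prevalence",
    "recovery_experiment",
    "coverage_experiment",
    "RecoveryReport",
    "hail_like_config",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative specification of a synthetic cohort.

    ``factors`` maps each exhaustive factor to its level distribution
    (summing to 1); ``comorbidities`` gives marginal presence probabilities
    of independent binary flags.  ``risk_ratios`` is keyed by level label or
    comorbidity name; missing keys default to a ratio of 1.
    """

    n_individuals: int
    factors: dict[str, dict[str, float]]
    comorbidities: dict[str, float] = field(default_factory=dict)
    baseline_risk: float = 0.02
    risk_ratios: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ConfigError("n_individuals must be positive")
        if not 0.0 <= self.baseline_risk <= 1.0:
            raise ConfigError("baseline_risk must be in [0, 1]")
        labels: set[str] = set()
        for name, dist in self.factors.items():
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(
                    f"factor {name!r} distribution sums to {total}, expected 1"
                )
            if any(p < 0 for p in dist.values()):
                raise ConfigError(f"factor {name!r} has a negative probability")
            dup = labels & set(dist)
            if dup:
                raise ConfigError(f"duplicate level labels across factors: {dup}")
            labels |= set(dist)
        for name, p in self.comorbidities.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"comorbidity {name!r} probability {p} invalid")
            if name in labels:
                raise ConfigError(f"label {name!r} reused by a comorbidity")
        for key, r in self.risk_ratios.items():
            if r < 0:
                raise ConfigError(f"negative risk ratio for {key!r}")
        worst, combo = self._max_risk()
        if worst > 1.0 + 1e-12:
            raise ConfigError(
                f"risk product {worst:.4g} exceeds 1 for combination {combo}"
            )

    def ratio(self, key: str) -> float:
        return self.risk_ratios.get(key, 1.0)

    def _max_risk(self) -> tuple[float, list[str]]:
        """Largest reachable individual risk and the combination achieving it."""
        worst = self.baseline_risk
        combo: list[str] = []
        for name, dist in self.factors.items():
            reachable = [lev for lev, p in dist.items() if p > 0]
            if not reachable:
                continue
            best = max(reachable, key=self.ratio)
            worst *= self.ratio(best)
            combo.append(best)
        for name, p in self.comorbidities.items():
            if p > 0 and self.ratio(name) > 1.0:
                worst *= self.ratio(name)
                combo.append(name)
        return worst, combo


@dataclass(frozen=True)
class CohortRecord:
    """One synthetic individual (a row view of the cohort frame)."""

    id: int
    levels: dict[str, str]       # factor -> level
    flags: dict[str, bool]       # comorbidity -> present
    disease: bool


def generate_cohort(cfg: SyntheticConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw a cohort as a data frame, one row per individual.

    Columns: ``id``, one string column per exhaustive factor, one boolean
    column per comorbidity, and boolean ``disease``.  Reproducible from the
    seed (``cfg.seed`` unless overridden).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_individuals
    data: dict[str, np.ndarray] = {"id": np.arange(n)}
    risk = np.full(n, cfg.baseline_risk)
    for name, dist in cfg.factors.items():
        levels = list(dist)
        idx = rng.choice(len(levels), size=n, p=list(dist.values()))
        data[name] = np.array(levels, dtype=object)[idx]
        ratios = np.array([cfg.ratio(lev) for lev in levels])
        risk *= ratios[idx]
    for name, p in cfg.comorbidities.items():
        flags = rng.random(n) < p
        data[name] = flags
        r = cfg.ratio(name)
        if r != 1.0:
            risk = np.where(flags, risk * r, risk)
    data["disease"] = rng.random(n) < risk
    return pd.DataFrame(data)


def iter_records(cohort: pd.DataFrame) -> "list[CohortRecord]":
    """Materialize :class:`CohortRecord` views of a cohort frame."""
    factor_cols = [
        c for c in cohort.columns
        if c not in ("id", "disease") and cohort[c].dtype == object
    ]
    flag_cols = [
        c for c in cohort.columns
        if c not in ("id", "disease") and cohort[c].dtype == bool
    ]
    return [
        CohortRecord(
            id=int(row.id),
            levels={c: getattr(row, c) for c in factor_cols},
            flags={c: bool(getattr(row, c)) for c in flag_cols},
            disease=bool(row.disease),
        )
        for row in cohort.itertuples(index=False)
    ]


def summarize_cohort(
    cohort: pd.DataFrame, disease_label: str = "disease"
) -> tuple[CaseSeries, PopulationReference, float]:
    """Collapse individual records onto the published-table shapes.

    Returns the case series (counts per level among cases), the population
    reference (level proportions over the *whole* cohort) and the observed
    prevalence.  Raises if the cohort contains no cases.
    """
    if len(cohort) == 0:
        raise ValidationError("empty cohort")
    diseased = cohort[cohort["disease"]]
    n_cases = len(diseased)
    if n_cases == 0:
        raise ValidationError("cohort contains no cases; cannot build a case series")
    n = len(cohort)

    factor_cols = [
        c for c in cohort.columns
        if c not in ("id", "disease") and cohort[c].dtype == object
    ]
    flag_cols = [
        c for c in cohort.columns
        if c not in ("id", "disease") and cohort[c].dtype == bool
    ]

    factors: list[FactorSummary] = []
    pop_entries: dict[str, float] = {}
    for col in factor_cols:
        case_counts = diseased[col].value_counts()
        pop_counts = cohort[col].value_counts()
        levels = tuple(
            LevelSummary(
                factor_name=col,
                level_label=str(lev),
                case_count=int(case_counts.get(lev, 0)),
                case_proportion=int(case_counts.get(lev, 0)) / n_cases,
            )
            for lev in sorted(pop_counts.index)
        )
        factors.append(FactorSummary(name=col, exhaustive=True, levels=levels))
        for lev in pop_counts.index:
            pop_entries[str(lev)] = int(pop_counts[lev]) / n
    for col in flag_cols:
        k_case = int(diseased[col].sum())
        factors.append(
            FactorSummary(
                name=col,
                exhaustive=False,
                levels=(
                    LevelSummary(col, col, k_case, k_case / n_cases),
                ),
            )
        )
        frac = float(cohort[col].mean())
        if frac > 0:
            pop_entries[col] = frac

    cases = CaseSeries(
        disease_label=disease_label,
        n_cases=n_cases,
        n_screened=n,
        factors=tuple(factors),
    )
    pop = PopulationReference(entries=pop_entries, source_note="synthetic cohort")
    return cases, pop, n_cases / n


def _mean_ratio(cfg: SyntheticConfig, factor: str) -> float:
    return sum(p * cfg.ratio(lev) for lev, p in cfg.factors[factor].items())


def _comorbidity_mean(cfg: SyntheticConfig, name: str) -> float:
    p = cfg.comorbidities[name]
    return (1.0 - p) + p * cfg.ratio(name)


def expected_prevalence(cfg: SyntheticConfig) -> float:
    """Marginal P(D) of the generative model, in closed form."""
    out = cfg.baseline_risk
    for factor in cfg.factors:
        out *= _mean_ratio(cfg, factor)
    for name in cfg.comorbidities:
        out *= _comorbidity_mean(cfg, name)
    return out


def true_conditional_risk(cfg: SyntheticConfig, target: str) -> float:
    """Closed-form P(D | level) (or P(D | comorbidity present)) under the
    multiplicative model with independent factors."""
    out = cfg.baseline_risk
    owner = None
    for factor, dist in cfg.factors.items():
        if target in dist:
            owner = factor
            break
    if owner is not None:
        out *= cfg.ratio(target)
        for factor in cfg.factors:
            if factor != owner:
                out *= _mean_ratio(cfg, factor)
        for name in cfg.comorbidities:
            out *= _comorbidity_mean(cfg, name)
        return out
    if target in cfg.comorbidities:
        out *= cfg.ratio(target)
        for factor in cfg.factors:
            out *= _mean_ratio(cfg, factor)
        for name in cfg.comorbidities:
            if name != target:
                out *= _comorbidity_mean(cfg, name)
        return out
    raise KeyError(target)


@dataclass(frozen=True)
class RecoveryReport:
    """Bias/RMSE of pipeline posterior estimates against generative truth."""

    replicates: int
    truth: dict[str, float]
    mean_estimate: dict[str, float]
    bias: dict[str, float]
    rmse: dict[str, float]
    prior_inflation: float | None = None  # estimate ratio under a misspecified prior

    def to_frame(self) -> pd.DataFrame:
        levels = list(self.truth)
        return pd.DataFrame(
            {
                "level": levels,
                "truth": [self.truth[l] for l in levels],
                "mean_estimate": [self.mean_estimate[l] for l in levels],
                "bias": [self.bias[l] for l in levels],
                "rmse": [self.rmse[l] for l in levels],
            }
        )


def _estimate_tables(cohort: pd.DataFrame) -> RiskTable:
    cases, pop, prevalence = summarize_cohort(cohort)
    return build_risk_table(cases, pop, prior="observed")


def recovery_experiment(
    cfg: SyntheticConfig,
    replicates: int,
    seed: int = 0,
    misspecified_prior: float | None = None,
) -> RecoveryReport:
    """Generate → summarize → estimate, repeatedly, against known truth.

    Each replicate builds the risk table with the prior set to the observed
    prevalence and records the posterior per level.  When
    ``misspecified_prior`` is given, the mean multiplicative inflation of the
    estimates under that prior (relative to the observed-prevalence prior)
    is reported as well — the posterior is exactly linear in the prior, so a
    prior off by a factor c inflates every estimate by c.
    """
    if replicates == 0:
        return RecoveryReport(0, {}, {}, {}, {})
    targets = [lev for dist in cfg.factors.values() for lev in dist] + list(
        cfg.comorbidities
    )
    truth = {t: true_conditional_risk(cfg, t) for t in targets}
    seeds = np.random.SeedSequence(seed).generate_state(replicates) % (2**31)
    estimates: dict[str, list[float]] = {t: [] for t in targets}
    inflations: list[float] = []
    for s in seeds:
        cohort = generate_cohort(cfg, seed=int(s))
        cases, pop, prevalence = summarize_cohort(cohort)
        table = build_risk_table(cases, pop, prior="observed")
        for t in targets:
            try:
                estimates[t].append(table.row(t).posterior)
            except KeyError:  # level absent among cases in this replicate
                pass
        if misspecified_prior is not None:
            table2 = build_risk_table(cases, pop, prior=misspecified_prior)
            row = table.rows[0]
            if row.posterior > 0:
                inflations.append(
                    table2.row(row.level_label).posterior / row.posterior
                )
    mean_est = {t: float(np.mean(v)) for t, v in estimates.items() if v}
    bias = {t: mean_est[t] - truth[t] for t in mean_est}
    rmse = {
        t: float(math.sqrt(np.mean([(x - truth[t]) ** 2 for x in v])))
        for t, v in estimates.items()
        if v
    }
    return RecoveryReport(
        replicates=replicates,
        truth={t: truth[t] for t in mean_est},
        mean_estimate=mean_est,
        bias=bias,
        rmse=rmse,
        prior_inflation=float(np.mean(inflations)) if inflations else None,
    )


def coverage_experiment(
    cfg: SyntheticConfig,
    level: str,
    runs: int,
    seed: int = 0,
    bootstrap_replicates: int = 1000,
    confidence: float = 0.95,
) -> tuple[int, int]:
    """How often nominal bootstrap intervals cover the generative truth.

    Each run draws a fresh cohort, estimates the posterior for ``level``
    with the prior set to the observed prevalence, and builds a percentile
    bootstrap interval that resamples both the case-level counts and the
    cohort prevalence.  Returns ``(covered, total)``; a well-calibrated
    interval covers the closed-form truth in about ``confidence`` of runs.
    """
    from .uncertainty import BootstrapConfig, bootstrap_posterior

    truth = true_conditional_risk(cfg, level)
    seeds = np.random.SeedSequence(seed).generate_state(2 * runs) % (2**31)
    covered = total = 0
    for i in range(runs):
        cohort = generate_cohort(cfg, seed=int(seeds[2 * i]))
        try:
            cases, pop, prevalence = summarize_cohort(cohort)
        except ValidationError:  # a run with zero cases carries no interval
            continue
        bcfg = BootstrapConfig(
            replicates=bootstrap_replicates,
            seed=int(seeds[2 * i + 1]),
            confidence=confidence,
            resample_prior=True,
        )
        intervals = bootstrap_posterior(cases, pop, prevalence, bcfg)
        if level not in intervals:
            continue
        total += 1
        if intervals[level].lower <= truth <= intervals[level].upper:
            covered += 1
    return covered, total


def hail_like_config(
    n_individuals: int = 200_000,
    target_prevalence: float = 0.02,
    seed: int = 0,
) -> SyntheticConfig:
    """A cohort emulating the adult outpatient cross-section the pipeline
    targets: five age bands (adults 40+, distribution from the UN reference
    proportions renormalized to the covered ages), a near-balanced gender
    split, a small illiterate minority, and common comorbidities.  Risk
    ratios rise steeply with age; the baseline is solved so the marginal
    prevalence equals ``target_prevalence`` (≈2%, typical of outpatient
    glaucoma screening).
    """
    factors = {
        "age": {
            "40–49 years": 0.5482,
            "50–59 years": 0.2742,
            "60–69 years": 0.1148,
            "70–79 years": 0.0434,
            "≥80 years": 0.0194,
        },
        "gender": {"Male": 0.5778, "Female": 0.4222},
        "education": {"Illiterate": 0.0062, "Literate": 0.9938},
    }
    comorbidities = {"Diabetes Mellitus": 0.1617, "Hypertension": 0.25}
    risk_ratios = {
        "40–49 years": 1.0,
        "50–59 years": 2.7,
        "60–69 years": 5.2,
        "70–79 years": 4.2,
        "≥80 years": 4.4,
        "Male": 0.9,
        "Female": 1.1,
        "Illiterate": 4.0,
        "Literate": 1.0,
        "Diabetes Mellitus": 2.8,
        "Hypertension": 0.9,
    }
    probe = SyntheticConfig(
        n_individuals=n_individuals,
        factors=factors,
        comorbidities=comorbidities,
        baseline_risk=1e-6,
        risk_ratios=risk_ratios,
        seed=seed,
    )
    scale = expected_prevalence(probe) / 1e-6
    return SyntheticConfig(
        n_individuals=n_individuals,
        factors=factors,
        comorbidities=comorbidities,
        baseline_risk=target_prevalence / scale,
        risk_ratios=risk_ratios,
        seed=seed,
    )
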