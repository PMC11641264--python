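"""Prevalence, binomial confidence intervals, percent rendering, sample size.

The interval machinery delegates to :func:`statsmodels.stats.proportion.
proportion_confint`; this module fixes the conventions that make the output
reproduce printed epidemiological tables: Wald bounds clipped to ``[0, 1]``
and percentages rounded half-up at the requested precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

from .errors import DomainError

__all__ = [
    "IntervalEstimate",
    "SampleSizeSpec",
    "point_prevalence",
    "binomial_interval",
    "wald_interval",
    "wilson_interval",
    "clopper_pearson_interval",
    "format_percent",
    "daniel_sample_size",
]

EN_DASH = "–"

_METHOD_MAP = {"wald": "normal", "wilson": "wilson", "clopper_pearson": "beta"}


@dataclass(frozen=True)
class IntervalEstimate:
    """A point estimate with confidence bounds.

    Binomial proportions always live in ``[0, 1]`` (enforced by the interval
    constructors, which clip).  Bootstrap intervals for Bayes posteriors may
    exceed 1 when the inputs are mutually inconsistent — such values signal
    infeasibility and are deliberately not clamped — so the dataclass itself
    only requires the bounds to be ordered and non-negative.
    """

    point: float
    lower: float
    upper: float
    method: str
    confidence: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower <= self.point <= self.upper):
            raise DomainError(
                f"interval bounds out of order: "
                f"{self.lower} <= {self.point} <= {self.upper} violated"
            )

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def render(self, decimals: int = 1) -> str:
        """Render as e.g. ``"45.6–59.4%"``; an upper bound of exactly 1
        renders as ``"100"`` (no decimals), matching common table style."""
        lo = format_percent(self.lower, decimals).rstrip("%")
        hi = format_percent(self.upper, decimals).rstrip("%")
        if self.upper == 1.0:
            hi = "100"
        return f"{lo}{EN_DASH}{hi}%"


@dataclass(frozen=True)
class SampleSizeSpec:
    """Inputs of the single-proportion precision formula (Daniel's formula)."""

    expected_prevalence: float
    confidence: float = 0.95
    absolute_precision: float = 0.05
    loss_to_followup: float = 0.0

    def __post_init__(self) -> None:
        for name in ("expected_prevalence", "confidence", "absolute_precision"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise DomainError(f"{name}={v} must be in (0, 1)")
        if not 0.0 <= self.loss_to_followup < 1.0:
            raise DomainError("loss_to_followup must be in [0, 1)")


def point_prevalence(k: int, n: int) -> float:
    """Point prevalence ``k/n`` of a condition among ``n`` screened people."""
    if n <= 0:
        raise DomainError("n must be positive")
    if not 0 <= k <= n:
        raise DomainError(f"k={k} outside [0, n={n}]")
    return k / n


def binomial_interval(
    k: int, n: int, confidence: float = 0.95, method: str = "wald"
) -> IntervalEstimate:
    """Confidence interval for a binomial proportion.

    ``method`` is one of ``wald`` (normal approximation, clipped to [0, 1]),
    ``wilson`` (score interval) or ``clopper_pearson`` (exact).
    """
    if n <= 0:
        raise DomainError("n must be positive")
    if not 0 <= k <= n:
        raise DomainError(f"k={k} outside [0, n={n}]")
    if not 0.0 < confidence < 1.0:
        raise DomainError("confidence must be in (0, 1)")
    if method not in _METHOD_MAP:
        raise DomainError(f"unknown interval method {method!r}")
    lower, upper = proportion_confint(
        k, n, alpha=1.0 - confidence, method=_METHOD_MAP[method]
    )
    lower = min(max(float(lower), 0.0), 1.0)
    upper = min(max(float(upper), 0.0), 1.0)
    # boundary counts have mathematically exact bounds; remove float noise
    if k == 0:
        lower = 0.0
    if k == n:
        upper = 1.0
    point = k / n
    return IntervalEstimate(
        point=point,
        lower=min(lower, point),
        upper=max(upper, point),
        method=method,
        confidence=confidence,
    )


def wald_interval(k: int, n: int, confidence: float = 0.95) -> IntervalEstimate:
    """Wald (normal-approximation) interval, clipped to ``[0, 1]``."""
    return binomial_interval(k, n, confidence, method="wald")


def wilson_interval(k: int, n: int, confidence: float = 0.95) -> IntervalEstimate:
    """Wilson score interval; lower bound strictly positive whenever k > 0."""
    return binomial_interval(k, n, confidence, method="wilson")


def clopper_pearson_interval(
    k: int, n: int, confidence: float = 0.95
) -> IntervalEstimate:
    """Exact (Clopper–Pearson) interval."""
    return binomial_interval(k, n, confidence, method="clopper_pearson")


def format_percent(x: float, decimals: int = 1, *, trim: bool = False) -> str:
    """Format a fraction as a percentage string with round-half-up.

    Decimal arithmetic on ``repr(x)`` keeps half-way cases (e.g. 0.005 at one
    decimal) rounding up, where native float formatting would round to even.
    With ``trim=True`` trailing zeros (and a bare decimal point) are removed
    after rounding, so 0.161 renders as ``"16.1%"`` at two decimals.
    """
    if not 0.0 <= x <= 1.0 + 1e-12:
        raise DomainError(f"fraction {x} outside [0, 1]")
    quantum = Decimal(1).scaleb(-decimals) if decimals > 0 else Decimal(1)
    value = (Decimal(repr(x)) * 100).quantize(quantum, rounding=ROUND_HALF_UP)
    text = str(value)
    if trim and "." in text:
        text = text.rstrip("0").rstrip(".")
    return f"{text}%"


def daniel_sample_size(spec: SampleSizeSpec) -> int:
    """Required sample size for estimating a proportion to a given precision.

    n = ceil(z^2 p (1-p) / d^2), inflated by 1/(1-loss) for anticipated
    loss to follow-up, where z is the two-sided normal quantile at the
    requested confidence, p the expected prevalence and d the absolute
    precision.
    """
    z = norm.ppf(0.5 + spec.confidence / 2.0)
    p = spec.expected_prevalence
    d = spec.absolute_precision
    n = z * z * p * (1.0 - p) / (d * d)
    if spec.loss_to_followup > 0.0:
        n /= 1.0 - spec.loss_to_followup
    return math.ceil(n)
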