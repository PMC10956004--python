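"""Cumulative price to walk and the marginal-value (MV) statistic.

The integral of a fitted price-to-walk curve over a fixed window (0–30 min
by default, about the average time walked per session) is the *cumulative
price*: what continuous walking over that window would cost, in USD.  The
MV of a comparison condition against a baseline is the difference of the
two cumulative prices; dividing by the baseline cumulative price expresses
it as a percentage, which removes the large between-subject differences in
the absolute valuation of time.  A positive MV means walking is cheaper
(the comparison condition adds value); negative means it imposes a cost.

Closed form: ∫ k·e^{βt} dt = (k/β)(e^{βt₂} − e^{βt₁}), with the k·(t₂−t₁)
limit used when |β| < 1e-12.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, expm1

from .fitting import PriceToWalkFit

__all__ = [
    "IntegrationBounds",
    "DEFAULT_BOUNDS",
    "NormalizationError",
    "MarginalValueResult",
    "cumulative_price_closed_form",
    "cumulative_price",
    "marginal_value",
    "hourly_rate",
    "mv_to_hourly",
]

#: Below this |β| the exponential integral switches to its b→0 limit.
RATE_EPS = 1e-12


class NormalizationError(ValueError):
    """Baseline cumulative price is non-positive; MV% is undefined."""


@dataclass(frozen=True)
class IntegrationBounds:
    """Time window (minutes) over which curves are integrated."""

    t1: float = 0.0
    t2: float = 30.0

    def __post_init__(self) -> None:
        if self.t2 <= self.t1:
            raise ValueError(f"need t2 > t1, got [{self.t1}, {self.t2}]")

    @property
    def width_minutes(self) -> float:
        return self.t2 - self.t1


DEFAULT_BOUNDS = IntegrationBounds()


@dataclass(frozen=True)
class MarginalValueResult:
    mv_usd: float
    mv_percent: float
    baseline_condition: str
    comparison_condition: str
    bounds: IntegrationBounds
    baseline_cumulative: float
    comparison_cumulative: float
    baseline_fit: PriceToWalkFit | None = None
    comparison_fit: PriceToWalkFit | None = None


def cumulative_price_closed_form(
    k: float, beta: float, bounds: IntegrationBounds = DEFAULT_BOUNDS
) -> float:
    """∫ k·e^{βt} dt over [t1, t2], exact, continuous through β = 0."""
    if abs(beta) < RATE_EPS:
        return k * bounds.width_minutes
    # expm1 keeps full precision as beta -> 0 (no cancellation)
    return k * exp(beta * bounds.t1) * expm1(beta * bounds.width_minutes) / beta


def cumulative_price(
    fit: PriceToWalkFit, bounds: IntegrationBounds = DEFAULT_BOUNDS
) -> float:
    """Cumulative price to walk of a fitted curve, USD over the window."""
    return cumulative_price_closed_form(fit.k_hat, fit.effective_rate, bounds)


def marginal_value(
    fit_baseline: PriceToWalkFit,
    fit_comparison: PriceToWalkFit,
    bounds: IntegrationBounds = DEFAULT_BOUNDS,
) -> MarginalValueResult:
    """MV of the comparison condition relative to the baseline.

    mv_usd = cumulative(baseline) − cumulative(comparison);
    mv_percent = 100 · mv_usd / cumulative(baseline).
    """
    cum1 = cumulative_price(fit_baseline, bounds)
    cum2 = cumulative_price(fit_comparison, bounds)
    mv_usd = cum1 - cum2
    if cum1 <= 0:
        raise NormalizationError(
            f"baseline cumulative price {cum1:.4f} is not positive; cannot normalize MV"
        )
    return MarginalValueResult(
        mv_usd=mv_usd,
        mv_percent=100.0 * mv_usd / cum1,
        baseline_condition=fit_baseline.condition,
        comparison_condition=fit_comparison.condition,
        bounds=bounds,
        baseline_cumulative=cum1,
        comparison_cumulative=cum2,
        baseline_fit=fit_baseline,
        comparison_fit=fit_comparison,
    )


def hourly_rate(cumulative: float, bounds: IntegrationBounds = DEFAULT_BOUNDS) -> float:
    """Express a cumulative price over the window as USD per hour."""
    return cumulative / (bounds.width_minutes / 60.0)


def mv_to_hourly(rate_usd_per_h: float, mv_percent: float) -> float:
    """Convert an MV percentage to USD/h against a baseline hourly rate."""
    return rate_usd_per_h * mv_percent / 100.0
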