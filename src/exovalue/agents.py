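"""Bidding agents: exponential robo-bidders and honest human participants.

Robo-bidders quote a deterministic exponential of the number of intervals
they have walked (their auction wins), ``k · exp(b · t_k)``, corrupted by a
small Gaussian noise term so a human opponent cannot intuit the model.  When
a robo-bidder loses an auction its deterministic price is frozen; fresh
noise is drawn each interval unless the literal-constant mode is enabled.

A synthetic honest human bids their internal price to walk, an exponential
in *accumulated walking minutes* (2 min per auction won): fatigue accrues
only while walking, not while resting between lost auctions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .auction import AuctionError

__all__ = [
    "RoboBidderParams",
    "RoboBidderState",
    "HumanAgentParams",
    "HumanAgentState",
    "robo_bid",
    "advance_robo_state",
    "human_bid",
    "advance_human_state",
    "make_default_robo_cohort",
    "round_to_cents",
]

#: Bids are quoted on a cent grid and floored at one cent.
MIN_BID_USD = 0.01

# Default priors for the computerized opponents.  Calibrated (see
# docs/methods.md) so a median honest human with the default subject prior
# walks roughly half the session and all quoted prices stay within the
# realistic $0.10–$5.00 range.
DEFAULT_ROBO_K_RANGE = (0.40, 0.90)   # USD, initial price
DEFAULT_ROBO_B_RANGE = (0.18, 0.32)   # per walked 2-min interval
DEFAULT_ROBO_NOISE_SD = 0.01          # USD


def round_to_cents(amount: float) -> float:
    """Round to the cent grid, flooring at the $0.01 minimum bid."""
    return max(round(amount * 100), 1) / 100.0


@dataclass(frozen=True)
class RoboBidderParams:
    """Parameters of one robo-bidder's price curve k·exp(b·t_k) + noise."""

    k_init: float                 # initial price, USD
    b_rate: float                 # exponential rate per walked interval
    noise_sd: float = DEFAULT_ROBO_NOISE_SD   # USD
    #: If True, a losing robo-bidder re-quotes its previous number verbatim
    #: (noise included) instead of drawing fresh noise around the frozen
    #: deterministic price.
    literal_constant_on_loss: bool = False

    def __post_init__(self) -> None:
        if self.k_init < MIN_BID_USD:
            raise AuctionError(f"k_init must be >= {MIN_BID_USD}, got {self.k_init}")
        if self.b_rate < 0 or self.noise_sd < 0:
            raise AuctionError("b_rate and noise_sd must be non-negative")


@dataclass(frozen=True)
class RoboBidderState:
    """Evolving state: t_k counts only intervals the robo-bidder walked."""

    intervals_walked: int = 0
    last_bid: float | None = None
    last_won: bool = False


@dataclass(frozen=True)
class HumanAgentParams:
    """Generative parameters of a synthetic honest participant.

    ``b_true`` is the fatigue rate per *walked* minute; the honest strategy
    quotes k_true·exp(b_true·minutes_walked) plus bid noise.  The
    fixed-markup strategy (robustness checks only) adds a constant to the
    honest quote.
    """

    k_true: float                  # USD
    b_true: float                  # per walked minute
    bid_noise_sd: float = 0.0      # USD
    strategy: str = "honest"       # "honest" | "fixed-markup"
    markup_usd: float = 0.25
    #: When False, bids skip cent rounding (validation studies that need
    #: exact parameter recovery); live protocols always quantize.
    quantize: bool = True

    def __post_init__(self) -> None:
        if self.k_true < MIN_BID_USD:
            raise AuctionError(f"k_true must be >= {MIN_BID_USD}, got {self.k_true}")
        if self.b_true < 0 or self.bid_noise_sd < 0:
            raise AuctionError("b_true and bid_noise_sd must be non-negative")
        if self.strategy not in ("honest", "fixed-markup"):
            raise AuctionError(f"unknown strategy {self.strategy!r}")


@dataclass(frozen=True)
class HumanAgentState:
    minutes_walked: float = 0.0
    observed_clearing_prices: tuple[float, ...] = field(default_factory=tuple)


def robo_bid(
    params: RoboBidderParams, state: RoboBidderState, rng: np.random.Generator
) -> float:
    """Quote one robo-bidder price for the next auction, in USD."""
    if (
        params.literal_constant_on_loss
        and state.last_bid is not None
        and not state.last_won
    ):
        return state.last_bid
    deterministic = params.k_init * np.exp(params.b_rate * state.intervals_walked)
    noise = rng.normal(0.0, params.noise_sd) if params.noise_sd > 0 else 0.0
    return round_to_cents(deterministic + noise)


def advance_robo_state(
    state: RoboBidderState, won: bool, bid: float | None = None
) -> RoboBidderState:
    """Advance after one auction: t_k increments only on a win."""
    return replace(
        state,
        intervals_walked=state.intervals_walked + (1 if won else 0),
        last_bid=state.last_bid if bid is None else bid,
        last_won=won,
    )


def human_bid(
    params: HumanAgentParams, state: HumanAgentState, rng: np.random.Generator
) -> float:
    """Quote the synthetic participant's price to walk, in USD."""
    price = params.k_true * np.exp(params.b_true * state.minutes_walked)
    if params.strategy == "fixed-markup":
        price += params.markup_usd
    noise = rng.normal(0.0, params.bid_noise_sd) if params.bid_noise_sd > 0 else 0.0
    if not params.quantize:
        return max(price + noise, MIN_BID_USD)
    return round_to_cents(price + noise)


def advance_human_state(
    state: HumanAgentState,
    won: bool,
    clearing_price: float,
    interval_minutes: float = 2.0,
) -> HumanAgentState:
    """Advance after one auction.

    Walking time accrues only on a win; the disclosed clearing price is
    recorded either way (the participant always learns the winning bid).
    """
    return HumanAgentState(
        minutes_walked=state.minutes_walked + (interval_minutes if won else 0.0),
        observed_clearing_prices=state.observed_clearing_prices + (clearing_price,),
    )


def make_default_robo_cohort(
    n: int,
    rng: np.random.Generator,
    k_range: tuple[float, float] = DEFAULT_ROBO_K_RANGE,
    b_range: tuple[float, float] = DEFAULT_ROBO_B_RANGE,
    noise_sd: float = DEFAULT_ROBO_NOISE_SD,
) -> list[RoboBidderParams]:
    """Draw ``n`` robo-bidder parameter sets from a uniform prior.

    Defaults: k_init ~ U(0.40, 0.90) USD (cent-rounded), b_rate ~
    U(0.18, 0.32) per walked interval, noise SD $0.01.
    """
    if n < 1:
        raise AuctionError(f"need at least one robo-bidder, got n={n}")
    cohort = []
    for _ in range(n):
        k = round_to_cents(rng.uniform(*k_range))
        b = float(rng.uniform(*b_range))
        cohort.append(RoboBidderParams(k_init=k, b_rate=b, noise_sd=noise_sd))
    return cohort
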