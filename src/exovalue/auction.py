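"""Sealed-bid second-price (Vickrey) auction settlement.

Two variants are supported:

* **selling** (reverse): bidders compete to *sell* a service — the lowest
  bid wins and the winner is paid the second-lowest bid.  This is the form
  used to auction off 2-minute walking bouts.
* **buying** (forward): bidders compete to *buy* — the highest bid wins and
  the winner pays the second-highest bid.

In either variant the winner's own bid never sets the price, which makes
truthful bidding the dominant strategy.  Amounts are held in integer cents
internally so settlement is exact and free of float drift.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AuctionError",
    "SealedBid",
    "AuctionOutcome",
    "settle_reverse_vickrey",
    "settle_forward_vickrey",
    "usd_to_cents",
    "cents_to_usd",
    "expected_seller_payoff",
    "enumerate_competitor_vectors",
    "truthful_bidding_regret",
]

#: Smallest permissible bid: one cent.
MIN_BID_CENTS = 1


class AuctionError(ValueError):
    """An auction could not be settled (too few bids, invalid amounts...)."""


def usd_to_cents(amount: float) -> int:
    """Convert a dollar amount to integer cents (round half to even)."""
    return int(round(amount * 100))


def cents_to_usd(cents: int) -> float:
    return cents / 100.0


@dataclass(frozen=True)
class SealedBid:
    """One bidder's sealed offer, in integer cents."""

    bidder_id: str
    amount_cents: int

    def __post_init__(self) -> None:
        if self.amount_cents < MIN_BID_CENTS:
            raise AuctionError(
                f"bid of {self.amount_cents} cents from {self.bidder_id!r} "
                f"is below the {MIN_BID_CENTS}-cent minimum"
            )

    @classmethod
    def from_usd(cls, bidder_id: str, amount: float) -> "SealedBid":
        return cls(bidder_id, usd_to_cents(amount))

    @property
    def amount(self) -> float:
        """Bid amount in USD."""
        return cents_to_usd(self.amount_cents)


@dataclass(frozen=True)
class AuctionOutcome:
    """Settlement record of a single sealed-bid second-price auction.

    ``sorted_bids`` is ascending for the selling variant and descending for
    the buying variant, so the clearing price is always the amount of the
    second element.
    """

    winner_id: str
    clearing_price_cents: int
    sorted_bids: tuple[SealedBid, ...]
    variant: str  # "selling" | "buying"
    tie_broken: bool

    @property
    def clearing_price(self) -> float:
        return cents_to_usd(self.clearing_price_cents)


def _validate(bids: Sequence[SealedBid]) -> None:
    if len(bids) < 2:
        raise AuctionError(f"need at least 2 bids to settle, got {len(bids)}")
    ids = [b.bidder_id for b in bids]
    if len(set(ids)) != len(ids):
        raise AuctionError("duplicate bidder_id within one auction")


def _settle(
    bids: Sequence[SealedBid], rng: np.random.Generator, variant: str
) -> AuctionOutcome:
    _validate(bids)
    reverse = variant == "buying"
    ordered = sorted(bids, key=lambda b: b.amount_cents, reverse=reverse)
    best = ordered[0].amount_cents
    tied = [b for b in ordered if b.amount_cents == best]
    tie_broken = len(tied) > 1
    winner = tied[int(rng.integers(len(tied)))] if tie_broken else ordered[0]
    # Second element of the sorted multiset; equals the tied value on a tie.
    clearing = ordered[1].amount_cents
    return AuctionOutcome(
        winner_id=winner.bidder_id,
        clearing_price_cents=clearing,
        sorted_bids=tuple(ordered),
        variant=variant,
        tie_broken=tie_broken,
    )


def settle_reverse_vickrey(
    bids: Sequence[SealedBid], rng: np.random.Generator
) -> AuctionOutcome:
    """Settle a selling auction: lowest bid wins, second-lowest is paid.

    Ties for the lowest bid are broken uniformly at random via ``rng``.
    """
    return _settle(bids, rng, "selling")


def settle_forward_vickrey(
    bids: Sequence[SealedBid], rng: np.random.Generator
) -> AuctionOutcome:
    """Settle a buying auction: highest bid wins, second-highest is paid."""
    return _settle(bids, rng, "buying")


# ---------------------------------------------------------------------------
# Incentive-compatibility verification (selling variant)
# ---------------------------------------------------------------------------

def expected_seller_payoff(
    bid_cents: int, value_cents: int, competitor_cents: Sequence[int]
) -> float:
    """Exact expected payoff of one seller against fixed competitor bids.

    Payoff is ``clearing_price − value`` on a win and 0 otherwise; under a
    tie for the lowest bid the winner is uniform among the tied bidders and
    the clearing price equals the tied value, so the expectation is the
    winning payoff divided by the number of tied bidders.
    """
    m = min(competitor_cents)
    if bid_cents > m:
        return 0.0
    if bid_cents < m:
        return float(m - value_cents)
    n_tied = 1 + sum(1 for c in competitor_cents if c == m)
    return (m - value_cents) / n_tied


def enumerate_competitor_vectors(
    grid_cents: Sequence[int], max_competitors: int
) -> list[tuple[int, ...]]:
    """All competitor-bid multisets with 1..max_competitors bids on a grid."""
    out: list[tuple[int, ...]] = []
    for n in range(1, max_competitors + 1):
        out.extend(itertools.combinations_with_replacement(grid_cents, n))
    return out


def truthful_bidding_regret(
    value_grid_cents: Sequence[int],
    bid_grid_cents: Sequence[int],
    competitor_vectors: Iterable[tuple[int, ...]],
) -> float:
    """Maximum payoff gain of any deviation from truthful bidding.

    For every competitor multiset and every private value ``v`` on the value
    grid, compares the expected payoff of bidding exactly ``v`` against every
    alternative bid on the bid grid.  A return value ≤ 0 establishes, by
    exhaustive enumeration, that truthful bidding is a dominant strategy of
    the selling second-price rule on those grids.
    """
    bid_grid = np.asarray(bid_grid_cents, dtype=np.int64)
    value_grid = np.asarray(value_grid_cents, dtype=np.int64)
    worst = -np.inf
    for comps in competitor_vectors:
        m = min(comps)
        n_tied = 1 + sum(1 for c in comps if c == m)
        for v in value_grid:
            margin = float(m - v)
            # payoff(bid): margin if bid < m; margin/n_tied if bid == m; else 0
            payoffs = np.where(
                bid_grid < m, margin, np.where(bid_grid == m, margin / n_tied, 0.0)
            )
            truthful = expected_seller_payoff(int(v), int(v), comps)
            worst = max(worst, float(payoffs.max() - truthful))
    return worst
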