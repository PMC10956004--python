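"""Sequential-auction walking session simulator.

One session pits a single participant against ``n_robo`` computerized
opponents in back-to-back sealed-bid reverse Vickrey auctions, each selling
one 2-minute treadmill bout.  The session length is drawn uniformly between
50 and 70 minutes (so participants cannot wait out their opponents), giving
25–35 auctions.  The winner of each auction — the lowest bidder — walks the
interval and is paid the second-lowest bid; everyone else rests.  Only the
clearing price is disclosed to the participant after each auction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .agents import (
    HumanAgentParams,
    HumanAgentState,
    RoboBidderParams,
    RoboBidderState,
    advance_human_state,
    advance_robo_state,
    human_bid,
    robo_bid,
)
from .auction import AuctionError, SealedBid, settle_reverse_vickrey

__all__ = [
    "HUMAN_BIDDER_ID",
    "SessionConfig",
    "IntervalRecord",
    "SessionLog",
    "SessionSummary",
    "draw_session_duration",
    "run_session",
    "session_summary",
]

#: Fixed bidder_id used for the (simulated or live) human participant.
HUMAN_BIDDER_ID = "human"

CONDITIONS = ("walking-no-exo", "exo-powered", "exo-powered-off")


@dataclass(frozen=True)
class SessionConfig:
    interval_minutes: float = 2.0
    duration_lo: float = 50.0
    duration_hi: float = 70.0
    n_robo: int = 3
    condition: str = "walking-no-exo"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.duration_lo > self.duration_hi:
            raise AuctionError("duration_lo must be <= duration_hi")
        if self.interval_minutes <= 0:
            raise AuctionError("interval_minutes must be positive")
        if self.n_robo < 1:
            raise AuctionError("need at least one robo-bidder")


@dataclass(frozen=True)
class IntervalRecord:
    """One auction interval: all sealed bids and the settlement."""

    interval_index: int          # 1-based
    t_start: float               # minutes from session start
    bids: tuple[SealedBid, ...]
    winner_id: str
    clearing_price: float        # USD
    human_walked: bool


@dataclass(frozen=True)
class SessionLog:
    """Complete interval-by-interval record of one session."""

    config: SessionConfig
    scheduled_minutes: float
    records: tuple[IntervalRecord, ...]
    human_earnings: float        # USD, sum of clearing prices on wins
    human_walk_minutes: float
    session_id: str = "session"
    subject_id: str = "S01"

    @property
    def n_auctions(self) -> int:
        return len(self.records)

    @property
    def condition(self) -> str:
        return self.config.condition

    def human_bids(self) -> list[tuple[float, float]]:
        """(t_start, bid_usd) pairs for the participant, all intervals."""
        out = []
        for rec in self.records:
            for bid in rec.bids:
                if bid.bidder_id == HUMAN_BIDDER_ID:
                    out.append((rec.t_start, bid.amount))
        return out


@dataclass(frozen=True)
class SessionSummary:
    n_auctions: int
    wins: int
    win_rate: float
    walk_minutes: float
    earnings: float
    mean_bid: float


def draw_session_duration(config: SessionConfig, rng: np.random.Generator) -> float:
    """Draw the randomized session length, uniform on [lo, hi] minutes."""
    return float(rng.uniform(config.duration_lo, config.duration_hi))


def run_session(
    human: HumanAgentParams,
    robos: list[RoboBidderParams],
    config: SessionConfig,
    rng: np.random.Generator,
    session_id: str = "session",
    subject_id: str = "S01",
) -> SessionLog:
    """Simulate one full session and return its complete bid log.

    The number of auctions is floor(scheduled / interval): a bid buys a full
    interval, so a partial trailing interval is dropped.  Each interval the
    participant and every robo-bidder submit sealed bids; the reverse
    Vickrey rule settles; only the winner's state walks forward.  The
    participant observes the clearing price every interval; robo-bidders
    observe only their own win/loss.
    """
    if len(robos) < 1:
        raise AuctionError("need at least one robo-bidder")
    scheduled = draw_session_duration(config, rng)
    n_auctions = math.floor(scheduled / config.interval_minutes)

    human_state = HumanAgentState()
    robo_states = [RoboBidderState() for _ in robos]
    records: list[IntervalRecord] = []
    earnings = 0.0

    for i in range(1, n_auctions + 1):
        t_start = (i - 1) * config.interval_minutes
        bids = [SealedBid.from_usd(HUMAN_BIDDER_ID, human_bid(human, human_state, rng))]
        for j, (params, state) in enumerate(zip(robos, robo_states)):
            bids.append(SealedBid.from_usd(f"robo{j + 1}", robo_bid(params, state, rng)))
        outcome = settle_reverse_vickrey(bids, rng)
        human_won = outcome.winner_id == HUMAN_BIDDER_ID
        if human_won:
            earnings += outcome.clearing_price
        human_state = advance_human_state(
            human_state, human_won, outcome.clearing_price, config.interval_minutes
        )
        robo_states = [
            advance_robo_state(state, outcome.winner_id == f"robo{j + 1}", bid.amount)
            for j, (state, bid) in enumerate(zip(robo_states, bids[1:]))
        ]
        records.append(
            IntervalRecord(
                interval_index=i,
                t_start=t_start,
                bids=tuple(bids),
                winner_id=outcome.winner_id,
                clearing_price=outcome.clearing_price,
                human_walked=human_won,
            )
        )

    return SessionLog(
        config=config,
        scheduled_minutes=scheduled,
        records=tuple(records),
        human_earnings=round(earnings, 2),
        human_walk_minutes=human_state.minutes_walked,
        session_id=session_id,
        subject_id=subject_id,
    )


def session_summary(log: SessionLog) -> SessionSummary:
    """Wins, win rate, walking time, earnings and mean bid for one log."""
    if not log.records:
        raise AuctionError("cannot summarize an empty session log")
    wins = sum(rec.human_walked for rec in log.records)
    bids = [amount for _, amount in log.human_bids()]
    return SessionSummary(
        n_auctions=log.n_auctions,
        wins=wins,
        win_rate=wins / log.n_auctions,
        walk_minutes=log.human_walk_minutes,
        earnings=log.human_earnings,
        mean_bid=float(np.mean(bids)),
    )
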