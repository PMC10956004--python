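"""Shared fixtures and handcrafted session-log builders."""

from __future__ import annotations

import numpy as np
import pytest

from exovalue.auction import SealedBid
from exovalue.session import HUMAN_BIDDER_ID, IntervalRecord, SessionConfig, SessionLog


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def build_log(
    human_bids: list[float],
    wins: list[bool],
    condition: str = "walking-no-exo",
    interval_minutes: float = 2.0,
    session_id: str = "fixture",
    subject_id: str = "S01",
) -> SessionLog:
    """Construct a consistent SessionLog from a human bid/win sequence.

    A single synthetic robo opponent is placed one dollar above the human
    bid when the human wins and one cent below when they lose, so the
    second-price settlement semantics hold exactly.
    """
    assert len(human_bids) == len(wins)
    records = []
    earnings = 0.0
    for i, (bid, won) in enumerate(zip(human_bids, wins), start=1):
        if won:
            robo_amount = round(bid + 1.00, 2)
            clearing = robo_amount  # second-lowest
            winner = HUMAN_BIDDER_ID
            earnings += clearing
        else:
            robo_amount = max(round(bid - 0.01, 2), 0.01)
            clearing = bid  # human's bid is second-lowest
            winner = "robo1"
        records.append(
            IntervalRecord(
                interval_index=i,
                t_start=(i - 1) * interval_minutes,
                bids=(
                    SealedBid.from_usd(HUMAN_BIDDER_ID, bid),
                    SealedBid.from_usd("robo1", robo_amount),
                ),
                winner_id=winner,
                clearing_price=clearing,
                human_walked=won,
            )
        )
    n = len(records)
    return SessionLog(
        config=SessionConfig(
            interval_minutes=interval_minutes,
            duration_lo=n * interval_minutes,
            duration_hi=n * interval_minutes,
            condition=condition,
        ),
        scheduled_minutes=n * interval_minutes,
        records=tuple(records),
        human_earnings=round(earnings, 2),
        human_walk_minutes=interval_minutes * sum(wins),
        session_id=session_id,
        subject_id=subject_id,
    )


def curve_bids(k: float, b: float, wins: list[bool], interval: float = 2.0) -> list[float]:
    """Noiseless honest bids k·exp(b·w_i) with w_i = walked minutes before i."""
    bids, w = [], 0.0
    for won in wins:
        bids.append(k * np.exp(b * w))
        if won:
            w += interval
    return bids
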