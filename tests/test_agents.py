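"""Robo-bidder and honest-human bid generation and state updates."""

from __future__ import annotations

import numpy as np
import pytest

from exovalue.agents import (
    HumanAgentParams,
    HumanAgentState,
    RoboBidderParams,
    RoboBidderState,
    advance_human_state,
    advance_robo_state,
    human_bid,
    make_default_robo_cohort,
    robo_bid,
)
from exovalue.auction import AuctionError


class TestRoboBid:
    def test_initial_price_at_zero_intervals(self, rng):
        params = RoboBidderParams(k_init=0.60, b_rate=0.08, noise_sd=0.0)
        assert robo_bid(params, RoboBidderState(), rng) == pytest.approx(0.60)

    def test_exponential_growth_cent_rounded(self, rng):
        # 0.60 * e^0.8 = 1.33532... -> 1.34
        params = RoboBidderParams(k_init=0.60, b_rate=0.08, noise_sd=0.0)
        state = RoboBidderState(intervals_walked=10)
        assert robo_bid(params, state, rng) == pytest.approx(1.34)

    def test_noise_contract_monte_carlo(self):
        """Mean ~ deterministic value, SD ~ $0.01, over 1e5 draws."""
        rng = np.random.default_rng(99)
        params = RoboBidderParams(k_init=0.60, b_rate=0.08, noise_sd=0.01)
        state = RoboBidderState(intervals_walked=10)
        det = 0.60 * np.exp(0.8)
        draws = np.array([robo_bid(params, state, rng) for _ in range(100_000)])
        assert abs(draws.mean() - det) < 0.001
        assert abs(draws.std() - 0.01) < 0.001  # within 10% of $0.01

    def test_deterministic_part_depends_only_on_walked_intervals(self, rng):
        params = RoboBidderParams(k_init=0.75, b_rate=0.2, noise_sd=0.0)
        state = RoboBidderState(intervals_walked=4, last_bid=9.99, last_won=True)
        assert robo_bid(params, state, rng) == robo_bid(params, state, rng)

    def test_nondecreasing_in_walked_intervals(self, rng):
        params = RoboBidderParams(k_init=0.50, b_rate=0.15, noise_sd=0.0)
        bids = [
            robo_bid(params, RoboBidderState(intervals_walked=t), rng)
            for t in range(12)
        ]
        assert all(b2 >= b1 for b1, b2 in zip(bids, bids[1:]))

    def test_literal_constant_mode_reuses_exact_losing_bid(self, rng):
        params = RoboBidderParams(
            k_init=0.60, b_rate=0.08, noise_sd=0.01, literal_constant_on_loss=True
        )
        state = RoboBidderState(intervals_walked=3, last_bid=0.77, last_won=False)
        assert robo_bid(params, state, rng) == 0.77
        assert robo_bid(params, state, rng) == 0.77


class TestRoboState:
    def test_win_increments_walked_intervals(self):
        assert advance_robo_state(RoboBidderState(3), won=True).intervals_walked == 4

    def test_loss_freezes_walked_intervals(self):
        # the deterministic price of a losing robo-bidder stays constant
        assert advance_robo_state(RoboBidderState(3), won=False).intervals_walked == 3

    def test_five_wins_from_zero(self):
        state = RoboBidderState()
        for _ in range(5):
            state = advance_robo_state(state, won=True)
        assert state.intervals_walked == 5


class TestHumanBid:
    def test_initial_price(self, rng):
        params = HumanAgentParams(k_true=0.50, b_true=0.05)
        assert human_bid(params, HumanAgentState(), rng) == pytest.approx(0.50)

    def test_fatigue_after_twenty_walked_minutes(self, rng):
        # 0.50 * e^1.0 = 1.35914 -> 1.36
        params = HumanAgentParams(k_true=0.50, b_true=0.05)
        state = HumanAgentState(minutes_walked=20.0)
        assert human_bid(params, state, rng) == pytest.approx(1.36)

    def test_stateless_deterministic_part(self, rng):
        params = HumanAgentParams(k_true=0.50, b_true=0.05)
        state = HumanAgentState(minutes_walked=8.0)
        assert human_bid(params, state, rng) == human_bid(params, state, rng)

    def test_honest_noiseless_bids_lie_on_curve(self, rng):
        params = HumanAgentParams(k_true=0.42, b_true=0.03, quantize=False)
        for w in (0.0, 2.0, 10.0, 30.0):
            got = human_bid(params, HumanAgentState(minutes_walked=w), rng)
            assert got == pytest.approx(0.42 * np.exp(0.03 * w), rel=1e-12)

    def test_fixed_markup_strategy_adds_constant(self, rng):
        honest = HumanAgentParams(k_true=0.50, b_true=0.0)
        markup = HumanAgentParams(
            k_true=0.50, b_true=0.0, strategy="fixed-markup", markup_usd=0.25
        )
        state = HumanAgentState()
        assert human_bid(markup, state, rng) - human_bid(honest, state, rng) == (
            pytest.approx(0.25)
        )


class TestHumanState:
    def test_win_accrues_two_minutes(self):
        state = advance_human_state(HumanAgentState(), won=True, clearing_price=0.75)
        assert state.minutes_walked == 2.0
        assert state.observed_clearing_prices == (0.75,)

    def test_loss_accrues_no_walking_but_observes_price(self):
        state = advance_human_state(HumanAgentState(), won=False, clearing_price=0.60)
        assert state.minutes_walked == 0.0
        assert state.observed_clearing_prices == (0.60,)

    def test_seven_wins_in_twelve_auctions(self):
        state = HumanAgentState()
        for i in range(12):
            state = advance_human_state(state, won=(i % 12 < 7), clearing_price=1.0)
        assert state.minutes_walked == 14.0
        assert len(state.observed_clearing_prices) == 12


class TestDefaultRoboCohort:
    def test_three_distinct_sets_in_realistic_range(self, rng):
        cohort = make_default_robo_cohort(3, rng)
        assert len(cohort) == 3
        assert len(set((p.k_init, p.b_rate) for p in cohort)) == 3
        assert all(0.10 <= p.k_init <= 5.00 for p in cohort)

    def test_deterministic_under_fixed_seed(self):
        a = make_default_robo_cohort(3, np.random.default_rng(5))
        b = make_default_robo_cohort(3, np.random.default_rng(5))
        assert a == b

    def test_single_competitor_is_valid(self, rng):
        assert len(make_default_robo_cohort(1, rng)) == 1

    def test_rejects_empty_cohort(self, rng):
        with pytest.raises(AuctionError):
            make_default_robo_cohort(0, rng)


def test_invalid_parameters_rejected():
    with pytest.raises(AuctionError):
        RoboBidderParams(k_init=0.0, b_rate=0.1)
    with pytest.raises(AuctionError):
        RoboBidderParams(k_init=0.5, b_rate=-0.1)
    with pytest.raises(AuctionError):
        HumanAgentParams(k_true=0.5, b_true=0.03, strategy="adversarial")
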