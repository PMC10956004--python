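"""Synthetic cohort generation, ground truth, and study analysis."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import exovalue as ev
from exovalue.cohort import (
    BASELINE_CONDITION,
    exact_cumulative_by_key,
    exact_cumulative_price,
    paper_design,
    true_mv,
    validation_design,
)

from conftest import build_log, curve_bids


class TestTrueMv:
    def test_identical_parameters_give_zero(self):
        assert true_mv((0.5, 0.04), (0.5, 0.04)) == 0.0

    def test_known_pair(self):
        assert true_mv((0.50, 0.04), (0.50, 0.03)) == pytest.approx(16.1, abs=0.05)

    def test_doubling_k_gives_minus_hundred_percent(self):
        assert true_mv((0.5, 0.04), (1.0, 0.04)) == pytest.approx(-100.0)


class TestSimulateCohort:
    def test_paper_design_counts(self):
        rng = np.random.default_rng(0)
        logs, truth = ev.simulate_cohort(paper_design(), rng)
        assert len(logs) == 42  # 16 baseline + 16 powered + 10 powered-off
        by_cond = {}
        for log in logs:
            by_cond[log.condition] = by_cond.get(log.condition, 0) + 1
        assert by_cond == {
            "walking-no-exo": 16,
            "exo-powered": 16,
            "exo-powered-off": 10,
        }
        assert len(truth.params) == 42

    def test_repeaters_add_seven_baseline_sessions(self):
        rng = np.random.default_rng(0)
        logs, _ = ev.simulate_cohort(paper_design(repeaters=True), rng)
        assert len(logs) == 49  # 3 subjects x2 extra + 1 subject x1 extra
        baseline = [log for log in logs if log.condition == BASELINE_CONDITION]
        per_subject = {}
        for log in baseline:
            per_subject[log.subject_id] = per_subject.get(log.subject_id, 0) + 1
        assert sorted(per_subject.values(), reverse=True) == [3, 3, 3, 2] + [1] * 12

    def test_repeat_sessions_have_distinct_ids_and_distinct_draws(self):
        spec = dataclasses.replace(
            paper_design(),
            n_subjects=1,
            conditions=(ev.ConditionSpec(BASELINE_CONDITION, repeat_sessions=3),),
        )
        rng = np.random.default_rng(4)
        logs, _ = ev.simulate_cohort(spec, rng)
        assert len(logs) == 3
        assert len({log.session_id for log in logs}) == 3
        assert len({log.scheduled_minutes for log in logs}) == 3

    def test_fixed_seed_reproduces_exactly(self):
        a, _ = ev.simulate_cohort(paper_design(), np.random.default_rng(9))
        b, _ = ev.simulate_cohort(paper_design(), np.random.default_rng(9))
        assert a == b

    def test_ground_truth_self_mv_is_zero(self):
        rng = np.random.default_rng(1)
        _, truth = ev.simulate_cohort(paper_design(), rng)
        for (sid, cond) in list(truth.params)[:5]:
            assert truth.true_mv_percent(sid, cond, cond) == pytest.approx(0.0)


class TestExactCumulative:
    def test_all_wins_matches_closed_form(self):
        wins = [True] * 30
        log = build_log(curve_bids(0.5, 0.04, wins), wins)
        got = exact_cumulative_price(log, 0.5, 0.04)
        assert got == pytest.approx(
            ev.cumulative_price_closed_form(0.5, 0.04), rel=1e-12
        )

    def test_no_wins_is_flat_price(self):
        wins = [False] * 30
        log = build_log([0.5] * 30, wins)
        assert exact_cumulative_price(log, 0.5, 0.04) == pytest.approx(15.0)

    def test_interleaved_schedule_between_extremes(self):
        wins = [True, False] * 15
        log = build_log(curve_bids(0.5, 0.04, wins), wins)
        got = exact_cumulative_price(log, 0.5, 0.04)
        assert ev.cumulative_price_closed_form(0.5, 0.0) < got
        assert got < ev.cumulative_price_closed_form(0.5, 0.04)


class TestRecovery:
    def test_validation_cohort_recovers_mv_within_one_point(self):
        """Dominant subjects (c = 1): the pipeline MV%% matches the
        closed-form ground truth to within one point per subject."""
        rng = np.random.default_rng(13)
        logs, truth = ev.simulate_cohort(validation_design(), rng)
        assert all(s.win_rate == 1.0 for s in truth.sessions)
        report = ev.analyze_study(logs, responder_threshold_pct=9.4)
        pairs = {
            "exo_plus_assistance": (BASELINE_CONDITION, "exo-powered"),
            "unpowered_exo": (BASELINE_CONDITION, "exo-powered-off"),
        }
        for name, (bc, cc) in pairs.items():
            for sid, res in report.mv_results[name].items():
                expected = true_mv(truth.params[(sid, bc)], truth.params[(sid, cc)])
                assert res.mv_percent == pytest.approx(expected, abs=1.0)

    def test_noiseless_default_cohort_tracks_exact_path_truth(self):
        """At the realistic design the fitted cumulative tracks the exact
        generative path integral closely even though the closed form in
        c*t does not hold exactly."""
        spec = paper_design(bid_noise_sd=0.0)
        rng = np.random.default_rng(3)
        logs, truth = ev.simulate_cohort(spec, rng)
        cum_true = exact_cumulative_by_key(logs, truth)
        rel_errs = []
        for log in logs:
            fit = ev.fit_price_to_walk(log)
            est = ev.cumulative_price(fit)
            rel_errs.append(abs(est - cum_true[(log.subject_id, log.condition)])
                            / cum_true[(log.subject_id, log.condition)])
        assert float(np.mean(rel_errs)) < 0.02

    def test_repeat_variability_shrinks_with_bid_noise(self):
        """Intra-subject cumulative-price spread rises with bid noise,
        exercising the MDC pipeline end to end."""
        spreads = {}
        for noise in (0.0, 0.10):
            spec = dataclasses.replace(
                paper_design(bid_noise_sd=noise),
                n_subjects=4,
                conditions=(
                    ev.ConditionSpec(BASELINE_CONDITION, repeat_sessions=3),
                ),
            )
            logs, _ = ev.simulate_cohort(spec, np.random.default_rng(30))
            cums = {}
            for log in logs:
                fit = ev.fit_price_to_walk(log)
                cums.setdefault(log.subject_id, []).append(ev.cumulative_price(fit))
            rel = ev.repeatability(cums)
            spreads[noise] = rel.intra_subject_sd_pct
        assert spreads[0.10] > spreads[0.0]


class TestAnalyzeStudy:
    def test_end_to_end_report_structure(self):
        rng = np.random.default_rng(42)
        logs, _ = ev.simulate_cohort(paper_design(repeaters=True), rng)
        report = ev.analyze_study(logs)
        assert set(report.summaries) >= {"exo_plus_assistance"}
        assert report.summaries["exo_plus_assistance"].n == 16
        assert report.summaries["unpowered_exo"].n == 10
        assert report.reliability is not None
        assert report.reliability.mdc_pct is not None
        assert report.responder_threshold_pct == report.reliability.mdc_pct
        labels = [r.label for r in report.responders]
        assert len(labels) == 16
        counts = {x: labels.count(x) for x in ("positive", "negative", "indeterminate")}
        assert sum(counts.values()) == 16

    def test_without_repeats_threshold_must_come_from_caller(self):
        rng = np.random.default_rng(42)
        logs, _ = ev.simulate_cohort(paper_design(), rng)
        report = ev.analyze_study(logs, responder_threshold_pct=9.4)
        assert report.reliability is None
        assert report.responder_threshold_pct == 9.4
        assert len(report.responders) == 16

    def test_rejects_empty_input(self):
        with pytest.raises(ev.AuctionError):
            ev.analyze_study([])
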