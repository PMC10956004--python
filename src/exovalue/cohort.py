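"""Synthetic study generator with known ground truth, and study analysis.

Generates complete synthetic studies — subjects × conditions × repeat
sessions — so the whole pipeline (simulate → fit → MV → cohort stats) is
testable end to end without any external data.  Each synthetic subject is
an honest bidder whose price to walk is k_true·exp(b_true·w) in walked
minutes w; condition effects act multiplicatively on the fatigue rate
b_true (a harder condition raises it, assistance lowers it), with
per-subject lognormal heterogeneity creating a realistic responder spread.

Ground truth records the generating parameters and, after simulation, each
session's realized win rate, so true MVs can be computed with the same
composite-rate semantics (β = b·c) the estimation pipeline uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .agents import (
    DEFAULT_ROBO_B_RANGE,
    DEFAULT_ROBO_K_RANGE,
    DEFAULT_ROBO_NOISE_SD,
    HumanAgentParams,
    make_default_robo_cohort,
)
from .auction import AuctionError
from .fitting import PriceToWalkFit, fit_price_to_walk
from .session import SessionConfig, SessionLog, run_session
from .stats import (
    CohortSummary,
    ReliabilityResult,
    ResponderLabel,
    classify_responders,
    one_sample_t,
    reliability_analysis,
)
from .value import (
    DEFAULT_BOUNDS,
    IntegrationBounds,
    MarginalValueResult,
    cumulative_price,
    cumulative_price_closed_form,
    marginal_value,
)

__all__ = [
    "ConditionSpec",
    "CohortSpec",
    "SessionTruth",
    "GroundTruth",
    "true_mv",
    "simulate_cohort",
    "paper_design",
    "validation_design",
    "exact_cumulative_price",
    "exact_cumulative_by_key",
    "StudyReport",
    "analyze_study",
]

BASELINE_CONDITION = "walking-no-exo"


@dataclass(frozen=True)
class ConditionSpec:
    """One walking condition and its effect on subject parameters."""

    name: str
    b_multiplier: float = 1.0
    k_multiplier: float = 1.0
    #: How many subjects (taken from the front of the roster) experience
    #: this condition; None means everyone.
    n_participants: int | None = None
    repeat_sessions: int = 1

    def __post_init__(self) -> None:
        if self.b_multiplier <= 0 or self.k_multiplier <= 0:
            raise AuctionError("condition multipliers must be positive")
        if self.repeat_sessions < 1:
            raise AuctionError("repeat_sessions must be >= 1")


def _default_conditions() -> tuple[ConditionSpec, ...]:
    return (
        ConditionSpec(BASELINE_CONDITION, b_multiplier=1.0),
        ConditionSpec("exo-powered", b_multiplier=0.93),
        ConditionSpec("exo-powered-off", b_multiplier=1.35, n_participants=10),
    )


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic study.

    Subject parameters are drawn uniformly from ``k_range`` (USD) and
    ``b_range`` (per walked minute).  ``condition_jitter_sd`` is the σ of a
    lognormal multiplier applied per subject × non-baseline condition on
    top of the condition's b_multiplier, producing between-subject spread
    in condition response.  ``baseline_repeats`` lists (subject_index,
    extra_sessions) pairs adding repeat baseline sessions for reliability.
    """

    n_subjects: int = 16
    conditions: tuple[ConditionSpec, ...] = field(default_factory=_default_conditions)
    k_range: tuple[float, float] = (0.30, 0.90)
    b_range: tuple[float, float] = (0.025, 0.055)
    condition_jitter_sd: float = 0.35
    bid_noise_sd: float = 0.05
    n_robo: int = 3
    baseline_repeats: tuple[tuple[int, int], ...] = ()
    robo_k_range: tuple[float, float] = DEFAULT_ROBO_K_RANGE
    robo_b_range: tuple[float, float] = DEFAULT_ROBO_B_RANGE
    robo_noise_sd: float = DEFAULT_ROBO_NOISE_SD

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise AuctionError("need at least one subject")
        if not self.conditions:
            raise AuctionError("need at least one condition")


@dataclass(frozen=True)
class SessionTruth:
    """Generating parameters and realized win rate of one session."""

    subject_id: str
    condition: str
    repeat: int          # 0-based repeat index within subject × condition
    k_true: float
    b_true: float
    win_rate: float


@dataclass
class GroundTruth:
    """Per-subject × condition generating parameters with realized win rates."""

    params: dict[tuple[str, str], tuple[float, float]]
    sessions: list[SessionTruth] = field(default_factory=list)

    def subjects_in(self, condition: str) -> list[str]:
        return sorted({s for (s, c) in self.params if c == condition})

    def mean_win_rate(self, subject_id: str, condition: str) -> float:
        rates = [
            s.win_rate
            for s in self.sessions
            if s.subject_id == subject_id and s.condition == condition
        ]
        if not rates:
            raise AuctionError(f"no sessions for {subject_id!r} / {condition!r}")
        return float(np.mean(rates))

    def true_mv_percent(
        self,
        subject_id: str,
        base_condition: str,
        comp_condition: str,
        bounds: IntegrationBounds = DEFAULT_BOUNDS,
        use_win_rate: bool = True,
    ) -> float:
        """Ground-truth MV% implied by the generating parameters.

        With ``use_win_rate`` the curve rates are b_true scaled by the
        session's realized win rate — the same composite-rate convention
        the estimation pipeline applies — so the comparison with
        pipeline output is like for like.
        """
        k1, b1 = self.params[(subject_id, base_condition)]
        k2, b2 = self.params[(subject_id, comp_condition)]
        if use_win_rate:
            b1 = b1 * self.mean_win_rate(subject_id, base_condition)
            b2 = b2 * self.mean_win_rate(subject_id, comp_condition)
        return true_mv((k1, b1), (k2, b2), bounds)


def true_mv(
    params_base: tuple[float, float],
    params_cond: tuple[float, float],
    bounds: IntegrationBounds = DEFAULT_BOUNDS,
) -> float:
    """Closed-form MV% between two (k, rate) parameter pairs.

    100 · (∫base − ∫cond) / ∫base with analytic exponential integrals.
    """
    k1, b1 = params_base
    k2, b2 = params_cond
    cum1 = cumulative_price_closed_form(k1, b1, bounds)
    cum2 = cumulative_price_closed_form(k2, b2, bounds)
    return 100.0 * (cum1 - cum2) / cum1


def simulate_cohort(
    spec: CohortSpec, rng: np.random.Generator
) -> tuple[list[SessionLog], GroundTruth]:
    """Simulate every subject × condition × repeat session of a study.

    Each session gets a fresh robo-bidder cohort drawn from the default
    prior.  The returned GroundTruth carries the generating parameters and
    realized win rates for every log.
    """
    extra_repeats = dict(spec.baseline_repeats)
    subject_ids = [f"S{i + 1:02d}" for i in range(spec.n_subjects)]
    logs: list[SessionLog] = []
    truth = GroundTruth(params={})

    for idx, sid in enumerate(subject_ids):
        k_true = float(rng.uniform(*spec.k_range))
        b_true = float(rng.uniform(*spec.b_range))
        for cond in spec.conditions:
            if cond.n_participants is not None and idx >= cond.n_participants:
                continue
            b_mult = cond.b_multiplier
            if cond.name != BASELINE_CONDITION and spec.condition_jitter_sd > 0:
                b_mult *= float(
                    np.exp(rng.normal(0.0, spec.condition_jitter_sd))
                )
            k_cond = k_true * cond.k_multiplier
            b_cond = b_true * b_mult
            truth.params[(sid, cond.name)] = (k_cond, b_cond)
            human = HumanAgentParams(
                k_true=k_cond, b_true=b_cond, bid_noise_sd=spec.bid_noise_sd
            )
            n_sessions = cond.repeat_sessions
            if cond.name == BASELINE_CONDITION:
                n_sessions += extra_repeats.get(idx, 0)
            for rep in range(n_sessions):
                robos = make_default_robo_cohort(
                    spec.n_robo,
                    rng,
                    k_range=spec.robo_k_range,
                    b_range=spec.robo_b_range,
                    noise_sd=spec.robo_noise_sd,
                )
                config = SessionConfig(condition=cond.name, n_robo=spec.n_robo)
                log = run_session(
                    human,
                    robos,
                    config,
                    rng,
                    session_id=f"{sid}-{cond.name}-r{rep}",
                    subject_id=sid,
                )
                logs.append(log)
                wins = sum(rec.human_walked for rec in log.records)
                truth.sessions.append(
                    SessionTruth(
                        subject_id=sid,
                        condition=cond.name,
                        repeat=rep,
                        k_true=k_cond,
                        b_true=b_cond,
                        win_rate=wins / log.n_auctions,
                    )
                )
    return logs, truth


def paper_design(
    repeaters: bool = False, bid_noise_sd: float = 0.05
) -> CohortSpec:
    """The study design preset: 16 + 16 + 10 sessions.

    All 16 subjects walk the baseline and powered conditions; the first 10
    also walk with the device powered off.  With ``repeaters``, four of the
    remaining subjects repeat the baseline (three twice more, one once) so
    test–retest reliability and the MDC can be estimated.
    """
    baseline_repeats = (((10, 2), (11, 2), (12, 2), (13, 1)) if repeaters else ())
    spec = CohortSpec(bid_noise_sd=bid_noise_sd, baseline_repeats=baseline_repeats)
    return spec


def validation_design(
    n_subjects: int = 16, bid_noise_sd: float = 0.0
) -> CohortSpec:
    """A pipeline-validation design with dominant (always-winning) subjects.

    Robo-bidder opening prices are set far above any subject price, so the
    subject wins every auction (win rate c = 1) and their bids lie exactly
    on the generative curve k·exp(b·t), up to cent rounding and any bid
    noise.  In this regime the closed-form ``true_mv`` on the generating
    parameters is the exact estimand, which makes the design suitable for
    parameter-recovery and bias studies.  Subject fatigue rates are kept
    modest and condition effects deterministic so bids stay below the robo
    floor for a full 70-minute session.
    """
    conditions = (
        ConditionSpec(BASELINE_CONDITION, b_multiplier=1.0),
        ConditionSpec("exo-powered", b_multiplier=0.93),
        ConditionSpec("exo-powered-off", b_multiplier=1.35, n_participants=10),
    )
    return CohortSpec(
        n_subjects=n_subjects,
        conditions=conditions,
        k_range=(0.30, 0.90),
        b_range=(0.015, 0.035),
        condition_jitter_sd=0.0,
        bid_noise_sd=bid_noise_sd,
        robo_k_range=(40.0, 60.0),
        robo_b_range=(0.0, 0.0),
        robo_noise_sd=0.0,
    )


def exact_cumulative_price(
    log: SessionLog,
    k_true: float,
    b_true: float,
    bounds: IntegrationBounds = DEFAULT_BOUNDS,
) -> float:
    """Exact window integral of the generative price path for one session.

    The subject's true price at session time t is k·exp(b·w(t)), where the
    walked time w(t) is piecewise linear in t — rising during walked
    intervals, flat during rests.  Integrating that path over the window
    gives the exact cumulative price the fitted exponential estimates; it
    reduces to the closed form k/β·(e^{βt₂}−e^{βt₁}) only when wins are
    perfectly interleaved (w = c·t).
    """
    total = 0.0
    w = 0.0
    dt = log.config.interval_minutes
    for rec in log.records:
        t0, t1 = rec.t_start, rec.t_start + dt
        if t1 <= bounds.t1:
            if rec.human_walked:
                w += dt
            continue
        if t0 >= bounds.t2:
            break
        lo, hi = max(t0, bounds.t1), min(t1, bounds.t2)
        w_at_lo = w + (lo - t0 if rec.human_walked else 0.0)
        if rec.human_walked:
            if b_true > 0:
                total += (k_true / b_true) * (
                    np.exp(b_true * (w_at_lo + hi - lo)) - np.exp(b_true * w_at_lo)
                )
            else:
                total += k_true * (hi - lo)
            w += dt
        else:
            total += k_true * np.exp(b_true * w_at_lo) * (hi - lo)
    return float(total)


def exact_cumulative_by_key(
    logs: Sequence[SessionLog],
    truth: GroundTruth,
    bounds: IntegrationBounds = DEFAULT_BOUNDS,
) -> dict[tuple[str, str], float]:
    """Exact generative cumulative price per subject × condition.

    Repeat sessions are averaged, mirroring the estimation pipeline.
    """
    acc: dict[tuple[str, str], list[float]] = {}
    for log in logs:
        key = (log.subject_id, log.condition)
        k, b = truth.params[key]
        acc.setdefault(key, []).append(exact_cumulative_price(log, k, b, bounds))
    return {key: float(np.mean(vals)) for key, vals in acc.items()}


# ---------------------------------------------------------------------------
# End-to-end analysis of a set of session logs
# ---------------------------------------------------------------------------

@dataclass
class StudyReport:
    """Everything the pipeline computes from a set of session logs."""

    fits: dict[tuple[str, str, int], PriceToWalkFit]
    cumulative: dict[tuple[str, str], float]       # mean over repeats, USD
    mv_results: dict[str, dict[str, MarginalValueResult]]  # comparison -> subject -> MV
    summaries: dict[str, CohortSummary]
    reliability: ReliabilityResult | None
    responders: list[ResponderLabel]
    responder_threshold_pct: float | None
    bounds: IntegrationBounds

    def mv_percents(self, comparison: str) -> dict[str, float]:
        return {
            sid: res.mv_percent for sid, res in self.mv_results[comparison].items()
        }


#: Named condition pairs analyzed by default: comparison name ->
#: (baseline condition of the pair, comparison condition).
DEFAULT_COMPARISONS: Mapping[str, tuple[str, str]] = {
    "exo_plus_assistance": (BASELINE_CONDITION, "exo-powered"),
    "unpowered_exo": (BASELINE_CONDITION, "exo-powered-off"),
    "assistance_alone": ("exo-powered-off", "exo-powered"),
}


def analyze_study(
    logs: Sequence[SessionLog],
    bounds: IntegrationBounds = DEFAULT_BOUNDS,
    confidence: float = 0.95,
    responder_threshold_pct: float | None = None,
    comparisons: Mapping[str, tuple[str, str]] = DEFAULT_COMPARISONS,
) -> StudyReport:
    """Run fit → cumulative price → MV → cohort stats on session logs.

    Repeat sessions of a subject × condition are fitted separately; their
    cumulative prices are averaged for MV computation and feed the
    repeatability/MDC analysis.  The responder threshold defaults to the
    computed MDC when repeats are present, else must be supplied.
    """
    if not logs:
        raise AuctionError("no session logs to analyze")

    fits: dict[tuple[str, str, int], PriceToWalkFit] = {}
    cums: dict[tuple[str, str], list[float]] = {}
    for log in logs:
        key2 = (log.subject_id, log.condition)
        rep = sum(1 for (s, c, _) in fits if (s, c) == key2)
        fit = fit_price_to_walk(log)
        fits[(log.subject_id, log.condition, rep)] = fit
        cums.setdefault(key2, []).append(cumulative_price(fit, bounds))

    cumulative = {key: float(np.mean(v)) for key, v in cums.items()}

    # Mean-cumulative fits are not averaged directly; MV uses each pair's
    # first-session fit unless repeats exist, in which case the repeat
    # cumulative mean replaces the baseline cumulative via a rescaled fit.
    def _fit_for(subject: str, condition: str) -> PriceToWalkFit:
        first = fits[(subject, condition, 0)]
        mean_cum = cumulative[(subject, condition)]
        own_cum = cumulative_price(first, bounds)
        if own_cum == 0 or abs(mean_cum - own_cum) < 1e-12:
            return first
        # Rescale k so the fit's cumulative equals the repeat mean (the
        # integral is linear in k); the rate is left at the first fit's.
        scale = mean_cum / own_cum
        return replace(first, k_hat=first.k_hat * scale)

    mv_results: dict[str, dict[str, MarginalValueResult]] = {}
    summaries: dict[str, CohortSummary] = {}
    for name, (base_cond, comp_cond) in comparisons.items():
        per_subject: dict[str, MarginalValueResult] = {}
        for subject in sorted({s for (s, c) in cumulative}):
            if (subject, base_cond) in cumulative and (subject, comp_cond) in cumulative:
                per_subject[subject] = marginal_value(
                    _fit_for(subject, base_cond), _fit_for(subject, comp_cond), bounds
                )
        if per_subject:
            mv_results[name] = per_subject
            if len(per_subject) >= 2:
                summaries[name] = one_sample_t(
                    [r.mv_percent for r in per_subject.values()]
                )

    reliability = None
    repeats_by_subject = {
        subj: vals
        for (subj, cond), vals in cums.items()
        if cond == BASELINE_CONDITION and len(vals) >= 2
    }
    if repeats_by_subject:
        reliability = reliability_analysis(repeats_by_subject, confidence)

    threshold = responder_threshold_pct
    if threshold is None and reliability is not None:
        threshold = reliability.mdc_pct

    responders: list[ResponderLabel] = []
    if threshold is not None and "exo_plus_assistance" in mv_results:
        responders = classify_responders(
            {
                sid: r.mv_percent
                for sid, r in mv_results["exo_plus_assistance"].items()
            },
            threshold,
        )

    return StudyReport(
        fits=fits,
        cumulative=cumulative,
        mv_results=mv_results,
        summaries=summaries,
        reliability=reliability,
        responders=responders,
        responder_threshold_pct=threshold,
        bounds=bounds,
    )
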