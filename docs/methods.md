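# Methods

This note records the models, numerical choices and design decisions behind
`exovalue`, and what the synthetic experiments do and do not establish.

## The auction instrument

Each session is a series of sealed-bid second-price auctions in the
*selling* direction: every bidder quotes the payment they demand to walk
the next 2-minute treadmill bout; the lowest quote wins and is paid the
second-lowest quote. Because the winner's own bid never sets the price,
quoting one's true internal price is a dominant strategy — this is verified
in the test suite by exhaustive payoff enumeration rather than assumed.
Amounts are held in integer cents so settlement is exact; the minimum bid
is $0.01. Ties for the best bid are broken uniformly at random (the cent
grid makes ties possible even though they are rare), and the clearing price
under a tie equals the tied value, the standard multiset convention.

The enumeration check exploits an exact reduction: a seller's expected
payoff against fixed competitor bids depends only on the competitor minimum
m and its tie multiplicity — (m − v) on a strict win, (m − v)/(ties + 1)
on a tie, 0 otherwise. This makes exhaustive verification over
cent-resolution value and deviation grids × all competitor multisets
tractable; the reduction itself is cross-checked against Monte-Carlo
settlement of the actual auction engine.

## Agents

**Robo-bidders** quote k·exp(b·t_k) + ε, ε ~ N(0, σ²) with σ = $0.01 by
default (σ is a standard deviation in dollars). t_k counts only intervals
the robo-bidder walked: winning increments it, losing freezes the
deterministic price. Fresh noise is drawn every auction by default; a
literal-constant mode that re-quotes the exact previous number after a loss
is available behind `literal_constant_on_loss`.

**Synthetic participants** bid honestly: k·exp(b·w) + ε, where the fatigue
clock w is *accumulated walking time* (2 min per win), not session time —
resting does not fatigue. A fixed-markup strategy exists only for
robustness experiments. All quoted prices are cent-rounded and floored at
$0.01; a `quantize=False` switch skips rounding for validation studies
that need exact parameter recovery.

Default priors (units, value, rationale):

| parameter | default | why |
|---|---|---|
| subject k | U(0.30, 0.90) USD | opening bids at the sub-dollar scale seen in practice |
| subject b | U(0.025, 0.055) /walked-min | doubling time 13–28 walked min; bids stay in a realistic $0.10–$5 range over a session |
| robo k | U(0.40, 0.90) USD | comparable opening prices to the subject pool |
| robo b | U(0.18, 0.32) /walked-interval | see calibration below |
| robo σ | $0.01 | masks the deterministic model from the opponent |
| bid noise SD | $0.05 | reproduces fit quality (R² ≈ 0.9) typical of real sessions |

Calibration argument: in a sequence of these auctions the bidders
equilibrate — each agent's log-price grows at a common per-auction rate g,
with g = 1/(1/(2b_h) + Σᵢ 1/bᵢ), and the subject's win share is
c = g/(2b_h). With the medians above, 1/(2b_h) ≈ 12.5 and Σ 1/bᵢ ≈ 12.3,
so a median subject walks about half the session, matching the intended
protocol regime; simulation confirms a median share of 0.48 and bids
within ≈ $0.24–$4.10.

## Session protocol

Session length is uniform on [50, 70] min (mean 60), drawn per session so
participants cannot wait out their opponents; with 2-minute intervals this
gives 25–35 auctions. The auction count is floor(duration/interval): a bid
buys a whole bout, so a partial trailing interval is dropped. Every bidder
bids every interval, including after losses. Only the clearing price is
disclosed to the participant each interval; robo-bidders observe only their
own win/loss. Earnings are the sum of clearing prices over won intervals
and never include the subject's own bid.

## Curve fitting

The price-to-walk model Y(t) = k·exp(b·c·t) is fit to *all* bids of a
session (wins and losses) by nonlinear least squares in bid space, with the
win rate c fixed from the log, not estimated. Initialization: k₀ is the
first bid and b₀ the slope of an ordinary regression of log(bid) on c·t;
bounds k > 0, b ≥ 0 by default (bids trend upward with fatigue) with an
unconstrained-rate option; convergence at relative parameter tolerance
1e-8, at most 10⁴ objective evaluations. R² = 1 − SS_res/SS_tot, with the
all-constant-bids case returning b = 0 and R² = 1 by convention (zero
residual on zero variance). A win rate of zero leaves the model
unidentifiable and raises a degenerate-model error. The returned optimum is
tested against an independent brute-force grid search over
k ∈ [0.01, 10] × b ∈ [0, 0.2].

The composite rate β = b·c deserves a note. The generative fatigue clock is
walking time w, and w ≈ c·t only when wins are evenly interleaved. The fit
therefore recovers b itself exactly only when the subject wins every
auction (c = 1, w = t); under irregular win patterns the rate is recovered
to within ~10%, and the fitted curve should be read as the best exponential
summary of the realized session, not as a direct measurement of b.

## Cumulative price and marginal value

Cumulative price integrates the *fitted* curve, i.e. uses β = b·c, over
[t₁, t₂] = [0, 30] min (about the average time walked per session; common
bounds are used for every subject). The closed form is evaluated with
`expm1` to remain accurate through β → 0, switching to the limit k·(t₂−t₁)
below |β| = 1e-12; agreement with adaptive quadrature is 1e-9 relative
across β ∈ [−0.1, 0.1]. MV is the baseline-minus-comparison difference of
cumulative prices, normalized by the baseline cumulative price of the pair
to give MV%; a non-positive baseline cumulative raises a normalization
error. Dollar values are kept at full precision internally and rounded only
for display (cents; one decimal for $/h). For the 30-minute window the
identity mv_to_hourly(hourly_rate(C_base), MV%) = 2·MV(USD) holds exactly
and is asserted numerically.

## Cohort statistics

Sample SDs use the n−1 denominator throughout. The one-sample t-test is the
closed form t = mean/(SD/√n) with a two-tailed p from the t distribution
(cross-checked against an independent statistical routine); Cohen's d is
the uncorrected one-sample form mean/SD. Intra-subject repeatability is the
sample SD of a subject's repeated cumulative prices as a percentage of that
subject's mean, averaged over subjects with ≥ 2 repeats (others are
excluded with a warning). MDC = z·√2·SD_intra with z(95%) = 1.959964 — the
difference-of-two-measurements form — giving MDC/SD ≈ 2.772. Responder
classification uses strict inequalities against ±threshold, defaulting to
the computed MDC when repeat sessions are available.

Published small-cohort reports of this kind of analysis sometimes print
p-values and effect sizes that are not mutually consistent with their
printed means, SDs and Ns under these standard definitions; this package
deliberately implements the standard definitions and does not attempt to
reproduce any inconsistent triple.

## Synthetic cohorts and ground truth

`paper_design()` builds the reference study shape: 16 subjects in the
baseline and powered conditions, the first 10 also in the unpowered
condition (42 sessions), and optionally four repeaters (three with two
extra baseline sessions, one with one; 49 sessions) to drive the MDC
pipeline. Condition effects act multiplicatively on the fatigue rate b
(assistance ×0.93, the unpowered device ×1.35), with per-subject lognormal
jitter (σ = 0.35) creating responder heterogeneity; an additive-k option
exists for robustness tests. Each session draws a fresh robo cohort.

Ground truth is recorded at two levels. `true_mv` is the closed-form MV% of
two (k, rate) pairs. `exact_cumulative_price` integrates the *generative*
price path k·exp(b·w(t)) over the window using the realized walk schedule
(w piecewise linear in t); this is the exact estimand of the fitted curve
and the honest reference for pipeline validation, because the closed form
in c·t holds only for perfectly interleaved wins.

`validation_design()` places robo opening prices far above any subject
price, so subjects win every auction (c = 1) and their bids lie exactly on
k·exp(b·t) up to cent rounding. In this regime the measured behavior is:
estimator recovery of (k, b) to 1e-6 on unquantized bids, per-subject MV%
within 0.5 points of the closed-form truth through the full pipeline
(cent rounding only), and cohort-mean MV% bias of a few hundredths of a
point at the realistic design with bid noise, measured against the exact
path integral over 200 replicate cohorts.

**Effect attenuation.** The instrument compresses condition effects: in
equilibrium the measured session-time rate is β = b·c and
∂log β/∂log b equals the subject's win share, so at a 50% walk share a
×1.35 change in b moves measured MV by roughly −8 to −10%, not the −16%
the rate change alone would suggest — stronger opponents absorb part of any
condition effect. Larger generative effects widen measured MVs but push
bids past the realistic $5 cap, so the defaults favor the protocol's bid
range and walk share. Consequently the synthetic cohort reproduces the
sign structure of the reference regime (assistance positive, added mass
negative, their combination near zero) but not the magnitudes reported
from human cohorts, whose opponents and valuations were not generated by
this model.

What passing tests show: the pipeline is internally consistent, unbiased
against its own generative model, and exact where exactness is claimed.
What they do not show: that real participants bid honestly, that human
fatigue follows a single exponential in walking time, or that real
condition effects are multiplicative on the fatigue rate.

## Problem sizes

The test suite and acceptance script use 10⁴ duration draws, 300 protocol
sessions, 200 replicate cohorts of 8 subjects for the bias study, 400×400
grid searches, and single full study simulations (49 sessions); these sizes
keep every Monte-Carlo estimate's standard error well inside the asserted
tolerances while the whole suite runs in well under a minute.
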