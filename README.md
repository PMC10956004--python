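# exovalue

Auction-based economic valuation of wearable assistive devices.

Metabolic benefit is the usual yardstick for augmentative exoskeletons, but
users often cannot perceive metabolic savings, and perception is what drives
adoption. `exovalue` implements an alternative instrument: participants sell
2-minute bouts of strenuous treadmill walking in a series of sealed-bid
**reverse Vickrey auctions** against computerized opponents. The lowest bid
wins and is paid the *second-lowest* bid, which makes bidding one's true
"price to walk" the dominant strategy. As fatigue builds, bids rise; the bid
trajectory prices the participant's experience of a walking condition
(ordinary shoes, a powered exoskeleton, or the same device unpowered) in
dollars.

## Model

A session's bids (winning and losing) are fit with a first-order exponential
in session time *t*:

    Y(t) = k · exp(b · c · t)

where *k* is the initial price (USD), *b* the fatigue rate per walked
minute, and *c* the participant's win rate, which rescales session time
toward walking time (fatigue accrues only while walking). Integrating a
fitted curve over a fixed window gives the **cumulative price to walk**

    C = ∫_{t₁}^{t₂} k·e^{β t} dt = (k/β)(e^{β t₂} − e^{β t₁}),   β = b·c

with [t₁, t₂] = [0, 30] min by default. The **marginal value** of a
comparison condition against a baseline is

    MV = C_baseline − C_comparison,
    MV% = 100 · MV / C_baseline

Positive MV means walking is cheaper in the comparison condition — the
device adds value. Cohort inference uses one-sample two-tailed t-tests,
SEM = SD/√N and Cohen's d = mean/SD; test–retest reliability of repeated
baseline sessions yields the minimum detectable change
MDC = z₉₅ · √2 · SD_intra, against which subjects are classified as
positive, negative or indeterminate responders.

The computerized opponents ("robo-bidders") bid k·exp(b·t_k) + ε with
ε ~ N(0, $0.01²), where t_k counts only the intervals the robo-bidder has
walked: a loser's price freezes until it wins again. A synthetic-cohort
generator produces complete studies (subjects × conditions × repeats) with
known ground truth, so the whole pipeline is testable end to end.

## Worked example

Simulate one baseline and one assisted session for the same synthetic
subject (assistance lowers the fatigue rate), then fit and compare:

```sh
$ exovalue simulate --duration-lo 60 --duration-hi 60 --seed 1 --out-dir demo
wrote demo/sim-1-walking-no-exo.csv | seed=1 condition=walking-no-exo auctions=30 wins=15 win_rate=0.50 walk=30 min earnings=$18.02 mean_bid=$1.11

$ exovalue simulate --duration-lo 60 --duration-hi 60 --seed 1 \
    --condition exo-powered --b-true 0.034 --out-dir demo
wrote demo/sim-1-exo-powered.csv | seed=1 condition=exo-powered auctions=30 wins=16 win_rate=0.53 walk=32 min earnings=$18.27 mean_bid=$1.06

$ exovalue fit demo/sim-1-walking-no-exo.csv
sim-1-walking-no-exo: k=$0.5641 b=0.04233/min c=0.500 R2=0.982 n=30

$ exovalue mv demo/sim-1-walking-no-exo.csv demo/sim-1-exo-powered.csv
MV = $0.66 (2.8% of baseline $23.64) over [0, 30] min
```

The fit recovers the generating parameters (k = $0.60, b = 0.04/min) up to
bid quantization and win-pattern effects; the assisted condition is worth
$0.66 (2.8% of the baseline cumulative price) to this subject over a
30-minute walk. A full synthetic study — 16 baseline, 16 powered and 10
unpowered sessions plus repeat baselines for four subjects — runs end to
end with:

```sh
$ exovalue cohort --seed 7 --repeaters --out-dir demo/study
$ exovalue report demo/study/report.json
Synthetic study report (seed=7, version 0.1.0, n_logs=49)
  exo_plus_assistance: mean MV +0.8% (SD 8.7%, SEM 2.2%, N=16), t(15)=0.38, p=0.712, d=0.09
  unpowered_exo: mean MV -7.4% (SD 5.8%, SEM 1.8%, N=10), t(9)=-4.01, p=0.003, d=-1.27
  assistance_alone: mean MV +8.7% (SD 5.9%, SEM 1.9%, N=10), t(9)=4.64, p=0.001, d=1.47
  reliability: intra-subject SD 4.12%, MDC 11.4% (95%, N=4)
  responders (threshold ±11.4%): 1 positive, 2 negative, 13 indeterminate
```

Wearing the unpowered device imposes a significant cost, the assistance
alone adds significant value, and the two roughly cancel — the device plus
assistance is near-neutral on average, with individual responders on both
sides of the MDC threshold.

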