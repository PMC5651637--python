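# Methods

## Overview

The package estimates how a transport policy that shifts trips between
modes would change daily transport-related moderate-to-vigorous
physical activity (T-MVPA), overall and by educational stratum. It is
organized as four stages — data integration, mode likelihoods, scenario
simulation, reporting — over two inputs: a large one-day travel survey
and a small multi-day donor cohort with accelerometer-measured per-trip
T-MVPA. Because the real datasets of this design are proprietary, a
synthetic generator stands in for both, with a documented ground-truth
mechanism so every downstream stage is verifiable against known truth.

## Synthetic study population

`modeshift.synth` draws persons (age 35–83, gender, education E1/E2/E3,
work situation, ordered income correlated with education) and assigns a
residence zone — city core ("paris"), adjacent, non-adjacent — with
education-dependent core probabilities (defaults 0.06 / 0.14 / 0.25 for
E1/E2/E3). Zone drives log-normally distributed accessibility
covariates (network distances to the nearest public-transport, train,
metro, tram and bus stations) and contextual measures (area education,
destinations, intersections, park surface, population density).

Trips start at the residence; the arrival zone follows a
zone-transition matrix and a latent trip distance is drawn log-normally
with zone-pair medians (0.85 km within the core up to 10–11 km for
core↔periphery) and log-sd 1.05, giving the heavy short-trip mass of
urban travel diaries. Mode choice is a multinomial logit over four
modes whose systematic utilities encode the standard regularities —
walking for short trips, private motorized for long trips and
higher incomes, public transport favoured by core departures and good
station access — with intercepts calibrated by iterative proportional
fitting so the realized composition matches the configured shares
(defaults walking .335, bicycle .015, public transport .143, private
motorized .507, back-computed from the policy plan's printed conversion
counts). Durations are whole minutes, `speed = distance / duration`
exactly, and the rush-hour flag derives from the departure hour
(8–11 am, 4–7 pm). Defaults: 21,332 survey persons × 1 day ×
Poisson(3.85) trips; 229 donor persons × 7 days × Poisson(4.45).

### Ground-truth T-MVPA mechanism

Per-mode parametric function, rounded to whole minutes and clipped to
`[0, duration]`:

| mode              | mechanism                                         | default |
|-------------------|---------------------------------------------------|---------|
| bicycle           | exactly the trip duration (no noise)              | —       |
| walking           | `walk_fraction × duration + ε`                    | 0.85    |
| public transport  | `pt_base + pt_access_weight × access_walk + ε`    | 5 min + 0.25 × walk-minutes to/from stations (at 80 m/min) |
| private motorized | `pm_fraction × duration + ε`                      | 0.05    |
| noise ε           | Gaussian, sd `noise_sd`                           | 5.5 min |

The noise level was calibrated once so the donor-fitted integration
forest's out-of-bag R² lands near the value reported for this design on
real data (≈0.67), then frozen. The donor's "observed" T-MVPA is the
count of minutes above the 2690 counts/min vector-magnitude cut-point
in an emulated per-minute accelerometer series; the series is
constructed to realize the mechanism's value exactly (strictly-greater
comparison at the cut-point), so donor tables are produced with the
vectorized mechanism directly.

What the generator does **not** emulate: GPS measurement error and trip
mis-detection, day-to-day behavioural correlation within persons,
household structure, seasonal effects, non-response, and the spatial
autocorrelation of real accessibility surfaces. Passing tests therefore
demonstrate that the pipeline's machinery is correct and that its
qualitative conclusions follow from the encoded gradients — not that
the real-data magnitudes would be reproduced.

## Data integration

Random-forest regressor (default 500 trees, `max_features` = 1/3,
standard n-with-replacement bootstrap ⇒ ≈63.2% unique in-bag / ≈36.8%
OOB per tree) on the donor over the full 45-variable predictor set.
Validation is strictly out-of-bag: per observation, the mean of its OOB
trees' predictions; R² from those. Survey predictions are clipped to
`[0, duration]` (a physical bound; T-MVPA minutes cannot exceed trip
minutes) and bicycle trips bypass the model entirely, returning the
trip duration.

## Mode likelihoods

Random-forest classifier (default 500 trees, `max_features` = sqrt) on
the survey, mode as outcome, duration/speed/T-MVPA excluded from the
predictors. Per trip, the *hard votes* of its OOB trees are tallied
into per-mode shares — deliberately tree-vote proportions, not
calibrated probabilities. Trips OOB in fewer than 30 trees (config) are
a hard error rather than a noisy share; with ≥200 trees at survey scale
this floor is never hit in practice.

## Logit-shift rescaling

To convert a likelihood vector with arbitrary mean into selection
probabilities with a prescribed mean *f*, probabilities are clipped to
`[1e-6, 1−1e-6]` (vote shares can be exactly 0 or 1), mapped to logits,
shifted by a constant, and mapped back. The achieved mean is strictly
increasing in the shift, so bisection over an auto-expanding bracket
converges globally; tolerance 1e-8 on the mean, 200-iteration cap, and
an exact zero shift in the identity case. The transform preserves
ranks and the (0,1) range by construction.

## Scenario simulation

A scenario prescribes relative increases per destination mode (defaults
+11.8% public transport, +2.5% walking/biking — configuration constants
of the policy plan, not re-derived here) and a multiplier. Expected
conversions are `round(increase × multiplier × mode count)`
(half-away-from-zero, keeping small counts stable); selection fractions
divide by the candidate count (private motorized trips in the main
scenario; all non-destination trips in single-mode promotions), with
infeasibility errors when a fraction would exceed 1.

Selection uses **one categorical draw per candidate** over
{destinations, no change} with the independently rescaled likelihoods
as probabilities. The design it replaces — independent binomial draws
per destination — has the same expectations but can select one trip for
two destinations; the categorical draw is expectation-equivalent and
conflict-free. Rows whose rescaled probabilities sum above 1 are
renormalized (error above 1.5 as pathological; never observed at the
default fractions).

Converted trips get duration re-predicted by a forest fitted on the
original, pre-shift survey with mode as a predictor (floored at
1 minute), speed recomputed from the new duration, and T-MVPA
re-predicted by the integration model (biking override applies). These
re-predictions are deterministic given the fitted forests, so they are
computed once per (candidate, destination) and reused across
repetitions; each of the default 100 repetitions — independent RNG
streams spawned from the scenario seed — only redraws the selection.
The likelihood and prediction forests are fitted once per study, not
per repetition.

## Reporting

Per-person daily T-MVPA is decomposed by mode (mode columns always sum
to the total). The baseline table reports stratum means with
normal-approximation 95% CIs across persons — the baseline is a single
deterministic prediction pass, so across-repetition percentiles are
undefined for it. Gains tables report the mean over repetitions of
(scenario stratum mean − baseline stratum mean) with percentile
(2.5/97.5) intervals across repetitions. The inequality summary is the
E3−E1 gap at baseline and in the gains; a positive gain gap flags
amplification. Tables render at one decimal.

## Problem sizes and numerical choices

- Library forest defaults are 500 trees; the full-scale analysis
  scripts and the large test fixture use 200 trees for the two big
  forests, `min_samples_leaf=10` for the classifier, and fit the
  duration forest on a 25k-trip subsample with depth cap 16. The
  properties checked at that scale (vote-share normalization, binomial
  calibration, conservation, gain signs and orderings) do not depend on
  forest size; tree counts only add Monte-Carlo noise to the shares.
- Seeds: every stochastic component takes an explicit seed;
  `numpy.random.SeedSequence` spawning keeps the generator, each
  forest and each repetition on independent, reproducible streams.
- Degenerate inputs: empty probability vectors, single-mode surveys,
  zero-duration trips, infeasible plans and missing predictor columns
  all raise typed, descriptive errors rather than propagating NaNs.

## Known limitations

- Scenarios reassign modes of existing trips only; trip generation,
  destination choice and induced demand are out of scope, as are
  compensation effects in non-transport physical activity and
  downstream health outcomes.
- OOB likelihoods are only defined for the trips the mode forest was
  fitted on; scoring new trips would require refitting.
- The synthetic accessibility surfaces are independent log-normal
  draws, so spatial correlation between neighbouring persons is absent;
  education-related effects flow exclusively through the configured
  zone and access gradients.
- The amplification finding is a property of the encoded gradient: with
  a flat education→zone mapping the E3−E1 gain gap vanishes, which is
  itself a useful falsification check.
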