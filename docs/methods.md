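# Methods

This note records the model, the defaults and why they were chosen, the
conventions the statistics follow, and what the synthetic cohorts can and
cannot tell you.

## Game engine

**World.** One player facility at the center of a square arena (side 10
distance units) with N = 50 computer facilities placed uniformly at
random per round. Positions are fixed within a round. Computer
facilities draw a static biosecurity level uniformly from {0, 1, 2, 3} at
round start; exactly one randomly chosen computer facility begins each
round infected. These three choices (layout, neighbor levels, single
index case) are modeling conventions: the source design specifies the
player's surroundings only qualitatively, so we picked the simplest
spatially homogeneous initialization and exposed every piece of it in
configuration.

**Transmission.** The per-pair monthly probability is
`min(p_inf / D², 1) · a(k)` with `p_inf = 0.15`, D the Euclidean distance
floored at `min_distance = 1` (so the probability never exceeds p_inf),
and `a(k)` the attenuation from the *target's* biosecurity level k. The
statement "each successive level reduces the probability of infection by
25%" is read multiplicatively, `a(k) = 0.75^k`, so every increment removes
a quarter of the remaining hazard; the linear reading
`a(k) = 1 − 0.25k` is available via `TransmissionParams(adjustment="linear")`.
Multiple infected sources act independently: a clean facility is infected
with probability `1 − ∏(1 − pᵢ)`. Spread is synchronous: infections
acquired this month transmit from next month on. There is no recovery
within a round.

**Rounds and money.** Six decision months per round. Within a month the
order is: observe → purchase reveals (a reveal updates the observation
immediately) → at most one biosecurity upgrade → disease spread. A
disease reveal is a current-month snapshot of the 10 nearest facilities
and may be repurchased monthly; a biosecurity reveal persists for the
round because neighbor levels are static. Player infection truncates the
round and costs $25,000. The per-round endowment defaults to $10,000;
the source design reports only net session profits and never states the
income structure, so profit *magnitudes* are configuration-dependent and
are deliberately not used as reference quantities. Balance accounting is
exact: delta = endowment − spends − penalty, enforced by test for every
seed.

**Treatment schedule.** Each of the two information dimensions (disease,
biosecurity) is visible, hidden, or revealable; one quarter of rounds are
fully visible and the remaining 75% cycle round-robin over the eight
uncertainty combinations, with revealable dimensions alternating between
the $1,000 and $2,000 price points. The generator therefore requires
n_rounds divisible by 4 and at least 24 rounds so every combination
occurs at both prices; the default is 32.

## Policy agents

Human decision rules are not prescribed by the emulated design; the three
named strategies are formalized as explicit synthetic conventions:

- *risk averse*: upgrades every month until High;
- *risk tolerant*: never upgrades;
- *opportunistic*: upgrades when perceived threat ≥ `threat_threshold`
  (default 0.05).

Perceived threat combines the true transmission probabilities of
facilities known to be infected (identical kernel to the engine — under
full visibility the perception equals the engine's probability exactly)
with a `hidden_prior` (default 0.15, the baseline hazard of one adjacent
source) scaled by the fraction of facilities still hidden; under full
cloaking the perception is exactly the prior.

Reveal purchases are Bernoulli per eligible month with propensity
`reveal_propensity`, multiplied by `reveal_price_sensitivity = 0.5` per
$1,000 above the base price — the propensity halves at $2,000, mirroring
the finding that cohort differences in information purchase vanish at the
higher price.

Cohorts draw per-participant parameters from truncated normals (normal
draws clipped to valid ranges). The default two-cohort configuration
encodes the study conditions the pipeline is meant to detect: reveal
propensity 0.4 (industry-fair-like) vs 0.2 (online-marketplace-like),
n = 50 each. Lottery behavior per cohort is a switch-row distribution
(mean 6.2, sd 2.2 / 2.0) with a choice-flip error rate (0.05 / 0.02),
chosen so the generated safe-ratio means and spreads match the published
summary statistics of the two human samples (≈0.52 ± 0.21/0.20).

## Lottery instrument

Ten rows; row k pays each option's high payoff with probability k/10.
Packaged payoff presets: Expo (A: $2.00/$1.60, B: $3.85/$0.10) and MTurk
(A: $0.60/$0.50, B: $1.10/$0.05). Scoring: safe ratio = #A/10; exactly
0.4 is risk neutral (boundary assigned to neutral, strictly above/below
to averse/tolerant); switch count tallies every adjacent A↔B alternation.
EV ties go to Option A (conservative; no tie occurs in either preset).
One uniformly drawn row is realized for payment, which is what makes each
row incentive-compatible. The EV-maximizing agent crosses over after row
4 on both presets (4 safe choices), the maximin agent switches only at
the degenerate row 10.

## Statistical conventions

- Mann–Whitney U: exact null enumeration when the smaller sample has
  ≤ 8 observations and the pooled data are tie-free; otherwise the
  tie-corrected normal approximation with continuity correction. All-tied
  samples return p = 1 by convention.
- Two-sample KS: exact D, asymptotic p.
- Spearman: midranks for ties; exact permutation p (two-sided on |r|) for
  n ≤ 8, t approximation otherwise; fewer than 3 pairs is degenerate and
  reported as NaN by the comparison pipeline.
- χ²: Pearson statistic without continuity correction, (r−1)(c−1) df;
  zero marginals are rejected.
- Normality: D'Agostino–Pearson omnibus, required n ≥ 20; used only to
  justify rank tests in reports.
- FDR: Benjamini–Hochberg step-up within a declared family. The default
  plan puts the four reveal contrasts (2 information types × 2 prices) in
  one family, and follows the reporting conventions of the emulated
  analysis: two-tailed tests for rating and profit contrasts, one-tailed
  (first cohort greater) for reveal contrasts. Both tails are exposed
  per plan entry.

These wrappers delegate the numerics to scipy; the test suite checks them
against independent brute-force oracles (full enumeration of group
assignments for U, ECDF scans for D, hand midranking and permutation
enumeration for Spearman, a from-definition BH implementation).

## Seeding

One master seed per experiment feeds named `SeedSequence` child streams
(schedule, cohort draws, per-participant sessions, lotteries). No global
RNG state is used anywhere; identical configuration + seed reproduces
every artifact byte for byte.

## What the synthetic cohorts do and do not show

The generator reproduces the *statistical structure* the pipeline
analyzes — two groups with independently configurable investment policy,
information-purchase propensity, and lottery behavior — not fitted human
behavior. Passing tests therefore demonstrate that the pipeline is
correctly calibrated (nominal type-I error on identically generated
cohorts), has power to detect propensity differences of the magnitude the
study design contrasts (0.4 vs 0.2 at n = 50), and does not manufacture
correlation between game risk and lottery risk when the two are generated
independently. They do not reproduce the published human test statistics
or distributions, which would require the unpublished raw data; the
report structure is a template, not a replication.

## Problem sizes used by the test suite

- Monte-Carlo kernel recovery: 100,000 single-month replicates.
- Type-I calibration: 400 replicate null experiments at the summary
  level (identically distributed reveal counts for both cohorts); the
  game engine adds no information to this calibration of the test itself.
- Power check: 200 replicate experiments, n = 50 per cohort, run with the
  full engine on the disease-revealable rounds of the default 32-round
  schedule — the only rounds that can contribute to the tested count;
  rounds are independent, so restricting to them leaves the statistic's
  distribution unchanged while keeping the simulation quick.
- Generative-independence check: 200 replicates of a 40-participant
  cohort playing 8-round sessions; the property is about independence of
  the two generated behaviors, not session length.

## Known limitations

- Agents do not learn or adapt within or across rounds.
- Computer facilities never change biosecurity within a round and are
  never affected by the player's choices.
- The endowment/income structure is a free parameter; session-profit
  levels are comparable only within one configuration.
- The demographic χ² test is provided as an operation, but no demographic
  generator ships.
- Policy thresholds for the three named strategies are conventions, not
  estimates of human decision rules.
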