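# agrisk

A headless, scriptable re-implementation of a biosecurity-investment
experimental game for livestock disease management, together with the
paired-lottery (multiple price list) risk instrument and the complete
behavioral-risk analysis pipeline. Policy agents replace human players, so
the decision metrics, treatment comparisons, and risk classifications used
in this line of behavioral research can be computed, stress-tested, and
extended on fully synthetic cohorts.

## Who this is for

Researchers in agricultural epidemiology and experimental economics who
work with "serious game" decision data: it provides a deterministic,
seedable engine for the game mechanics, a generative model of participant
cohorts, and the exact statistical conventions (rank tests, FDR control)
used to compare them — without needing human-subject data.

## The model

**Game.** A player facility sits among N = 50 computer-controlled
facilities on a 2-D arena. Each round is a "decision year" of six months.
Per month the player may raise their biosecurity level one step
(None → Low → Medium → High, $1,000 per step) and, under some information
treatments, pay $1,000 or $2,000 to reveal the disease or biosecurity
status of the 10 nearest facilities. At month end, disease spreads from
each infected facility to each clean one with probability

    p(D, k) = min(p_inf / D², 1) · 0.75^k,      p_inf = 0.15,

where D is the pairwise Euclidean distance (floored at 1) and k ∈ {0..3}
the *target's* biosecurity level — each level removes 25% of the hazard.
Independent sources combine as 1 − ∏(1 − pᵢ). If the player is infected
the round ends immediately with a −$25,000 penalty. A session is 32 rounds
(up to 192 monthly decisions); 25% of rounds are fully visible, the other
75% cloak disease and/or biosecurity status. Simulation dollars convert to
USD at $23,500/$ (online preset) or $12,000/$ (trade-show preset).

**Risk metrics.** The biosecurity investment rating of participant *i* is

    R_i = mean monthly post-decision biosecurity status ∈ [0, 3],

normalized by the number of decisions actually made (truncated rounds
count only the months played). The lottery instrument is ten paired
choices; at row k the high payoff of each option pays with probability
k/10. Risk aversion is the safe-choice ratio (#A/10): exactly 0.4 is risk
neutral, above is risk averse, below risk tolerant.

**Statistics.** Cohort contrasts use Mann–Whitney U (exact null for small
tie-free samples, tie-corrected normal approximation otherwise), the
two-sample Kolmogorov–Smirnov test, Spearman rank correlation with
midranks, the Pearson χ² frequency test, and the D'Agostino–Pearson
normality check; families of related contrasts are adjusted with the
Benjamini–Hochberg step-up procedure.

## Worked example

`examples/play_session.py` runs one opportunistic agent through a full
32-round session:

```
rounds played:        32 (infected in 4)
monthly decisions:    186 (cap 192 when never infected)
investment rating R:  1.581  (0=None .. 3=High)
session profit:       $121,000 sim = $5.15 USD at the online rate
```

186 < 192 because four rounds truncated on infection; R ≈ 1.6 means the
agent typically sat between Low and Medium protection.

`examples/fdr_adjustment.py` adjusts the packaged four-test family of
one-tailed reveal contrasts:

```
BH step-up over one four-test family:
  infection_1000     p = 0.0487 -> p_adj = 0.078
  infection_2000     p = 0.2835 -> p_adj = 0.283
  biosecurity_1000   p = 0.0013 -> p_adj = 0.005 *
  biosecurity_2000   p = 0.0587 -> p_adj = 0.078
```

Only the $1,000 biosecurity contrast survives FDR control at 0.05.

The other examples cover the transmission kernel
(`transmission_kernel.py`), the lottery instrument and switch-count
diagnostics (`lottery_instrument.py`), and a full two-cohort experiment
with the default comparison plan (`cohort_comparison.py`).

## Command line

A thin CLI wraps the library:

```
agrisk run --seed 1 --out results/            # end-to-end experiment
agrisk simulate --config cfg.yaml --out log.csv
agrisk lottery --agent ev_maximizer --n 50 --seed 1 --out lottery.csv
agrisk analyze --log log.csv --lottery lottery.csv --out report.json
agrisk fixtures --kind worked_examples --out fx.json
```

## Layout

- `src/agrisk/world.py` — arena, transmission kernel, monthly spread
- `src/agrisk/treatments.py` — visibility regimes and schedule generator
- `src/agrisk/engine.py` — actions, observation masking, rounds, sessions
- `src/agrisk/agents.py` — threshold policies and the cohort generator
- `src/agrisk/lottery.py` — paired-lottery schedules, agents, scoring
- `src/agrisk/stats.py`, `metrics.py`, `compare.py` — the analysis pipeline
- `src/agrisk/logio.py`, `config.py`, `cli.py`, `plots.py` — I/O and orchestration
- `docs/methods.md` — modeling assumptions, defaults, and limitations
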