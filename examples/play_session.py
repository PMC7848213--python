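"""Play one full 32-round session with an opportunistic policy agent and
summarize its behavior."""

import numpy as np

from agrisk import (
    EconomyParams,
    PolicyParams,
    ThresholdPolicy,
    TransmissionParams,
    biosecurity_rating,
    convert_to_usd,
    run_session,
    session_profit,
)
from agrisk.economy import MTURK_CONVERSION
from agrisk.treatments import generate_treatment_schedule

schedule = generate_treatment_schedule(n_rounds=32, rng_seed=11)
policy = ThresholdPolicy(
    PolicyParams(strategy="opportunistic", threat_threshold=0.05, reveal_propensity=0.3)
)
results, records = run_session(
    policy, schedule, EconomyParams(), TransmissionParams(), rng_seed=42
)

statuses = [r.post_decision_biosecurity for rnd in records for r in rnd]
n_infected = sum(res.infected for res in results)
profit = session_profit(results)
print(f"rounds played:        {len(results)} (infected in {n_infected})")
print(f"monthly decisions:    {len(statuses)} (cap 192 when never infected)")
print(f"investment rating R:  {biosecurity_rating(statuses):.3f}  (0=None .. 3=High)")
print(f"session profit:       ${profit:,.0f} sim "
      f"= ${convert_to_usd(profit, MTURK_CONVERSION):.2f} USD at the online rate")
print("\nR is the mean post-decision biosecurity status over all decision")
print("months; higher R means more risk-averse in-game investment.")
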