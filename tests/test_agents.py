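"""Policy agents: threat perception, strategy rules, cohort generation."""

import numpy as np
import pytest

from agrisk import (
    CohortSpec,
    EconomyParams,
    PolicyParams,
    Strategy,
    TransmissionParams,
    TreatmentSpec,
    Visibility,
    combine_sources,
    decide,
    init_world,
    make_cohort,
    perceived_threat,
    transmission_probability,
)
from agrisk.agents import ThresholdPolicy, _effective_reveal_propensity
from agrisk.engine import ActionKind, RoundState, observe, run_session
from agrisk.metrics import biosecurity_rating
from agrisk.treatments import generate_treatment_schedule

FULL = TreatmentSpec(Visibility.VISIBLE, Visibility.VISIBLE)
HIDDEN = TreatmentSpec(Visibility.HIDDEN, Visibility.HIDDEN)
REVEALABLE = TreatmentSpec(
    Visibility.REVEALABLE,
    Visibility.REVEALABLE,
    reveal_price_disease=1000.0,
    reveal_price_biosecurity=2000.0,
)


def observation_for(treatment, seed=3, n=25, n_infected=4):
    economy = EconomyParams()
    world = init_world(n, seed)
    world.infected[:] = False
    world.infected[1 : 1 + n_infected] = True
    state = RoundState(
        world=world,
        treatment=treatment,
        economy=economy,
        transmission=TransmissionParams(),
        balance=economy.round_endowment,
    )
    return state, observe(state)


class TestPerceivedThreat:
    def test_visibly_clean_world_is_zero(self):
        _, obs = observation_for(FULL, n_infected=0)
        assert perceived_threat(obs, PolicyParams()) == 0.0

    def test_full_visibility_matches_engine_probability(self):
        state, obs = observation_for(FULL)
        params = TransmissionParams()
        expected = combine_sources(
            [
                transmission_probability(d, 0, params)
                for d, inf in zip(
                    state.world.distances[0, 1:], state.world.infected[1:]
                )
                if inf
            ]
        )
        assert perceived_threat(obs, PolicyParams()) == pytest.approx(
            expected, abs=1e-15
        )

    def test_fully_hidden_equals_prior(self):
        _, obs = observation_for(HIDDEN)
        p = PolicyParams(hidden_prior=0.37)
        assert perceived_threat(obs, p) == pytest.approx(0.37)

    def test_partial_reveal_between_prior_and_truth(self):
        from agrisk.engine import REVEAL_DISEASE, apply_action

        state, _ = observation_for(REVEALABLE)
        apply_action(state, REVEAL_DISEASE)
        obs = observe(state)
        p = PolicyParams(hidden_prior=0.2)
        threat = perceived_threat(obs, p)
        assert 0.0 < threat < 1.0


class TestDecide:
    def test_risk_averse_always_upgrades(self, rng):
        _, obs = observation_for(FULL, n_infected=0)
        actions = decide(obs, PolicyParams(strategy=Strategy.RISK_AVERSE), rng)
        assert ActionKind.INCREASE_BIOSECURITY in [a.kind for a in actions]

    def test_risk_tolerant_never_upgrades(self, rng):
        _, obs = observation_for(FULL)
        params = PolicyParams(strategy=Strategy.RISK_TOLERANT, reveal_propensity=0.0)
        actions = decide(obs, params, rng)
        assert [a.kind for a in actions] == [ActionKind.NO_ACTION]

    def test_opportunistic_threshold_rule(self, rng):
        # One visible source at D = sqrt(1.5): threat = 0.15/1.5 = 0.10.
        from agrisk.world import WorldState

        world = WorldState(
            positions=np.array([[0.0, 0.0], [np.sqrt(1.5), 0.0]]),
            levels=np.array([0, 0]),
            infected=np.array([False, True]),
        )
        economy = EconomyParams()
        state = RoundState(
            world=world,
            treatment=FULL,
            economy=economy,
            transmission=TransmissionParams(),
            balance=economy.round_endowment,
        )
        obs = observe(state)
        below = PolicyParams(strategy=Strategy.OPPORTUNISTIC, threat_threshold=0.05)
        above = PolicyParams(strategy=Strategy.OPPORTUNISTIC, threat_threshold=0.15)
        assert ThresholdPolicy(below).choose_upgrade(obs, rng) is not None
        assert ThresholdPolicy(above).choose_upgrade(obs, rng) is None

    def test_reveal_propensity_and_price_sensitivity(self, rng):
        params = PolicyParams(reveal_propensity=0.4, reveal_price_sensitivity=0.5)
        assert _effective_reveal_propensity(params, 1000.0) == pytest.approx(0.4)
        assert _effective_reveal_propensity(params, 2000.0) == pytest.approx(0.2)
        sure = PolicyParams(reveal_propensity=1.0, reveal_price_sensitivity=1.0)
        _, obs = observation_for(REVEALABLE)
        kinds = {a.kind for a in ThresholdPolicy(sure).choose_reveals(obs, rng)}
        assert kinds == {ActionKind.REVEAL_DISEASE, ActionKind.REVEAL_BIOSECURITY}


class TestMakeCohort:
    def test_determinism(self):
        spec = CohortSpec(name="x", n_participants=50)
        assert make_cohort(spec, 5) == make_cohort(spec, 5)

    def test_labels_and_valid_ranges(self):
        spec = CohortSpec(name="pe", n_participants=30)
        cohort = make_cohort(spec, 2)
        assert len(cohort) == 30
        for p in cohort:
            assert p.cohort == "pe"
            assert 0.0 <= p.policy_params.threat_threshold <= 1.0
            assert 0.0 <= p.policy_params.reveal_propensity <= 1.0
            assert 1 <= p.lottery_switch_row <= 11

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(name="x", n_participants=0)


class TestStrategyOrdering:
    def test_rating_order_averse_ge_opportunistic_ge_tolerant(self, economy):
        """Mean investment rating orders with the named strategies."""
        schedule = generate_treatment_schedule(32, 2)[:8]
        transmission = TransmissionParams()
        ratings = {}
        for strategy in Strategy:
            statuses = []
            for seed in range(25):
                policy = ThresholdPolicy(
                    PolicyParams(strategy=strategy, threat_threshold=0.05)
                )
                _, records = run_session(
                    policy, schedule, economy, transmission, 1000 + seed
                )
                statuses.extend(
                    r.post_decision_biosecurity for round_ in records for r in round_
                )
            ratings[strategy] = biosecurity_rating(statuses)
        assert (
            ratings[Strategy.RISK_AVERSE]
            > ratings[Strategy.OPPORTUNISTIC]
            > ratings[Strategy.RISK_TOLERANT]
        )
        assert ratings[Strategy.RISK_TOLERANT] == 0.0
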