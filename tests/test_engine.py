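"""Action legality, round truncation, money conservation, and sessions."""

import numpy as np
import pytest

from agrisk import (
    EconomyParams,
    IllegalActionError,
    TransmissionParams,
    TreatmentSpec,
    Visibility,
    convert_to_usd,
)
from agrisk.economy import EXPO_CONVERSION, MTURK_CONVERSION
from agrisk.engine import (
    INCREASE,
    NO_ACTION,
    REVEAL_BIOSECURITY,
    REVEAL_DISEASE,
    DecisionAction,
    RoundState,
    apply_action,
    observe,
    records_to_rows,
    run_round,
    run_session,
    session_profit,
)
from agrisk.world import WorldState, init_world

REVEALABLE = TreatmentSpec(
    Visibility.REVEALABLE,
    Visibility.REVEALABLE,
    reveal_price_disease=1000.0,
    reveal_price_biosecurity=2000.0,
)
FULL = TreatmentSpec(Visibility.VISIBLE, Visibility.VISIBLE)


def make_state(treatment=FULL, n=20, seed=4):
    economy = EconomyParams()
    world = init_world(n, seed)
    return RoundState(
        world=world,
        treatment=treatment,
        economy=economy,
        transmission=TransmissionParams(),
        balance=economy.round_endowment,
    )


class NoActionPolicy:
    def choose_reveals(self, obs, rng):
        return []

    def choose_upgrade(self, obs, rng):
        return None


class UpgradeFirstMonths:
    """Upgrade in months 1..k, otherwise nothing."""

    def __init__(self, k):
        self.k = k

    def choose_reveals(self, obs, rng):
        return []

    def choose_upgrade(self, obs, rng):
        return INCREASE if obs.month <= self.k and obs.can_upgrade else None


class AlwaysRevealAndUpgrade:
    def choose_reveals(self, obs, rng):
        out = []
        if obs.can_reveal_disease:
            out.append(REVEAL_DISEASE)
        if obs.can_reveal_biosecurity:
            out.append(REVEAL_BIOSECURITY)
        return out

    def choose_upgrade(self, obs, rng):
        return INCREASE if obs.can_upgrade else None


def two_facility_world(distance=1.0):
    """Player plus a single infected source at a given distance."""
    return WorldState(
        positions=np.array([[0.0, 0.0], [distance, 0.0]]),
        levels=np.array([0, 0]),
        infected=np.array([False, True]),
    )


class TestApplyAction:
    def test_upgrade_costs_and_raises_level(self):
        state = make_state()
        spend = apply_action(state, INCREASE)
        assert spend == 1000.0
        assert state.world.player_level == 1
        assert state.balance == state.economy.round_endowment - 1000.0

    def test_upgrade_at_high_errors(self):
        state = make_state()
        state.world.levels[0] = 3
        with pytest.raises(IllegalActionError):
            apply_action(state, INCREASE)

    def test_second_upgrade_same_month_errors(self):
        state = make_state()
        apply_action(state, INCREASE)
        with pytest.raises(IllegalActionError):
            apply_action(state, INCREASE)
        state.begin_month()
        apply_action(state, INCREASE)  # next month is legal again
        assert state.world.player_level == 2

    def test_reveal_under_visible_treatment_errors(self):
        state = make_state(FULL)
        with pytest.raises(IllegalActionError):
            apply_action(state, REVEAL_DISEASE)

    def test_reveal_uncovers_nearest_and_charges_price(self):
        state = make_state(REVEALABLE)
        spend = apply_action(state, REVEAL_DISEASE)
        assert spend == 1000.0
        obs = observe(state)
        revealed = ~np.isnan(obs.infection_view)
        assert revealed.sum() == state.economy.reveal_count
        # the revealed ones are the nearest computer facilities
        d = state.world.distances[0, 1:]
        assert d[revealed].max() <= d[~revealed].min()

    def test_disease_reveal_is_monthly_snapshot(self):
        state = make_state(REVEALABLE)
        apply_action(state, REVEAL_DISEASE)
        with pytest.raises(IllegalActionError):
            apply_action(state, REVEAL_DISEASE)
        state.begin_month()
        assert np.isnan(observe(state).infection_view).all()  # snapshot expired
        apply_action(state, REVEAL_DISEASE)  # repurchase next month is legal

    def test_biosecurity_reveal_persists_for_round(self):
        state = make_state(REVEALABLE)
        apply_action(state, REVEAL_BIOSECURITY)
        state.begin_month()
        assert (~np.isnan(observe(state).biosecurity_view)).sum() == 10
        with pytest.raises(IllegalActionError):
            apply_action(state, REVEAL_BIOSECURITY)

    def test_no_action_is_free(self):
        state = make_state()
        assert apply_action(state, NO_ACTION) == 0.0


class TestRunRound:
    def test_safe_round_runs_six_months(self, economy, no_transmission, rng):
        world = init_world(20, 1)
        result, records = run_round(
            world, NoActionPolicy(), FULL, economy, no_transmission, rng
        )
        assert result.months_played == 6
        assert not result.infected
        assert result.final_balance_delta == economy.round_endowment
        assert len(records) == 6

    def test_forced_infection_truncates_with_penalty(self, economy, rng):
        world = two_facility_world(distance=1.0)
        result, records = run_round(
            world, NoActionPolicy(), FULL, economy, TransmissionParams(p_inf=1.0), rng
        )
        assert result.months_played == 1
        assert result.infected
        assert records[0].infected_this_month
        assert result.final_balance_delta == economy.round_endowment - 25_000.0

    def test_three_upgrades_reach_high(self, economy, no_transmission, rng):
        world = init_world(20, 1)
        result, records = run_round(
            world, UpgradeFirstMonths(3), FULL, economy, no_transmission, rng
        )
        assert result.final_balance_delta == economy.round_endowment - 3_000.0
        assert [r.post_decision_biosecurity for r in records] == [1, 2, 3, 3, 3, 3]

    def test_stale_world_rejected(self, economy, transmission, rng):
        world = init_world(5, 1)
        world.levels[0] = 1
        with pytest.raises(ValueError):
            run_round(world, NoActionPolicy(), FULL, economy, transmission, rng)

    def test_illegal_policy_action_surfaces(self, economy, no_transmission, rng):
        class BadPolicy(NoActionPolicy):
            def choose_reveals(self, obs, rng):
                return [REVEAL_DISEASE]  # illegal under full visibility

        with pytest.raises(IllegalActionError):
            run_round(
                init_world(5, 1), BadPolicy(), FULL, economy, no_transmission, rng
            )


class TestRunSession:
    def test_uninfected_session_has_full_record_count(self, economy, no_transmission):
        from agrisk.treatments import generate_treatment_schedule

        schedule = generate_treatment_schedule(32, 5)
        results, records = run_session(
            NoActionPolicy(), schedule, economy, no_transmission, 123
        )
        assert sum(len(r) for r in records) == 192
        assert all(res.months_played == 6 for res in results)

    def test_truncation_iff_infected(self, economy, transmission):
        from agrisk.treatments import generate_treatment_schedule

        schedule = generate_treatment_schedule(32, 5)
        results, _ = run_session(
            NoActionPolicy(), schedule, economy, transmission, 7
        )
        for res in results:
            assert (res.months_played < 6) == res.infected or res.months_played == 6

    def test_money_conservation_many_seeds(self, economy, transmission):
        for seed in range(12):
            world = init_world(25, seed)
            result, records = run_round(
                world,
                AlwaysRevealAndUpgrade(),
                REVEALABLE,
                economy,
                transmission,
                np.random.default_rng(seed),
            )
            spends = sum(r.spend for r in records)
            penalty = economy.infection_penalty if result.infected else 0.0
            assert result.final_balance_delta == pytest.approx(
                economy.round_endowment - spends - penalty
            )

    def test_session_profit_is_sum_of_deltas(self, economy, transmission, small_schedule):
        results, _ = run_session(
            AlwaysRevealAndUpgrade(), small_schedule, economy, transmission, 42
        )
        assert session_profit(results) == pytest.approx(
            sum(r.final_balance_delta for r in results)
        )

    def test_fixed_seed_reproducibility(self, economy, transmission, small_schedule):
        out = []
        for _ in range(2):
            results, records = run_session(
                AlwaysRevealAndUpgrade(), small_schedule, economy, transmission, 99
            )
            out.append(records_to_rows("p0", "c", results, records))
        assert out[0] == out[1]


class TestCurrency:
    @pytest.mark.parametrize(
        "sim, rate, usd",
        [(23_500, MTURK_CONVERSION, 1.0), (12_000, EXPO_CONVERSION, 1.0), (0, 5000, 0.0)],
    )
    def test_conversion(self, sim, rate, usd):
        assert convert_to_usd(sim, rate) == pytest.approx(usd)

    def test_rejects_bad_rate(self):
        with pytest.raises(ValueError):
            convert_to_usd(100, 0)
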