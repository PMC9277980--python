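"""Adjusting-amount staircase: worked example, lattice, replay, bounds."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from discountkit.agents import ChoicePolicy, DiscountForm, DiscountingAgent, DiscountModel
from discountkit.exceptions import ConfigurationError, StateError, ValidationError
from discountkit.staircase import (
    CANONICAL_DELAYS,
    Choice,
    DelayCondition,
    StaircaseConfig,
    advance_staircase,
    indifference_point,
    init_staircase,
    replay_choices,
    replay_frame,
    run_condition,
    run_session,
    trials_to_frame,
)

D, I = Choice.DELAYED, Choice.IMMEDIATE
THREE_YEARS = CANONICAL_DELAYS[5]


def agent_with_value(value: float, delay: DelayCondition, amount: float = 2000.0):
    """Deterministic hyperbolic agent whose subjective value at ``delay`` is ``value``."""
    k = (amount / value - 1.0) / delay.delay_days
    return DiscountingAgent(model=DiscountModel(form=DiscountForm.HYPERBOLIC, k=k))


class TestWorkedExample:
    def test_first_offer_is_half_the_delayed_amount(self, staircase_config):
        state = init_staircase(staircase_config, THREE_YEARS)
        assert state.immediate_amount == 1000.0
        assert state.adjustment == 500.0
        assert state.trial_index == 1

    def test_delayed_then_immediate_gives_1500_then_1250(self, staircase_config):
        s2 = advance_staircase(init_staircase(staircase_config), D, staircase_config)
        assert s2.immediate_amount == 1500.0
        s3 = advance_staircase(s2, I, staircase_config)
        assert s3.immediate_amount == 1250.0

    def test_scales_proportionally_with_delayed_amount(self):
        cfg = StaircaseConfig(delayed_amount=1000.0)
        state = init_staircase(cfg)
        assert state.immediate_amount == 500.0
        assert state.adjustment == 250.0


class TestReplaySequences:
    @pytest.mark.parametrize(
        "choices, amounts",
        [
            ([D] * 6, [1000.0, 1500.0, 1750.0, 1875.0, 1937.5, 1968.75, 1984.375]),
            ([I] * 6, [1000.0, 500.0, 250.0, 125.0, 62.5, 31.25, 15.625]),
            # alternating: 1000 + 500 - 250 + 125 - 62.5 + 31.25 - 15.625
            ([D, I, D, I, D, I], None),
        ],
    )
    def test_hand_replayed_amount_sequences(self, staircase_config, choices, amounts):
        got = replay_choices(choices, staircase_config)
        if amounts is None:
            amounts = [1000.0]
            for c, step in zip(choices, [500.0, 250.0, 125.0, 62.5, 31.25, 15.625]):
                amounts.append(amounts[-1] + step if c is D else amounts[-1] - step)
        assert got == amounts

    @given(st.lists(st.sampled_from([D, I]), min_size=6, max_size=6))
    def test_estimate_lies_on_odd_lattice(self, choices):
        cfg = StaircaseConfig()
        final = replay_choices(choices, cfg)[-1]
        m = final / cfg.resolution
        assert m == round(m) and int(round(m)) % 2 == 1
        assert 0 < final < cfg.delayed_amount

    @given(
        st.lists(st.sampled_from([D, I]), min_size=6, max_size=6),
        st.integers(min_value=0, max_value=5),
    )
    def test_flipping_a_choice_to_delayed_weakly_increases_estimate(self, choices, pos):
        cfg = StaircaseConfig()
        flipped = list(choices)
        flipped[pos] = D
        assert replay_choices(flipped, cfg)[-1] >= replay_choices(choices, cfg)[-1]


class TestBisectionBound:
    @given(st.floats(min_value=1.0, max_value=1999.0))
    def test_deterministic_agent_recovered_within_resolution(self, true_value):
        cfg = StaircaseConfig()
        agent = agent_with_value(true_value, THREE_YEARS)
        _, ip = run_condition(agent, cfg, THREE_YEARS, np.random.default_rng(0))
        assert abs(ip.value - true_value) <= cfg.resolution

    def test_always_delayed_agent_hits_the_ceiling(self, staircase_config):
        agent = DiscountingAgent(model=DiscountModel(k=0.0))  # never discounts
        _, ip = run_condition(agent, staircase_config, THREE_YEARS, np.random.default_rng(0))
        assert ip.value == 1984.375


class TestSessionStructure:
    def test_default_session_has_42_trials_and_7_points(self, staircase_config, rng):
        agent = DiscountingAgent(model=DiscountModel(k=0.005))
        trials, points = run_session(agent, staircase_config, rng)
        assert len(trials) == 42
        assert len(points) == 7
        assert [p.delay.label for p in points] == [d.label for d in CANONICAL_DELAYS]

    def test_reduced_session(self, rng):
        cfg = StaircaseConfig(trials_per_delay=1, delays=CANONICAL_DELAYS[:2])
        agent = DiscountingAgent(model=DiscountModel(k=0.005))
        trials, points = run_session(agent, cfg, rng)
        assert len(trials) == 2 and len(points) == 2

    def test_recorded_trials_replay_exactly(self, staircase_config, rng):
        agent = DiscountingAgent(model=DiscountModel(k=0.002))
        trials, points = run_session(agent, staircase_config, rng, participant_id="p0")
        frame = trials_to_frame(trials)
        replayed = replay_frame(frame, staircase_config)
        assert replayed["value"].tolist() == [p.value for p in points]

    def test_replay_frame_rejects_corrupted_amounts(self, staircase_config, rng):
        agent = DiscountingAgent(model=DiscountModel(k=0.002))
        trials, _ = run_session(agent, staircase_config, rng)
        frame = trials_to_frame(trials)
        frame.loc[3, "immediate_amount"] += 1.0
        with pytest.raises(ValidationError, match="replay"):
            replay_frame(frame, staircase_config)


class TestErrors:
    def test_cannot_advance_past_the_final_trial(self, staircase_config):
        state = init_staircase(staircase_config)
        for _ in range(6):
            state = advance_staircase(state, D, staircase_config)
        with pytest.raises(StateError):
            advance_staircase(state, D, staircase_config)

    def test_indifference_point_requires_complete_condition(self, staircase_config):
        state = init_staircase(staircase_config)
        with pytest.raises(StateError, match="incomplete"):
            indifference_point(state, staircase_config, THREE_YEARS)

    @pytest.mark.parametrize(
        "kwargs, field",
        [
            ({"delayed_amount": -5}, "delayed_amount"),
            ({"trials_per_delay": 0}, "trials_per_delay"),
            ({"delays": (CANONICAL_DELAYS[1], CANONICAL_DELAYS[0])}, "delays"),
        ],
    )
    def test_invalid_config_names_the_field(self, kwargs, field):
        with pytest.raises(ConfigurationError, match=field):
            StaircaseConfig(**kwargs)

    def test_negative_delay_rejected(self):
        with pytest.raises(ConfigurationError, match="delay_days"):
            DelayCondition("yesterday", -1.0)
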