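"""Adjusting-amount staircase for intertemporal choice.

The task asks a responder to choose repeatedly between a smaller immediate
reward and a fixed larger delayed reward (default $2000).  Within each delay
condition the immediate amount starts at half the delayed amount and is
adjusted up after a DELAYED choice and down after an IMMEDIATE choice, with
the adjustment halving on every trial (a binary search on the subjective
value).  After the final trial the indifference point is the amount that a
hypothetical next trial would have presented.

With the defaults (6 trials, $2000) every reachable indifference point lies
on the lattice of odd multiples of $2000 / 2**7 = $15.625, and for any
deterministic threshold responder the estimate is within one lattice step of
the true subjective value.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, StateError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .agents import DiscountingAgent

__all__ = [
    "Choice",
    "DelayCondition",
    "StaircaseConfig",
    "StaircaseState",
    "TrialRecord",
    "IndifferencePoint",
    "CANONICAL_DELAYS",
    "DAYS_PER_MONTH",
    "DAYS_PER_YEAR",
    "init_staircase",
    "advance_staircase",
    "indifference_point",
    "replay_choices",
    "run_condition",
    "run_session",
    "trials_to_frame",
    "frame_to_trials",
    "replay_frame",
]

#: Average Gregorian month / Julian year, used to express labelled delays in
#: days.  Only delay *normalization* depends on this convention; the staircase
#: itself never looks at the delay value.
DAYS_PER_MONTH = 30.4375
DAYS_PER_YEAR = 365.25


class Choice(str, Enum):
    """A single intertemporal choice."""

    IMMEDIATE = "immediate"
    DELAYED = "delayed"


@dataclass(frozen=True)
class DelayCondition:
    """A labelled delay at which the delayed reward would be received."""

    label: str
    delay_days: float

    def __post_init__(self) -> None:
        if not self.delay_days > 0:
            raise ConfigurationError(
                f"delay_days must be positive, got {self.delay_days!r} for {self.label!r}"
            )


#: The seven canonical delay conditions: 1 week to 10 years.
CANONICAL_DELAYS: tuple[DelayCondition, ...] = (
    DelayCondition("1 week", 7.0),
    DelayCondition("1 month", DAYS_PER_MONTH),
    DelayCondition("3 months", 3 * DAYS_PER_MONTH),
    DelayCondition("6 months", 6 * DAYS_PER_MONTH),
    DelayCondition("1 year", DAYS_PER_YEAR),
    DelayCondition("3 years", 3 * DAYS_PER_YEAR),
    DelayCondition("10 years", 10 * DAYS_PER_YEAR),
)


@dataclass(frozen=True)
class StaircaseConfig:
    """Task parameters: the delayed amount, trials per delay, and delays."""

    delayed_amount: float = 2000.0
    trials_per_delay: int = 6
    delays: tuple[DelayCondition, ...] = CANONICAL_DELAYS

    def __post_init__(self) -> None:
        if not self.delayed_amount > 0:
            raise ConfigurationError(
                f"delayed_amount must be positive, got {self.delayed_amount!r}"
            )
        if not (isinstance(self.trials_per_delay, int) and self.trials_per_delay >= 1):
            raise ConfigurationError(
                f"trials_per_delay must be a positive integer, got {self.trials_per_delay!r}"
            )
        if len(self.delays) == 0:
            raise ConfigurationError("delays must be non-empty")
        days = [d.delay_days for d in self.delays]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ConfigurationError(
                f"delays must be strictly increasing in delay_days, got {days}"
            )

    @property
    def resolution(self) -> float:
        """Lattice spacing of the indifference-point estimate."""
        return self.delayed_amount / 2 ** (self.trials_per_delay + 1)


@dataclass(frozen=True)
class StaircaseState:
    """The evolving immediate amount within one delay condition.

    ``trial_index`` is the 1-based index of the trial whose immediate amount
    is currently on offer; after all ``trials_per_delay`` choices have been
    consumed it equals ``trials_per_delay + 1`` and ``immediate_amount`` is
    the amount a hypothetical next trial would present.
    """

    immediate_amount: float
    adjustment: float
    trial_index: int


@dataclass(frozen=True)
class TrialRecord:
    """One presented trial and the choice made on it."""

    participant_id: str
    delay: DelayCondition
    trial_index: int
    immediate_amount: float
    choice: Choice


@dataclass(frozen=True)
class IndifferencePoint:
    """Estimated immediate amount subjectively equivalent to the delayed reward."""

    delay: DelayCondition
    value: float


def init_staircase(config: StaircaseConfig, delay: DelayCondition | None = None) -> StaircaseState:
    """Start a staircase: first offer is half the delayed amount.

    The first adjustment is half of the first trial's immediate/delayed
    difference, i.e. a quarter of the delayed amount.
    """
    first = config.delayed_amount / 2
    return StaircaseState(
        immediate_amount=first,
        adjustment=(config.delayed_amount - first) / 2,
        trial_index=1,
    )


def advance_staircase(
    state: StaircaseState, choice: Choice, config: StaircaseConfig
) -> StaircaseState:
    """Consume the choice for the currently offered trial.

    A DELAYED choice means the immediate amount was too small and is raised
    by the current adjustment; an IMMEDIATE choice lowers it.  The adjustment
    then halves.  Only ``trials_per_delay`` choices may be consumed.
    """
    if state.trial_index > config.trials_per_delay:
        raise StateError(
            f"staircase already complete: {config.trials_per_delay} choices consumed"
        )
    if choice is Choice.DELAYED:
        amount = state.immediate_amount + state.adjustment
    elif choice is Choice.IMMEDIATE:
        amount = state.immediate_amount - state.adjustment
    else:  # pragma: no cover - guarded by the enum
        raise ValidationError(f"unknown choice {choice!r}")
    return StaircaseState(
        immediate_amount=amount,
        adjustment=state.adjustment / 2,
        trial_index=state.trial_index + 1,
    )


def indifference_point(
    final_state: StaircaseState, config: StaircaseConfig, delay: DelayCondition
) -> IndifferencePoint:
    """Read the indifference point off a completed staircase.

    After the final choice the state's immediate amount already equals the
    amount a hypothetical next trial would present, which is the estimate of
    the subjective value of the delayed reward.
    """
    if final_state.trial_index != config.trials_per_delay + 1:
        raise StateError(
            f"condition incomplete: {final_state.trial_index - 1} of "
            f"{config.trials_per_delay} choices consumed"
        )
    return IndifferencePoint(delay=delay, value=final_state.immediate_amount)


def replay_choices(choices: Sequence[Choice], config: StaircaseConfig) -> list[float]:
    """Pure replay: choice sequence -> the amounts presented on each trial.

    Returns ``len(choices) + 1`` amounts; the last is the hypothetical
    next-trial amount (the indifference point when the sequence is complete).
    """
    state = init_staircase(config)
    amounts = [state.immediate_amount]
    for c in choices:
        state = advance_staircase(state, c, config)
        amounts.append(state.immediate_amount)
    return amounts


def run_condition(
    agent: "DiscountingAgent",
    config: StaircaseConfig,
    delay: DelayCondition,
    rng: "np.random.Generator",
    participant_id: str = "agent",
) -> tuple[list[TrialRecord], IndifferencePoint]:
    """Run one delay condition against a simulated responder."""
    state = init_staircase(config, delay)
    records: list[TrialRecord] = []
    for _ in range(config.trials_per_delay):
        choice = agent.choose(
            immediate=state.immediate_amount,
            delayed=config.delayed_amount,
            delay_days=delay.delay_days,
            rng=rng,
        )
        records.append(
            TrialRecord(
                participant_id=participant_id,
                delay=delay,
                trial_index=state.trial_index,
                immediate_amount=state.immediate_amount,
                choice=choice,
            )
        )
        state = advance_staircase(state, choice, config)
    return records, indifference_point(state, config, delay)


def run_session(
    agent: "DiscountingAgent",
    config: StaircaseConfig,
    rng: "np.random.Generator",
    participant_id: str = "agent",
) -> tuple[list[TrialRecord], list[IndifferencePoint]]:
    """Run every delay condition; 42 trials and 7 indifference points at defaults."""
    trials: list[TrialRecord] = []
    points: list[IndifferencePoint] = []
    for delay in config.delays:
        recs, ip = run_condition(agent, config, delay, rng, participant_id)
        trials.extend(recs)
        points.append(ip)
    return trials, points


def trials_to_frame(records: Iterable[TrialRecord]) -> pd.DataFrame:
    """Trial records -> the trial-level CSV schema (one row per trial)."""
    return pd.DataFrame(
        {
            "participant_id": r.participant_id,
            "delay_label": r.delay.label,
            "delay_days": r.delay.delay_days,
            "trial_index": r.trial_index,
            "immediate_amount": r.immediate_amount,
            "choice": r.choice.value,
        }
        for r in records
    )


def replay_frame(
    frame: pd.DataFrame, config: StaircaseConfig | None = None, verify: bool = True
) -> pd.DataFrame:
    """Replay a trial table and return one indifference point per condition.

    The staircase is deterministic given the choice sequence, so the
    presented amounts are recomputed from the recorded choices; with
    ``verify`` the recomputed amounts must match the recorded ones exactly,
    which guards against corrupted or incomplete trial tables.  Returns a
    frame with columns participant_id, delay_label, delay_days, value.
    """
    config = config or StaircaseConfig()
    t = config.trials_per_delay
    f = frame.sort_values(["participant_id", "delay_days", "trial_index"], kind="stable")
    sizes = f.groupby(["participant_id", "delay_days"], sort=False).size()
    if not (sizes == t).all():
        bad = sizes[sizes != t].index[0]
        raise StateError(f"condition {bad} has {sizes[sizes != t].iloc[0]} trials, expected {t}")
    idx = f["trial_index"].to_numpy().reshape(-1, t)
    if not (idx == np.arange(1, t + 1)).all():
        raise StateError("trial_index within a condition must be 1..trials_per_delay")
    delayed_choice = (f["choice"].to_numpy() == Choice.DELAYED.value).reshape(-1, t)
    amount = np.full(len(delayed_choice), config.delayed_amount / 2)
    adjustment = config.delayed_amount / 4
    for j in range(t):
        if verify:
            recorded = f["immediate_amount"].to_numpy().reshape(-1, t)[:, j]
            if not np.array_equal(recorded, amount):
                raise ValidationError(
                    f"recorded amounts at trial {j + 1} do not match the staircase replay"
                )
        amount = np.where(delayed_choice[:, j], amount + adjustment, amount - adjustment)
        adjustment /= 2
    heads = f.iloc[::t][["participant_id", "delay_label", "delay_days"]].reset_index(drop=True)
    heads["value"] = amount
    return heads


def frame_to_trials(frame: pd.DataFrame) -> list[TrialRecord]:
    """Inverse of :func:`trials_to_frame`."""
    required = {
        "participant_id",
        "delay_label",
        "delay_days",
        "trial_index",
        "immediate_amount",
        "choice",
    }
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"trial table missing columns: {sorted(missing)}")
    return [
        TrialRecord(
            participant_id=str(row.participant_id),
            delay=DelayCondition(row.delay_label, float(row.delay_days)),
            trial_index=int(row.trial_index),
            immediate_amount=float(row.immediate_amount),
            choice=Choice(row.choice),
        )
        for row in frame.itertuples(index=False)
    ]
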