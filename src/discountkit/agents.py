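"""Parametric simulated responders for the staircase task.

An agent combines a discounting model, which assigns a subjective value
V(A, D) to an amount A delayed by D days, with a choice policy that turns
the comparison between the immediate offer and V into a choice.  Supported
forms:

* hyperbolic      V = A / (1 + kD)
* exponential     V = A * exp(-kD)
* hyperboloid     V = A / (1 + kD)^s   (equals hyperbolic at s = 1)

The deterministic policy picks IMMEDIATE exactly when the immediate offer
exceeds V (ties go to DELAYED).  The logistic policy chooses IMMEDIATE with
probability sigmoid((immediate - V) / temperature): noise acts on the
currency difference, so temperature is a dollar scale, and the policy
converges to the deterministic one as temperature -> 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import special

from .exceptions import ConfigurationError, ValidationError
from .staircase import Choice

__all__ = [
    "DiscountForm",
    "PolicyKind",
    "DiscountModel",
    "ChoicePolicy",
    "DiscountingAgent",
    "subjective_value",
]


class DiscountForm(str, Enum):
    HYPERBOLIC = "hyperbolic"
    EXPONENTIAL = "exponential"
    HYPERBOLOID = "hyperboloid"


class PolicyKind(str, Enum):
    DETERMINISTIC = "deterministic"
    LOGISTIC = "logistic"


@dataclass(frozen=True)
class DiscountModel:
    """A discounting functional form with rate k (1/day) and exponent s."""

    form: DiscountForm = DiscountForm.HYPERBOLIC
    k: float = 0.01
    s: float = 1.0

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ConfigurationError(f"k must be nonnegative, got {self.k!r}")
        if not self.s > 0:
            raise ConfigurationError(f"s must be positive, got {self.s!r}")


@dataclass(frozen=True)
class ChoicePolicy:
    """How subjective values are turned into choices."""

    kind: PolicyKind = PolicyKind.DETERMINISTIC
    temperature: float = 0.0

    def __post_init__(self) -> None:
        if self.kind is PolicyKind.LOGISTIC and not self.temperature > 0:
            raise ConfigurationError(
                f"temperature must be positive for a logistic policy, got {self.temperature!r}"
            )


def subjective_value(model: DiscountModel, amount, delay_days):
    """Discounted value of ``amount`` received after ``delay_days`` days.

    Vectorized over ``amount`` and ``delay_days``.
    """
    amount = np.asarray(amount, dtype=float)
    delay_days = np.asarray(delay_days, dtype=float)
    if np.any(amount <= 0):
        raise ValidationError(f"amount must be positive, got {amount!r}")
    if np.any(delay_days < 0):
        raise ValidationError(f"delay_days must be nonnegative, got {delay_days!r}")
    if model.form is DiscountForm.HYPERBOLIC:
        v = amount / (1.0 + model.k * delay_days)
    elif model.form is DiscountForm.EXPONENTIAL:
        v = amount * np.exp(-model.k * delay_days)
    else:
        v = amount / (1.0 + model.k * delay_days) ** model.s
    return v if v.ndim else float(v)


@dataclass(frozen=True)
class DiscountingAgent:
    """A discount model plus a choice policy; generates staircase choices."""

    model: DiscountModel
    policy: ChoicePolicy = ChoicePolicy()
    id: str = "agent"

    def value(self, amount: float, delay_days: float) -> float:
        return subjective_value(self.model, amount, delay_days)

    def choose(
        self,
        immediate: float,
        delayed: float,
        delay_days: float,
        rng: np.random.Generator | None = None,
    ) -> Choice:
        """Choose between an immediate offer and the delayed reward."""
        if immediate <= 0 or delayed <= 0:
            raise ValidationError("amounts must be positive")
        v = self.value(delayed, delay_days)
        if self.policy.kind is PolicyKind.DETERMINISTIC:
            return Choice.IMMEDIATE if immediate > v else Choice.DELAYED
        if rng is None:
            raise ValidationError("a seeded rng is required for a logistic policy")
        p_immediate = special.expit((immediate - v) / self.policy.temperature)
        return Choice.IMMEDIATE if rng.random() < p_immediate else Choice.DELAYED
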