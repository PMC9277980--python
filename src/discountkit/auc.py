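"""Area-under-the-curve scoring of discounting data.

Indifference points are normalized — delay by the longest task delay, value
by the delayed amount — and connected piecewise-linearly; the area under
that curve (trapezoid rule) is the AuC, a theory-neutral discounting
measure on [0, 1].  Higher AuC means shallower discounting.

By default a (0, 1) anchor point is prepended (an undelayed reward keeps
its full value), so the curve spans the whole unit interval and AuC = 1
corresponds to no discounting at all.  The anchor is a flag because the
convention is not universal; both variants are supported and tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .staircase import CANONICAL_DELAYS, IndifferencePoint

__all__ = ["DiscountingCurve", "AucScore", "normalize_curve", "compute_auc", "points_frame"]

#: Default normalization horizon: the 10-year task delay, in days.
DEFAULT_MAX_DELAY_DAYS = CANONICAL_DELAYS[-1].delay_days


@dataclass(frozen=True)
class DiscountingCurve:
    """Normalized (delay, value) points, optionally anchored at (0, 1)."""

    x: np.ndarray  # normalized delays, strictly increasing, last = 1
    y: np.ndarray  # normalized values in [0, 1]
    anchored: bool

    def __post_init__(self) -> None:
        x, y = np.asarray(self.x, float), np.asarray(self.y, float)
        if x.shape != y.shape or x.ndim != 1 or x.size < 2:
            raise ValidationError("curve needs >= 2 matched (x, y) points")
        if np.any(np.diff(x) <= 0):
            raise ValidationError("normalized delays must be strictly increasing")
        if np.any((y < 0) | (y > 1)):
            raise ValidationError("normalized values must lie in [0, 1]")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)


@dataclass(frozen=True)
class AucScore:
    """Trapezoid area under a normalized discounting curve, in [0, 1]."""

    value: float


def _as_pairs(points: Iterable) -> list[tuple[float, float]]:
    pairs = []
    for p in points:
        if isinstance(p, IndifferencePoint):
            pairs.append((p.delay.delay_days, p.value))
        else:
            d, v = p
            pairs.append((float(d), float(v)))
    return pairs


def normalize_curve(
    points: Sequence,
    delayed_amount: float = 2000.0,
    max_delay_days: float | None = None,
    anchor: bool = True,
) -> DiscountingCurve:
    """Build the normalized discounting curve from indifference points.

    ``points`` may be :class:`IndifferencePoint` objects or raw
    ``(delay_days, value)`` pairs, in increasing delay order.  Delays are
    divided by ``max_delay_days`` (default: the largest delay supplied, or
    the canonical 10-year horizon when the points carry canonical delays)
    and values by ``delayed_amount``.
    """
    pairs = _as_pairs(points)
    if len(pairs) < 2:
        raise ValidationError("need at least 2 indifference points")
    delays = np.array([d for d, _ in pairs])
    values = np.array([v for _, v in pairs])
    if len(set(delays.tolist())) != len(delays):
        raise ValidationError(f"duplicate delays in {delays.tolist()}")
    if np.any(np.diff(delays) <= 0):
        raise ValidationError("points must be sorted by increasing delay")
    if np.any((values < 0) | (values > delayed_amount)):
        raise ValidationError(
            f"indifference values must lie within [0, {delayed_amount}]"
        )
    if max_delay_days is None:
        max_delay_days = float(delays[-1])
    if delays[-1] != max_delay_days:
        raise ValidationError(
            f"largest delay {delays[-1]} must equal the normalization horizon {max_delay_days}"
        )
    x = delays / max_delay_days
    y = values / delayed_amount
    if anchor:
        x = np.concatenate([[0.0], x])
        y = np.concatenate([[1.0], y])
    return DiscountingCurve(x=x, y=y, anchored=anchor)


def compute_auc(curve: DiscountingCurve) -> AucScore:
    """Trapezoid-rule area under the curve over its x-span."""
    if curve.x[-1] != 1.0:
        raise ValidationError("curve must extend to the maximum delay (x = 1)")
    return AucScore(value=float(np.trapezoid(curve.y, curve.x)))


def points_frame(
    participant_points: dict[str, Sequence[IndifferencePoint]],
    delayed_amount: float = 2000.0,
    anchor: bool = True,
) -> pd.DataFrame:
    """Participant-level table: AuC plus one raw indifference point per delay."""
    rows = []
    for pid, pts in participant_points.items():
        curve = normalize_curve(pts, delayed_amount=delayed_amount, anchor=anchor)
        row = {"participant_id": pid, "auc": compute_auc(curve).value}
        for p in pts:
            row[f"ip_{p.delay.label.replace(' ', '_')}"] = p.value
        rows.append(row)
    return pd.DataFrame(rows)
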