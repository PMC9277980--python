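"""Questionnaire scoring, distress index, exclusions, vaccination coding.

GAD-7 (7 anxiety items) and PHQ-9 (9 depression items) are rated 0-3 per
item and summed; the psychological distress index is the sum of the two
sample-standardized totals, so it has mean 0 by construction and standard
deviation sqrt(2 + 2r) where r is the correlation between the totals.

Exclusions are applied in a fixed precedence order — ineligible, incomplete
survey, missing vaccination status, more than one failed attention check
(a single failure is retained), excluded country — and each participant is
counted under the first rule it trips, so the report partitions the removed
rows.

The four-level vaccination status collapses to a binary outcome: fully or
partially vaccinated count as vaccinated; unvaccinated-but-planning and
unvaccinated-not-planning count as unvaccinated.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, SchemaError, ValidationError

__all__ = [
    "VACCINATION_LEVELS",
    "VACCINATED_LEVELS",
    "ExclusionReport",
    "score_scale",
    "distress_index",
    "binarize_vaccination",
    "apply_exclusions",
]

VACCINATION_LEVELS = ("full", "partial", "unvacc_planning", "unvacc_not_planning")
VACCINATED_LEVELS = frozenset({"full", "partial"})

#: Columns apply_exclusions needs, beyond participant_id.
_EXCLUSION_COLUMNS = ("eligible", "completed", "vaccination_raw", "attention_fails", "country")


def score_scale(items, n_items: int, max_item: int = 3) -> int:
    """Total score of one questionnaire scale (sum of item scores).

    Raises a validation error listing the offending item indices when items
    are missing or out of the 0..max_item range; missing items are never
    silently zeroed.
    """
    arr = np.asarray(items, dtype=float)
    if arr.shape != (n_items,):
        raise ValidationError(f"expected {n_items} items, got shape {arr.shape}")
    bad = np.nonzero(~np.isfinite(arr) | (arr < 0) | (arr > max_item) | (arr % 1 != 0))[0]
    if bad.size:
        raise ValidationError(f"items out of range or missing at indices {bad.tolist()}")
    return int(arr.sum())


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateInputError("scale totals have zero variance; cannot standardize")
    return (v - v.mean()) / sd


def distress_index(gad7_totals, phq9_totals) -> np.ndarray:
    """Sum of sample-standardized GAD-7 and PHQ-9 totals (mean 0 by design)."""
    g = np.asarray(gad7_totals, dtype=float)
    p = np.asarray(phq9_totals, dtype=float)
    if g.shape != p.shape or g.ndim != 1 or g.size < 2:
        raise ValidationError("need two equal-length vectors with >= 2 entries")
    return _zscore(g) + _zscore(p)


def binarize_vaccination(raw):
    """4-level vaccination status -> 1 (vaccinated) / 0 (unvaccinated).

    Accepts a single level or a pandas Series.
    """
    if isinstance(raw, pd.Series):
        unknown = set(raw.dropna().unique()) - set(VACCINATION_LEVELS)
        if unknown or raw.isna().any():
            raise ValidationError(
                f"unknown or missing vaccination levels: {sorted(map(str, unknown)) or 'NA'}"
            )
        return raw.isin(VACCINATED_LEVELS).astype(int)
    if raw not in VACCINATION_LEVELS:
        raise ValidationError(f"unknown vaccination level {raw!r}")
    return int(raw in VACCINATED_LEVELS)


@dataclass
class ExclusionReport:
    """Counts of removed participants by (first-matching) reason."""

    ineligible: int = 0
    incomplete: int = 0
    missing_vaccination: int = 0
    attention_fail: int = 0
    excluded_country: int = 0
    n_in: int = 0
    n_out: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def n_excluded(self) -> int:
        return (
            self.ineligible
            + self.incomplete
            + self.missing_vaccination
            + self.attention_fail
            + self.excluded_country
        )


def apply_exclusions(
    raw: pd.DataFrame,
    excluded_countries: tuple[str, ...] = ("ZAF",),
    max_attention_fails: int = 1,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Filter a raw participant table and account for every removed row.

    Rules, in precedence order: not eligible; survey not completed;
    vaccination status missing; attention-check failures strictly greater
    than ``max_attention_fails``; country in ``excluded_countries``.
    The counts are independent of row order.
    """
    missing = [c for c in _EXCLUSION_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"raw table missing columns: {missing}")
    report = ExclusionReport(n_in=len(raw))
    if raw.empty:
        return raw.copy(), report

    remaining = np.ones(len(raw), dtype=bool)

    def take(mask: np.ndarray) -> int:
        nonlocal remaining
        hit = remaining & np.asarray(mask, bool)
        remaining &= ~hit
        return int(hit.sum())

    report.ineligible = take(~raw["eligible"].fillna(False).astype(bool).to_numpy())
    report.incomplete = take(~raw["completed"].fillna(False).astype(bool).to_numpy())
    report.missing_vaccination = take(raw["vaccination_raw"].isna().to_numpy())
    report.attention_fail = take(
        raw["attention_fails"].fillna(0).to_numpy(dtype=float) > max_attention_fails
    )
    report.excluded_country = take(raw["country"].isin(excluded_countries).to_numpy())

    clean = raw.loc[remaining].copy()
    report.n_out = len(clean)
    return clean, report
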