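"""Regional COVID-19 severity index via principal component analysis.

Six epidemiological metrics per country-week — weekly cases and deaths,
cumulative cases and deaths, and cumulative cases/deaths per 100,000
population — are standardized (mean 0, SD 1 with the n-1 denominator, which
makes the analysis equivalent to PCA of the correlation matrix) and
decomposed by SVD.  Components with eigenvalue > 1 are considered reliable;
the severity index is the PC1 score, sign-oriented so that its loading on
deaths per 100k is positive (higher score = more severe situation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, RetentionError, SchemaError

__all__ = [
    "SEVERITY_METRICS",
    "PcaResult",
    "standardize",
    "pca_svd",
    "severity_scores",
    "severity_index",
    "participant_severity",
]

#: The six ECDC-style metric columns, in canonical order.
SEVERITY_METRICS = (
    "weekly_cases",
    "weekly_deaths",
    "cum_cases",
    "cum_deaths",
    "cases_per_100k",
    "deaths_per_100k",
)


@dataclass(frozen=True)
class PcaResult:
    """Eigenvalues (descending), orthonormal loadings (p x m), scores (n x m)."""

    eigenvalues: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    columns: tuple[str, ...]

    @property
    def variance_fraction(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()

    def to_summary(self) -> dict:
        return {
            "eigenvalues": self.eigenvalues.tolist(),
            "variance_fraction": self.variance_fraction.tolist(),
            "loadings": {
                col: self.loadings[i].tolist() for i, col in enumerate(self.columns)
            },
        }


def standardize(matrix, ddof: int = 1) -> np.ndarray:
    """Column-wise z-scoring (mean 0, SD 1, sample SD by default)."""
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise DegenerateInputError(f"expected a 2-D matrix, got ndim={x.ndim}")
    sd = x.std(axis=0, ddof=ddof)
    constant = np.nonzero(sd == 0)[0]
    if constant.size:
        raise DegenerateInputError(f"constant columns at indices {constant.tolist()}")
    return (x - x.mean(axis=0)) / sd


def pca_svd(standardized: np.ndarray, columns: tuple[str, ...] | None = None) -> PcaResult:
    """PCA of a standardized matrix via singular value decomposition.

    Eigenvalues are singular_value**2 / (n - 1), identical to the
    eigenvalues of the sample correlation matrix of the raw data; on a
    p-column standardized input they sum to p.  Rank deficiency triggers a
    warning and the component count is reduced accordingly.
    """
    z = np.asarray(standardized, dtype=float)
    n, p = z.shape
    if n <= p:
        raise DegenerateInputError(f"need more rows than columns, got {n} x {p}")
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    tol = s[0] * max(n, p) * np.finfo(float).eps
    rank = int((s > tol).sum())
    if rank < p:
        warnings.warn(
            f"rank-deficient input: keeping {rank} of {p} components", stacklevel=2
        )
    eigenvalues = eigenvalues[:rank]
    loadings = vt[:rank].T  # p x rank, orthonormal columns
    scores = z @ loadings  # n x rank; equals u * s on the kept components
    if columns is None:
        columns = tuple(f"col{i}" for i in range(p))
    return PcaResult(
        eigenvalues=eigenvalues, loadings=loadings, scores=scores, columns=tuple(columns)
    )


def severity_scores(
    result: PcaResult,
    orient_by: str = "deaths_per_100k",
    retention_threshold: float = 1.0,
) -> np.ndarray:
    """PC1 component scores, oriented so higher = more severe.

    Requires the leading eigenvalue to exceed the retention threshold
    (Kaiser rule, lambda > 1); the sign is fixed so the PC1 loading on
    ``orient_by`` is positive.
    """
    lam1 = result.eigenvalues[0]
    if lam1 <= retention_threshold:
        raise RetentionError(
            f"leading eigenvalue {lam1:.4f} <= {retention_threshold}; no reliable component"
        )
    try:
        j = result.columns.index(orient_by)
    except ValueError:
        raise SchemaError(f"orientation column {orient_by!r} not among {result.columns}")
    sign = 1.0 if result.loadings[j, 0] >= 0 else -1.0
    return sign * result.scores[:, 0]


def severity_index(
    epi: pd.DataFrame, metrics: tuple[str, ...] = SEVERITY_METRICS
) -> tuple[pd.Series, PcaResult]:
    """Severity index for each row of an epidemiological table."""
    missing = [m for m in metrics if m not in epi.columns]
    if missing:
        raise SchemaError(f"epi table missing metric columns: {missing}")
    z = standardize(epi[list(metrics)].to_numpy())
    result = pca_svd(z, columns=metrics)
    scores = severity_scores(result)
    return pd.Series(scores, index=epi.index, name="severity_index"), result


def participant_severity(
    epi: pd.DataFrame,
    participants: pd.DataFrame,
    metrics: tuple[str, ...] = SEVERITY_METRICS,
) -> tuple[pd.DataFrame, PcaResult]:
    """Severity index with one PCA row per participant.

    Each participant contributes the epi record of their (country,
    survey week); repeated country-weeks are therefore weighted by how many
    participants they cover, mirroring a per-participant extraction.
    """
    for col in ("participant_id", "country", "survey_week"):
        if col not in participants.columns:
            raise SchemaError(f"participant table missing column {col!r}")
    for col in ("country", "iso_week"):
        if col not in epi.columns:
            raise SchemaError(f"epi table missing column {col!r}")
    merged = participants[["participant_id", "country", "survey_week"]].merge(
        epi,
        left_on=("country", "survey_week"),
        right_on=("country", "iso_week"),
        how="left",
        validate="many_to_one",
    )
    if merged[list(metrics)].isna().any().any():
        bad = merged.loc[merged[list(metrics)].isna().any(axis=1), "participant_id"]
        raise SchemaError(
            f"no epi record for {len(bad)} participants (e.g. {bad.iloc[0]!r})"
        )
    z = standardize(merged[list(metrics)].to_numpy())
    result = pca_svd(z, columns=metrics)
    merged["severity_index"] = severity_scores(result)
    return merged[["participant_id", "country", "survey_week", "severity_index"]], result
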