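"""Synthetic multinational cohort generator.

Emulates the statistical structure the analysis pipeline assumes, so every
stage is testable end-to-end without any external data:

* 13 countries of unequal size, each with a Normal(0, sigma_u) random
  intercept on the log-odds of being vaccinated (default sigma_u^2 = 1.54);
* hyperbolic discounting agents with log-normally distributed rates k
  (defaults chosen so the implied AuC distribution has mean ~0.40 and
  SD ~0.25), whose staircase sessions produce the trial table and the
  measured AuC;
* demographics from documented marginal distributions (age shifted
  log-normal around 30 y, ordinal education, 0-100 relative income,
  ~22% essential workers) drawn independently of each other;
* GAD-7 / PHQ-9 item responses from a one-factor latent distress model;
* a Bernoulli vaccination outcome with logit = intercept + X beta + u_c,
  using by default the fixed-effect estimates of the reference analysis
  (age 0.04, education 0.27, income 0.004, essential 0.58, distress 0.001,
  AuC 0.53; intercept -2.50) — note the near-zero distress coefficient is
  deliberate, so "distress is not a unique predictor" emerges honestly;
* a country-week epidemiological table with a shared severity factor so a
  dominant first principal component exists, weekly counts summing exactly
  to the cumulative columns.

All randomness flows from one root seed through named SeedSequence streams,
so regenerating with the same config is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import special

from .exceptions import ConfigurationError
from .staircase import StaircaseConfig
from .survey import distress_index

__all__ = [
    "COUNTRIES",
    "DEFAULT_BETA",
    "DEFAULT_FACTOR_LOADING",
    "CohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "generate_epi_table",
    "factor_model_matrix",
]

#: ISO-3 codes for the 13 simulated countries (Australasia, Europe, North America).
COUNTRIES: tuple[str, ...] = (
    "AUS", "CAN", "CHE", "DEU", "ESP", "FRA", "GBR",
    "GRC", "IRL", "ITA", "MEX", "NZL", "USA",
)

#: Generator fixed effects on the log-odds scale (reference-analysis estimates).
DEFAULT_BETA: dict[str, float] = {
    "age": 0.04,
    "education": 0.27,
    "income": 0.004,
    "essential_worker": 0.58,
    "distress_index": 0.001,
    "auc": 0.53,
}

#: Equicorrelated one-factor loading for which the population PC1 variance
#: fraction of a 6-column matrix is 0.635: (1 + 5 a^2) / 6 = 0.635.
DEFAULT_FACTOR_LOADING: float = float(np.sqrt((0.635 * 6 - 1) / 5))


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for the synthetic cohort."""

    n_participants: int = 4452
    countries: tuple[str, ...] = COUNTRIES
    country_intercept_sd: float = float(np.sqrt(1.54))
    intercept: float = -2.50
    beta: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA))
    k_meanlog: float = -6.5
    k_sdlog: float = 1.6
    temperature: float = 0.0  # 0 = deterministic agents
    staircase: StaircaseConfig = field(default_factory=StaircaseConfig)
    n_weeks: int = 60
    factor_loading: float = DEFAULT_FACTOR_LOADING
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be positive")
        if len(self.countries) < 2:
            raise ConfigurationError("need at least 2 countries")
        if self.country_intercept_sd < 0:
            raise ConfigurationError("country_intercept_sd must be nonnegative")
        if self.temperature < 0:
            raise ConfigurationError("temperature must be nonnegative")
        if set(self.beta) != set(DEFAULT_BETA):
            raise ConfigurationError(
                f"beta must have exactly the keys {sorted(DEFAULT_BETA)}"
            )

    @property
    def n_countries(self) -> int:
        return len(self.countries)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["staircase"] = {
            "delayed_amount": self.staircase.delayed_amount,
            "trials_per_delay": self.staircase.trials_per_delay,
            "delays": [
                {"label": dl.label, "delay_days": dl.delay_days}
                for dl in self.staircase.delays
            ],
        }
        return d


@dataclass
class SyntheticCohort:
    """Generated tables plus the ground truth behind them."""

    participants: pd.DataFrame
    trials: pd.DataFrame
    epi: pd.DataFrame
    truth: pd.DataFrame
    config: CohortConfig


def _rng_streams(seed: int, names: tuple[str, ...]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def _simulate_staircases(ks: np.ndarray, config: StaircaseConfig, temperature: float,
                         rng: np.random.Generator):
    """Vectorized staircase sessions for hyperbolic deterministic/logistic agents.

    Returns (indifference points n x d, presented amounts n x d x t,
    delayed-choice flags n x d x t).
    """
    n = ks.size
    delays = config.delays
    a_total = config.delayed_amount
    n_d, n_t = len(delays), config.trials_per_delay
    points = np.empty((n, n_d))
    amounts = np.empty((n, n_d, n_t))
    chose_delayed = np.empty((n, n_d, n_t), dtype=bool)
    for di, delay in enumerate(delays):
        v = a_total / (1.0 + ks * delay.delay_days)
        amt = np.full(n, a_total / 2.0)
        adj = a_total / 4.0
        for t in range(n_t):
            if temperature > 0:
                p_imm = special.expit((amt - v) / temperature)
                imm = rng.random(n) < p_imm
            else:
                imm = amt > v  # ties go to DELAYED
            amounts[:, di, t] = amt
            chose_delayed[:, di, t] = ~imm
            amt = np.where(imm, amt - adj, amt + adj)
            adj /= 2.0
        points[:, di] = amt
    return points, amounts, chose_delayed


def _curve_auc(values: np.ndarray, delays_days: np.ndarray, delayed_amount: float) -> np.ndarray:
    """Anchored trapezoid AuC, rows = participants, columns = delays."""
    x = np.concatenate([[0.0], delays_days / delays_days[-1]])
    y = np.concatenate(
        [np.ones((values.shape[0], 1)), values / delayed_amount], axis=1
    )
    return np.trapezoid(y, x, axis=1)


def _distress_items(n: int, n_items: int, scale_latent: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """Ordinal 0-3 items from a latent scale score (one-factor model)."""
    loading = 0.85
    latent = loading * scale_latent[:, None] + np.sqrt(1 - loading**2) * rng.standard_normal(
        (n, n_items)
    )
    return np.digitize(latent, [0.35, 1.1, 1.8])


def generate_cohort(config: CohortConfig, rng: np.random.Generator | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort under the configured conditions."""
    if rng is None:
        if config.seed is None:
            raise ConfigurationError("config.seed is required when no rng is supplied")
        streams = _rng_streams(config.seed, ("demo", "task", "items", "outcome", "epi"))
    else:
        streams = {k: rng for k in ("demo", "task", "items", "outcome", "epi")}
    n = config.n_participants
    demo = streams["demo"]

    pid = np.array([f"p{i:05d}" for i in range(n)])
    weights = np.linspace(0.5, 1.5, config.n_countries)
    country = demo.choice(config.countries, size=n, p=weights / weights.sum())
    age = np.clip(18.0 + demo.lognormal(2.2257, 0.72, n), 18.0, 95.0)
    gender = demo.choice(["female", "male", "nonbinary"], size=n, p=[0.49, 0.49, 0.02])
    education = demo.choice([1, 2, 3], size=n, p=[0.30, 0.51, 0.19])
    income = 100.0 * demo.beta(1.6, 2.4, n)
    essential = (demo.random(n) < 0.22).astype(int)
    attention_fails = demo.choice([0, 1, 2, 3], size=n, p=[0.95, 0.03, 0.015, 0.005])

    # Discounting agents and their staircase sessions.
    ks = streams["task"].lognormal(config.k_meanlog, config.k_sdlog, n)
    points, amounts, chose_delayed = _simulate_staircases(
        ks, config.staircase, config.temperature, streams["task"]
    )
    delays_days = np.array([d.delay_days for d in config.staircase.delays])
    a_total = config.staircase.delayed_amount
    auc_measured = _curve_auc(points, delays_days, a_total)
    true_values = a_total / (1.0 + ks[:, None] * delays_days[None, :])
    auc_true = _curve_auc(true_values, delays_days, a_total)

    # Latent distress factor -> GAD-7 / PHQ-9 items -> standardized index.
    items_rng = streams["items"]
    z = items_rng.standard_normal(n)
    gad_latent = np.sqrt(0.8) * z + np.sqrt(0.2) * items_rng.standard_normal(n)
    phq_latent = np.sqrt(0.8) * z + np.sqrt(0.2) * items_rng.standard_normal(n)
    gad_items = _distress_items(n, 7, gad_latent, items_rng)
    phq_items = _distress_items(n, 9, phq_latent, items_rng)
    gad_total = gad_items.sum(axis=1)
    phq_total = phq_items.sum(axis=1)
    distress = distress_index(gad_total, phq_total)

    # Vaccination outcome: country random intercepts + fixed effects.
    outcome_rng = streams["outcome"]
    u = outcome_rng.normal(0.0, config.country_intercept_sd, config.n_countries)
    country_idx = {c: i for i, c in enumerate(config.countries)}
    u_row = u[np.array([country_idx[c] for c in country])]
    b = config.beta
    lp = (
        config.intercept
        + b["age"] * age
        + b["education"] * education
        + b["income"] * income
        + b["essential_worker"] * essential
        + b["distress_index"] * distress
        + b["auc"] * auc_measured
        + u_row
    )
    p_vacc = special.expit(lp)
    vaccinated = (outcome_rng.random(n) < p_vacc).astype(int)
    vaccination_raw = np.where(
        vaccinated == 1,
        np.where(outcome_rng.random(n) < 0.60, "full", "partial"),
        np.where(outcome_rng.random(n) < 0.78, "unvacc_planning", "unvacc_not_planning"),
    )

    epi = generate_epi_table(config, streams["epi"])
    last_weeks = np.arange(config.n_weeks - 2, config.n_weeks + 1)
    survey_week = demo.choice(last_weeks, size=n)

    participants = pd.DataFrame(
        {
            "participant_id": pid,
            "country": country,
            "survey_week": survey_week,
            "age": age,
            "gender": gender,
            "education": education,
            "income": income,
            "essential_worker": essential,
            "gad7_total": gad_total,
            "phq9_total": phq_total,
            "distress_index": distress,
            "auc": auc_measured,
            "vaccination_raw": vaccination_raw,
            "vaccinated": vaccinated,
            "eligible": True,
            "completed": True,
            "attention_fails": attention_fails,
        }
    )
    for j in range(7):
        participants[f"gad7_{j + 1}"] = gad_items[:, j]
    for j in range(9):
        participants[f"phq9_{j + 1}"] = phq_items[:, j]
    for di, d in enumerate(config.staircase.delays):
        participants[f"ip_{d.label.replace(' ', '_')}"] = points[:, di]

    n_d, n_t = len(config.staircase.delays), config.staircase.trials_per_delay
    trials = pd.DataFrame(
        {
            "participant_id": np.repeat(pid, n_d * n_t),
            "delay_label": np.tile(
                np.repeat([d.label for d in config.staircase.delays], n_t), n
            ),
            "delay_days": np.tile(np.repeat(delays_days, n_t), n),
            "trial_index": np.tile(np.arange(1, n_t + 1), n * n_d),
            "immediate_amount": amounts.reshape(-1),
            "choice": np.where(chose_delayed.reshape(-1), "delayed", "immediate"),
        }
    )

    truth = pd.DataFrame(
        {
            "participant_id": pid,
            "country": country,
            "k": ks,
            "auc_true": auc_true,
            "auc_measured": auc_measured,
            "u_country": u_row,
            "linear_predictor": lp,
            "p_vaccinated": p_vacc,
        }
    )

    return SyntheticCohort(
        participants=participants, trials=trials, epi=epi, truth=truth, config=config
    )


def generate_epi_table(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Country-week epidemiological table with a shared severity factor.

    Weekly cases and deaths follow log-normal series driven by a common
    country-level severity plus a smooth country-week severity wave, so the
    six derived metrics share a dominant first principal component.
    Cumulative columns are exact running sums of the weekly columns and the
    per-100k columns are cumulative counts scaled by population.
    """
    n_c, n_w = config.n_countries, config.n_weeks
    population = rng.lognormal(np.log(2e7), 0.8, n_c)
    base = rng.normal(0.0, 1.0, n_c)  # persistent country severity level
    wave = np.cumsum(rng.normal(0.0, 0.3, (n_c, n_w)), axis=1)
    severity = base[:, None] + wave
    log_cases = np.log(population)[:, None] - 9.5 + severity + 0.2 * rng.standard_normal((n_c, n_w))
    log_deaths = np.log(population)[:, None] - 14.0 + severity + 0.25 * rng.standard_normal((n_c, n_w))
    weekly_cases = np.rint(np.exp(log_cases)).astype(np.int64)
    weekly_deaths = np.rint(np.exp(log_deaths)).astype(np.int64)
    cum_cases = weekly_cases.cumsum(axis=1)
    cum_deaths = weekly_deaths.cumsum(axis=1)
    return pd.DataFrame(
        {
            "country": np.repeat(config.countries, n_w),
            "iso_week": np.tile(np.arange(1, n_w + 1), n_c),
            "population": np.repeat(population, n_w),
            "weekly_cases": weekly_cases.reshape(-1),
            "weekly_deaths": weekly_deaths.reshape(-1),
            "cum_cases": cum_cases.reshape(-1),
            "cum_deaths": cum_deaths.reshape(-1),
            "cases_per_100k": (cum_cases / population[:, None] * 1e5).reshape(-1),
            "deaths_per_100k": (cum_deaths / population[:, None] * 1e5).reshape(-1),
        }
    )


def factor_model_matrix(
    n: int,
    p: int = 6,
    loading: float = DEFAULT_FACTOR_LOADING,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Equicorrelated one-factor matrix: column_m = a*f + sqrt(1-a^2)*eps_m.

    The population correlation matrix has off-diagonal a^2, so the leading
    eigenvalue is 1 + (p-1) a^2 and the PC1 variance fraction
    (1 + (p-1) a^2) / p; at the default loading and p = 6 that fraction is
    0.635.  With loading = 1 the idiosyncratic term vanishes and PC1 carries
    all the variance.  Returns (matrix, factor).
    """
    if not 0 <= loading <= 1:
        raise ConfigurationError(f"loading must be in [0, 1], got {loading!r}")
    rng = rng or np.random.default_rng()
    f = rng.standard_normal(n)
    eps = rng.standard_normal((n, p))
    x = loading * f[:, None] + np.sqrt(1.0 - loading**2) * eps
    return x, f
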