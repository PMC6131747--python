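"""Synthetic clustered multi-instrument delirium severity data.

Emulates the structure of a hospital cohort in which every participant is
rated daily on all three severity instruments (a common-person design):
around 352 persons each contribute 1-15 daily assessments, for roughly 1178
assessments in total. Latent intensity follows a person random-intercept
model standardized to unit marginal variance,

    theta_{p,d} = u_p + e_{p,d},   u_p ~ N(0, sigma_u^2),
                                   e_{p,d} ~ N(0, 1 - sigma_u^2),

and item responses are drawn from the graded response model used by the
estimation engine. Severity is concentrated at low intensity: the default
generating parameters put many category locations 2-4+ SD above the latent
mean, so top categories are rare, as in real delirium cohorts.

Missingness is completely at random. Rater effects, dementia subgroups and
informative dropout are deliberately not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .instruments import InstrumentSpec, ResponseTable, load_bundled_specs
from .irt import ItemParams, cumulative_probs

__all__ = [
    "GeneratorConfig",
    "SimulatedStudy",
    "default_true_params",
    "simulate_theta",
    "simulate_responses",
    "simulate_study",
]

MAX_DAYS = 15

#: Generating item parameters as (loading, IRT locations b_k); tau = loading*b.
#: Cognition items (orientation, attention, memory) are the least intense;
#: perceptual disturbance, delusions, psychomotor signs, affect and
#: consciousness have minimum locations well above the latent mean, with
#: several top-category locations beyond 4 SD.
_TRUE_AB: dict[str, list[tuple[str, float, tuple[float, ...]]]] = {
    "DRS-R-98": [
        ("sleep_wake_disturbance", 1.2, (-0.8, 0.7, 2.8)),
        ("perceptual_disturbance", 1.6, (1.8, 3.0, 4.3)),
        ("delusions", 1.7, (2.2, 3.3, 4.5)),
        ("lability_of_affect", 1.3, (1.9, 3.2, 4.4)),
        ("language", 1.8, (1.0, 2.6, 4.2)),
        ("thought_process", 2.0, (0.9, 2.4, 3.9)),
        ("motor_agitation", 1.4, (1.6, 3.1, 4.4)),
        ("motor_retardation", 1.1, (1.5, 3.0, 4.3)),
        ("orientation", 2.2, (0.5, 1.8, 3.2)),
        ("attention", 2.4, (0.3, 1.7, 3.1)),
        ("short_term_memory", 1.9, (0.1, 1.5, 2.9)),
        ("long_term_memory", 1.6, (0.6, 2.0, 3.4)),
        ("visuospatial", 1.5, (0.8, 2.3, 4.1)),
    ],
    # Shared-domain items carry the same generating loading, and the same
    # location at the dichotomization-cut boundary, across instruments: the
    # anchors are measurement-invariant, which is the premise of the linking
    # design (the link between instruments generated on one common metric is
    # then the identity).
    "MDAS": [
        ("reduced_consciousness", 1.5, (1.7, 3.0, 4.3)),
        ("disorientation", 2.2, (0.5, 1.8, 3.2)),
        ("short_term_memory", 1.9, (0.1, 1.5, 2.9)),
        ("digit_span", 1.4, (0.4, 2.1, 4.1)),
        ("attention", 2.4, (0.3, 1.7, 3.1)),
        ("disorganized_thinking", 2.0, (0.9, 2.4, 3.9)),
        ("perceptual_disturbance", 1.6, (1.8, 3.0, 4.3)),
        ("delusions", 1.7, (2.2, 3.3, 4.5)),
        ("psychomotor_activity", 1.2, (1.5, 3.0, 4.3)),
        ("sleep_wake_disturbance", 1.2, (-0.8, 0.7, 2.8)),
    ],
    "CAM-S-long": [
        ("acute_onset_fluctuation", 0.9, (1.2,)),
        ("inattention", 2.4, (0.3, 2.2)),
        ("disorganized_thinking", 2.0, (0.9, 2.8)),
        ("altered_consciousness", 1.5, (1.8, 3.6)),
        ("disorientation", 2.2, (0.5, 2.4)),
        ("memory_impairment", 1.9, (0.1, 2.0)),
        ("perceptual_disturbance", 1.6, (1.8, 4.0)),
        ("psychomotor_agitation", 1.4, (1.6, 3.8)),
        ("psychomotor_retardation", 1.1, (1.5, 3.7)),
        ("sleep_wake_disturbance", 1.2, (-0.8, 0.7)),
    ],
}


def default_true_params(
    specs: Mapping[str, InstrumentSpec] | None = None,
) -> dict[str, list[ItemParams]]:
    """Generating item parameters for the bundled instruments."""
    specs = specs or load_bundled_specs(["DRS-R-98", "MDAS", "CAM-S-long"])
    out: dict[str, list[ItemParams]] = {}
    for name in specs:
        if name not in _TRUE_AB:
            raise KeyError(f"no default generating parameters for {name!r}")
        out[name] = [
            ItemParams(
                item_id=item_id,
                loading=a,
                thresholds=tuple(a * np.asarray(b)),
            )
            for item_id, a, b in _TRUE_AB[name]
        ]
    return out


def _truncated_geometric_p(mean_days: float) -> float:
    """Success probability of a geometric on 1..MAX_DAYS with given mean."""
    if not 1.0 < mean_days < (MAX_DAYS + 1) / 2:
        raise ValueError(f"mean days per person {mean_days} not attainable")
    k = np.arange(1, MAX_DAYS + 1)

    def mean_at(p: float) -> float:
        pmf = p * (1 - p) ** (k - 1)
        pmf = pmf / pmf.sum()
        return float((k * pmf).sum())

    return brentq(lambda p: mean_at(p) - mean_days, 1e-6, 1 - 1e-6)


@dataclass
class GeneratorConfig:
    """Study-design knobs for the synthetic cohort.

    The marginal variance of theta is standardized:
    person_intercept_sd^2 + daily_innovation_sd^2 must equal 1.
    """

    n_persons: int = 352
    target_total: int = 1178
    days_distribution: str = "geometric"  # or "uniform" on 1..15
    person_intercept_sd: float = np.sqrt(0.5)
    daily_innovation_sd: float = np.sqrt(0.5)
    missing_rate: float = 0.02
    seed: int = 0
    true_params: dict[str, list[ItemParams]] | None = None
    specs: dict[str, InstrumentSpec] | None = None

    def __post_init__(self) -> None:
        total_var = self.person_intercept_sd**2 + self.daily_innovation_sd**2
        if abs(total_var - 1.0) > 1e-8:
            raise ValueError(
                "person_intercept_sd^2 + daily_innovation_sd^2 must be 1, "
                f"got {total_var:.6f}"
            )
        if not 0.0 <= self.missing_rate <= 0.5:
            raise ValueError("missing_rate must lie in [0, 0.5]")
        if self.days_distribution not in ("geometric", "uniform"):
            raise ValueError(f"unknown days distribution {self.days_distribution!r}")


def _draw_days(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    k = np.arange(1, MAX_DAYS + 1)
    if config.days_distribution == "uniform":
        pmf = np.full(MAX_DAYS, 1.0 / MAX_DAYS)
    else:
        p = _truncated_geometric_p(config.target_total / config.n_persons)
        pmf = p * (1 - p) ** (k - 1)
        pmf = pmf / pmf.sum()
    return rng.choice(k, size=config.n_persons, p=pmf)


def simulate_theta(config: GeneratorConfig) -> pd.DataFrame:
    """Latent intensity per assessment: columns person_id, day, theta.

    theta is the sum of a person random intercept and an independent daily
    innovation; deterministic given config.seed.
    """
    rng = np.random.default_rng(config.seed)
    days = _draw_days(config, rng)
    person_ids = np.repeat(np.arange(1, config.n_persons + 1), days)
    day_idx = np.concatenate([np.arange(1, d + 1) for d in days])
    u = rng.normal(0.0, config.person_intercept_sd, size=config.n_persons)
    e = rng.normal(0.0, config.daily_innovation_sd, size=person_ids.size)
    theta = u[person_ids - 1] + e
    return pd.DataFrame(
        {"person_id": person_ids, "day": day_idx, "theta": theta}
    )


def simulate_responses(
    theta: pd.DataFrame,
    params_list: Sequence[ItemParams],
    spec: InstrumentSpec,
    missing_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> ResponseTable:
    """Draw graded item responses at the given latent intensities.

    For each assessment and item, category k is drawn with
    P(y >= k | theta) = logistic(loading * theta - tau_k); a single uniform
    draw per response inverts the cumulative curve. Missingness is applied
    completely at random at ``missing_rate``.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    th = theta["theta"].to_numpy()
    n = th.size
    data = theta[["person_id", "day"]].copy()
    by_id = {p.item_id: p for p in params_list}
    for it in spec.items:
        p = by_id[it.item_id]
        if len(p.thresholds) != it.n_categories - 1:
            raise ValueError(
                f"item {it.item_id!r}: {len(p.thresholds)} thresholds for "
                f"{it.n_categories} categories"
            )
        cum = cumulative_probs(p.loading, p.tau, th)  # (n, K-1)
        u = rng.uniform(size=(n, 1))
        y = (u < cum).sum(axis=1).astype(float)
        if missing_rate > 0:
            y[rng.uniform(size=n) < missing_rate] = np.nan
        data[it.item_id] = y
    return ResponseTable(instrument=spec.name, data=data)


@dataclass
class SimulatedStudy:
    """One synthetic cohort: tables per instrument plus the generating truth."""

    tables: dict[str, ResponseTable]
    theta: pd.DataFrame
    true_params: dict[str, list[ItemParams]]
    specs: dict[str, InstrumentSpec]
    config: GeneratorConfig = field(repr=False, default=None)


def simulate_study(config: GeneratorConfig | None = None) -> SimulatedStudy:
    """Simulate all instruments on identical person-days from a shared theta."""
    config = config or GeneratorConfig()
    specs = config.specs or load_bundled_specs(["DRS-R-98", "MDAS", "CAM-S-long"])
    true_params = config.true_params or default_true_params(specs)
    theta = simulate_theta(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    tables = {
        name: simulate_responses(
            theta, true_params[name], specs[name], config.missing_rate, rng
        )
        for name in specs
    }
    return SimulatedStudy(
        tables=tables,
        theta=theta,
        true_params=true_params,
        specs=dict(specs),
        config=config,
    )
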