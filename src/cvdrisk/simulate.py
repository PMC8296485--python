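"""Seeded synthetic survey cohorts with a configurable log-risk outcome model.

Binary risk factors are drawn from configurable marginal prevalences
(independently, or through a Gaussian-copula latent correlation), and the
binary outcome from a log-link risk model

    P(case | x) = min(exp(intercept + sum_f beta_f * x_f), p_cap)

The defaults reproduce the statistical structure of the study cohort this
package models: full-sample factor marginals, an intercept of -5.405 and
six log-risk coefficients.  The log link is not a probability model for
extreme covariate patterns (the all-factor linear predictor exceeds 0), so
probabilities are capped at ``p_cap`` and the number of capped patterns is
reported on the cohort.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import RiskFactorProfile, Sex

__all__ = [
    "DEFAULT_MARGINALS",
    "DEFAULT_COEFFICIENTS",
    "DEFAULT_INTERCEPT",
    "GeneratorConfig",
    "SyntheticCohort",
    "ConfigError",
    "generate_cohort",
    "split_modeling_validation",
    "expected_prevalence",
]

#: Full-sample factor prevalences (both study halves pooled).
DEFAULT_MARGINALS: dict[str, float] = {
    "age_ge_60": 0.727,
    "lack_of_exercise": 0.182,
    "smoking": 0.150,
    "hypertension": 0.553,
    "diabetes": 0.143,
    "family_history_cvd": 0.141,
    "male": 0.384,
    "alcohol": 0.142,
    "obesity": 0.219,
    "dyslipidemia": 0.432,
    "cardiopathy": 0.123,
}

#: Adjusted log-risk coefficients for the six model factors.
DEFAULT_COEFFICIENTS: dict[str, float] = {
    "age_ge_60": 1.189,
    "lack_of_exercise": 0.836,
    "smoking": 0.667,
    "hypertension": 0.920,
    "diabetes": 1.161,
    "family_history_cvd": 0.839,
}

DEFAULT_INTERCEPT: float = -5.405

#: Descriptive covariates carried on profiles but outside the outcome model.
_DESCRIPTIVE = ("male", "alcohol", "obesity", "dyslipidemia", "cardiopathy")


class ConfigError(ValueError):
    """Raised for an invalid generator configuration."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterization of a synthetic cohort.

    ``correlation``, when given, is a symmetric positive-definite latent
    correlation matrix over all factors in ``marginals`` (iteration order);
    factors are then thresholded from a latent multivariate normal so each
    marginal is preserved exactly in expectation.
    """

    n: int = 2138
    seed: int = 0
    marginals: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MARGINALS))
    intercept: float = DEFAULT_INTERCEPT
    coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS)
    )
    correlation: np.ndarray | None = None
    p_cap: float = 0.999

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ConfigError(f"n must be positive, got {self.n}")
        for name, p in self.marginals.items():
            if not 0.0 < p < 1.0:
                raise ConfigError(f"marginal for {name} must be in (0,1), got {p}")
        for name, b in self.coefficients.items():
            if not math.isfinite(b):
                raise ConfigError(f"coefficient for {name} must be finite, got {b}")
            if name not in self.marginals:
                raise ConfigError(f"coefficient for unknown factor {name!r}")
        if not 0.0 < self.p_cap <= 1.0:
            raise ConfigError(f"p_cap must be in (0,1], got {self.p_cap}")
        if self.correlation is not None:
            corr = np.asarray(self.correlation, dtype=float)
            k = len(self.marginals)
            if corr.shape != (k, k):
                raise ConfigError(
                    f"correlation must be {k}x{k} for {k} factors, got {corr.shape}"
                )
            if not np.allclose(corr, corr.T):
                raise ConfigError("correlation matrix must be symmetric")
            if not np.allclose(np.diag(corr), 1.0):
                raise ConfigError("correlation matrix must have unit diagonal")
            if np.linalg.eigvalsh(corr).min() <= 0:
                raise ConfigError("correlation matrix must be positive definite")


@dataclass(frozen=True)
class SyntheticCohort:
    """An ordered synthetic cohort; order is the enrolment order used for splitting."""

    profiles: list[RiskFactorProfile]
    config: GeneratorConfig
    realized_prevalence: float
    n_capped: int

    def __len__(self) -> int:
        return len(self.profiles)


def _draw_factors(config: GeneratorConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    names = list(config.marginals)
    probs = np.array([config.marginals[f] for f in names])
    if config.correlation is None:
        draws = rng.random((config.n, len(names))) < probs
    else:
        corr = np.asarray(config.correlation, dtype=float)
        chol = np.linalg.cholesky(corr)
        latent = rng.standard_normal((config.n, len(names))) @ chol.T
        draws = latent < stats.norm.ppf(probs)
    return {name: draws[:, j] for j, name in enumerate(names)}


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate a cohort; identical config (including seed) gives identical output."""
    rng = np.random.default_rng(config.seed)
    cols = _draw_factors(config, rng)

    eta = np.full(config.n, config.intercept, dtype=float)
    for name, beta in config.coefficients.items():
        eta += beta * cols[name]
    p = np.exp(eta)
    capped = p > config.p_cap
    n_capped = int(capped.sum())
    p = np.minimum(p, config.p_cap)
    outcome = rng.random(config.n) < p

    profiles = []
    for i in range(config.n):
        profiles.append(
            RiskFactorProfile(
                id=i + 1,
                age_ge_60=bool(cols["age_ge_60"][i]),
                lack_of_exercise=bool(cols["lack_of_exercise"][i]),
                hypertension=bool(cols["hypertension"][i]),
                diabetes=bool(cols["diabetes"][i]),
                smoking=bool(cols["smoking"][i]),
                family_history_cvd=bool(cols["family_history_cvd"][i]),
                sex=Sex.MALE if cols.get("male", np.zeros(config.n, bool))[i] else Sex.FEMALE,
                alcohol=bool(cols["alcohol"][i]) if "alcohol" in cols else False,
                obesity=bool(cols["obesity"][i]) if "obesity" in cols else False,
                dyslipidemia=bool(cols["dyslipidemia"][i]) if "dyslipidemia" in cols else False,
                cardiopathy=bool(cols["cardiopathy"][i]) if "cardiopathy" in cols else False,
                cvd_case=bool(outcome[i]),
            )
        )
    return SyntheticCohort(
        profiles=profiles,
        config=config,
        realized_prevalence=float(outcome.mean()),
        n_capped=n_capped,
    )


def split_modeling_validation(
    cohort: SyntheticCohort | list[RiskFactorProfile],
) -> tuple[list[RiskFactorProfile], list[RiskFactorProfile]]:
    """Deterministic odd/even split by 1-based enrolment position.

    Positions 1, 3, 5, ... go to the modeling half, positions 2, 4, 6, ...
    to the validation half; concatenating the halves alternately restores
    the cohort exactly.
    """
    profiles = cohort.profiles if isinstance(cohort, SyntheticCohort) else list(cohort)
    if not profiles:
        raise ValueError("cannot split an empty cohort")
    return profiles[0::2], profiles[1::2]


def expected_prevalence(config: GeneratorConfig) -> float:
    """Exact expected outcome prevalence under factor independence.

    Sums P(combination) * min(exp(eta), p_cap) over all 2^k combinations of
    the model factors (descriptive covariates do not enter the outcome).
    Only valid for ``correlation is None``.
    """
    if config.correlation is not None:
        raise ConfigError("closed-form prevalence requires independent factors")
    factors = list(config.coefficients)
    total = 0.0
    for combo in itertools.product((0, 1), repeat=len(factors)):
        prob = 1.0
        eta = config.intercept
        for f, x in zip(factors, combo):
            m = config.marginals[f]
            prob *= m if x else 1.0 - m
            eta += config.coefficients[f] * x
        total += prob * min(math.exp(eta), config.p_cap)
    return total
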