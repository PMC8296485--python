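"""Log-link Poisson regression on a binary prevalence outcome.

Fitting a Poisson GLM with log link to a 0/1 outcome estimates prevalence
ratios; exponentiated coefficients are reported as ORs with large-sample
Wald 95% intervals (beta +/- 1.96 * se).  Model-based (Hessian) standard
errors are the default; a robust sandwich (HC0) option is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "TermEstimate",
    "RegressionResult",
    "TwoByTwoTable",
    "RankDeficientDesignError",
    "fit_poisson_log_binary",
    "crude_chi2",
]

_Z975 = 1.96  # normal quantile for 95% Wald intervals

MAX_ITER = 100
TOL = 1e-10  # relative log-likelihood change


@dataclass(frozen=True)
class TermEstimate:
    name: str
    beta: float
    se: float
    wald_chi2: float
    p_value: float
    or_: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class RegressionResult:
    terms: list[TermEstimate]
    intercept: float
    intercept_se: float
    n: int
    converged: bool
    iterations: int
    log_likelihood: float

    def term(self, name: str) -> TermEstimate:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def or_map(self) -> dict[str, float]:
        return {t.name: t.or_ for t in self.terms}

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "n": self.n,
            "converged": self.converged,
            "iterations": self.iterations,
            "log_likelihood": self.log_likelihood,
            "terms": [
                {
                    "name": t.name,
                    "beta": t.beta,
                    "se": t.se,
                    "wald_chi2": t.wald_chi2,
                    "p_value": t.p_value,
                    "or": t.or_,
                    "ci_low": t.ci_low,
                    "ci_high": t.ci_high,
                }
                for t in self.terms
            ],
        }


@dataclass(frozen=True)
class TwoByTwoTable:
    exposed_cases: int
    exposed_noncases: int
    unexposed_cases: int
    unexposed_noncases: int

    def __post_init__(self) -> None:
        cells = (
            self.exposed_cases,
            self.exposed_noncases,
            self.unexposed_cases,
            self.unexposed_noncases,
        )
        if any(c < 0 for c in cells):
            raise ValueError(f"cell counts must be nonnegative, got {cells}")
        if sum(cells) == 0:
            raise ValueError("table total must be positive")


class RankDeficientDesignError(ValueError):
    """Raised when design columns are constant or linearly dependent."""


def _check_design(design: np.ndarray, names: list[str]) -> None:
    n, k = design.shape
    constant = [names[j] for j in range(k) if np.ptp(design[:, j]) == 0]
    if constant:
        raise RankDeficientDesignError(
            f"constant design column(s): {', '.join(constant)} "
            "(the intercept is added automatically)"
        )
    X = np.column_stack([np.ones(n), design])
    rank = np.linalg.matrix_rank(X)
    if rank < k + 1:
        # name the smallest collinear subset we can identify cheaply
        bad = []
        for j in range(k):
            others = np.column_stack(
                [np.ones(n)] + [design[:, m] for m in range(k) if m != j]
            )
            if np.linalg.matrix_rank(np.column_stack([others, design[:, j]])) == np.linalg.matrix_rank(others):
                bad.append(names[j])
        raise RankDeficientDesignError(
            f"rank-deficient design; collinear column(s): {', '.join(bad) or 'unknown'}"
        )


def fit_poisson_log_binary(
    outcomes: np.ndarray,
    design: np.ndarray,
    names: list[str] | None = None,
    robust: bool = False,
) -> RegressionResult:
    """Fit ``outcome ~ factors`` by log-link Poisson maximum likelihood (IRLS).

    Parameters
    ----------
    outcomes
        0/1 outcome vector, length n.
    design
        n x k matrix of 0/1 factor indicators, no intercept column.
    names
        Column names; defaults to ``x1..xk``.
    robust
        Use HC0 sandwich standard errors instead of model-based ones.

    A non-converged fit is returned with ``converged=False`` rather than
    raising; a rank-deficient design raises :class:`RankDeficientDesignError`
    naming the offending columns.
    """
    y = np.asarray(outcomes, dtype=float)
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if y.shape[0] != X.shape[0]:
        raise ValueError("outcomes and design have different lengths")
    k = X.shape[1]
    names = list(names) if names is not None else [f"x{j + 1}" for j in range(k)]
    if len(names) != k:
        raise ValueError("names length does not match design width")
    if len(set(names)) != k:
        raise ValueError("duplicate design column names")
    _check_design(X, names)

    Xc = sm.add_constant(X, prepend=True)
    model = sm.GLM(y, Xc, family=sm.families.Poisson())
    cov_type = "HC0" if robust else "nonrobust"
    fit = model.fit(maxiter=MAX_ITER, tol=TOL, cov_type=cov_type)

    params = np.asarray(fit.params)
    ses = np.asarray(fit.bse)
    terms = []
    for j, name in enumerate(names, start=1):
        beta = float(params[j])
        se = float(ses[j])
        wald = (beta / se) ** 2 if se > 0 else np.inf
        terms.append(
            TermEstimate(
                name=name,
                beta=beta,
                se=se,
                wald_chi2=wald,
                p_value=float(stats.chi2.sf(wald, df=1)),
                or_=float(np.exp(beta)),
                ci_low=float(np.exp(beta - _Z975 * se)),
                ci_high=float(np.exp(beta + _Z975 * se)),
            )
        )
    return RegressionResult(
        terms=terms,
        intercept=float(params[0]),
        intercept_se=float(ses[0]),
        n=int(y.shape[0]),
        converged=bool(fit.converged),
        iterations=int(fit.fit_history["iteration"]),
        log_likelihood=float(fit.llf),
    )


def crude_chi2(table: TwoByTwoTable) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) for a 2x2 table.

    Raises ``ValueError`` on a zero margin, where the statistic is undefined.
    """
    obs = np.array(
        [
            [table.exposed_cases, table.exposed_noncases],
            [table.unexposed_cases, table.unexposed_noncases],
        ],
        dtype=float,
    )
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: zero row or column margin")
    chi2, p, _, _ = stats.chi2_contingency(obs, correction=False)
    return float(chi2), float(p)
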