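"""Multivariable logistic regression by iteratively reweighted least squares.

Fits the two mortality models of interest — 25OHD plus age, sex, race, BMI,
patient type, and either the DCCI or the APACHE II score — and reports odds
ratios with Wald 95 % confidence intervals. The solver is plain Newton/IRLS
with step halving (so the log-likelihood never decreases), covariance from the
inverse Fisher information at the optimum, rank-deficiency detection via a
pivoted QR of the design matrix, and a separation flag instead of silently
diverging coefficients.

Categorical coding: sex reference male, race reference white, patient type
reference surgical. The headline odds ratios (per ng/mL 25OHD, per DCCI point,
per APACHE II point) are invariant to these reference choices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.special import expit

from .cohort import Cohort
from .errors import ConvergenceError, DegenerateInputError, RankDeficiencyError

log = logging.getLogger(__name__)

_ALLOWED_TERMS = (
    "vitd_25ohd", "age", "sex", "race", "bmi", "patient_type", "dcci", "apache_ii",
)

#: Unit of the odds ratio for each design column.
TERM_UNITS = {
    "vitd_25ohd": "per 1 ng/mL",
    "age": "per year",
    "bmi": "per kg/m^2",
    "dcci": "per index point",
    "apache_ii": "per score point",
    "sex[female]": "female vs male",
    "race[nonwhite]": "non-white vs white",
    "patient_type[medical]": "medical vs surgical",
}

# separation heuristic: ML logistic coefficients this large on these scales
# only arise when classes are (quasi-)separated
_SEPARATION_BOUND = 30.0


@dataclass(frozen=True)
class ModelSpec:
    """Ordered covariate list for a 90-day-mortality logistic model.

    DCCI and APACHE II are alternative severity covariates and never appear
    together in one model.
    """

    terms: tuple[str, ...]
    outcome: str = "death90"

    def __post_init__(self):
        unknown = [t for t in self.terms if t not in _ALLOWED_TERMS]
        if unknown:
            raise ValueError(f"unknown model terms: {unknown}")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("duplicate model terms")
        if "dcci" in self.terms and "apache_ii" in self.terms:
            raise ValueError("dcci and apache_ii are alternative covariates; use one")


#: 25OHD + demographics + comorbidity index.
DCCI_SPEC = ModelSpec(("vitd_25ohd", "age", "sex", "race", "bmi", "patient_type", "dcci"))
#: 25OHD + demographics + acute severity score.
APACHE_SPEC = ModelSpec(("vitd_25ohd", "age", "sex", "race", "bmi", "patient_type", "apache_ii"))


def design_matrix(spec: ModelSpec, frame: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Dense design matrix (intercept first) and its column names."""
    columns = [np.ones(len(frame))]
    names = ["intercept"]
    for term in spec.terms:
        if term == "sex":
            columns.append((frame["sex"] == "female").to_numpy(dtype=float))
            names.append("sex[female]")
        elif term == "race":
            columns.append((frame["race"] == "nonwhite").to_numpy(dtype=float))
            names.append("race[nonwhite]")
        elif term == "patient_type":
            columns.append((frame["patient_type"] == "medical").to_numpy(dtype=float))
            names.append("patient_type[medical]")
        else:
            columns.append(frame[term].to_numpy(dtype=float))
            names.append(term)
    return np.column_stack(columns), names


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic fit."""

    terms: tuple[str, ...]
    coefficients: np.ndarray
    covariance: np.ndarray
    converged: bool
    n_iter: int
    log_likelihood: float
    separation: bool
    n_obs: int
    n_dropped: int

    def coefficient(self, term: str) -> float:
        return float(self.coefficients[self.terms.index(term)])

    def se(self, term: str) -> float:
        i = self.terms.index(term)
        return float(np.sqrt(self.covariance[i, i]))

    def odds_ratio(self, term: str) -> tuple[float, float, float]:
        """(OR, ci_low, ci_high) for one term."""
        b, s = self.coefficient(term), self.se(term)
        return float(np.exp(b)), float(np.exp(b - 1.96 * s)), float(np.exp(b + 1.96 * s))


def _log_likelihood(y: np.ndarray, eta: np.ndarray) -> float:
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _check_rank(x: np.ndarray, names: list[str]) -> None:
    _, r, piv = scipy.linalg.qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    if rank < x.shape[1]:
        raise RankDeficiencyError([names[i] for i in piv[rank:]])


def fit(
    spec: ModelSpec,
    cohort: Cohort | pd.DataFrame,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LogisticFit:
    """Maximum-likelihood fit via IRLS with step halving.

    Complete-case: rows with missing values in the used columns are dropped
    and counted. Convergence is declared when the largest absolute
    coefficient update falls below ``tol``; complete/quasi-complete
    separation is flagged (coefficients diverging) rather than silently
    reported.
    """
    frame = cohort.frame if isinstance(cohort, Cohort) else cohort
    used = [spec.outcome] + [t for t in spec.terms]
    sub = frame.loc[:, used].dropna()
    n_dropped = len(frame) - len(sub)
    if n_dropped:
        log.info("fit: dropped %d incomplete rows", n_dropped)

    y = sub[spec.outcome].to_numpy(dtype=float)
    if y.sum() == 0 or y.sum() == y.size:
        raise DegenerateInputError("need at least one event and one non-event")
    x, names = design_matrix(spec, sub)
    _check_rank(x, names)

    beta = np.zeros(x.shape[1])
    eta = x @ beta
    ll = _log_likelihood(y, eta)
    converged = False
    n_iter = 0
    xtwx = None
    for n_iter in range(1, max_iter + 1):
        mu = expit(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        xtwx = x.T @ (x * w[:, None])
        score = x.T @ (y - mu)
        try:
            step = np.linalg.solve(xtwx, score)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular weighted normal equations: {exc}") from exc
        # step-halve until the log-likelihood does not decrease
        lam = 1.0
        while True:
            beta_new = beta + lam * step
            eta_new = x @ beta_new
            ll_new = _log_likelihood(y, eta_new)
            if ll_new >= ll - 1e-12 or lam < 1e-4:
                break
            lam *= 0.5
        delta = lam * step
        beta, eta, ll = beta_new, eta_new, ll_new
        if np.max(np.abs(delta)) < tol:
            converged = True
            break

    separation = bool(np.max(np.abs(beta)) > _SEPARATION_BOUND)
    if separation:
        log.warning("fit: coefficients diverging; (quasi-)separation suspected")
    # Fisher information at the optimum
    mu = expit(eta)
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    xtwx = x.T @ (x * w[:, None])
    covariance = np.linalg.inv(xtwx)
    return LogisticFit(
        terms=tuple(names),
        coefficients=beta,
        covariance=covariance,
        converged=converged,
        n_iter=n_iter,
        log_likelihood=ll,
        separation=separation,
        n_obs=len(sub),
        n_dropped=n_dropped,
    )


def or_table(fit_result: LogisticFit) -> pd.DataFrame:
    """Odds ratios with Wald 95 % CIs, one row per non-intercept term."""
    if not fit_result.converged:
        raise ConvergenceError(
            f"refusing to tabulate an unconverged fit "
            f"(n_iter={fit_result.n_iter}, separation={fit_result.separation})"
        )
    rows = []
    for term in fit_result.terms:
        if term == "intercept":
            continue
        or_, lo, hi = fit_result.odds_ratio(term)
        rows.append({
            "term": term,
            "odds_ratio": or_,
            "ci_low": lo,
            "ci_high": hi,
            "unit": TERM_UNITS.get(term, ""),
        })
    return pd.DataFrame(rows, columns=["term", "odds_ratio", "ci_low", "ci_high", "unit"])
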