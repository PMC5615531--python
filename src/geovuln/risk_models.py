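"""Odds-ratio models for geriatric depression risk.

Implements the statistical layer of the analysis: 2x2 crude odds ratios with
95% Wald (Woolf) confidence intervals, Welch t-test group comparisons,
Pearson correlation matrices, complete-case filtering, and the multivariable
binomial logistic regression

    log(p / (1-p)) = b0 + b1*older_ages + b2*male + ... + b15*smoking

fitted by iteratively reweighted least squares (IRLS) with step-halving.
Adjusted odds ratios are exp(beta) with Wald CIs from the observed
information.  Three nested model specifications are predefined: Model 1
(social vulnerability factors + confounders), Model 2 (environmental
measures + confounders), Model 3 (both).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "TwoByTwoTable",
    "ORResult",
    "LogisticModelSpec",
    "LogisticFit",
    "LogisticRegressionIRLS",
    "reconstruct_table",
    "crude_or",
    "group_compare",
    "correlation_matrix",
    "complete_case_filter",
    "fit_logistic_irls",
    "adjusted_ors",
    "SOCIAL_TERMS",
    "ENV_TERMS",
    "CONFOUNDER_TERMS",
    "MODEL_TERMS",
]

Z95 = 1.96  # fixed 95% Wald multiplier

SOCIAL_TERMS = ["older_ages", "male", "not_married", "low_education", "living_alone"]
ENV_TERMS = ["pct_residential", "pct_vegetation",
             "avg_build_height_pctile", "std_build_height_pctile"]
CONFOUNDER_TERMS = ["dementia", "physical_activity", "cardiovascular",
                    "respiratory", "alcohol", "smoking"]
MODEL_TERMS = {
    1: SOCIAL_TERMS + CONFOUNDER_TERMS,
    2: ENV_TERMS + CONFOUNDER_TERMS,
    3: SOCIAL_TERMS + ENV_TERMS + CONFOUNDER_TERMS,
}


# ---------------------------------------------------------------------------
# 2x2 tables and crude ORs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoByTwoTable:
    """Exposure x outcome counts: a/b exposed/unexposed cases, c/d controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if any(v < 0 for v in (self.a, self.b, self.c, self.d)):
            raise ValueError("cell counts must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d


@dataclass(frozen=True)
class ORResult:
    or_point: float
    ci_low: float
    ci_high: float

    def __post_init__(self):
        if not (0 < self.ci_low <= self.or_point <= self.ci_high):
            raise ValueError("requires 0 < ci_low <= or <= ci_high")

    @property
    def significant(self) -> bool:
        """True iff the 95% CI excludes 1 (the asterisk rule)."""
        return self.ci_low > 1.0 or self.ci_high < 1.0


def reconstruct_table(n_case: int, pct_case: float,
                      n_control: int, pct_control: float) -> TwoByTwoTable:
    """Rebuild a 2x2 table from group sizes and printed exposure percentages.

    Counts are ``round(n * pct / 100)`` with round-half-to-even (the numpy
    default), complements fill the unexposed cells.
    """
    if n_case < 0 or n_control < 0:
        raise ValueError("group sizes must be non-negative")
    for p in (pct_case, pct_control):
        if not 0 <= p <= 100:
            raise ValueError("percentages must be within [0, 100]")
    a = int(np.round(n_case * pct_case / 100.0))
    c = int(np.round(n_control * pct_control / 100.0))
    return TwoByTwoTable(a=a, b=n_case - a, c=c, d=n_control - c)


def crude_or(table: TwoByTwoTable) -> ORResult:
    """Crude odds ratio ad/bc with the Woolf/Wald 95% CI on the log scale.

    No continuity correction: a zero cell is an error naming the cell.
    """
    for name in "abcd":
        if getattr(table, name) == 0:
            raise ValueError(f"cell '{name}' is zero; crude OR undefined "
                             "(no continuity correction applied)")
    a, b, c, d = table.a, table.b, table.c, table.d
    or_point = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = np.log(or_point)
    return ORResult(or_point=float(or_point),
                    ci_low=float(np.exp(log_or - Z95 * se)),
                    ci_high=float(np.exp(log_or + Z95 * se)))


# ---------------------------------------------------------------------------
# Group comparison and correlations
# ---------------------------------------------------------------------------

def group_compare(case_values, control_values) -> tuple[float, float]:
    """Welch two-sample t-test between case and control values.

    Binary indicators enter as 0/1 numerics, i.e. the test compares
    proportions via their means.  Returns (t, p).
    """
    case_values = np.asarray(case_values, dtype=float)
    control_values = np.asarray(control_values, dtype=float)
    if case_values.size < 2 or control_values.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(case_values) == 0 and np.var(control_values) == 0:
        same = np.mean(case_values) == np.mean(control_values)
        return (0.0, 1.0) if same else (np.inf, 0.0)
    t, p = stats.ttest_ind(case_values, control_values, equal_var=False)
    return float(t), float(p)


def correlation_matrix(table: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Pearson correlation matrix over complete rows of the given columns."""
    cols = columns if columns is not None else list(table.columns)
    sub = table[cols].dropna()
    if len(sub) < 3:
        raise ValueError("need at least 3 complete rows")
    constant = [c for c in cols if sub[c].nunique() <= 1]
    if constant:
        warnings.warn(f"constant columns give undefined correlations: {constant}")
    return sub.corr(method="pearson")


def complete_case_filter(table: pd.DataFrame,
                         columns: list[str] | None = None) -> tuple[pd.DataFrame, int]:
    """Drop rows with any missing analysis field; returns (filtered, n_removed)."""
    cols = columns if columns is not None else list(table.columns)
    kept = table.dropna(subset=[c for c in cols if c in table.columns])
    n_removed = len(table) - len(kept)
    if len(kept) == 0:
        raise ValueError("complete-case filtering removed every row")
    return kept, n_removed


# ---------------------------------------------------------------------------
# IRLS logistic regression
# ---------------------------------------------------------------------------

def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        bad = [names[j] for j in piv[rank:]]
        raise ValueError(f"design matrix is singular; collinear columns: {bad}")


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable Bernoulli log-likelihood sum(y*eta - log(1+exp(eta)))
    return float(np.sum(y * eta) - np.sum(np.logaddexp(0.0, eta)))


class LogisticRegressionIRLS(BaseEstimator, ClassifierMixin):
    """Binomial logistic regression by iteratively reweighted least squares.

    Maximises the Bernoulli log-likelihood with Newton/IRLS steps and
    step-halving (the log-likelihood never decreases across iterations);
    convergence when the largest coefficient update falls below ``tol``.
    Standard errors come from the inverse observed information.  Diverging
    coefficients (|beta| beyond ``separation_threshold``) flag quasi-complete
    separation and the fit is marked non-converged.

    Attributes after ``fit``: ``coef_`` (incl. intercept first when
    ``fit_intercept``), ``se_``, ``loglik_``, ``converged_``, ``n_iter_``.
    """

    def __init__(self, fit_intercept: bool = True, tol: float = 1e-8,
                 max_iter: int = 100, separation_threshold: float = 25.0):
        self.fit_intercept = fit_intercept
        self.tol = tol
        self.max_iter = max_iter
        self.separation_threshold = separation_threshold

    def _design(self, X: np.ndarray) -> np.ndarray:
        return np.column_stack([np.ones(len(X)), X]) if self.fit_intercept else X

    def fit(self, X, y, feature_names: list[str] | None = None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        if not np.isfinite(X).all() or not np.isfinite(y).all():
            raise ValueError("fit requires complete cases (finite X and y)")
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError("y must be binary 0/1")
        if y.min() == y.max():
            raise ValueError("need at least one case and one control")
        names = feature_names or [f"x{j}" for j in range(X.shape[1])]
        if self.fit_intercept:
            names = ["intercept"] + list(names)
        D = self._design(X)
        _check_full_rank(D, names)

        beta = np.zeros(D.shape[1])
        eta = D @ beta
        ll = _loglik(y, eta)
        ll_path = [ll]
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            p = expit(eta)
            w = p * (1.0 - p)
            # Newton step: (D' W D) delta = D'(y - p)
            wd = D * w[:, None]
            try:
                delta = linalg.solve(D.T @ wd, D.T @ (y - p), assume_a="pos")
            except linalg.LinAlgError:
                break
            step = 1.0
            for _ in range(30):  # step-halving keeps the log-likelihood monotone
                cand = beta + step * delta
                ll_new = _loglik(y, D @ cand)
                if ll_new >= ll - 1e-12:
                    break
                step /= 2.0
            beta = beta + step * delta
            eta = D @ beta
            ll = _loglik(y, eta)
            ll_path.append(ll)
            if np.max(np.abs(step * delta)) < self.tol:
                converged = True
                break

        if np.max(np.abs(beta)) > self.separation_threshold:
            converged = False
            warnings.warn("diverging coefficients: possible (quasi-)complete separation")

        p = expit(eta)
        w = p * (1.0 - p)
        info = D.T @ (D * w[:, None])
        try:
            cov = linalg.inv(info)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except linalg.LinAlgError:
            cov = np.full_like(info, np.nan)
            se = np.full(D.shape[1], np.nan)

        self.feature_names_ = names
        self.coef_ = beta
        self.se_ = se
        self.cov_ = cov
        self.loglik_ = ll
        self.loglik_path_ = ll_path
        self.converged_ = converged
        self.n_iter_ = it
        self.classes_ = np.array([0.0, 1.0])
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self._design(X) @ self.coef_

    def predict_proba(self, X):
        p1 = expit(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.decision_function(X) > 0).astype(float)


# ---------------------------------------------------------------------------
# Named-model layer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogisticModelSpec:
    """Which predictors enter the regression (outcome: GDS-15 >= 8)."""

    model_id: int
    terms: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.terms:
            if self.model_id not in MODEL_TERMS:
                raise ValueError(f"unknown model id {self.model_id} and no terms given")
            object.__setattr__(self, "terms", tuple(MODEL_TERMS[self.model_id]))
            return
        terms = tuple(self.terms)
        if len(set(terms)) != len(terms):
            raise ValueError("duplicate terms in model specification")
        if self.model_id in MODEL_TERMS and set(terms) != set(MODEL_TERMS[self.model_id]):
            raise ValueError(f"term list does not match model {self.model_id}")
        object.__setattr__(self, "terms", terms)


@dataclass
class LogisticFit:
    spec: LogisticModelSpec
    terms: list[str]                      # non-intercept terms, design order
    beta: np.ndarray                      # intercept first
    se: np.ndarray
    converged: bool
    n_used: int
    n_removed: int
    loglik: float
    estimator: LogisticRegressionIRLS = field(repr=False, default=None)


def fit_logistic_irls(spec: LogisticModelSpec, data: pd.DataFrame,
                      outcome: str = "case",
                      standardize_activity: bool = True) -> LogisticFit:
    """Fit a named model on a cohort+features table.

    Rows with any missing analysis value are dropped (complete-case analysis).
    The physical-activity score is standardised to mean 0 / SD 1 within the
    analysis sample so its coefficient is scale-free; all other terms enter on
    their native (0/1 or 0–100) scales so ORs read per unit / per percentage
    point.
    """
    cols = [outcome] + list(spec.terms)
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"data lacks required columns: {missing}")
    sub, n_removed = complete_case_filter(data, cols)
    X = sub[list(spec.terms)].to_numpy(dtype=float).copy()
    if standardize_activity and "physical_activity" in spec.terms:
        j = list(spec.terms).index("physical_activity")
        sd = X[:, j].std()
        if sd > 0:
            X[:, j] = (X[:, j] - X[:, j].mean()) / sd
    y = sub[outcome].to_numpy(dtype=float)
    est = LogisticRegressionIRLS().fit(X, y, feature_names=list(spec.terms))
    return LogisticFit(spec=spec, terms=list(spec.terms), beta=est.coef_, se=est.se_,
                       converged=est.converged_, n_used=len(sub),
                       n_removed=n_removed, loglik=est.loglik_, estimator=est)


def adjusted_ors(fit: LogisticFit) -> dict[str, ORResult]:
    """Per-term OR = exp(beta) with Wald 95% CI exp(beta +/- 1.96 se)."""
    if not fit.converged:
        raise ValueError("cannot report adjusted ORs from a non-converged fit")
    out: dict[str, ORResult] = {}
    for j, term in enumerate(fit.terms, start=1):
        b, s = fit.beta[j], fit.se[j]
        out[term] = ORResult(or_point=float(np.exp(b)),
                             ci_low=float(np.exp(b - Z95 * s)),
                             ci_high=float(np.exp(b + Z95 * s)))
    return out
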