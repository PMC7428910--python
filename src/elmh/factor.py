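"""Exploratory factor scoring for the 44-item questionnaire.

The instrument groups its 44 Likert items into 8 domains (mental
health, attitude to patients, diversified, adjustment, persevering,
teamwork, physical health, behavior) of sizes 16, 5, 4, 4, 5, 4, 4 and
2.  Factors are retained by the eigenvalue >= 1.0 rule, extracted by
principal components and varimax-rotated, and person-level factor
scores use the Bartlett weighted-least-squares estimator

    F = (L' Psi^-1 L)^-1 L' Psi^-1 z

with loadings ``L``, uniqueness diagonal ``Psi`` and standardized
responses ``z``.  For single-respondent scoring on a device the package
also ships the eight published sum-to-factor-score regression
shortcuts, mapping a domain raw sum linearly to its factor score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from .errors import EstimationError, InputError

__all__ = [
    "DomainSpec", "ScoreRegression", "DEFAULT_DOMAIN_SPEC",
    "DEFAULT_SCORE_REGRESSION", "retain_factors", "extract_factors",
    "varimax", "bartlett_scores", "regression_factor_score",
    "fit_score_regressions", "FactorScorer",
]

DOMAIN_NAMES = ("mental health", "attitude to patients", "diversified",
                "adjustment", "persevering", "teamwork", "physical health",
                "behavior")
DOMAIN_SIZES = (16, 5, 4, 4, 5, 4, 4, 2)


@dataclass(frozen=True)
class DomainSpec:
    """Assignment of items to the 8 questionnaire domains."""

    domain_names: tuple = DOMAIN_NAMES
    domain_sizes: tuple = DOMAIN_SIZES

    def __post_init__(self):
        if len(self.domain_names) != len(self.domain_sizes):
            raise InputError("domain_names and domain_sizes length mismatch")

    @property
    def n_items(self) -> int:
        return int(sum(self.domain_sizes))

    @property
    def n_domains(self) -> int:
        return len(self.domain_sizes)

    @property
    def item_assignment(self) -> np.ndarray:
        """Item index -> domain index (consecutive blocks)."""
        return np.repeat(np.arange(self.n_domains), self.domain_sizes)

    def domain_sums(self, responses) -> np.ndarray:
        """Per-person raw sum for each domain; (n, n_domains)."""
        X = np.asarray(responses, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_items:
            raise InputError(f"expected {self.n_items} items, "
                             f"got {X.shape[1]}")
        assign = self.item_assignment
        return np.column_stack([X[:, assign == d].sum(axis=1)
                                for d in range(self.n_domains)])


DEFAULT_DOMAIN_SPEC = DomainSpec()


@dataclass(frozen=True)
class ScoreRegression:
    """Per-domain linear maps from domain raw sum to factor score."""

    intercepts: tuple
    slopes: tuple

    def __post_init__(self):
        if len(self.intercepts) != len(self.slopes):
            raise InputError("intercepts and slopes length mismatch")


# The published per-domain regression coefficients shipped as defaults so
# the single-respondent assessment path works without refitting.
DEFAULT_SCORE_REGRESSION = ScoreRegression(
    intercepts=(-3.2516, -7.7062, -3.6067, -4.7129,
                -4.9833, -5.4556, -2.5251, -4.2156),
    slopes=(0.08190, 0.3711, 0.3104, 0.3349,
            0.2821, 0.5632, 0.2220, 0.6377),
)


def retain_factors(eigenvalues) -> int:
    """Number of factors retained by the eigenvalue >= 1.0 rule."""
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.size == 0:
        raise InputError("eigenvalues must be non-empty")
    if np.any(np.diff(ev) > 1e-12):
        raise InputError("eigenvalues must be sorted in descending order")
    k = int(np.sum(ev >= 1.0))
    if k == 0:
        warnings.warn("no eigenvalue reaches 1.0; no factor meets the "
                      "retention criterion", UserWarning)
    return k


def varimax(loadings, max_iter=200, tol=1e-10):
    """Varimax rotation of a loading matrix (orthogonal, kaiser-free)."""
    L = np.asarray(loadings, dtype=float).copy()
    p, k = L.shape
    if k < 2:
        return L
    R = np.eye(k)
    var = 0.0
    for _ in range(max_iter):
        LR = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (LR ** 3 - LR @ np.diag((LR ** 2).sum(axis=0)) / p))
        R = u @ vt
        new_var = s.sum()
        if new_var - var < tol:
            break
        var = new_var
    return L @ R


def _correlation_matrix(X):
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd <= 0) or not np.all(np.isfinite(sd)):
        raise EstimationError("constant or non-finite item column; "
                              "correlation matrix is singular")
    return np.corrcoef(X, rowvar=False)


def extract_factors(responses, n_factors: int, rotate: bool = True):
    """Principal-component factor extraction with varimax rotation.

    Returns ``(loadings, uniquenesses)`` with loadings (n_items,
    n_factors) and per-item uniqueness in (0, 1]; for each item
    communality + uniqueness = 1.
    """
    if n_factors < 1:
        raise InputError("n_factors must be >= 1")
    R = _correlation_matrix(responses)
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1][:n_factors]
    lam = evals[order]
    if np.any(lam <= 0):
        raise EstimationError("singular correlation matrix")
    loadings = evecs[:, order] * np.sqrt(lam)
    if rotate:
        loadings = varimax(loadings)
    # sign convention: dominant loading of each factor positive
    signs = np.sign(loadings[np.argmax(np.abs(loadings), axis=0),
                             np.arange(loadings.shape[1])])
    loadings = loadings * signs
    communality = (loadings ** 2).sum(axis=1)
    uniqueness = np.clip(1.0 - communality, 1e-12, 1.0)
    return loadings, uniqueness


def bartlett_scores(responses, loadings, uniquenesses,
                    means=None, sds=None):
    """Bartlett weighted-least-squares factor scores.

    Standardization uses the cohort's own item means/SDs unless
    ``means``/``sds`` from a stored model are supplied (required when
    scoring a single new respondent).
    """
    X = np.asarray(responses, dtype=float)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    L = np.asarray(loadings, dtype=float)
    psi = np.asarray(uniquenesses, dtype=float)
    if np.any(psi <= 0):
        raise EstimationError("zero or negative uniqueness; Bartlett "
                              "weighting is singular")
    if means is None or sds is None:
        if X.shape[0] < 2:
            raise InputError("single-respondent scoring requires stored "
                             "cohort means and sds")
        means = X.mean(axis=0)
        sds = X.std(axis=0, ddof=1)
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if np.any(sds <= 0):
        raise EstimationError("zero item SD; cannot standardize")
    z = (X - means) / sds
    w = L / psi[:, None]                     # Psi^-1 L
    scores = np.linalg.solve(L.T @ w, w.T @ z.T).T
    return scores[0] if single else scores


def regression_factor_score(domain_index: int, raw_sum: float,
                            regression: ScoreRegression =
                            DEFAULT_SCORE_REGRESSION) -> float:
    """Shortcut factor score: intercept + slope * domain raw sum.

    ``domain_index`` is 1-based (domains 1-8 as published).
    """
    k = len(regression.intercepts)
    if not 1 <= domain_index <= k:
        raise InputError(f"domain_index must be in 1..{k}")
    return (regression.intercepts[domain_index - 1]
            + regression.slopes[domain_index - 1] * raw_sum)


def fit_score_regressions(raw_sums, scores) -> ScoreRegression:
    """Per-domain OLS of factor score on domain raw sum."""
    S = np.asarray(raw_sums, dtype=float)
    F = np.asarray(scores, dtype=float)
    if S.shape != F.shape or S.ndim != 2:
        raise InputError("raw_sums and scores must be equal-shape 2-D")
    if S.shape[0] < 3:
        raise InputError("need at least 3 persons")
    intercepts, slopes = [], []
    for d in range(S.shape[1]):
        s = S[:, d]
        if np.ptp(s) == 0:
            raise EstimationError(f"zero variance in domain {d + 1} raw sums")
        slope, intercept = np.polyfit(s, F[:, d], 1)
        intercepts.append(float(intercept))
        slopes.append(float(slope))
    return ScoreRegression(intercepts=tuple(intercepts),
                           slopes=tuple(slopes))


def align_factors_to_domains(loadings, domain_spec: DomainSpec):
    """Reorder (and sign) factor columns to match questionnaire domains.

    Extraction returns factors in eigenvalue order, which need not match
    the instrument's domain numbering.  Columns are assigned to domains
    by maximizing the total squared loading each factor places on its
    domain's items (optimal one-to-one assignment), then signed so the
    mean loading on the assigned domain's items is positive.  Requires
    as many factors as domains.
    """
    from scipy.optimize import linear_sum_assignment

    L = np.asarray(loadings, dtype=float)
    k = domain_spec.n_domains
    if L.shape[1] != k:
        raise InputError("alignment requires one factor per domain")
    assign = domain_spec.item_assignment
    affinity = np.zeros((k, k))  # (domain, factor)
    for d in range(k):
        affinity[d] = (L[assign == d] ** 2).sum(axis=0)
    _, cols = linear_sum_assignment(-affinity)
    aligned = L[:, cols].copy()
    for d in range(k):
        if aligned[assign == d, d].mean() < 0:
            aligned[:, d] *= -1.0
    return aligned, cols


class FactorScorer:
    """EFA + Bartlett scoring as a scikit-learn style transformer.

    ``fit`` extracts ``n_factors`` varimax-rotated principal-component
    factors (or retains by the eigenvalue rule when ``n_factors=None``)
    and stores the cohort item means/SDs; ``transform`` returns Bartlett
    factor scores using the stored statistics, so a single new
    respondent is scored consistently with the fitting cohort.  With
    ``align_to`` set to a :class:`DomainSpec` (and one factor per
    domain), factor columns are reordered to the instrument's domain
    numbering.
    """

    def __init__(self, n_factors=None, rotate=True, align_to=None):
        self.n_factors = n_factors
        self.rotate = rotate
        self.align_to = align_to

    def get_params(self, deep=True):
        return {"n_factors": self.n_factors, "rotate": self.rotate,
                "align_to": self.align_to}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        R = _correlation_matrix(X)
        evals = np.sort(np.linalg.eigvalsh(R))[::-1]
        self.eigenvalues_ = evals
        k = self.n_factors
        if k is None:
            k = max(retain_factors(evals), 1)
        self.n_factors_ = int(k)
        self.loadings_, self.uniquenesses_ = extract_factors(
            X, self.n_factors_, rotate=self.rotate)
        if self.align_to is not None:
            self.loadings_, _ = align_factors_to_domains(
                self.loadings_, self.align_to)
        self.means_ = X.mean(axis=0)
        self.sds_ = X.std(axis=0, ddof=1)
        return self

    def transform(self, X):
        if not hasattr(self, "loadings_"):
            raise EstimationError("FactorScorer is not fitted")
        return bartlett_scores(X, self.loadings_, self.uniquenesses_,
                               means=self.means_, sds=self.sds_)

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)
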