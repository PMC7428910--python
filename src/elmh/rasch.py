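"""Continuous-response Rasch model: person measures, item difficulties,
outfit mean-square person-fit statistics, and rating-scale category curves.

The model places persons (severity ``theta``) and items (difficulty
``delta``) on a common logit scale.  For a response bounded on
``[m, M]`` the expected score is the scaled logistic

    E_j(theta) = m + (M - m) * sigma(theta - delta_j),

with model variance ``W_j = (M - m)^2 * p_j * (1 - p_j)`` where
``p_j = sigma(theta - delta_j)``.  Estimation is joint maximum
likelihood on the [0, 1]-rescaled responses: the estimating equations
``sum_j (x_pj - p_pj) = 0`` (persons) and ``sum_p (x_pj - p_pj) = 0``
(items) are solved by alternating Newton steps, with item difficulties
centred to mean zero.

The person-fit statistic is the outfit mean square, the average squared
standardized residual across the ``L`` items a person answered:

    outfit_p = (1 / L) * sum_j (O_pj - E_pj)^2 / W_pj.

Its expectation is ~1 under model fit; values >= 2.0 flag aberrant
response patterns (careless or random responding).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit, logsumexp

from .errors import EstimationError, InputError

__all__ = [
    "RaschFit",
    "RatingScaleCurves",
    "RaschModel",
    "fit_rasch",
    "expected_and_variance",
    "outfit_mnsq",
    "rating_scale_curves",
    "score_person",
]

# Winsteps-style adjustment (in raw score units) pulling all-minimum /
# all-maximum response strings off the boundary so they get finite measures.
EXTREME_ADJUST = 0.3


@dataclass
class RaschFit:
    """Result container for a joint maximum-likelihood Rasch fit."""

    person_measures: np.ndarray      # (n,) logits
    item_difficulties: np.ndarray    # (L,) logits, mean 0
    expected_scores: np.ndarray      # (n, L) response units
    model_variances: np.ndarray      # (n, L) response units squared
    outfit: np.ndarray               # (n,) dimensionless, >= 0
    response_min: float
    response_max: float
    converged: bool
    n_iter: int

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "person_measures": self.person_measures.tolist(),
            "item_difficulties": self.item_difficulties.tolist(),
            "outfit": self.outfit.tolist(),
            "response_min": self.response_min,
            "response_max": self.response_max,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }


@dataclass
class RatingScaleCurves:
    """Category-probability curves of the Rasch rating-scale model."""

    thresholds: np.ndarray     # (K-1,) logits
    grid: np.ndarray           # (G,) measure values
    probabilities: np.ndarray  # (G, K), rows sum to 1

    def to_frame(self):
        import pandas as pd

        k = self.probabilities.shape[1]
        out = pd.DataFrame(self.probabilities,
                           columns=[f"cat{i}" for i in range(k)])
        out.insert(0, "measure", self.grid)
        return out


def expected_and_variance(theta, difficulties, response_min, response_max):
    """Expected scores and model variances at a given measure.

    Parameters
    ----------
    theta : float or array
        Person measure(s) in logits.
    difficulties : array
        Item difficulties in logits.
    response_min, response_max : float
        Bounds of the response scale (``m`` and ``M``).

    Returns
    -------
    expected, variance : arrays broadcast over ``theta`` x ``difficulties``.
    """
    if not response_max > response_min:
        raise InputError("response_max must exceed response_min")
    theta = np.asarray(theta, dtype=float)
    difficulties = np.asarray(difficulties, dtype=float)
    if not (np.all(np.isfinite(difficulties)) and np.all(np.isfinite(theta))):
        raise InputError("theta and difficulties must be finite")
    span = response_max - response_min
    p = expit(theta[..., None] - difficulties) if theta.ndim else \
        expit(theta - difficulties)
    expected = response_min + span * p
    variance = span ** 2 * p * (1.0 - p)
    return expected, variance


def outfit_mnsq(observed_row, expected_row, variance_row) -> float:
    """Outfit mean square: mean squared standardized residual over items."""
    o = np.asarray(observed_row, dtype=float)
    e = np.asarray(expected_row, dtype=float)
    w = np.asarray(variance_row, dtype=float)
    if not (o.shape == e.shape == w.shape) or o.ndim != 1 or o.size < 1:
        raise InputError("observed, expected and variance rows must be "
                         "1-D and of equal length >= 1")
    if np.any(w <= 0):
        raise InputError("model variances must be strictly positive")
    return float(np.mean((o - e) ** 2 / w))


def _solve_logistic_sum(target, offsets, x0, max_iter=50, tol=1e-12):
    """Vectorized Newton solve of ``sum_j expit(x_i - offsets[i, j]) = target_i``.

    ``offsets`` is (n, L); monotone in x, so damped Newton is safe.
    """
    x = np.array(x0, dtype=float)
    for _ in range(max_iter):
        p = expit(x[:, None] - offsets)
        f = p.sum(axis=1) - target
        fp = np.maximum((p * (1.0 - p)).sum(axis=1), 1e-10)
        step = f / fp
        np.clip(step, -2.0, 2.0, out=step)  # damp far-from-solution steps
        x -= step
        if np.max(np.abs(step)) < tol:
            break
    return x


def fit_rasch(observed, response_min, response_max,
              tol: float = 1e-6, max_iter: int = 500) -> RaschFit:
    """Joint maximum-likelihood fit of the continuous-response Rasch model.

    ``observed`` is persons x items on the ``[response_min, response_max]``
    scale.  Alternates Newton updates of person measures and item
    difficulties until the largest absolute parameter change falls below
    ``tol`` (or ``max_iter`` sweeps); difficulties are centred to mean 0.
    Extreme response strings (all-minimum / all-maximum) have their raw
    score adjusted by 0.3 score units so they receive finite measures.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise InputError("observed must be 2-D with >= 2 persons and >= 2 items")
    if not response_max > response_min:
        raise InputError("response_max must exceed response_min")
    if np.any(obs < response_min) or np.any(obs > response_max):
        raise InputError("responses outside [response_min, response_max]")
    if np.ptp(obs) == 0:
        raise EstimationError("degenerate data: all responses identical")

    n, L = obs.shape
    span = response_max - response_min
    x = (obs - response_min) / span  # rescale to [0, 1]
    adj = EXTREME_ADJUST / span

    row_target = x.sum(axis=1)
    row_target = np.where(row_target <= 0, adj, row_target)
    row_target = np.where(row_target >= L, L - adj, row_target)
    col_target = x.sum(axis=0)
    col_target = np.where(col_target <= 0, adj, col_target)
    col_target = np.where(col_target >= n, n - adj, col_target)

    theta = logit(np.clip(row_target / L, 1e-6, 1 - 1e-6))
    delta = -logit(np.clip(col_target / n, 1e-6, 1 - 1e-6))
    delta -= delta.mean()

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        theta_new = _solve_logistic_sum(
            row_target, np.broadcast_to(delta, (n, L)), theta)
        delta_new = -_solve_logistic_sum(
            col_target, np.broadcast_to(-theta_new[:, None].T, (L, n)),
            -delta)
        shift = delta_new.mean()
        delta_new -= shift
        theta_new = theta_new - shift
        change = max(np.max(np.abs(theta_new - theta)),
                     np.max(np.abs(delta_new - delta)))
        theta, delta = theta_new, delta_new
        if change < tol:
            converged = True
            break
    if not converged:
        warnings.warn("Rasch JML did not converge within "
                      f"{max_iter} iterations; returning last iterate",
                      RuntimeWarning)

    expected, variance = expected_and_variance(
        theta, delta, response_min, response_max)
    resid2 = (obs - expected) ** 2 / variance
    outfit = resid2.mean(axis=1)
    return RaschFit(person_measures=theta, item_difficulties=delta,
                    expected_scores=expected, model_variances=variance,
                    outfit=outfit, response_min=float(response_min),
                    response_max=float(response_max),
                    converged=converged, n_iter=it)


def score_person(responses, difficulties, response_min, response_max):
    """Measure and outfit for one person against anchored item difficulties.

    Used by the assessment path, where difficulties come from a stored
    model rather than being re-estimated.  Returns ``(measure, outfit)``.
    """
    r = np.asarray(responses, dtype=float)
    delta = np.asarray(difficulties, dtype=float)
    if r.shape != delta.shape:
        raise InputError("responses and difficulties must have equal length")
    span = response_max - response_min
    x = (r - response_min) / span
    target = x.sum()
    L = r.size
    adj = EXTREME_ADJUST / span
    target = min(max(target, adj), L - adj)
    theta = _solve_logistic_sum(
        np.array([target]), delta[None, :],
        np.array([logit(np.clip(target / L, 1e-6, 1 - 1e-6))]))[0]
    expected, variance = expected_and_variance(
        theta, delta, response_min, response_max)
    return float(theta), outfit_mnsq(r, expected, variance)


def rating_scale_curves(difficulty, thresholds, grid) -> RatingScaleCurves:
    """Category-probability curves of the rating-scale model.

    ``P(k | theta) = exp(sum_{h<=k} (theta - delta - tau_h)) / normaliser``
    with the empty sum equal to 0 for the lowest category; every grid row
    sums to 1 by construction.  Adjacent categories ``k-1`` and ``k`` are
    equally likely exactly at ``theta = delta + tau_k``.
    """
    tau = np.asarray(thresholds, dtype=float)
    g = np.asarray(grid, dtype=float)
    if g.size == 0:
        raise InputError("grid must be non-empty")
    if not np.all(np.isfinite(tau)):
        raise InputError("thresholds must be finite")
    # cumulative numerator exponents: (G, K)
    steps = g[:, None] - difficulty - tau[None, :]
    exponents = np.concatenate(
        [np.zeros((g.size, 1)), np.cumsum(steps, axis=1)], axis=1)
    probs = np.exp(exponents - logsumexp(exponents, axis=1, keepdims=True))
    return RatingScaleCurves(thresholds=tau, grid=g, probabilities=probs)


class RaschModel:
    """Continuous-response Rasch estimator (scikit-learn style).

    Parameters
    ----------
    response_min, response_max : float
        Bounds of the response scale.
    tol : float
        Convergence tolerance on the largest parameter change.
    max_iter : int
        Maximum alternating sweeps.

    Attributes (after :meth:`fit`)
    ------------------------------
    person_measures_ : (n,) person logits
    item_difficulties_ : (L,) item logits, mean 0
    outfit_ : (n,) person outfit mean squares
    fit_ : the full :class:`RaschFit`
    """

    def __init__(self, response_min=1.0, response_max=5.0,
                 tol=1e-6, max_iter=500):
        self.response_min = response_min
        self.response_max = response_max
        self.tol = tol
        self.max_iter = max_iter

    def get_params(self, deep=True):
        return {"response_min": self.response_min,
                "response_max": self.response_max,
                "tol": self.tol, "max_iter": self.max_iter}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):
        res = fit_rasch(X, self.response_min, self.response_max,
                        tol=self.tol, max_iter=self.max_iter)
        self.fit_ = res
        self.person_measures_ = res.person_measures
        self.item_difficulties_ = res.item_difficulties
        self.outfit_ = res.outfit
        self.converged_ = res.converged
        return self

    def transform(self, X=None):
        """Return the (measure, outfit) feature pair for the fitted cohort."""
        if not hasattr(self, "fit_"):
            raise EstimationError("RaschModel is not fitted")
        return np.column_stack([self.person_measures_, self.outfit_])
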