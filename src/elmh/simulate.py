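"""Synthetic questionnaire cohorts with a known latent structure.

Generates respondent-by-item Likert matrices under the same
continuous-response Rasch model the analysis assumes: person severities
``theta ~ N(trait_mean, trait_sd)``, item difficulties equally spaced
on ``[-difficulty_spread, +difficulty_spread]``, and responses scattered
about the model-expected score ``E = m + (M - m) p`` and rounded to the
Likert range.  The scatter is Beta-distributed on the response interval
with mean ``p`` and variance ``noise_sd^2 * p * (1 - p)``: ``noise_sd``
is the residual standard deviation as a fraction of the model-implied
one ``sqrt(W_pj)``, so ``noise_sd = 1`` produces respondents exactly as
noisy as the model assumes (outfit MNSQ ~ 1; the Bernoulli limit of the
Beta), and ``noise_sd = 0`` reproduces the rounded expected scores.
Unlike additive Gaussian noise, the Beta mechanism never needs clipping,
so neither the expected score nor the residual variance is distorted by
boundary truncation.

A configurable fraction of respondents is *aberrant* — they answer
uniformly at random over the Likert range (careless/guessing
behaviour), which inflates their outfit mean square.  Each cohort is
labeled by fitting the Rasch model to its own responses and applying
the standard cutoffs (0 logits, outfit 2.0), so downstream classifiers
can be checked against generator-side truth.

Defaults emulate the study cohort this pipeline targets: 352
respondents, 44 items in 8 domains (16/5/4/4/5/4/4/2), ~6.8% aberrant
responders and a trait mean of -0.85 logits, which yields a
four-quadrant class structure dominated by quadrant III (healthy).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EstimationError
from .factor import DOMAIN_SIZES
from .quadrant import classify_cohort
from .rasch import expected_and_variance, fit_rasch

__all__ = ["SimulationConfig", "SimulatedCohort", "simulate_cohort",
           "write_cohort", "read_cohort", "item_difficulties",
           "eight_domain_config"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort."""

    n_persons: int = 352
    n_items: int = 44
    domain_sizes: tuple = DOMAIN_SIZES
    likert_min: int = 1
    likert_max: int = 5
    trait_mean: float = -0.85      # logits
    trait_sd: float = 1.0          # logits
    difficulty_spread: float = 4.0  # logits
    noise_sd: float = 1.0          # fraction of model sd sqrt(W), in [0, 1]
    aberrant_fraction: float = 0.068
    domain_trait_sd: float = 0.0   # >0 adds independent per-domain traits
    seed: int = 0

    def __post_init__(self):
        if self.n_persons < 0:
            raise ConfigurationError("n_persons must be >= 0")
        if self.n_items < 1:
            raise ConfigurationError("n_items must be >= 1")
        if sum(self.domain_sizes) != self.n_items:
            raise ConfigurationError(
                "domain_sizes must sum to n_items "
                f"({sum(self.domain_sizes)} != {self.n_items})")
        if not self.likert_min < self.likert_max:
            raise ConfigurationError("likert_min must be < likert_max")
        if not 0.0 <= self.aberrant_fraction <= 1.0:
            raise ConfigurationError("aberrant_fraction must be in [0, 1]")
        if not 0.0 <= self.noise_sd <= 1.0:
            raise ConfigurationError(
                "noise_sd must be in [0, 1] (residual sd as a fraction of "
                "the model-implied sd)")
        if self.trait_sd < 0:
            raise ConfigurationError("trait_sd must be >= 0")
        if self.domain_trait_sd < 0:
            raise ConfigurationError("domain_trait_sd must be >= 0")
        if self.difficulty_spread < 0:
            raise ConfigurationError("difficulty_spread must be >= 0")


@dataclass
class SimulatedCohort:
    """A generated cohort plus the truth that generated it."""

    responses: pd.DataFrame          # person_id index, i01..iNN columns
    true_theta: np.ndarray           # (n,) logits
    true_difficulty: np.ndarray      # (n_items,) logits
    aberrant_flags: np.ndarray       # (n,) bool
    true_quadrant: list              # per-person quadrant name or None
    config: SimulationConfig

    def to_numpy(self) -> np.ndarray:
        return self.responses.to_numpy()


def eight_domain_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Conditions with eight independent domain traits and no shared one.

    Emulates an instrument whose eight domains measure genuinely distinct
    constructs: no shared severity (``trait_sd=0``), strong per-domain
    traits, moderate noise.  Under these conditions exploratory factor
    analysis retains exactly the eight domain factors by the
    eigenvalue >= 1 rule.
    """
    fields = dict(trait_sd=0.0, domain_trait_sd=2.0, noise_sd=0.4,
                  aberrant_fraction=0.0, seed=seed)
    fields.update(overrides)
    return SimulationConfig(**fields)


def item_difficulties(config: SimulationConfig) -> np.ndarray:
    """Equally spaced difficulties on [-spread, +spread], mean 0."""
    if config.n_items == 1:
        return np.zeros(1)
    return np.linspace(-config.difficulty_spread, config.difficulty_spread,
                       config.n_items)


def _item_columns(n_items: int):
    return [f"i{j + 1:02d}" for j in range(n_items)]


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate one cohort; identical config (incl. seed) => identical cohort."""
    rng = np.random.default_rng(config.seed)
    n, L = config.n_persons, config.n_items
    m, M = float(config.likert_min), float(config.likert_max)
    delta = item_difficulties(config)

    theta = rng.normal(config.trait_mean, config.trait_sd, size=n)
    n_aberrant = int(round(config.aberrant_fraction * n))
    aberrant = np.zeros(n, dtype=bool)
    aberrant[rng.permutation(n)[:n_aberrant]] = True

    theta_eff = np.repeat(theta[:, None], L, axis=1)
    if config.domain_trait_sd > 0 and n > 0:
        assign = np.repeat(np.arange(len(config.domain_sizes)),
                           config.domain_sizes)
        eta = rng.normal(0.0, config.domain_trait_sd,
                         size=(n, len(config.domain_sizes)))
        theta_eff = theta_eff + eta[:, assign]

    p = 1.0 / (1.0 + np.exp(-(theta_eff - delta[None, :])))
    if config.noise_sd == 0.0:
        frac = p
    elif config.noise_sd == 1.0:
        # Bernoulli limit: the model's own two-point variance p(1-p)
        frac = (rng.random(size=(n, L)) < p).astype(float)
    else:
        # Beta with mean p and variance noise_sd^2 * p(1-p)
        nu = (1.0 - config.noise_sd ** 2) / config.noise_sd ** 2
        frac = rng.beta(np.maximum(p * nu, 1e-12),
                        np.maximum((1.0 - p) * nu, 1e-12), size=(n, L))
    conforming = np.rint(np.clip(m + (M - m) * frac, m, M))

    random_resp = rng.integers(config.likert_min, config.likert_max + 1,
                               size=(n, L)).astype(float)
    values = np.where(aberrant[:, None], random_resp, conforming)

    responses = pd.DataFrame(values.astype(int), columns=_item_columns(L),
                             index=[f"p{i + 1:03d}" for i in range(n)])
    responses.index.name = "person_id"

    true_quadrant: list = [None] * n
    if n >= 2:
        try:
            fit = fit_rasch(values, m, M)
            labels, _ = classify_cohort(fit)
            true_quadrant = [lab.quadrant for lab in labels]
        except EstimationError:
            pass  # degenerate cohort (e.g. all-identical); leave unlabeled

    return SimulatedCohort(responses=responses, true_theta=theta,
                           true_difficulty=delta, aberrant_flags=aberrant,
                           true_quadrant=true_quadrant, config=config)


def _truth_path(path: Path) -> Path:
    return path.with_suffix(".truth.json")


def write_cohort(cohort: SimulatedCohort, path) -> Path:
    """Write responses as CSV and the generating truth as a JSON sidecar."""
    path = Path(path)
    cohort.responses.to_csv(path)
    truth = {
        "schema_version": 1,
        "theta": cohort.true_theta.tolist(),
        "difficulty": cohort.true_difficulty.tolist(),
        "aberrant": [bool(a) for a in cohort.aberrant_flags],
        "quadrant": cohort.true_quadrant,
        "config": asdict(cohort.config),
    }
    _truth_path(path).write_text(json.dumps(truth, indent=1))
    return path


def read_cohort(path):
    """Read a responses CSV (and its truth sidecar if present).

    Returns ``(responses, truth_dict_or_None)``.
    """
    path = Path(path)
    responses = pd.read_csv(path, index_col="person_id")
    tp = _truth_path(path)
    truth = json.loads(tp.read_text()) if tp.exists() else None
    return responses, truth
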