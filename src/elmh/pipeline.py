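"""End-to-end orchestration: responses -> factor scores -> Rasch fit ->
quadrant labels -> trained micro-CNN -> model bundle."""

from __future__ import annotations

import numpy as np

from .cnn import MicroCNN
from .evaluate import ModelBundle
from .factor import (DEFAULT_DOMAIN_SPEC, FactorScorer,
                     fit_score_regressions)
from .quadrant import classify_cohort
from .rasch import RaschModel

__all__ = ["fit_model_bundle", "label_cohort", "train_cnn_on_labels"]


def fit_model_bundle(responses, response_min=1.0, response_max=5.0,
                     domain_spec=DEFAULT_DOMAIN_SPEC) -> ModelBundle:
    """Fit the unsupervised half of the pipeline on a cohort.

    Extracts one varimax factor per questionnaire domain, regresses each
    domain's Bartlett score on its raw sum (the on-device scoring
    shortcut), and fits the continuous-response Rasch model to the raw
    items to anchor the item difficulties.  The returned bundle carries
    everything the assessment path needs except (optionally) trained CNN
    parameters.
    """
    X = np.asarray(responses, dtype=float)
    scorer = FactorScorer(n_factors=domain_spec.n_domains,
                          align_to=domain_spec).fit(X)
    scores = scorer.transform(X)
    sums = domain_spec.domain_sums(X)
    regression = fit_score_regressions(sums, scores)
    rasch = RaschModel(response_min=response_min,
                       response_max=response_max).fit(X)
    return ModelBundle(item_difficulties=rasch.item_difficulties_,
                       response_min=response_min, response_max=response_max,
                       score_regression=regression, domain_spec=domain_spec,
                       item_means=scorer.means_, item_sds=scorer.sds_,
                       loadings=scorer.loadings_,
                       uniquenesses=scorer.uniquenesses_)


def label_cohort(responses, response_min=1.0, response_max=5.0):
    """Rasch-fit a cohort and return (fit, labels, counts)."""
    rasch = RaschModel(response_min=response_min,
                       response_max=response_max).fit(
        np.asarray(responses, dtype=float))
    labels, counts = classify_cohort(rasch.fit_)
    return rasch.fit_, labels, counts


def train_cnn_on_labels(responses, labels, seed=0, learning_rate=2.0,
                        max_epochs=5000, likert_min=1, likert_max=5):
    """Train the micro-CNN to reproduce quadrant labels; returns the
    fitted :class:`MicroCNN`."""
    y = np.asarray([str(lab) for lab in labels])
    clf = MicroCNN(seed=seed, learning_rate=learning_rate,
                   max_epochs=max_epochs, likert_min=likert_min,
                   likert_max=likert_max)
    return clf.fit(np.asarray(responses, dtype=float), y)
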