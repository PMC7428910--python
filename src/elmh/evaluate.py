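"""Classifier evaluation, the discriminant baseline, survey planning,
and the per-respondent assessment report.

The discriminant baseline is classical linear discriminant analysis
with equal class priors: class means, a pooled within-class covariance,
and linear scores ``x' S^-1 mu_c - 0.5 mu_c' S^-1 mu_c``.  It is run on
two feature sets — the 8 factor scores alone, and the 8 factor scores
plus the outfit MNSQ — to quantify how much the person-fit statistic
adds to the classification.

The survey-planning utility is the standard finite-population sample
size: ``n0 = z^2 p (1-p) / margin^2`` corrected by
``n = n0 / (1 + (n0 - 1) / population)`` and rounded up.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.stats import norm

from .errors import EstimationError, InputError
from .factor import (DEFAULT_DOMAIN_SPEC, DEFAULT_SCORE_REGRESSION,
                     DomainSpec, ScoreRegression, regression_factor_score)
from .quadrant import QUADRANTS, classify_person
from .rasch import score_person
from . import cnn as _cnn

__all__ = ["ConfusionMatrix", "confusion_matrix", "accuracy",
           "DiscriminantBaseline", "discriminant_baseline",
           "required_sample_size", "ModelBundle", "AssessmentReport",
           "assess_respondent"]

ADVISORY = {
    "I": "Low confidence: the response pattern misfits the model; "
         "the apparent illness signal may not be real.",
    "II": "Mental-illness class: a consultation with a mental-health or "
          "occupational-medicine physician is advised.",
    "III": "Healthy class: no indication of workplace mental illness.",
    "IV": "Low confidence: the response pattern misfits the model; "
          "the apparent healthy result may not be real.",
}


@dataclass
class ConfusionMatrix:
    """Counts by (true, predicted) class pair."""

    counts: np.ndarray
    labels: tuple = QUADRANTS

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.counts, index=list(self.labels),
                            columns=list(self.labels))


def confusion_matrix(true_labels, predicted_labels,
                     labels=QUADRANTS) -> ConfusionMatrix:
    t = np.asarray([str(x) for x in true_labels])
    p = np.asarray([str(x) for x in predicted_labels])
    if t.shape != p.shape:
        raise InputError("true and predicted label vectors differ in length")
    idx = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for a, b in zip(t, p):
        counts[idx[a], idx[b]] += 1
    return ConfusionMatrix(counts=counts, labels=tuple(labels))


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction correctly classified: trace / total."""
    if cm.total == 0:
        raise InputError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


class DiscriminantBaseline:
    """Equal-prior linear discriminant classifier.

    Fits class means and a pooled within-class covariance; a singular
    pooled covariance triggers an automatic ridge (1e-6 on the diagonal)
    with a warning.
    """

    def __init__(self, ridge: float = 1e-6):
        self.ridge = ridge

    def get_params(self, deep=True):
        return {"ridge": self.ridge}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray([str(v) for v in y])
        if X.ndim != 2 or X.shape[1] < 1:
            raise InputError("X must be 2-D with >= 1 feature")
        classes = [q for q in QUADRANTS if q in set(y)] \
            if set(y) <= set(QUADRANTS) else sorted(set(y))
        if len(classes) < 2:
            raise EstimationError("need >= 2 classes present")
        means = np.stack([X[y == c].mean(axis=0) for c in classes])
        scatter = np.zeros((X.shape[1], X.shape[1]))
        for c, mu in zip(classes, means):
            d = X[y == c] - mu
            scatter += d.T @ d
        cov = scatter / (X.shape[0] - len(classes))
        try:
            cov_inv = np.linalg.inv(cov)
            if not np.all(np.isfinite(cov_inv)) or \
                    np.linalg.cond(cov) > 1e12:
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            warnings.warn("singular pooled covariance; applying ridge "
                          f"regularization ({self.ridge} on the diagonal)",
                          UserWarning)
            cov_inv = np.linalg.inv(cov + self.ridge * np.eye(X.shape[1]))
        self.classes_ = np.asarray(classes)
        self.means_ = means
        self.cov_inv_ = cov_inv
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        a = self.means_ @ self.cov_inv_                       # (C, k)
        const = -0.5 * np.einsum("ck,ck->c", a, self.means_)  # (C,)
        return X @ a.T + const

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y)))


def discriminant_baseline(features, labels, ridge: float = 1e-6):
    """Fit-and-resubstitute LDA predictions for a labeled feature matrix."""
    model = DiscriminantBaseline(ridge=ridge).fit(features, labels)
    return model.predict(features)


def required_sample_size(population: int, confidence: float = 0.95,
                         margin: float = 0.05, p: float = 0.5) -> int:
    """Finite-population sample size for estimating a proportion."""
    if population < 1:
        raise InputError("population must be >= 1")
    if not 0 < margin < 1:
        raise InputError("margin must be in (0, 1)")
    if not 0 < confidence < 1:
        raise InputError("confidence must be in (0, 1)")
    z = norm.ppf(1 - (1 - confidence) / 2)
    n0 = z ** 2 * p * (1 - p) / margin ** 2
    n = n0 / (1 + (n0 - 1) / population)
    return int(math.ceil(n))


@dataclass
class ModelBundle:
    """Everything the assessment path needs, persistable as JSON."""

    item_difficulties: np.ndarray
    response_min: float
    response_max: float
    score_regression: ScoreRegression = DEFAULT_SCORE_REGRESSION
    domain_spec: DomainSpec = DEFAULT_DOMAIN_SPEC
    cnn_params: "_cnn.CnnParameters | None" = None
    cnn_class_order: tuple = QUADRANTS
    item_means: np.ndarray | None = None
    item_sds: np.ndarray | None = None
    loadings: np.ndarray | None = None
    uniquenesses: np.ndarray | None = None

    def save(self, path) -> Path:
        doc = {
            "schema_version": 1,
            "item_difficulties": np.asarray(self.item_difficulties).tolist(),
            "response_min": self.response_min,
            "response_max": self.response_max,
            "regression": {"intercepts": list(self.score_regression.intercepts),
                           "slopes": list(self.score_regression.slopes)},
            "domain_sizes": list(self.domain_spec.domain_sizes),
            "domain_names": list(self.domain_spec.domain_names),
            "cnn_class_order": list(self.cnn_class_order),
        }
        for name in ("item_means", "item_sds", "loadings", "uniquenesses"):
            v = getattr(self, name)
            doc[name] = None if v is None else np.asarray(v).tolist()
        if self.cnn_params is not None:
            doc["cnn"] = {
                "filters": self.cnn_params.filters.tolist(),
                "filter_bias": self.cnn_params.filter_bias.tolist(),
                "pool_weights": self.cnn_params.pool_weights.tolist(),
                "pool_bias": self.cnn_params.pool_bias.tolist(),
            }
        Path(path).write_text(json.dumps(doc, indent=1))
        return Path(path)

    @classmethod
    def load(cls, path) -> "ModelBundle":
        doc = json.loads(Path(path).read_text())
        params = None
        if "cnn" in doc:
            c = doc["cnn"]
            params = _cnn.CnnParameters(
                np.asarray(c["filters"], dtype=float),
                np.asarray(c["filter_bias"], dtype=float),
                np.asarray(c["pool_weights"], dtype=float),
                np.asarray(c["pool_bias"], dtype=float))
        opt = {name: (None if doc.get(name) is None
                      else np.asarray(doc[name], dtype=float))
               for name in ("item_means", "item_sds", "loadings",
                            "uniquenesses")}
        return cls(
            item_difficulties=np.asarray(doc["item_difficulties"],
                                         dtype=float),
            response_min=doc["response_min"],
            response_max=doc["response_max"],
            score_regression=ScoreRegression(
                intercepts=tuple(doc["regression"]["intercepts"]),
                slopes=tuple(doc["regression"]["slopes"])),
            domain_spec=DomainSpec(domain_names=tuple(doc["domain_names"]),
                                   domain_sizes=tuple(doc["domain_sizes"])),
            cnn_params=params,
            cnn_class_order=tuple(doc.get("cnn_class_order", QUADRANTS)),
            **opt)


@dataclass
class AssessmentReport:
    """Per-respondent result of the full assessment path."""

    person_id: str
    domain_sums: list
    factor_scores: list
    measure: float
    outfit: float
    quadrant: str
    semantics: str
    confidence: str
    class_outputs: list | None
    advisory: str

    def to_json(self, path=None) -> str:
        doc = {"schema_version": 1, **asdict(self)}
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def assess_respondent(responses, bundle: ModelBundle,
                      person_id: str = "respondent") -> AssessmentReport:
    """Run one respondent through the full assessment path.

    Computes domain raw sums, the published regression factor scores, the
    Rasch measure and outfit against the stored item difficulties, the
    quadrant label with its confidence, the micro-CNN class outputs when
    parameters are bundled, and the advisory text key.
    """
    r = np.asarray(responses, dtype=float).ravel()
    spec = bundle.domain_spec
    if r.size != spec.n_items:
        missing = spec.n_items - r.size
        raise InputError(f"expected {spec.n_items} item responses, got "
                         f"{r.size} ({missing} missing)" if missing > 0
                         else f"expected {spec.n_items} item responses, "
                              f"got {r.size}")
    if np.any(~np.isfinite(r)):
        bad = [f"i{j + 1:02d}" for j in np.where(~np.isfinite(r))[0]]
        raise InputError("missing responses for items: " + ", ".join(bad))
    if np.any(r < bundle.response_min) or np.any(r > bundle.response_max):
        raise InputError("responses outside the instrument's response range")

    sums = spec.domain_sums(r)[0]
    fscores = [regression_factor_score(d + 1, sums[d],
                                       bundle.score_regression)
               for d in range(spec.n_domains)]
    measure, outfit = score_person(r, bundle.item_difficulties,
                                   bundle.response_min, bundle.response_max)
    label = classify_person(measure, outfit)
    outputs = None
    if bundle.cnn_params is not None:
        _, out = _cnn.predict(r, bundle.cnn_params,
                              likert_min=bundle.response_min,
                              likert_max=bundle.response_max,
                              class_order=bundle.cnn_class_order)
        outputs = [float(v) for v in out]
    return AssessmentReport(
        person_id=person_id,
        domain_sums=[float(s) for s in sums],
        factor_scores=[float(f) for f in fscores],
        measure=measure, outfit=outfit,
        quadrant=label.quadrant, semantics=label.semantics,
        confidence=label.confidence, class_outputs=outputs,
        advisory=ADVISORY[label.quadrant])
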