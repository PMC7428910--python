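"""Four-quadrant classification from (measure, outfit MNSQ).

Respondents are placed in a plane with the person measure (logits) on
one axis and the outfit mean square on the other, and cut at 0 logits
and outfit 2.0:

    II  — mental illness (measure > 0, outfit < 2): high severity,
          model-consistent responding; high confidence.
    III — health / MI-free (measure <= 0, outfit < 2): high confidence.
    I   — false MI (measure > 0, outfit >= 2): the apparent severity is
          driven by an aberrant response pattern; low confidence.
    IV  — false health (measure <= 0, outfit >= 2): low confidence.

Boundary convention: a measure of exactly 0 falls on the healthy side,
and an outfit of exactly 2.0 counts as misfit.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .rasch import RaschFit

__all__ = ["Quadrant", "QuadrantLabel", "classify_person", "classify_cohort",
           "QuadrantClassifier", "QUADRANTS", "MEASURE_CUT", "OUTFIT_CUT"]

QUADRANTS = ("I", "II", "III", "IV")
MEASURE_CUT = 0.0
OUTFIT_CUT = 2.0

_SEMANTICS = {"I": "false MI", "II": "MI", "III": "health",
              "IV": "false health"}
_CONFIDENCE = {"I": "low", "II": "high", "III": "high", "IV": "low"}


@dataclass(frozen=True)
class QuadrantLabel:
    quadrant: str        # "I" | "II" | "III" | "IV"
    semantics: str       # false MI | MI | health | false health
    confidence: str      # high for II/III, low for I/IV

    def __str__(self):
        return self.quadrant


def Quadrant(quadrant: str) -> QuadrantLabel:
    """Build the :class:`QuadrantLabel` for a quadrant name."""
    if quadrant not in QUADRANTS:
        raise InputError(f"unknown quadrant {quadrant!r}")
    return QuadrantLabel(quadrant, _SEMANTICS[quadrant],
                         _CONFIDENCE[quadrant])


def classify_person(measure: float, outfit: float,
                    measure_cut: float = MEASURE_CUT,
                    outfit_cut: float = OUTFIT_CUT) -> QuadrantLabel:
    """Assign one respondent a quadrant from (measure, outfit)."""
    if not (np.isfinite(measure) and np.isfinite(outfit)):
        raise InputError("measure and outfit must be finite")
    if outfit < 0:
        raise InputError("outfit must be non-negative")
    misfit = outfit >= outfit_cut
    high = measure > measure_cut
    if misfit:
        return Quadrant("I" if high else "IV")
    return Quadrant("II" if high else "III")


def classify_cohort(fit: RaschFit, measure_cut: float = MEASURE_CUT,
                    outfit_cut: float = OUTFIT_CUT):
    """Labels plus per-quadrant counts for a fitted cohort.

    Returns ``(labels, counts)`` where counts is a dict over quadrants
    I–IV summing to the cohort size.
    """
    labels = [classify_person(m, o, measure_cut, outfit_cut)
              for m, o in zip(fit.person_measures, fit.outfit)]
    counts = Counter(lab.quadrant for lab in labels)
    return labels, {q: counts.get(q, 0) for q in QUADRANTS}


class QuadrantClassifier:
    """Rule-based (measure, outfit) -> quadrant classifier.

    A stateless scikit-learn-style classifier: ``fit`` records the classes
    and ``predict`` applies the fixed cutoffs to an (n, 2) array of
    ``[measure, outfit]`` pairs.
    """

    def __init__(self, measure_cut: float = MEASURE_CUT,
                 outfit_cut: float = OUTFIT_CUT):
        self.measure_cut = measure_cut
        self.outfit_cut = outfit_cut

    def get_params(self, deep=True):
        return {"measure_cut": self.measure_cut,
                "outfit_cut": self.outfit_cut}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None):
        self.classes_ = np.asarray(QUADRANTS)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise InputError("X must be (n, 2): columns [measure, outfit]")
        return np.asarray([classify_person(m, o, self.measure_cut,
                                           self.outfit_cut).quadrant
                           for m, o in X])
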