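"""ROC-based threshold calibration and exact binomial confidence intervals.

The ROC is built over candidate thresholds placed at midpoints between
consecutive distinct scores (plus sentinels beyond the extremes), with the
positive call defined as *score strictly greater than threshold*.  On
integer-valued HU data this midpoint rule is what produces half-integer
operating points such as 24.5 HU.  Two operating-point criteria are
provided: Youden's J and the "closest top left" distance; ties are broken
toward the smallest threshold (maximizing sensitivity).

Diagnostic proportions are reported with exact Clopper–Pearson intervals,
the construction that reproduces printed bounds like 91.48–99.38% for
97/100 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin


@dataclass
class ROCResult:
    """Empirical ROC over midpoint candidate thresholds (ascending)."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_pos: int
    n_neg: int

    @property
    def youden_threshold(self) -> float:
        return youden_threshold(self)

    @property
    def topleft_threshold(self) -> float:
        return topleft_threshold(self)


@dataclass(frozen=True)
class BinomialCI:
    """Exact binomial proportion CI; bounds are percentages."""

    successes: int
    trials: int
    level: float
    estimate: float
    lower: float
    upper: float


def _as_binary_labels(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "US":
        mapping = {"pos": 1, "neg": 0, "positive": 1, "negative": 0}
        try:
            labels = np.array([mapping[str(v).lower()] for v in labels])
        except KeyError as e:
            raise ValueError(f"unrecognized label {e}") from None
    return labels.astype(bool)


def roc(scores, labels) -> ROCResult:
    """Empirical ROC of a score for a binary outcome.

    Candidate thresholds are the midpoints between consecutive distinct
    sorted scores plus one sentinel below the minimum and one above the
    maximum; a case is called positive when its score exceeds the threshold.
    The AUC is the trapezoidal area under the resulting empirical curve,
    which equals the normalized Mann–Whitney U statistic (ties counted half).
    """
    scores = np.asarray(scores, dtype=np.float64)
    y = _as_binary_labels(labels)
    if scores.shape != y.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    pos = np.sort(scores[y])
    neg = np.sort(scores[~y])
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need at least one positive and one negative case")

    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate(([distinct[0] - 1.0], mids, [distinct[-1] + 1.0]))

    # sens(t) = P(pos > t), spec(t) = P(neg <= t); searchsorted on sorted arrays
    sens = 1.0 - np.searchsorted(pos, thresholds, side="right") / pos.size
    spec = np.searchsorted(neg, thresholds, side="right") / neg.size

    # traverse the curve from (0,0) (highest threshold) to (1,1) (lowest);
    # along ascending thresholds fpr is non-increasing, so reverse
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens[::-1], fpr[::-1]))
    return ROCResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        n_pos=int(pos.size),
        n_neg=int(neg.size),
    )


def youden_threshold(roc_result: ROCResult) -> float:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Ties are broken toward the smallest threshold.
    """
    j = roc_result.sensitivity + roc_result.specificity - 1.0
    return float(roc_result.thresholds[int(np.argmax(j))])


def topleft_threshold(roc_result: ROCResult) -> float:
    """Threshold minimizing the squared distance to the perfect corner,
    (1 - sens)^2 + (1 - spec)^2; ties toward the smallest threshold."""
    d2 = (1.0 - roc_result.sensitivity) ** 2 + (1.0 - roc_result.specificity) ** 2
    return float(roc_result.thresholds[int(np.argmin(d2))])


def clopper_pearson(successes: int, trials: int, level: float = 0.95) -> BinomialCI:
    """Exact (Clopper–Pearson) two-sided binomial CI, in percent."""
    successes, trials = int(successes), int(trials)
    if trials < 1 or not 0 <= successes <= trials:
        raise ValueError(f"invalid counts: {successes}/{trials}")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    ci = stats.binomtest(successes, trials).proportion_ci(
        confidence_level=level, method="exact"
    )
    return BinomialCI(
        successes=successes,
        trials=trials,
        level=level,
        estimate=100.0 * successes / trials,
        lower=100.0 * float(ci.low),
        upper=100.0 * float(ci.high),
    )


class HUThresholdClassifier(BaseEstimator, ClassifierMixin):
    """Single-threshold classifier on a scalar score (median HU).

    Predicts the positive class when the score strictly exceeds the
    threshold.  The threshold is either fixed (``criterion='fixed'``,
    default 24.5 HU — the hemopericardium operating point) or calibrated on
    the training scores by ROC analysis with Youden's J or the
    closest-top-left criterion.

    Attributes
    ----------
    threshold_ : float
        The operating threshold after :meth:`fit`.
    roc_ : ROCResult or None
        The training ROC when a data-driven criterion was used.
    """

    def __init__(self, criterion: str = "fixed", threshold: float = 24.5):
        self.criterion = criterion
        self.threshold = threshold

    @staticmethod
    def _scores(X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("expected a single score column")
            X = X[:, 0]
        if X.ndim != 1:
            raise ValueError("expected a 1-D score vector or (n, 1) array")
        return X

    def fit(self, X, y=None):
        if self.criterion not in ("fixed", "youden", "topleft"):
            raise ValueError(f"unknown criterion {self.criterion!r}")
        scores = self._scores(X)
        self.classes_ = np.array([False, True])
        if self.criterion == "fixed":
            self.threshold_ = float(self.threshold)
            self.roc_ = None
        else:
            if y is None:
                raise ValueError("labels are required for ROC calibration")
            self.roc_ = roc(scores, y)
            self.threshold_ = (
                youden_threshold(self.roc_)
                if self.criterion == "youden"
                else topleft_threshold(self.roc_)
            )
        return self

    def decision_function(self, X) -> np.ndarray:
        return self._scores(X) - self.threshold_

    def predict(self, X) -> np.ndarray:
        return self.decision_function(X) > 0
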