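"""Gaussian naive Bayes, probability fusion, and evaluation metrics.

The decision stage combines two class-probability sources — the CNN of
:mod:`dermoborder.cnn` and a Gaussian naive Bayes fitted on the
27-value irregularity descriptor — with the product-sum rule

    P = (CNN_p1 * GnB_p1 + CNN_p2 * GnB_p2) / 2

where subscript 1 is the irregular class and 2 the regular class.  P is
bounded by [0, 0.5] and is maximal exactly when both models agree with
certainty; it measures joint agreement rather than class direction.
Decisions for a test batch use the adaptive threshold

    threshold = (max(P) + mean(P)) / 2

with P_i < threshold read as regular and P_i > threshold as irregular
(the P_i = threshold tie goes to irregular: a false "regular" call is
the clinically riskier error, so ties escalate).

Label convention everywhere: 1 = regular, 0 = irregular.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

IRREGULAR, REGULAR = 0, 1


@dataclass
class GaussianNBModel:
    """Per-class feature means/variances and priors (classes [0, 1])."""

    priors: np.ndarray        # shape (2,), order [irregular, regular]
    means: np.ndarray         # shape (2, n_features)
    variances: np.ndarray     # shape (2, n_features), floored
    n_features: int = field(init=False)

    def __post_init__(self):
        self.n_features = self.means.shape[1]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "priors": self.priors.tolist(),
                    "means": self.means.tolist(),
                    "variances": self.variances.tolist(),
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "GaussianNBModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            priors=np.array(d["priors"]),
            means=np.array(d["means"]),
            variances=np.array(d["variances"]),
        )


def gnb_fit(features: np.ndarray, labels: np.ndarray) -> GaussianNBModel:
    """Fit per-class Gaussians: sample means/variances plus frequency priors.

    Variances are floored at 1e-9 times the largest feature variance so
    constant features (e.g. ZM1, pinned at 1/pi) stay usable.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels)
    if set(np.unique(y)) != {IRREGULAR, REGULAR}:
        raise ValueError("labels must contain both classes {0, 1}")
    means, variances, priors = [], [], []
    floor = max(1e-9 * float(np.var(x, axis=0).max()), 1e-12)
    for cls in (IRREGULAR, REGULAR):
        xc = x[y == cls]
        if xc.shape[0] < 2:
            raise ValueError(f"need >= 2 samples for class {cls}, got {xc.shape[0]}")
        means.append(xc.mean(axis=0))
        variances.append(np.maximum(xc.var(axis=0), floor))
        priors.append(xc.shape[0] / x.shape[0])
    return GaussianNBModel(
        priors=np.array(priors), means=np.array(means), variances=np.array(variances)
    )


def gnb_predict(model: GaussianNBModel, x: np.ndarray) -> tuple[float, float]:
    """(p_irregular, p_regular) for one descriptor, normalized to sum 1.

    The per-feature Gaussian densities are multiplied with the prior in
    the log domain; the evidence term is a shared constant and drops out
    in the normalization.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size != model.n_features:
        raise ValueError(f"expected {model.n_features} features, got {x.size}")
    log_post = (
        np.log(model.priors)
        - 0.5 * np.sum(np.log(2 * np.pi * model.variances), axis=1)
        - 0.5 * np.sum((x[None, :] - model.means) ** 2 / model.variances, axis=1)
    )
    log_post -= log_post.max()
    p = np.exp(log_post)
    p /= p.sum()
    return float(p[IRREGULAR]), float(p[REGULAR])


def ensemble_score(cnn_p: tuple[float, float], gnb_p: tuple[float, float]) -> float:
    """Fused agreement score P = (c1*g1 + c2*g2)/2, in [0, 0.5]."""
    for pair in (cnn_p, gnb_p):
        if abs(pair[0] + pair[1] - 1.0) > 1e-6:
            raise ValueError(f"probability pair {pair} does not sum to 1")
    return (cnn_p[0] * gnb_p[0] + cnn_p[1] * gnb_p[1]) / 2.0


def decision_threshold(scores) -> float:
    """Adaptive batch threshold (max(P) + mean(P)) / 2."""
    scores = np.asarray(list(scores), dtype=float)
    if scores.size == 0:
        raise ValueError("cannot derive a threshold from an empty score list")
    return float((scores.max() + scores.mean()) / 2.0)


def decide(p: float, threshold: float) -> int:
    """1 (regular) when P < threshold, else 0 (irregular); ties irregular."""
    return REGULAR if p < threshold else IRREGULAR


@dataclass
class MetricsReport:
    """Confusion counts plus rates in percent.

    ``sensitivity`` is the regular-class recall and ``specificity`` the
    irregular-class recall; the F-score treats irregular as the
    positive class (harmonic mean of its precision and recall).
    """

    n_regular: int
    n_irregular: int
    correct_regular: int
    correct_irregular: int
    accuracy: float
    sensitivity: float
    specificity: float
    f_score: float

    @property
    def confusion(self) -> np.ndarray:
        """Rows = truth (irregular, regular), columns = prediction."""
        return np.array(
            [
                [self.correct_irregular, self.n_irregular - self.correct_irregular],
                [self.n_regular - self.correct_regular, self.correct_regular],
            ]
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {k: getattr(self, k) for k in (
                    "n_regular", "n_irregular", "correct_regular",
                    "correct_irregular", "accuracy", "sensitivity",
                    "specificity", "f_score",
                )},
                fh,
                indent=2,
            )


def evaluate(decisions, labels) -> MetricsReport:
    """Score predictions against truth; all rates in percent."""
    pred = np.asarray(list(decisions))
    true = np.asarray(list(labels))
    if pred.shape != true.shape:
        raise ValueError("decisions and labels must have equal length")
    for arr, name in ((pred, "decisions"), (true, "labels")):
        if not np.isin(arr, (IRREGULAR, REGULAR)).all():
            raise ValueError(f"{name} must take values in {{0, 1}}")
    n_reg = int((true == REGULAR).sum())
    n_irr = int((true == IRREGULAR).sum())
    ok_reg = int(((true == REGULAR) & (pred == REGULAR)).sum())
    ok_irr = int(((true == IRREGULAR) & (pred == IRREGULAR)).sum())
    total = true.size
    accuracy = 100.0 * (ok_reg + ok_irr) / total if total else 0.0
    sensitivity = 100.0 * ok_reg / n_reg if n_reg else 0.0
    specificity = 100.0 * ok_irr / n_irr if n_irr else 0.0
    pred_irr = int((pred == IRREGULAR).sum())
    precision = ok_irr / pred_irr if pred_irr else 0.0
    recall = ok_irr / n_irr if n_irr else 0.0
    f_score = (
        100.0 * 2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    return MetricsReport(
        n_regular=n_reg,
        n_irregular=n_irr,
        correct_regular=ok_reg,
        correct_irregular=ok_irr,
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        f_score=f_score,
    )


def jaccard_index(segmentation: np.ndarray, ground_truth: np.ndarray) -> float:
    """Intersection over union of two masks, in percent."""
    s = np.asarray(segmentation, dtype=bool)
    g = np.asarray(ground_truth, dtype=bool)
    union = np.logical_or(s, g).sum()
    if union == 0:
        return 100.0
    return 100.0 * np.logical_and(s, g).sum() / union
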