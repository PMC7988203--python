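"""Seed-labeled hyperplane classification of VVR vs. normal episodes.

Episodes live in a two-feature space: the maximal systolic-pressure drop
(BPmaxdrop, mmHg) and the maximal |dBRS| excursion.  A small seed set is
labeled from unambiguous BPmaxdrop values alone (very large drop = VVR,
very small = normal); a linear discriminant is then learned on the seeds
and used to classify everything else.  Single-threshold baselines on
BPmaxdrop (conventionally 25 mmHg, sometimes 18 mmHg) are evaluated
alongside for comparison — the joint two-feature boundary separates the
classes better than any single pressure threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "NORMAL",
    "VVR",
    "UNLABELED",
    "FeaturePoint",
    "Hyperplane",
    "EvaluationReport",
    "seed_label",
    "fit_hyperplane",
    "classify",
    "evaluate",
]

NORMAL = "normal"
VVR = "vvr"
UNLABELED = "unlabeled"

_MAX_EPOCHS = 10_000


@dataclass(frozen=True)
class FeaturePoint:
    """One episode in (BPmaxdrop, |dBRS|max) feature space."""

    episode_id: str
    bp_max_drop: float  # mmHg, >= 0
    delta_brs_max: float  # magnitude, >= 0
    label: str = UNLABELED

    def __post_init__(self) -> None:
        if self.label not in (NORMAL, VVR, UNLABELED):
            raise ValueError(f"unknown label {self.label!r}")
        if not (np.isfinite(self.bp_max_drop) and np.isfinite(self.delta_brs_max)):
            raise ValueError("features must be finite")
        if self.bp_max_drop < 0 or self.delta_brs_max < 0:
            raise ValueError("features are magnitudes and must be >= 0")

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.bp_max_drop, self.delta_brs_max])


@dataclass
class Hyperplane:
    """Linear decision boundary on standardized features.

    Decision rule: ``sign(w . (x - center)/scale + b)``; a nonnegative
    score classifies as VVR (boundary ties resolve toward detection).
    """

    w: np.ndarray
    b: float
    center: np.ndarray
    scale: np.ndarray
    train_error: float

    def score(self, points) -> np.ndarray:
        X = np.array([p.xy for p in points], dtype=float)
        Xs = (X - self.center) / self.scale
        return Xs @ self.w + self.b

    def predict(self, points) -> list[str]:
        return [VVR if s >= 0 else NORMAL for s in self.score(points)]


def seed_label(
    points,
    vvr_seed_drop: float = 35.0,
    normal_seed_drop: float = 10.0,
) -> list[FeaturePoint]:
    """Label the unambiguous extremes of BPmaxdrop; leave the rest open.

    Drops at or above ``vvr_seed_drop`` become VVR seeds, at or below
    ``normal_seed_drop`` normal seeds.  Both classes must receive at
    least one seed or no discriminant can be trained.
    """
    if not vvr_seed_drop > normal_seed_drop:
        raise ValueError("vvr_seed_drop must exceed normal_seed_drop")
    out = []
    for p in points:
        if p.bp_max_drop >= vvr_seed_drop:
            out.append(replace(p, label=VVR))
        elif p.bp_max_drop <= normal_seed_drop:
            out.append(replace(p, label=NORMAL))
        else:
            out.append(replace(p, label=UNLABELED))
    labels = {p.label for p in out}
    if VVR not in labels or NORMAL not in labels:
        raise ValueError(
            "seed set incomplete: need at least one point per class "
            f"(got {sorted(labels - {UNLABELED})})"
        )
    return out


def fit_hyperplane(points) -> Hyperplane:
    """Learn the separating hyperplane from labeled points.

    Margin perceptron on standardized features with a deterministic pass
    order; when it has not converged within 10^4 epochs (inseparable
    data) the least-squares discriminant is used instead.  The training
    error is reported, never raised.
    """
    labeled = [p for p in points if p.label in (NORMAL, VVR)]
    if not labeled:
        raise ValueError("no labeled points")
    y = np.array([1.0 if p.label == VVR else -1.0 for p in labeled])
    if len(set(y)) < 2:
        raise ValueError("single-class input: need both classes to fit")
    X = np.array([p.xy for p in labeled], dtype=float)
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale < 1e-12] = 1.0
    Xs = (X - center) / scale

    # margin perceptron, fixed pass order
    w = np.zeros(2)
    b = 0.0
    margin = 0.1
    lr = 0.1
    converged = False
    for _ in range(_MAX_EPOCHS):
        updated = False
        for xi, yi in zip(Xs, y):
            if yi * (xi @ w + b) <= margin:
                w = w + lr * yi * xi
                b = b + lr * yi
                updated = True
        if not updated:
            converged = True
            break
    if not converged or np.linalg.norm(w) < 1e-12:
        # least-squares discriminant: [X 1] beta ~= y
        A = np.hstack([Xs, np.ones((len(y), 1))])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        w, b = beta[:2], float(beta[2])
    plane = Hyperplane(w=w, b=float(b), center=center, scale=scale, train_error=0.0)
    pred = plane.predict(labeled)
    plane.train_error = float(
        np.mean([pl != p.label for pl, p in zip(pred, labeled)])
    )
    return plane


def classify(points, plane: Hyperplane) -> list[FeaturePoint]:
    """Assign every unlabeled point; seed labels are never overwritten."""
    out = []
    for p in points:
        if p.label == UNLABELED:
            out.append(replace(p, label=plane.predict([p])[0]))
        else:
            out.append(p)
    return out


@dataclass
class ConfusionCounts:
    tp: int = 0  # true VVR called VVR
    tn: int = 0
    fp: int = 0  # normal called VVR
    fn: int = 0  # VVR missed

    @property
    def errors(self) -> int:
        return self.fp + self.fn


@dataclass
class EvaluationReport:
    """Hyperplane confusion counts plus single-threshold baselines."""

    hyperplane: ConfusionCounts
    baselines: dict = field(default_factory=dict)  # threshold -> ConfusionCounts


def _confusion(pred: list[str], truth: list[str]) -> ConfusionCounts:
    c = ConfusionCounts()
    for p, t in zip(pred, truth):
        if t == VVR:
            if p == VVR:
                c.tp += 1
            else:
                c.fn += 1
        else:
            if p == VVR:
                c.fp += 1
            else:
                c.tn += 1
    return c


def evaluate(
    predicted,
    truth,
    baselines: tuple = (25.0, 18.0),
) -> EvaluationReport:
    """Compare hyperplane labels and BPmaxdrop-threshold baselines to truth.

    ``predicted`` and ``truth`` are FeaturePoint lists aligned by
    episode_id; each baseline threshold classifies VVR iff
    ``bp_max_drop >= threshold``.
    """
    if [p.episode_id for p in predicted] != [t.episode_id for t in truth]:
        raise ValueError("episode id mismatch between predictions and truth")
    truth_labels = [t.label for t in truth]
    report = EvaluationReport(
        hyperplane=_confusion([p.label for p in predicted], truth_labels)
    )
    for thr in baselines:
        pred = [VVR if p.bp_max_drop >= thr else NORMAL for p in predicted]
        report.baselines[thr] = _confusion(pred, truth_labels)
    return report


def best_threshold_errors(points, truth) -> int:
    """Fewest misclassifications any single BPmaxdrop threshold achieves.

    Sweeps every decision boundary the data admits (midpoints of sorted
    drops plus the extremes); used to show the two-feature discriminant
    beats the best possible one-feature rule.
    """
    drops = np.array([p.bp_max_drop for p in points])
    truth_labels = [t.label for t in truth]
    cuts = np.concatenate([[-np.inf], np.sort(drops), [np.inf]])
    best = len(points)
    for thr in cuts:
        pred = [VVR if d >= thr else NORMAL for d in drops]
        best = min(best, _confusion(pred, truth_labels).errors)
    return best
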