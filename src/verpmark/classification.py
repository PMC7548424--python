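"""Linear maximum-margin biomarker (SVMP1) and fixed threshold rules.

The SVMP1 score is a weighted sum of the 13 posterior z-scores learned by a
soft-margin linear SVM with grid-searched cost. Scores are always oriented
so that LOWER values are more CC-like, which makes development-cohort
thresholds directly transferable to a validation cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

__all__ = [
    "LinearBiomarkerModel",
    "ThresholdRule",
    "train_linear_svm",
    "svmp1_score",
    "classify",
    "DEFAULT_COST_GRID",
]

DEFAULT_COST_GRID: tuple[float, ...] = tuple(2.0**k for k in range(-5, 6))


@dataclass(frozen=True)
class LinearBiomarkerModel:
    """Linear decision function over the posterior electrode z-scores."""

    weights: np.ndarray  # (13,)
    bias: float
    cost: float
    electrodes: tuple[str, ...]
    training_cohort: str = ""
    flipped: bool = False  # sign flipped to enforce CC-low orientation

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 1 or not np.all(np.isfinite(w)):
            raise ValueError("weights must be a finite 1-D vector")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["weights"] = {e: float(w) for e, w in
                        zip(self.electrodes, self.weights)}
        d["electrodes"] = list(self.electrodes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LinearBiomarkerModel":
        electrodes = tuple(d["electrodes"])
        weights = np.array([d["weights"][e] for e in electrodes])
        return cls(
            weights=weights, bias=d["bias"], cost=d["cost"],
            electrodes=electrodes,
            training_cohort=d.get("training_cohort", ""),
            flipped=d.get("flipped", False),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2,
                                         sort_keys=True))

    @classmethod
    def load(cls, path) -> "LinearBiomarkerModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class ThresholdRule:
    """Fixed decision cut-off; boundary values classify as CC."""

    biomarker: str  # "mpp1" | "svmp1"
    threshold: float
    cc_low: bool = True  # scores <= threshold -> CC
    source_cohort: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdRule":
        return cls(**d)


def train_linear_svm(
    features: np.ndarray,
    is_cc: np.ndarray,
    cost_grid: Sequence[float] = DEFAULT_COST_GRID,
    electrodes: Optional[Sequence[str]] = None,
    cv_folds: int = 5,
    seed: int = 0,
    class_weight: Optional[str] = None,
    training_cohort: str = "",
) -> LinearBiomarkerModel:
    """Fit a soft-margin linear SVM, cost chosen by stratified CV accuracy.

    Ties in cross-validated accuracy resolve to the smallest cost. The
    returned model is oriented so that mean(score | CC) < mean(score | rest).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(is_cc, dtype=bool)
    if len(cost_grid) == 0:
        raise ValueError("cost grid must be non-empty")
    if y.all() or not y.any():
        raise ValueError("training data must contain both classes")
    if min((~y).sum(), y.sum()) < 2:
        raise ValueError("need at least 2 participants per class")
    if electrodes is None:
        electrodes = tuple(f"e{i}" for i in range(X.shape[1]))

    n_folds = min(cv_folds, int(y.sum()), int((~y).sum()))
    best_cost, best_acc = None, -np.inf
    for cost in sorted(cost_grid):
        clf = SVC(kernel="linear", C=cost, class_weight=class_weight,
                  tol=1e-8)
        if n_folds >= 2:
            cv = StratifiedKFold(n_splits=n_folds, shuffle=True,
                                 random_state=seed)
            acc = cross_val_score(clf, X, y, cv=cv, scoring="accuracy").mean()
        else:
            acc = clf.fit(X, y).score(X, y)
        if acc > best_acc:  # strict: first (smallest) cost wins ties
            best_cost, best_acc = cost, acc

    final = SVC(kernel="linear", C=best_cost, class_weight=class_weight,
                tol=1e-8).fit(X, y)
    w = final.coef_.ravel().astype(float)
    b = float(final.intercept_[0])
    scores = X @ w + b
    flipped = bool(scores[y].mean() >= scores[~y].mean())
    if flipped:
        w, b = -w, -b
    return LinearBiomarkerModel(
        weights=w, bias=b, cost=float(best_cost),
        electrodes=tuple(electrodes), training_cohort=training_cohort,
        flipped=flipped,
    )


def svmp1_score(model: LinearBiomarkerModel, z_posterior: np.ndarray) -> float:
    """score = w . z + bias (lower = more CC-like)."""
    z = np.asarray(z_posterior, dtype=float)
    if z.shape[-1] != model.weights.size:
        raise ValueError(
            f"expected {model.weights.size} posterior z-scores, "
            f"got {z.shape[-1]}"
        )
    return z @ model.weights + model.bias


def classify(score: float, rule: ThresholdRule) -> str:
    """Apply a fixed threshold; scores exactly at the boundary count as CC."""
    on_cc_side = score <= rule.threshold if rule.cc_low \
        else score >= rule.threshold
    return "CC" if on_cc_side else "not-CC"
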