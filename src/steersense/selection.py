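"""Systematic dimensionality reduction: kNN mutual information and blocked
backward feature elimination.

Two routes reduce the 42 features along a fixed schedule (steps of five from
42 down to 2, then to 1):

* **MI filter** — each feature's dependence on the behaviour label is scored
  with the discrete-continuous k-nearest-neighbour mutual-information
  estimator (k = 3) on each of the 25 balanced, standardised training folds;
  features are ranked once by mean score and subsets formed by truncation.
* **BFE wrapper** — at every step, each remaining feature is excluded in turn
  and the classifier retrained/validated on all 25 folds; the mean validation
  balanced accuracy *without* the feature is its (inverse) importance, and
  the block of least-important features is dropped.

Both produce a :class:`SelectionTrace` recording nested subsets, per-step
scores and per-feature survival counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import digamma

from .evaluation import (
    FoldSplit,
    PreparedSplit,
    prepare_splits,
    score_subset_over_splits,
)
from .features import feature_columns

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# mutual information


def mi_knn(x: np.ndarray, y: np.ndarray, k: int = 3) -> float:
    """kNN mutual information between a scalar feature and discrete labels.

    For each point, the distance to its k-th nearest neighbour *within its
    own class* defines a radius; ``m`` counts neighbours from *all* classes
    inside that radius. The estimate, in nats, is::

        psi(N) - <psi(N_x)> + psi(k) - <psi(m)>

    Tie handling (documented here, used nowhere else): neighbours are counted
    at distance strictly less than the k-th within-class neighbour distance
    (the radius is shrunk by one ulp), and the count enters the digamma as
    ``m + 1`` so the point itself is accounted for. Estimates are unclamped
    and may be slightly negative under independence.
    """
    x = np.asarray(x, dtype=float).reshape(-1, 1)
    y = np.asarray(y)
    n = len(x)
    if n != len(y):
        raise ValueError("x and y must have equal length")
    if k < 1:
        raise ValueError("k must be >= 1")

    radius = np.empty(n)
    n_x = np.empty(n)
    for cls in np.unique(y):
        mask = y == cls
        count = int(mask.sum())
        if count <= k:
            raise ValueError(f"class {cls!r} has {count} members; needs > k={k}")
        tree = cKDTree(x[mask])
        # k+1 because the query point is its own nearest neighbour
        dist, _ = tree.query(x[mask], k=k + 1)
        radius[mask] = np.nextafter(dist[:, -1], 0.0)
        n_x[mask] = count

    full_tree = cKDTree(x)
    m = full_tree.query_ball_point(x, radius, return_length=True) - 1  # minus self
    return float(
        digamma(n) - np.mean(digamma(n_x)) + digamma(k) - np.mean(digamma(m + 1))
    )


@dataclass
class MIScore:
    feature: str
    estimates: list[float]

    @property
    def mean(self) -> float:
        return float(np.mean(self.estimates))


def rank_by_mi(
    table: pd.DataFrame,
    splits: list[FoldSplit],
    k: int = 3,
    features: list[str] | None = None,
    prepared: list[PreparedSplit] | None = None,
) -> list[MIScore]:
    """Per-feature MI on every training fold; descending mean-score order."""
    features = features or feature_columns(table)
    if prepared is None:
        prepared = prepare_splits(table, splits, features)
    scores = []
    for j, name in enumerate(features):
        estimates = []
        for ps in prepared:
            try:
                estimates.append(mi_knn(ps.X_train[:, j], ps.y_train, k=k))
            except ValueError as exc:
                raise ValueError(f"MI failed for feature {name!r}: {exc}") from exc
        scores.append(MIScore(feature=name, estimates=estimates))
    scores.sort(key=lambda s: -s.mean)
    return scores


# ---------------------------------------------------------------------------
# schedules and traces


def default_schedule(n_features: int = 42, step: int = 5) -> list[int]:
    """Feature counts visited by the reduction: steps of five down to 2, then 1."""
    counts = [n_features]
    while counts[-1] - step >= 2:
        counts.append(counts[-1] - step)
    if counts[-1] > 1:
        counts.append(1)
    return counts


def validate_schedule(schedule: list[int], n_features: int) -> list[int]:
    schedule = [int(c) for c in schedule]
    if not schedule:
        raise ValueError("empty schedule")
    if schedule[0] > n_features:
        raise ValueError("schedule starts above the available feature count")
    if any(b >= a for a, b in zip(schedule, schedule[1:])):
        raise ValueError("schedule must be strictly decreasing")
    if schedule[-1] < 1:
        raise ValueError("schedule must end at >= 1 feature")
    return schedule


@dataclass
class SelectionStep:
    features: tuple[str, ...]
    scores: list[float] | None = None  # 25 per-fold balanced accuracies


@dataclass
class SelectionTrace:
    method: str  # "MI" or "BFE"
    schedule: list[int]
    steps: list[SelectionStep] = field(default_factory=list)

    def subset(self, count: int) -> tuple[str, ...]:
        for step in self.steps:
            if len(step.features) == count:
                return step.features
        raise KeyError(f"no step with {count} features")

    def survival_counts(self) -> dict[str, int]:
        """Number of reduction transitions each feature survived."""
        counts = {f: 0 for f in self.steps[0].features}
        for step in self.steps[1:]:
            for f in step.features:
                counts[f] += 1
        return counts

    def to_jsonable(self) -> dict:
        return {
            "method": self.method,
            "schedule": self.schedule,
            "steps": [
                {"features": list(s.features), "scores": s.scores} for s in self.steps
            ],
            "survival_counts": self.survival_counts(),
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_jsonable(), fh, indent=2)

    @classmethod
    def load(cls, path: str | Path) -> "SelectionTrace":
        with open(path) as fh:
            d = json.load(fh)
        trace = cls(method=d["method"], schedule=d["schedule"])
        trace.steps = [
            SelectionStep(features=tuple(s["features"]), scores=s["scores"])
            for s in d["steps"]
        ]
        return trace

    def survival_frame(self) -> pd.DataFrame:
        counts = self.survival_counts()
        return pd.DataFrame(
            {"feature": list(counts), "reduction_steps_survived": list(counts.values())}
        )


def reduce_by_mi(ranking: list[MIScore], schedule: list[int]) -> SelectionTrace:
    """Nested subsets formed by truncating the one-shot MI ranking."""
    names = [s.feature for s in ranking]
    schedule = validate_schedule(schedule, len(names))
    trace = SelectionTrace(method="MI", schedule=schedule)
    for count in schedule:
        trace.steps.append(SelectionStep(features=tuple(names[:count])))
    return trace


# ---------------------------------------------------------------------------
# backward feature elimination


def bfe_eliminate(
    table: pd.DataFrame,
    model_factory,
    splits: list[FoldSplit],
    schedule: list[int],
    features: list[str] | None = None,
    prepared: list[PreparedSplit] | None = None,
) -> SelectionTrace:
    """Blocked backward elimination with consensus ranking over the 25 folds.

    At each schedule transition, every remaining feature is excluded in turn
    and the model re-trained/validated on all folds and repetitions; the
    features whose exclusion leaves the highest mean validation balanced
    accuracy are the least important and are removed as a block. Fold
    failures (e.g. non-converging models) are logged and dropped from the
    mean. Ties in importance are broken by catalogue order for determinism.
    """
    features = features or feature_columns(table)
    schedule = validate_schedule(schedule, len(features))
    if len(schedule[0:1]) and schedule[0] != len(features):
        # subset the catalogue to the schedule start, keeping order
        features = features[: schedule[0]]
    if prepared is None:
        prepared = prepare_splits(table, splits, features)
    name_to_col = {n: i for i, n in enumerate(features)}

    remaining = list(features[: schedule[0]])
    trace = SelectionTrace(method="BFE", schedule=schedule)

    def cols(names):
        return np.array([name_to_col[f] for f in names])

    # score the full starting set
    trace.steps.append(
        SelectionStep(
            features=tuple(remaining),
            scores=score_subset_over_splits(prepared, cols(remaining), model_factory).tolist(),
        )
    )

    for target in schedule[1:]:
        n_remove = len(remaining) - target
        importance = np.empty(len(remaining))
        for i, f in enumerate(remaining):
            subset = [g for g in remaining if g != f]
            accs = score_subset_over_splits(prepared, cols(subset), model_factory)
            finite = accs[np.isfinite(accs)]
            if len(finite) == 0:
                logger.warning("all folds failed excluding %r; treating as important", f)
                importance[i] = -np.inf  # keep the feature
            else:
                importance[i] = finite.mean()
        # remove the n_remove features with highest accuracy-when-excluded
        order = np.argsort(-importance, kind="stable")
        to_remove = {remaining[i] for i in order[:n_remove]}
        remaining = [f for f in remaining if f not in to_remove]
        trace.steps.append(
            SelectionStep(
                features=tuple(remaining),
                scores=score_subset_over_splits(
                    prepared, cols(remaining), model_factory
                ).tolist(),
            )
        )
    return trace
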