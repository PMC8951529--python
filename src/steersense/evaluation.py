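"""Grouped, steer-balanced evaluation protocol and performance metrics.

The protocol mirrors the study design: 3 of the 18 steers (one per farm
trial) are held out as a test set before any statistics are computed; the
remaining 15 go through 5-fold cross-validation grouped by steer (12 train /
3 validation), repeated 5 times for 25 train/validation runs. Within each
run the training set is balanced so every steer contributes the same number
of blocks (that of the shortest-observed steer, random under-sampling with
time order preserved) and features are standardised to zero mean / unit
variance with training-fold parameters only.

Performance is the balanced accuracy 0.5 * (TP/P + TN/N) per class, macro
averaged; confidence intervals come from a percentile bootstrap over the 25
per-run accuracies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import feature_columns
from .states import LABELS, encode_labels

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# splits


@dataclass(frozen=True)
class FoldSplit:
    repetition: int
    fold: int
    train_steers: tuple[str, ...]
    val_steers: tuple[str, ...]
    seed: int


def hold_out_test(
    steers: list[tuple[str, str]], seed: int
) -> tuple[list[str], list[str]]:
    """Pick one test steer per trial (before any preprocessing statistics).

    ``steers`` is a list of (steer_id, trial_id). Returns (test, development)
    steer-id lists, deterministic per seed.
    """
    by_trial: dict[str, list[str]] = {}
    for sid, tid in steers:
        by_trial.setdefault(tid, []).append(sid)
    if any(len(v) == 0 for v in by_trial.values()) or not by_trial:
        raise ValueError("every trial needs at least one steer")
    rng = np.random.default_rng(seed)
    test = [str(rng.choice(sorted(by_trial[t]))) for t in sorted(by_trial)]
    dev = [sid for sid, _ in steers if sid not in set(test)]
    return test, dev


def make_splits(
    development: list[str],
    n_folds: int = 5,
    n_repetitions: int = 5,
    seed: int = 0,
) -> list[FoldSplit]:
    """Grouped CV splits: per repetition every steer validates exactly once."""
    n = len(development)
    if n % n_folds != 0:
        raise ValueError(f"{n} steers are not divisible into {n_folds} folds")
    per_fold = n // n_folds
    splits: list[FoldSplit] = []
    for rep in range(n_repetitions):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), rep)))
        order = rng.permutation(sorted(development))
        for fold in range(n_folds):
            val = tuple(order[fold * per_fold : (fold + 1) * per_fold])
            train = tuple(s for s in order if s not in val)
            split_seed = int(
                np.random.SeedSequence(entropy=(int(seed), rep, fold)).generate_state(1)[0]
                % (2**31)
            )
            splits.append(
                FoldSplit(
                    repetition=rep + 1,
                    fold=fold + 1,
                    train_steers=train,
                    val_steers=val,
                    seed=split_seed,
                )
            )
    return splits


def balance_training(table: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Down-sample every steer to the minimum per-steer block count.

    Surviving blocks are chosen uniformly without replacement and re-sorted
    so each steer's time order is unchanged.
    """
    if len(table) == 0:
        raise ValueError("every training steer needs at least one block")
    counts = table.groupby("steer_id").size()
    m = int(counts.min())
    rng = np.random.default_rng(seed)
    parts = []
    for sid, grp in table.groupby("steer_id", sort=True):
        idx = np.sort(rng.choice(len(grp), size=m, replace=False))
        parts.append(grp.iloc[idx])
    return pd.concat(parts, axis=0)


# ---------------------------------------------------------------------------
# standardisation


@dataclass
class FeatureScaler:
    mean: np.ndarray
    sd: np.ndarray
    constant: np.ndarray  # boolean mask of zero-variance features


def fit_scaler(X: np.ndarray) -> FeatureScaler:
    X = np.asarray(X, dtype=float)
    if len(X) == 0:
        raise ValueError("cannot fit a scaler on an empty training set")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    constant = sd == 0.0
    if constant.any():
        logger.warning("%d constant feature(s) flagged by the scaler", constant.sum())
    return FeatureScaler(mean=mean, sd=np.where(constant, 1.0, sd), constant=constant)


def apply_scaler(scaler: FeatureScaler, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    Z = (X - scaler.mean) / scaler.sd
    Z[:, scaler.constant] = 0.0
    return Z


# ---------------------------------------------------------------------------
# metrics


def confusion_matrix(y_true, y_pred, n_classes: int = 3) -> np.ndarray:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def balanced_accuracy(cm: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-class 0.5*(TP/P + TN/N) and the macro mean over present classes."""
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    per_class = np.full(len(cm), np.nan)
    for c in range(len(cm)):
        P = cm[c].sum()
        N = total - P
        if P == 0:
            logger.warning("class %d absent from actuals; excluded from macro", c)
            continue
        TP = cm[c, c]
        TN = total - P - cm[:, c].sum() + TP
        per_class[c] = 0.5 * (TP / P + (TN / N if N > 0 else 1.0))
    macro = float(np.nanmean(per_class))
    return per_class, macro


@dataclass
class MetricsReport:
    confusion: np.ndarray
    per_class_balanced_accuracy: np.ndarray
    per_class_precision: np.ndarray
    per_class_recall: np.ndarray
    macro_balanced_accuracy: float
    weighted_balanced_accuracy: float
    weighted_precision: float
    weighted_recall: float
    support: np.ndarray
    ci: tuple[float, float] | None = None

    def to_jsonable(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "per_class_balanced_accuracy": self.per_class_balanced_accuracy.tolist(),
            "per_class_precision": self.per_class_precision.tolist(),
            "per_class_recall": self.per_class_recall.tolist(),
            "macro_balanced_accuracy": self.macro_balanced_accuracy,
            "weighted_balanced_accuracy": self.weighted_balanced_accuracy,
            "weighted_precision": self.weighted_precision,
            "weighted_recall": self.weighted_recall,
            "support": self.support.tolist(),
            "ci": list(self.ci) if self.ci is not None else None,
            "labels": list(LABELS),
        }


def metrics_report(y_true, y_pred, n_classes: int = 3) -> MetricsReport:
    """Confusion matrix, per-class precision/recall/balanced accuracy, and
    macro / support-weighted aggregates."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if len(y_true) == 0 or len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    cm = confusion_matrix(y_true, y_pred, n_classes)
    per_ba, macro_ba = balanced_accuracy(cm)
    support = cm.sum(axis=1).astype(float)
    pred_tot = cm.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred_tot > 0, np.diag(cm) / pred_tot, 0.0)
        recall = np.where(support > 0, np.diag(cm) / support, np.nan)
    w = support / support.sum()
    present = support > 0
    weighted_ba = float(np.sum(w[present] * per_ba[present]) / w[present].sum())
    weighted_precision = float(np.sum(w[present] * precision[present]) / w[present].sum())
    weighted_recall = float(np.sum(w[present] * recall[present]) / w[present].sum())
    return MetricsReport(
        confusion=cm,
        per_class_balanced_accuracy=per_ba,
        per_class_precision=precision,
        per_class_recall=recall,
        macro_balanced_accuracy=macro_ba,
        weighted_balanced_accuracy=weighted_ba,
        weighted_precision=weighted_precision,
        weighted_recall=weighted_recall,
        support=support,
    )


def bootstrap_ci(
    values, level: float = 0.95, B: int = 10000, seed: int = 0
) -> tuple[float, float]:
    """Percentile bootstrap interval of the mean of ``values``."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < 2:
        raise ValueError("need at least two values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(B, len(values)))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# prepared fold data and subset evaluation


@dataclass
class PreparedSplit:
    """Balanced, standardised train/validation matrices for one fold."""

    split: FoldSplit
    X_train: np.ndarray
    y_train: np.ndarray
    groups_train: np.ndarray
    X_val: np.ndarray
    y_val: np.ndarray
    groups_val: np.ndarray


def prepare_split(
    table: pd.DataFrame, split: FoldSplit, features: list[str] | None = None
) -> PreparedSplit:
    features = features or feature_columns(table)
    train = table[table["steer_id"].isin(split.train_steers)]
    val = table[table["steer_id"].isin(split.val_steers)]
    overlap = set(split.train_steers) & set(split.val_steers)
    if overlap:
        raise ValueError(f"steers in both train and validation: {sorted(overlap)}")
    train = balance_training(train, seed=split.seed)
    scaler = fit_scaler(train[features].to_numpy())
    return PreparedSplit(
        split=split,
        X_train=apply_scaler(scaler, train[features].to_numpy()),
        y_train=np.asarray(encode_labels(train["label"])),
        groups_train=train["steer_id"].to_numpy(),
        X_val=apply_scaler(scaler, val[features].to_numpy()),
        y_val=np.asarray(encode_labels(val["label"])),
        groups_val=val["steer_id"].to_numpy(),
    )


def prepare_splits(
    table: pd.DataFrame, splits: list[FoldSplit], features: list[str] | None = None
) -> list[PreparedSplit]:
    return [prepare_split(table, s, features) for s in splits]


def evaluate_subset(
    prepared: PreparedSplit, columns: np.ndarray, model_factory
) -> float:
    """Fit on the training fold restricted to ``columns``; return macro
    balanced accuracy on the validation fold."""
    model = model_factory()
    model.fit(
        prepared.X_train[:, columns], prepared.y_train, groups=prepared.groups_train
    )
    y_pred = model.predict(prepared.X_val[:, columns], groups=prepared.groups_val)
    cm = confusion_matrix(prepared.y_val, y_pred)
    return balanced_accuracy(cm)[1]


def score_subset_over_splits(
    prepared_splits: list[PreparedSplit],
    columns: np.ndarray,
    model_factory,
) -> np.ndarray:
    """One macro balanced accuracy per fold/repetition; NaN on model failure."""
    scores = np.full(len(prepared_splits), np.nan)
    for i, ps in enumerate(prepared_splits):
        try:
            scores[i] = evaluate_subset(ps, columns, model_factory)
        except Exception as exc:  # non-convergence etc.: score dropped
            logger.warning(
                "model failed on rep %d fold %d: %s", ps.split.repetition, ps.split.fold, exc
            )
    return scores


# ---------------------------------------------------------------------------
# grid search and knee selection


def make_model_factory(model: str, pls_components: int = 2, seed: int = 0):
    """Factories for the three classifiers with study-default hyperparameters."""
    from .models import HMMClassifier, LDAClassifier, PLSDAClassifier

    model = model.upper()
    if model == "LDA":
        return lambda: LDAClassifier()
    if model == "PLSDA":
        return lambda: PLSDAClassifier(n_components=pls_components)
    if model == "HMM":
        return lambda: HMMClassifier(seed=seed)
    raise ValueError(f"unknown model {model!r}")


def run_grid(
    table: pd.DataFrame,
    methods,
    schedule: list[int],
    pls_components: list[int],
    splits: list[FoldSplit],
    k_mi: int = 3,
    seed: int = 0,
    bootstrap_B: int = 10000,
):
    """Evaluate every (selection, model, feature count[, components]) cell.

    ``methods`` is an iterable of (selection, model) pairs with selection in
    {"MI", "BFE"} and model in {"HMM", "LDA", "PLSDA"}. Returns
    (results DataFrame, selection traces dict). Every feasible cell carries
    the 25 per-run accuracies, their mean and a bootstrap CI; PLS-DA cells
    with more components than features are marked skipped.
    """
    from .selection import bfe_eliminate, rank_by_mi, reduce_by_mi

    features = feature_columns(table)
    name_to_col = {n: i for i, n in enumerate(features)}
    prepared = prepare_splits(table, splits, features)

    mi_trace = None
    rows = []
    traces: dict = {}
    for sel, model in methods:
        sel, model = sel.upper(), model.upper()
        comp_list = pls_components if model == "PLSDA" else [None]
        for comps in comp_list:
            factory = make_model_factory(model, pls_components=comps or 2, seed=seed)
            if sel == "MI":
                if mi_trace is None:
                    ranking = rank_by_mi(table, splits, k=k_mi, features=features)
                    mi_trace = reduce_by_mi(ranking, schedule)
                trace = mi_trace
            else:
                trace = bfe_eliminate(
                    table,
                    factory,
                    splits,
                    schedule,
                    features=features,
                    prepared=prepared,
                )
            traces[(sel, model) if comps is None else (sel, model, comps)] = trace
            for step in trace.steps:
                count = len(step.features)
                if comps is not None and comps > count:
                    rows.append(
                        {
                            "selection": sel,
                            "model": model,
                            "n_components": comps,
                            "n_features": count,
                            "mean_balanced_accuracy": np.nan,
                            "ci_lo": np.nan,
                            "ci_hi": np.nan,
                            "accuracies": None,
                            "skipped": True,
                        }
                    )
                    continue
                cols = np.array([name_to_col[f] for f in step.features])
                if step.scores is not None and sel == "BFE":
                    accs = np.asarray(step.scores, dtype=float)
                else:
                    accs = score_subset_over_splits(prepared, cols, factory)
                finite = accs[np.isfinite(accs)]
                if len(finite) < 2:
                    rows.append(
                        {
                            "selection": sel,
                            "model": model,
                            "n_components": comps,
                            "n_features": count,
                            "mean_balanced_accuracy": np.nan,
                            "ci_lo": np.nan,
                            "ci_hi": np.nan,
                            "accuracies": accs.tolist(),
                            "skipped": True,
                        }
                    )
                    continue
                lo, hi = bootstrap_ci(finite, B=bootstrap_B, seed=seed)
                rows.append(
                    {
                        "selection": sel,
                        "model": model,
                        "n_components": comps,
                        "n_features": count,
                        "mean_balanced_accuracy": float(finite.mean()),
                        "ci_lo": lo,
                        "ci_hi": hi,
                        "accuracies": accs.tolist(),
                        "skipped": False,
                    }
                )
    return pd.DataFrame(rows), traces


def knee_select(
    curve: dict[int, float], delta: float = 0.01, override: int | None = None
) -> int:
    """Smallest feature count whose mean accuracy is within ``delta`` of the
    maximum (the knee); a manual override wins when given."""
    if override is not None:
        return override
    if not curve:
        raise ValueError("empty curve")
    best = max(curve.values())
    eligible = [c for c, v in curve.items() if v >= best - delta]
    return min(eligible)
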