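"""One-shot experiment reproducer: simulate -> segment -> featurise ->
select -> train -> evaluate, with every artefact seeded and manifest-stamped.

This is the library behind the ``steersense run-all`` command and the
programmatic entry point for reproducing the full pipeline on synthetic
herds. All numeric outputs are reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluation import (
    bootstrap_ci,
    hold_out_test,
    knee_select,
    make_model_factory,
    make_splits,
    metrics_report,
    prepare_splits,
    run_grid,
    apply_scaler,
    fit_scaler,
)
from .features import build_feature_table, default_catalogue, feature_columns
from .preprocess import segment_dataset
from .selection import default_schedule
from .states import encode_labels
from .synthdata import SimConfig, generate_dataset, write_dataset
from .evaluation import balance_training

logger = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    """Declarative description of one full experiment."""

    sim: SimConfig = field(default_factory=SimConfig)
    block_seconds: float = 90.0
    schedule: list[int] | None = None  # None -> default 42..1 schedule
    selection_methods: tuple[str, ...] = ("MI", "BFE")
    models: tuple[str, ...] = ("LDA",)
    pls_components: tuple[int, ...] = (2,)
    knee_delta: float = 0.01
    knee_override: int | None = None
    mi_k: int = 3
    bootstrap_B: int = 10000
    seed: int = 0

    def validate(self) -> None:
        self.sim.validate()
        for m in self.models:
            if m.upper() not in {"HMM", "LDA", "PLSDA"}:
                raise ValueError(f"unknown model {m!r}")
        for s in self.selection_methods:
            if s.upper() not in {"MI", "BFE"}:
                raise ValueError(f"unknown selection method {s!r}")
        if self.block_seconds <= 0:
            raise ValueError("block_seconds must be positive")

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_jsonable()
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_jsonable(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            d["sim"] = SimConfig.from_dict(d["sim"])
        for key in ("selection_methods", "models", "pls_components"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_jsonable(), fh, sort_keys=True)


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    feature_table: pd.DataFrame
    grid: pd.DataFrame
    traces: dict
    test_steers: list[str]
    dev_steers: list[str]
    knee_count: int
    knee_features: tuple[str, ...]
    validation_mean_at_knee: float
    validation_ci_at_knee: tuple[float, float]
    test_report: "object"


def _seed_for(base: int, tag: int) -> int:
    return int(
        np.random.SeedSequence(entropy=(int(base), tag)).generate_state(1)[0] % (2**31)
    )


def build_synthetic_feature_table(config: ExperimentConfig) -> pd.DataFrame:
    """Simulate the herd and return the block-level feature table."""
    traces, labels = generate_dataset(config.sim)
    blocks = segment_dataset(traces, labels, block_seconds=config.block_seconds)
    return build_feature_table(blocks, default_catalogue(fs=config.sim.sampling_rate))


def run_experiment(
    config: ExperimentConfig,
    outdir: str | Path | None = None,
    feature_table: pd.DataFrame | None = None,
    write_raw_dataset: bool = False,
) -> ExperimentResult:
    """Execute the full pipeline; optionally write artefacts to ``outdir``.

    The primary arm (the one used for knee selection and the final test-set
    evaluation) is BFE with the first configured model if BFE is enabled,
    otherwise MI with the first model.
    """
    config.validate()
    outpath = Path(outdir) if outdir is not None else None
    if outpath is not None:
        outpath.mkdir(parents=True, exist_ok=True)

    if write_raw_dataset and outpath is not None:
        traces, labels = generate_dataset(config.sim)
        write_dataset(traces, labels, outpath / "dataset", config=config.sim)

    if feature_table is None:
        feature_table = build_synthetic_feature_table(config)
    features = feature_columns(feature_table)
    schedule = config.schedule or default_schedule(len(features))

    test_steers, dev_steers = hold_out_test(
        sorted(
            {(s, t) for s, t in zip(feature_table["steer_id"], feature_table["trial_id"])}
        ),
        seed=_seed_for(config.seed, 1),
    )
    dev_table = feature_table[feature_table["steer_id"].isin(dev_steers)].reset_index(
        drop=True
    )
    splits = make_splits(dev_steers, seed=_seed_for(config.seed, 2))

    methods = [
        (sel, model) for sel in config.selection_methods for model in config.models
    ]
    grid, traces = run_grid(
        dev_table,
        methods,
        schedule,
        list(config.pls_components),
        splits,
        k_mi=config.mi_k,
        seed=_seed_for(config.seed, 3),
        bootstrap_B=config.bootstrap_B,
    )

    # primary arm for deployment-style selection
    primary_sel = "BFE" if "BFE" in {s.upper() for s in config.selection_methods} else "MI"
    primary_model = config.models[0].upper()
    arm = grid[
        (grid["selection"] == primary_sel)
        & (grid["model"] == primary_model)
        & (~grid["skipped"])
    ]
    curve = dict(zip(arm["n_features"], arm["mean_balanced_accuracy"]))
    knee = knee_select(curve, delta=config.knee_delta, override=config.knee_override)
    trace_key = (
        (primary_sel, primary_model)
        if primary_model != "PLSDA"
        else (primary_sel, primary_model, config.pls_components[0])
    )
    knee_features = traces[trace_key].subset(knee)
    knee_row = arm[arm["n_features"] == knee].iloc[0]

    # final model: fit on all development steers, evaluate on the test steers
    factory = make_model_factory(
        primary_model,
        pls_components=config.pls_components[0],
        seed=_seed_for(config.seed, 4),
    )
    test_report, bundle = fit_and_evaluate_final(
        feature_table,
        dev_steers,
        test_steers,
        list(knee_features),
        factory,
        seed=_seed_for(config.seed, 5),
    )

    result = ExperimentResult(
        config=config,
        feature_table=feature_table,
        grid=grid,
        traces=traces,
        test_steers=list(test_steers),
        dev_steers=list(dev_steers),
        knee_count=int(knee),
        knee_features=tuple(knee_features),
        validation_mean_at_knee=float(knee_row["mean_balanced_accuracy"]),
        validation_ci_at_knee=(float(knee_row["ci_lo"]), float(knee_row["ci_hi"])),
        test_report=test_report,
    )
    if outpath is not None:
        _write_artefacts(result, bundle, outpath)
    return result


def fit_and_evaluate_final(
    feature_table: pd.DataFrame,
    dev_steers: list[str],
    test_steers: list[str],
    features: list[str],
    model_factory,
    seed: int,
):
    """Balance + standardise on the development herd, fit, score test steers."""
    dev = feature_table[feature_table["steer_id"].isin(dev_steers)]
    test = feature_table[feature_table["steer_id"].isin(test_steers)]
    dev_bal = balance_training(dev, seed=seed)
    scaler = fit_scaler(dev_bal[features].to_numpy())
    model = model_factory()
    model.fit(
        apply_scaler(scaler, dev_bal[features].to_numpy()),
        np.asarray(encode_labels(dev_bal["label"])),
        groups=dev_bal["steer_id"].to_numpy(),
    )
    y_pred = model.predict(
        apply_scaler(scaler, test[features].to_numpy()),
        groups=test["steer_id"].to_numpy(),
    )
    report = metrics_report(np.asarray(encode_labels(test["label"])), y_pred)
    bundle = {
        "selected_features": list(features),
        "scaler_mean": scaler.mean.tolist(),
        "scaler_sd": scaler.sd.tolist(),
        "seed": int(seed),
        "model": type(model).__name__,
        "model_params": _model_params_jsonable(model),
        "catalogue_version": "1.0",
    }
    return report, bundle


def _model_params_jsonable(model) -> dict:
    from .models import HMMClassifier, LDAClassifier, PLSDAClassifier

    if isinstance(model, LDAClassifier) and model.model_ is not None:
        m = model.model_
        return {
            "classes": m.classes.tolist(),
            "means": m.means.tolist(),
            "covariance": m.covariance.tolist(),
            "priors": m.priors.tolist(),
            "coef": m.coef.tolist(),
            "intercept": m.intercept.tolist(),
        }
    if isinstance(model, PLSDAClassifier) and model.model_ is not None:
        m = model.model_
        return {
            "n_components": m.n_components,
            "x_mean": m.x_mean.tolist(),
            "y_mean": m.y_mean.tolist(),
            "x_weights": m.x_weights.tolist(),
            "x_loadings": m.x_loadings.tolist(),
            "y_loadings": m.y_loadings.tolist(),
            "coef": m.coef.tolist(),
            "kept_columns": m.kept_columns.tolist(),
        }
    if isinstance(model, HMMClassifier) and model.params_ is not None:
        p = model.params_
        return {
            "startprob": p.startprob.tolist(),
            "transmat": p.transmat.tolist(),
            "state_to_class": p.state_to_class.tolist(),
            "emissions": [
                {
                    "weights": e.weights.tolist(),
                    "means": e.means.tolist(),
                    "covariances": e.covariances.tolist(),
                }
                for e in p.emissions
            ],
        }
    return {}


def _write_artefacts(result: ExperimentResult, bundle: dict, outpath: Path) -> None:
    cfg_hash = result.config.config_hash()
    stamp = {"config_hash": cfg_hash, "seed": int(result.config.seed)}

    result.feature_table.to_csv(outpath / "features.csv", index=False)
    grid = result.grid.copy()
    grid["accuracies"] = grid["accuracies"].apply(
        lambda a: json.dumps(a) if a is not None else ""
    )
    grid.to_csv(outpath / "grid.csv", index=False)
    # curve CSVs per (selection, model[, components])
    for key, trace in result.traces.items():
        name = "_".join(str(k) for k in key).lower()
        trace.save(outpath / f"trace_{name}.json")
        trace.survival_frame().to_csv(outpath / f"survival_{name}.csv", index=False)
    curves = result.grid[~result.grid["skipped"]][
        ["selection", "model", "n_components", "n_features",
         "mean_balanced_accuracy", "ci_lo", "ci_hi"]
    ]
    curves.to_csv(outpath / "curves.csv", index=False)

    metrics = {
        **stamp,
        "test_steers": result.test_steers,
        "dev_steers": result.dev_steers,
        "knee_feature_count": result.knee_count,
        "knee_features": list(result.knee_features),
        "validation_mean_balanced_accuracy_at_knee": result.validation_mean_at_knee,
        "validation_ci_at_knee": list(result.validation_ci_at_knee),
        "test": result.test_report.to_jsonable(),
    }
    with open(outpath / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2)
    with open(outpath / "model_bundle.json", "w") as fh:
        json.dump({**stamp, **bundle}, fh, indent=2)
    with open(outpath / "manifest.json", "w") as fh:
        json.dump({**stamp, "config": result.config.to_jsonable()}, fh, indent=2)
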