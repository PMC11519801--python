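"""End-to-end orchestration: generate/load -> normalize -> split -> train ->
evaluate -> interpret, plus the time-course experiment and the CNN/DNN/MLP
comparison. Every intermediate is persisted in the documented plain-text
formats so each reported number can be recomputed from disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .dataset import SpectraDataset
from .errors import ConfigError, DesignError
from .interpret import (
    CARB_BAND,
    DEFAULT_HALF_WINDOW,
    TRP_BAND,
    ContributionReport,
    RatioReport,
    peak_contribution,
    probability_heatmap,
    ratio_statistic,
)
from .io import read_spectra, write_json, write_spectra
from .model import (
    EvaluationReport,
    ModelConfig,
    TrainConfig,
    TrainingResult,
    build_model,
    evaluate,
    save_model,
    train,
)
from .preprocess import SplitSpec, average_per_cell, minmax_normalize, split_dataset
from .synth import (
    SyntheticConfig,
    TimecourseConfig,
    generate_dataset,
    generate_timecourse,
    synthetic_config_from_dict,
    timecourse_config_from_dict,
)

__all__ = [
    "RunConfig",
    "RunReport",
    "run_experiment",
    "run_timecourse",
    "compare_algorithms",
    "run_config_from_dict",
]

logger = logging.getLogger(__name__)


def _stage(name: str, rows_in: int, rows_out: int) -> None:
    logger.info("stage=%s rows_in=%d rows_out=%d", name, rows_in, rows_out)


@dataclass(frozen=True)
class RunConfig:
    """Full description of one experiment run.

    Exactly one data source must be set: a synthetic generator config or an
    input spectra file. ``seed`` drives every stochastic stage; nested stage
    seeds are derived from it (data = seed, split = seed + 1,
    model init/train = seed + 2) so one integer reproduces the whole run.
    """

    synthetic: SyntheticConfig | None = field(default_factory=SyntheticConfig)
    input_path: str | None = None
    input_format: str = "wide_csv"
    per_cell: bool = False
    arch: str = "cnn"
    split: SplitSpec = field(default_factory=SplitSpec)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    half_window: float = DEFAULT_HALF_WINDOW
    ratio_bands: tuple[float, float] = (TRP_BAND, CARB_BAND)
    contribution_method: str = "occlusion"
    outdir: str | None = None
    save_spectra: bool = True
    seed: int = 0

    def validate(self) -> "RunConfig":
        if (self.synthetic is None) == (self.input_path is None):
            raise ConfigError("exactly one data source (synthetic | input_path) required")
        if self.synthetic is not None:
            self.synthetic.validate()
        self.split.validate()
        self.model.validate()
        self.train.validate()
        return self

    def config_hash(self) -> str:
        blob = json.dumps(_jsonable(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonable(obj: Any) -> Any:
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(getattr(obj, k)) for k in obj.__dataclass_fields__}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


@dataclass
class RunReport:
    """All run outputs plus provenance (config hash, seed, version)."""

    config: RunConfig
    dataset_summary: dict[str, Any]
    training: TrainingResult | None
    evaluations: dict[str, EvaluationReport]
    contribution: ContributionReport | None
    ratio: RatioReport | None
    timepoint_evaluations: dict[float, dict[str, EvaluationReport]] | None = None
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {
            "dataset_summary": self.dataset_summary,
            "provenance": self.provenance,
            "config": _jsonable(self.config),
        }
        if self.training is not None:
            out["training"] = self.training.to_dict()
        out["evaluations"] = {k: v.to_dict() for k, v in self.evaluations.items()}
        if self.contribution is not None:
            out["contribution"] = {
                "method": self.contribution.method,
                "centers": list(self.contribution.centers),
                "contribution_pct": self.contribution.contributions.tolist(),
            }
        if self.ratio is not None:
            out["ratio"] = self.ratio.to_dict()
        if self.timepoint_evaluations is not None:
            out["timepoints"] = {
                str(t): {k: v.to_dict() for k, v in evs.items()}
                for t, evs in self.timepoint_evaluations.items()
            }
        return out


# ---------------------------------------------------------------------------
# stage helpers


def _load_data(config: RunConfig) -> SpectraDataset:
    if config.synthetic is not None:
        synth = replace(config.synthetic, seed=config.seed)
        ds = generate_dataset(synth)
    else:
        ds = read_spectra(config.input_path, config.input_format)
    _stage("load", 0, ds.n_spectra)
    return ds


def _summary(ds: SpectraDataset) -> dict[str, Any]:
    labels, counts = np.unique(ds.labels, return_counts=True)
    cells = pd.Series(ds.cell_ids).dropna()
    return {
        "n_spectra": ds.n_spectra,
        "n_points": ds.n_points,
        "n_cells": int(cells.nunique()),
        "label_counts": {str(l): int(c) for l, c in zip(labels, counts)},
        "axis_range": [float(ds.wavenumbers[0]), float(ds.wavenumbers[-1])],
    }


def _persist_split_manifest(
    outdir: Path, subsets: dict[str, SpectraDataset], unit: str
) -> None:
    rows = []
    for name, ds in subsets.items():
        for sid, cid in zip(ds.spectrum_ids, ds.cell_ids):
            rows.append({"subset": name, "spectrum_id": sid, "cell_id": cid, "unit": unit})
    pd.DataFrame(rows).to_csv(outdir / "split_manifest.csv", index=False)


def _train_and_evaluate(
    data: SpectraDataset,
    config: RunConfig,
    arch: str | None = None,
) -> tuple[TrainingResult, dict[str, EvaluationReport], dict[str, SpectraDataset]]:
    split = replace(config.split, seed=config.seed + 1)
    train_set, val_set, test_set = split_dataset(data, split)
    subsets = {"train": train_set, "validation": val_set, "test": test_set}
    _stage("split", data.n_spectra, sum(s.n_spectra for s in subsets.values()))
    arch = arch or config.arch
    net, _ = build_model(arch, config.model, data.n_points, seed=config.seed + 2)
    tconf = replace(config.train, seed=config.seed + 2)
    result = train(net, train_set, val_set, tconf)
    _stage("train", train_set.n_spectra, result.epochs_run)
    evaluations = {
        name: evaluate(net, ds, threshold=tconf.decision_threshold)
        for name, ds in subsets.items()
    }
    _stage("evaluate", test_set.n_spectra, len(evaluations))
    return result, evaluations, subsets


# ---------------------------------------------------------------------------
# top-level experiments


def run_experiment(config: RunConfig) -> RunReport:
    """Execute the full pipeline once and persist all artifacts.

    Stages: load/generate, max-min normalize, optional per-cell averaging,
    seeded split, training, evaluation of all three subsets, band
    contributions on the test set, and the per-cell 1623/1025 ratio test on
    the whole (per-cell averaged) dataset.
    """
    config.validate()
    raw = _load_data(config)
    data = minmax_normalize(raw)
    _stage("normalize", raw.n_spectra, data.n_spectra)
    percell = average_per_cell(data) if raw.meta["cell_id"].notna().all() else None
    if config.per_cell:
        if percell is None:
            raise DesignError("per_cell=True requires cell_id metadata on every spectrum")
        data = percell
        _stage("average_per_cell", raw.n_spectra, data.n_spectra)

    result, evaluations, subsets = _train_and_evaluate(data, config)

    contribution = peak_contribution(
        result.model,
        subsets["test"],
        method=config.contribution_method,
        half_window=config.half_window,
    )
    ratio = None
    if percell is not None:
        try:
            ratio = ratio_statistic(
                percell,
                numerator=config.ratio_bands[0],
                denominator=config.ratio_bands[1],
                half_window=config.half_window,
            )
        except (DesignError, ValueError) as exc:  # e.g. single-class data
            logger.warning("ratio statistic skipped: %s", exc)

    report = RunReport(
        config=config,
        dataset_summary=_summary(data),
        training=result,
        evaluations=evaluations,
        contribution=contribution,
        ratio=ratio,
        provenance={
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "package_version": __version__,
        },
    )
    if config.outdir is not None:
        _persist_run(report, subsets, data, config)
    return report


def _persist_run(
    report: RunReport,
    subsets: dict[str, SpectraDataset],
    data: SpectraDataset,
    config: RunConfig,
) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.save_spectra:
        write_spectra(data, outdir / "spectra_normalized.csv", "wide_csv")
    _persist_split_manifest(outdir, subsets, config.split.unit)
    if report.training is not None:
        pd.DataFrame(report.training.to_dict() | {}).drop(
            columns=["epochs_run"], errors="ignore"
        ).assign(epoch=lambda d: np.arange(1, len(d) + 1)).to_csv(
            outdir / "curves.csv", index=False
        )
        save_model(report.training.model, config.model, outdir / "model.npz")
    for name, ev in report.evaluations.items():
        write_json(ev.to_dict(), outdir / f"metrics_{name}.json")
        probability_heatmap(ev).to_csv(outdir / f"heatmap_{name}.csv", index=False)
    if report.contribution is not None:
        report.contribution.to_frame().to_csv(outdir / "contributions.csv", index=False)
    if report.ratio is not None:
        write_json(report.ratio.to_dict(), outdir / "ratio_test.json")
        rows = [
            {"cell_id": cid, "label": lab, "ratio": val}
            for lab in report.ratio.ratios
            for cid, val in zip(report.ratio.cell_ids[lab], report.ratio.ratios[lab])
        ]
        pd.DataFrame(rows).to_csv(outdir / "ratio_per_cell.csv", index=False)
    write_json(report.to_dict(), outdir / "run_report.json")
    logger.info("run artifacts written to %s", outdir)


def run_timecourse(
    config: RunConfig,
    timecourse: TimecourseConfig | None = None,
    mode: str = "per_timepoint",
) -> RunReport:
    """Train and evaluate at each time point of a maturation time-course.

    ``per_timepoint`` (default) trains a fresh model on each time point's
    70/20/10 split; ``shared`` trains one model on the pooled training
    splits of all time points and evaluates it on each time point's test
    split. Each time point must contain both arms.
    """
    config.validate()
    if mode not in ("per_timepoint", "shared"):
        raise ConfigError(f"unknown time-course mode {mode!r}")
    if config.synthetic is None:
        raise ConfigError("run_timecourse currently requires a synthetic data source")
    tc = timecourse or TimecourseConfig(base=config.synthetic)
    tc = replace(tc, base=replace(tc.base, seed=config.seed))
    tc.validate()
    datasets = generate_timecourse(tc)

    per_tp: dict[float, dict[str, EvaluationReport]] = {}
    splits: dict[float, tuple[SpectraDataset, SpectraDataset, SpectraDataset]] = {}
    for t, ds in datasets.items():
        labels = set(ds.labels)
        if not {"mature", "immature"} <= labels:
            raise DesignError(f"time point {t} h lacks a treated or control arm")
        norm = minmax_normalize(ds)
        split = replace(config.split, seed=config.seed + 1)
        splits[t] = split_dataset(norm, split)

    if mode == "per_timepoint":
        for i, (t, (tr, va, te)) in enumerate(splits.items()):
            net, _ = build_model(config.arch, config.model, tr.n_points,
                                 seed=config.seed + 2 + i)
            tconf = replace(config.train, seed=config.seed + 2 + i)
            train(net, tr, va, tconf)
            per_tp[t] = {
                "test": evaluate(net, te, tconf.decision_threshold),
                "validation": evaluate(net, va, tconf.decision_threshold),
            }
    else:
        pool_tr = _concat([s[0] for s in splits.values()])
        pool_va = _concat([s[1] for s in splits.values()])
        net, _ = build_model(config.arch, config.model, pool_tr.n_points,
                             seed=config.seed + 2)
        tconf = replace(config.train, seed=config.seed + 2)
        train(net, pool_tr, pool_va, tconf)
        for t, (_, va, te) in splits.items():
            per_tp[t] = {
                "test": evaluate(net, te, tconf.decision_threshold),
                "validation": evaluate(net, va, tconf.decision_threshold),
            }

    report = RunReport(
        config=config,
        dataset_summary={str(t): _summary(ds) for t, ds in datasets.items()},
        training=None,
        evaluations={},
        contribution=None,
        ratio=None,
        timepoint_evaluations=per_tp,
        provenance={
            "seed": config.seed,
            "mode": mode,
            "config_hash": config.config_hash(),
            "package_version": __version__,
        },
    )
    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_json(report.to_dict(), outdir / "timecourse_report.json")
    return report


def _concat(datasets: list[SpectraDataset]) -> SpectraDataset:
    return SpectraDataset(
        datasets[0].wavenumbers.copy(),
        np.vstack([d.intensities for d in datasets]),
        pd.concat([d.meta for d in datasets], ignore_index=True),
    )


def run_config_from_dict(d: dict) -> RunConfig:
    """Build a :class:`RunConfig` from a plain mapping (YAML/JSON).

    Nested sections: ``synthetic``, ``split``, ``model``, ``train``; scalar
    fields pass through. Setting ``input_path`` clears the synthetic source.
    Unknown keys are rejected rather than silently ignored.
    """
    allowed = {"synthetic", "input_path", "input_format", "split", "model",
               "train", "timecourse", "per_cell", "arch", "half_window",
               "ratio_bands", "contribution_method", "outdir", "save_spectra",
               "seed"}
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown run-config keys: {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    if d.get("input_path") is not None:
        kwargs["synthetic"] = None
        kwargs["input_path"] = d["input_path"]
        kwargs["input_format"] = d.get("input_format", "wide_csv")
    elif "synthetic" in d:
        kwargs["synthetic"] = synthetic_config_from_dict(d["synthetic"] or {})
    if "split" in d:
        s = dict(d["split"])
        if "fractions" in s:
            s["fractions"] = tuple(s["fractions"])
        kwargs["split"] = SplitSpec(**s)
    if "model" in d:
        m = dict(d["model"])
        for key in ("mlp_hidden", "dnn_hidden"):
            if key in m:
                m[key] = tuple(m[key])
        kwargs["model"] = ModelConfig(**m)
    if "train" in d:
        kwargs["train"] = TrainConfig(**d["train"])
    for key in ("per_cell", "arch", "half_window", "contribution_method",
                "outdir", "save_spectra", "seed"):
        if key in d:
            kwargs[key] = d[key]
    if "ratio_bands" in d:
        kwargs["ratio_bands"] = tuple(d["ratio_bands"])
    return RunConfig(**kwargs).validate()


def timecourse_from_run_dict(d: dict) -> TimecourseConfig | None:
    if "timecourse" not in d:
        return None
    return timecourse_config_from_dict(d["timecourse"])


def compare_algorithms(
    config: RunConfig,
    archs: tuple[str, ...] = ("cnn", "dnn", "mlp"),
) -> pd.DataFrame:
    """Train each architecture on identical data and split; tabulate metrics.

    Deterministic for a fixed config seed: the table of accuracy,
    sensitivity, specificity and AUC per architecture is identical across
    repeated calls.
    """
    config.validate()
    raw = _load_data(config)
    data = minmax_normalize(raw)
    if config.per_cell:
        data = average_per_cell(data)
    rows = []
    for arch in archs:
        _, evaluations, _ = _train_and_evaluate(data, config, arch=arch)
        ev = evaluations["test"]
        rows.append(
            {
                "arch": arch,
                "accuracy": ev.accuracy,
                "sensitivity": ev.sensitivity,
                "specificity": ev.specificity,
                "auc": ev.auc,
                "n_test": ev.n,
                "seed": config.seed,
            }
        )
    table = pd.DataFrame(rows)
    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "algorithm_comparison.csv", index=False)
    return table
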