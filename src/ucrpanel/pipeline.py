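"""End-to-end pipeline: expression matrix -> volcano candidates -> ensemble
ranking -> rank-sum panel -> patient stratification & survival -> held-out
classification.

One :class:`PipelineConfig` drives the whole run; every stage's parameters
are validated before any computation starts, all randomness flows from
named seeds, and a manifest records parameter values, per-stage counts and
the files written.  A failed stage aborts with the stage name in the error.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import diffexpr as _diffexpr
from . import io as _io
from . import relevance as _relevance
from . import scoring as _scoring
from . import stratify as _stratify
from . import synthetic as _synthetic

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Validated configuration for a full run.

    Defaults encode the primary published setting: volcano p < 0.001 with a
    raw fold-change threshold of 3 (log2 1.58...), fivefold stratified CV
    over the four rankers, a 50% sum-score cutoff, four patient groups, and
    a 30% stratified held-out split.  The alternative published setting is
    FC 2 (log2 1), a 60% cutoff and three patient groups.
    """

    # input: paths to a matrix + annotation, or a synthetic study config
    matrix_path: str | None = None
    annotation_path: str | None = None
    matrix_format: str = "tsv"
    synthetic: _synthetic.SyntheticConfig | None = None

    # volcano stage
    p_threshold: float = 0.001
    fold_change: float = 3.0            # raw scale; converted to log2
    comparison_mode: str = "per_grade"  # or "pooled" (BlCa vs NBE)
    welch: bool = False

    # ensemble stage
    methods: tuple[str, ...] = _relevance.METHODS
    cv_folds: int = 5
    average_ranks: bool = False

    # panel stage
    cutoff_fraction: float = 0.5

    # stratification stage
    n_patient_groups: int = 4
    cluster_metric: str = "euclidean"
    cluster_linkage: str = "ward"

    # classifier stage
    test_fraction: float = 0.3

    outdir: str = "ucrpanel_out"
    seed: int = 0

    def validate(self) -> None:
        if self.synthetic is None and (self.matrix_path is None
                                       or self.annotation_path is None):
            raise ValueError("config needs either synthetic parameters or "
                             "matrix_path + annotation_path")
        if not 0 < self.p_threshold < 1:
            raise ValueError(f"p_threshold must be in (0,1), "
                             f"got {self.p_threshold}")
        if self.fold_change <= 0:
            raise ValueError("fold_change must be > 0")
        if self.comparison_mode not in ("per_grade", "pooled"):
            raise ValueError(f"unknown comparison_mode "
                             f"{self.comparison_mode!r}")
        unknown = set(self.methods) - set(_relevance.METHODS)
        if unknown or not self.methods:
            raise ValueError(f"methods must be a non-empty subset of "
                             f"{_relevance.METHODS}, got {self.methods}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0 <= self.cutoff_fraction <= 1:
            raise ValueError(f"cutoff_fraction must be in [0,1], "
                             f"got {self.cutoff_fraction}")
        if self.n_patient_groups < 1:
            raise ValueError("n_patient_groups must be >= 1")
        if not 0 < self.test_fraction < 1:
            raise ValueError(f"test_fraction must be in (0,1), "
                             f"got {self.test_fraction}")
        if self.synthetic is not None:
            self.synthetic.validate()

    @property
    def thresholds(self) -> _diffexpr.VolcanoThresholds:
        return _diffexpr.VolcanoThresholds(
            p_thr=self.p_threshold,
            lfc_thr=_diffexpr.fc_to_log2(self.fold_change))

    @property
    def comparisons(self) -> tuple[tuple[str, str], ...]:
        if self.comparison_mode == "pooled":
            return (("BlCa", "NBE"),)
        return _diffexpr.DEFAULT_COMPARISONS


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML pipeline config."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_mapping(raw)


def config_from_mapping(raw: Mapping[str, Any]) -> PipelineConfig:
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown pipeline config key(s): {sorted(unknown)}")
    kwargs = dict(raw)
    if kwargs.get("synthetic") is not None:
        kwargs["synthetic"] = _synthetic.config_from_mapping(
            kwargs["synthetic"])
    if "methods" in kwargs:
        kwargs["methods"] = tuple(kwargs["methods"])
    cfg = PipelineConfig(**kwargs)
    cfg.validate()
    return cfg


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name: str):
    def decorate(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"stage '{name}' failed: {exc}") from exc
        return wrapper
    return decorate


def _write_json(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest.

    Stage outputs are written under ``config.outdir``; the manifest (also
    written there as ``manifest.json``) lists parameters, per-stage counts
    and output files, and is byte-identical across runs with the same
    config and seeds.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict[str, Any] = {
        "parameters": _config_summary(config),
        "stages": {},
        "outputs": [],
    }

    def record(stage: str, counts: Mapping[str, Any],
               files: Sequence[str]) -> None:
        manifest["stages"][stage] = dict(counts)
        manifest["outputs"].extend(files)
        logger.info("stage %s: %s", stage, dict(counts))

    # ---- load / simulate -------------------------------------------------
    matrix, annotation, truth = _load_stage(config, outdir, record)

    # ---- volcano candidates ----------------------------------------------
    candidates, tables = _volcano_stage(config, matrix, annotation,
                                        outdir, record)
    if not candidates:
        logger.warning("no probe passed the volcano cutoffs; halting")
        manifest["halted_after"] = "volcano"
        _write_json(manifest, outdir / "manifest.json")
        return manifest

    # ---- ensemble importance ranking -------------------------------------
    importance_tables = _ensemble_stage(config, matrix, annotation,
                                        candidates, outdir, record)

    # ---- rank-sum aggregation & panel ------------------------------------
    panel, panel_meta = _panel_stage(config, importance_tables, outdir,
                                     record)
    if not panel:
        logger.warning("empty signature panel at cutoff %.2f; halting",
                       config.cutoff_fraction)
        manifest["halted_after"] = "panel"
        _write_json(manifest, outdir / "manifest.json")
        return manifest

    # ---- stratification & survival ---------------------------------------
    strat = _stratify_stage(config, matrix, annotation, panel, outdir,
                            record)

    # ---- held-out classification -----------------------------------------
    confusion = _classify_stage(config, matrix, annotation, panel, outdir,
                                record)

    manifest["panel"] = panel
    manifest["panel_meta"] = panel_meta
    if strat["logrank"] is not None:
        manifest["logrank"] = {"statistic": strat["logrank"].statistic,
                               "df": strat["logrank"].df,
                               "p_value": strat["logrank"].p_value}
    manifest["confusion"] = confusion.as_dict()
    _write_json(manifest, outdir / "manifest.json")
    manifest["outputs"].append("manifest.json")
    return manifest


@_stage("load")
def _load_stage(config, outdir, record):
    if config.synthetic is not None:
        matrix, annotation, truth = _synthetic.generate(config.synthetic)
        _io.write_matrix(matrix, outdir / "matrix.tsv")
        annotation.to_csv(outdir / "annotation.tsv", sep="\t")
        truth.to_json(outdir / "truth.json")
        files = ["matrix.tsv", "annotation.tsv", "truth.json"]
    else:
        matrix = _io.read_expression_matrix(config.matrix_path,
                                            config.matrix_format)
        _io.validate_expression_matrix(matrix)
        annotation = _io.read_annotation(config.annotation_path)
        truth = None
        files = []
    _io.lint_probe_names(matrix.index)
    record("load", {"n_probes": int(matrix.shape[0]),
                    "n_samples": int(matrix.shape[1])}, files)
    return matrix, annotation, truth


@_stage("volcano")
def _volcano_stage(config, matrix, annotation, outdir, record):
    candidates, tables = _diffexpr.select_candidates(
        matrix, annotation, config.thresholds, config.comparisons,
        config.welch)
    files = []
    for name, table in tables.items():
        fname = f"diff_{name}.tsv"
        _io.write_table(table, outdir / fname)
        files.append(fname)
    if candidates:
        cand = pd.DataFrame(index=pd.Index(candidates, name="feature_id"))
        cand["candidate"] = True
        _io.write_table(cand, outdir / "candidates.tsv")
        files.append("candidates.tsv")
    counts = {"n_candidates": len(candidates)}
    for name, table in tables.items():
        counts[f"hits_{name}"] = int((table["status"] != "ns").sum())
    record("volcano", counts, files)
    return candidates, tables


@_stage("rank")
def _ensemble_stage(config, matrix, annotation, candidates, outdir, record):
    X = matrix.loc[candidates].T  # samples x features
    y = annotation.reindex(X.index)["group"].isin(["LG", "HG"]).astype(int)
    cv = _relevance.CVConfig(k=config.cv_folds, seed=config.seed)
    tables = []
    files = []
    for method in config.methods:
        table = _relevance.cross_validated_importance(
            X, y, method, cv, average_ranks=config.average_ranks)
        fname = f"importance_{method}.tsv"
        _io.write_table(table, outdir / fname)
        files.append(fname)
        tables.append(table)
    record("rank", {"n_methods": len(tables),
                    "n_features": int(X.shape[1])}, files)
    return tables


@_stage("panel")
def _panel_stage(config, importance_tables, outdir, record):
    agg = _scoring.aggregate(importance_tables, config.cutoff_fraction)
    panel, meta = _scoring.select_panel(agg)
    _io.write_table(agg, outdir / "aggregate_scores.tsv")
    _write_json({"panel": panel, **meta}, outdir / "panel.json")
    record("panel", {"n_candidates": meta["n_candidates"],
                     "panel_size": meta["panel_size"]},
           ["aggregate_scores.tsv", "panel.json"])
    return panel, meta


@_stage("stratify")
def _stratify_stage(config, matrix, annotation, panel, outdir, record):
    strat = _stratify.stratify_patients(
        matrix, annotation, panel, config.n_patient_groups,
        config.cluster_metric, config.cluster_linkage)
    _write_json({str(s): int(g) for s, g in strat["groups"].items()},
                outdir / "groups.json")
    _io.write_table(strat["heatmap"], outdir / "heatmap.tsv")
    files = ["groups.json", "heatmap.tsv"]
    for g, curve in strat["km_curves"].items():
        fname = f"km_group_{g}.tsv"
        _io.write_table(curve, outdir / fname)
        files.append(fname)
    counts = {"n_groups": int(strat["groups"].nunique()),
              "n_samples": int(len(strat["groups"]))}
    if strat["logrank"] is not None:
        lr = strat["logrank"]
        _write_json({"statistic": lr.statistic, "df": lr.df,
                     "p_value": lr.p_value}, outdir / "logrank.json")
        files.append("logrank.json")
        counts["logrank_p"] = lr.p_value
    record("stratify", counts, files)
    return strat


@_stage("classify")
def _classify_stage(config, matrix, annotation, panel, outdir, record):
    labels = annotation["group"].isin(["LG", "HG"]).astype(int)
    labels = labels.reindex(matrix.columns.astype(str))
    split = _classify.stratified_split(matrix.columns, labels,
                                       config.test_fraction, config.seed)
    confusion = _classify.train_eval(matrix.loc[panel].T, labels, split,
                                     config.seed)
    _write_json(confusion.as_dict(), outdir / "confusion.json")
    record("classify", {"n_train": len(split[0]), "n_test": len(split[1]),
                        "accuracy": confusion.accuracy},
           ["confusion.json"])
    return confusion


def _config_summary(config: PipelineConfig) -> dict:
    out = dataclasses.asdict(config)
    if config.synthetic is not None:
        out["synthetic"] = dataclasses.asdict(config.synthetic)
        out["synthetic"]["survival_scale_by_group"] = list(
            config.synthetic.survival_scale_by_group)
    out["methods"] = list(config.methods)
    out["lfc_threshold"] = config.thresholds.lfc_thr
    return out
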