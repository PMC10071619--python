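"""End-to-end pipeline driver, demographics summary, result serialization.

``run_pipeline`` chains the stages — synthetic cohort (or a cohort read
from disk) -> functional connectivity -> classification (untuned and
tuned) -> MAD anomaly counting -> PageRank hub shifts -> demographics —
and writes every tabular output as CSV plus one JSON manifest holding the
seed, package versions and SHA-256 checksums of all written files.  Given
the same config and seed the outputs are byte-identical across runs (the
manifest carries no timestamps).

Demographics follow the conventional small-cohort summary: Chi-squared on
the 2x2 group-by-sex table (reported both with and without the Yates
continuity correction, since the two can disagree noticeably at n = 48)
and a two-sided Mann-Whitney U for age, with medians and IQRs per group.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml
from scipy.stats import chi2_contingency, mannwhitneyu

from . import __version__
from .anomaly import AnomalyReport, anomaly_report, control_reference
from .atlas import build_default_atlas
from .centrality import (
    DEFAULT_DAMPING,
    DEFAULT_RANK_SHIFT_THRESHOLD,
    DeviationReport,
    cohort_rank_vectors,
    rank_deviation,
)
from .classify import (
    DEFAULT_SPEC,
    ModelSpec,
    TuningResult,
    crossval_classify,
    default_grid,
    directional_importance,
    aggregate_by_network,
    nested_crossval_tune,
)
from .connectivity import fc_matrix, vectorize_features, write_fc_matrix
from .errors import PipelineStageError, ValidationError
from .synth import CohortDataset, SynthConfig, generate_cohort, read_cohort, write_cohort

logger = logging.getLogger("netmig")


# -- demographics --------------------------------------------------------


def demographics_table(dataset: CohortDataset) -> pd.DataFrame:
    """Group summaries and tests for the manifest covariates.

    Sex: Chi-squared on the 2x2 group-by-sex table, uncorrected and
    Yates-corrected.  Age: two-sided Mann-Whitney U, median (IQR) per
    group.  A variable constant in both groups is skipped with a notice.
    """
    patients, controls = dataset.patients, dataset.controls
    if not patients or not controls:
        raise ValidationError("demographics need both groups non-empty")
    rows = []

    def sex_counts(group):
        f = sum(1 for s in group if s.sex == "F")
        return f, len(group) - f

    pf, pm = sex_counts(patients)
    cf, cm = sex_counts(controls)
    table = np.array([[pf, pm], [cf, cm]])
    summary = f"patients {pf}F/{pm}M; controls {cf}F/{cm}M"
    if (table.sum(axis=0) == 0).any():
        rows.append(
            {"variable": "sex", "summary": summary, "test": "chi-squared",
             "statistic": np.nan, "p_value": np.nan,
             "note": "skipped: constant in both groups"}
        )
    else:
        for corrected in (False, True):
            res = chi2_contingency(table, correction=corrected)
            rows.append(
                {
                    "variable": "sex",
                    "summary": summary,
                    "test": "chi-squared"
                    + (" (Yates-corrected)" if corrected else " (uncorrected)"),
                    "statistic": float(res.statistic),
                    "p_value": float(res.pvalue),
                    "note": "",
                }
            )

    def med_iqr(vals):
        q1, q3 = np.percentile(vals, [25, 75])
        return f"{np.median(vals):g} ({q3 - q1:g})"

    p_ages = np.array([s.age_years for s in patients], dtype=float)
    c_ages = np.array([s.age_years for s in controls], dtype=float)
    summary = f"patients {med_iqr(p_ages)}; controls {med_iqr(c_ages)}"
    if np.ptp(np.concatenate([p_ages, c_ages])) == 0:
        rows.append(
            {"variable": "age_years", "summary": summary, "test": "mann-whitney-u",
             "statistic": np.nan, "p_value": np.nan,
             "note": "skipped: constant in both groups"}
        )
    else:
        res = mannwhitneyu(p_ages, c_ages, alternative="two-sided")
        rows.append(
            {"variable": "age_years", "summary": summary, "test": "mann-whitney-u",
             "statistic": float(res.statistic), "p_value": float(res.pvalue), "note": ""}
        )
    return pd.DataFrame(rows)


# -- run configuration ---------------------------------------------------


@dataclass
class RunConfig:
    """Everything `run_pipeline` needs; exactly one cohort source."""

    out_dir: Union[str, Path]
    seed: int = 0
    cohort_dir: Optional[Union[str, Path]] = None
    synth: Optional[SynthConfig] = None
    grid: Optional[list] = None  # list[ModelSpec]; None -> default grid
    untuned_spec: ModelSpec = field(default_factory=ModelSpec)
    nested_cv: bool = False
    mad_scaled: bool = False
    mad_half_credit: bool = False
    damping: float = DEFAULT_DAMPING
    rank_shift_threshold: int = DEFAULT_RANK_SHIFT_THRESHOLD
    run_centrality: bool = True
    write_fc_matrices: bool = False
    write_cohort_files: bool = False

    def __post_init__(self):
        if (self.cohort_dir is None) == (self.synth is None):
            raise ValidationError(
                "exactly one of cohort_dir or an inline synth config is required"
            )

    @classmethod
    def from_yaml(cls, path: Union[str, Path], **overrides) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        synth = raw.pop("synth", None)
        if synth is not None:
            synth.setdefault("fc_effects", [])
            synth["fc_effects"] = [tuple(e) for e in synth["fc_effects"]]
            synth.setdefault("hub_effects", [])
            synth["hub_effects"] = [tuple(e) for e in synth["hub_effects"]]
            if "age_range" in synth:
                synth["age_range"] = tuple(synth["age_range"])
            synth = SynthConfig(**synth)
        grid = raw.pop("grid", None)
        if grid is not None:
            grid = [ModelSpec(**g) for g in grid]
        untuned = raw.pop("untuned_spec", None)
        raw.update(overrides)
        return cls(
            synth=synth,
            grid=grid,
            untuned_spec=ModelSpec(**untuned) if untuned else ModelSpec(),
            **raw,
        )


@dataclass
class ReportBundle:
    """In-memory handles to every stage result plus the manifest."""

    dataset: CohortDataset
    demographics: pd.DataFrame
    untuned_cv: object
    tuning: TuningResult
    nested_cv: Optional[object]
    importance: object
    network_importance: object
    anomalies: AnomalyReport
    deviations: Optional[DeviationReport]
    manifest: dict
    out_dir: Path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        result = fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - annotate and re-raise
        raise PipelineStageError(name, exc) from exc
    logger.info("stage=%s elapsed=%.2fs", name, time.perf_counter() - t0)
    return result


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute every stage and serialize outputs under ``config.out_dir``."""
    out = Path(config.out_dir)
    if not out.exists():
        out.mkdir(parents=True)
        logger.info("created output directory %s", out)

    if config.synth is not None:
        synth_cfg = SynthConfig(**{**asdict_config(config.synth), "seed": config.seed})
        dataset = _stage("synth", generate_cohort, synth_cfg)
        if config.write_cohort_files:
            _stage("synth-write", write_cohort, dataset, out / "cohort")
    else:
        dataset = _stage("load-cohort", read_cohort, config.cohort_dir)
    logger.info(
        "cohort: %d patients, %d controls, %d regions",
        len(dataset.patients), len(dataset.controls), len(dataset.atlas),
    )

    written: list[Path] = []

    def save_csv(df: pd.DataFrame, name: str, **kwargs) -> None:
        path = out / name
        df.to_csv(path, **kwargs)
        written.append(path)

    def save_json(obj, name: str) -> None:
        path = out / name
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(path)

    # functional connectivity (features are recomputed inside classify;
    # matrices are only materialised on request)
    if config.write_fc_matrices:
        def _write_all():
            for s in dataset.subjects:
                if s.timeseries is not None:
                    fc = fc_matrix(s.timeseries, dataset.atlas)
                    path = out / f"fc_{s.subject_id}.tsv"
                    write_fc_matrix(fc, dataset.atlas, path)
                    written.append(path)
        _stage("fc-write", _write_all)

    demographics = _stage("demographics", demographics_table, dataset)
    save_csv(demographics, "demographics.csv", index=False)

    grid = config.grid if config.grid is not None else default_grid()
    untuned_cv = _stage("classify-untuned", crossval_classify, dataset, config.untuned_spec)
    tuning = _stage("classify-tune", tune_hyperparameters_entry, dataset, grid, config.untuned_spec)
    classification = {"untuned": untuned_cv.to_dict(), "tuning": tuning.to_dict()}
    nested = None
    if config.nested_cv:
        nested = _stage("classify-nested", nested_crossval_tune, dataset, grid,
                        outer_seed=config.seed)
        classification["nested"] = nested.to_dict()
    save_json(classification, "classification.json")

    importance = _stage("importance", directional_importance, dataset, tuning.best_spec)
    save_csv(importance.top(20), "feature_importance_top20.csv", index=False)
    network_importance = _stage("network-importance", aggregate_by_network,
                                importance, dataset.atlas)
    save_csv(network_importance.table, "network_importance.csv", index=False)

    def _mad():
        features = {
            s.subject_id: vectorize_features(fc_matrix(s.timeseries, dataset.atlas))
            for s in dataset.subjects
            if s.timeseries is not None
        }
        ref = control_reference(
            [features[s.subject_id] for s in dataset.controls], scaled=config.mad_scaled
        )
        return anomaly_report(
            dataset.patients,
            ref,
            dataset.atlas,
            [features[s.subject_id] for s in dataset.patients],
            half_credit=config.mad_half_credit,
        )

    anomalies = _stage("mad", _mad)
    save_csv(anomalies.counts.rename_axis("patient"), "anomaly_counts.csv")
    summary = anomalies.network_means.rename("mean_count").rename_axis("network")
    save_csv(summary.to_frame(), "anomaly_summary.csv")

    deviations = None
    if config.run_centrality:
        if any(s.structural is None for s in dataset.subjects):
            raise PipelineStageError(
                "pagerank",
                ValidationError(
                    "centrality requested but some subjects lack structural matrices"
                ),
            )
        def _centrality():
            p_ranks = cohort_rank_vectors(dataset.patients, damping=config.damping)
            c_ranks = cohort_rank_vectors(dataset.controls, damping=config.damping)
            ids = [s.subject_id for s in dataset.patients + dataset.controls]
            return rank_deviation(
                p_ranks, c_ranks, dataset.atlas.names,
                threshold=config.rank_shift_threshold, subject_ids=ids,
            )
        deviations = _stage("pagerank", _centrality)
        save_csv(deviations.flags, "pagerank_flags.csv", index=False)
        save_csv(deviations.table, "pagerank_ranks.csv", index=False)
        save_csv(deviations.heatmap.rename_axis("subject"), "pagerank_heatmap.csv")
        save_json({"subject_outliers": deviations.subject_outliers,
                   "threshold": deviations.threshold}, "pagerank_outliers.json")

    manifest = {
        "seed": config.seed,
        "versions": {
            "netmig": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "xgboost": __import__("xgboost").__version__,
        },
        "stages": ["synth" if config.synth else "load-cohort", "demographics",
                   "classify", "importance", "mad"]
        + (["pagerank"] if config.run_centrality else []),
        "config": {
            "nested_cv": config.nested_cv,
            "mad_scaled": config.mad_scaled,
            "mad_half_credit": config.mad_half_credit,
            "damping": config.damping,
            "rank_shift_threshold": config.rank_shift_threshold,
            "grid_size": len(grid),
        },
        "files": {},
    }
    for path in sorted(written):
        manifest["files"][path.name] = _sha256(path)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return ReportBundle(
        dataset=dataset,
        demographics=demographics,
        untuned_cv=untuned_cv,
        tuning=tuning,
        nested_cv=nested,
        importance=importance,
        network_importance=network_importance,
        anomalies=anomalies,
        deviations=deviations,
        manifest=manifest,
        out_dir=out,
    )


def asdict_config(synth: SynthConfig) -> dict:
    d = asdict(synth)
    d["fc_effects"] = [tuple(e) for e in synth.fc_effects]
    d["hub_effects"] = [tuple(e) for e in synth.hub_effects]
    d["age_range"] = tuple(synth.age_range)
    return d


def tune_hyperparameters_entry(dataset, grid, untuned_spec):
    from .classify import tune_hyperparameters

    return tune_hyperparameters(dataset, grid, default_spec=untuned_spec)
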