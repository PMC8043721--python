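"""CSV / YAML / JSON interchange and the end-to-end pipeline driver."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import alternatives, compare, llo, observer, stability
from .data import COLUMNS, BehaviorDataset, ConfigError, DataError
from .task import SubjectProfile, TaskConfig, default_profiles, generate_cohort

log = logging.getLogger("probdistort")


def write_dataset(data: BehaviorDataset, path) -> None:
    data.frame.to_csv(path, index=False)


def read_dataset(path, provenance: str | None = None) -> BehaviorDataset:
    """Read a trial-level CSV; empty ``true_p`` fields are allowed."""
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise DataError(f"{path}: empty file without header") from exc
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    if provenance is None:
        provenance = "external" if frame["true_p"].isna().any() else "synthetic"
    return BehaviorDataset(frame, provenance=provenance)


@dataclass
class PipelineConfig:
    """Structured configuration for the end-to-end analysis."""

    task: TaskConfig = field(default_factory=TaskConfig)
    profiles: list[SubjectProfile] | None = None
    observer_hazard: float | None = None  # defaults to the task hazard
    conditioning: str = "adjust"
    folds: int = 4
    bootstrap_b: int = 1000
    seed: int = 0
    input_csv: str | None = None  # external data: simulation is skipped
    fit_alternatives: bool = True

    _KEYS = {
        "task", "profiles", "observer_hazard", "conditioning", "folds",
        "bootstrap_b", "seed", "input_csv", "fit_alternatives",
    }

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - cls._KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if "task" in kwargs:
            kwargs["task"] = TaskConfig(**kwargs["task"])
        if kwargs.get("profiles"):
            kwargs["profiles"] = [SubjectProfile(**p) for p in kwargs["profiles"]]
        return cls(**kwargs)

    @property
    def hazard(self) -> float:
        return (
            self.task.hazard
            if self.observer_hazard is None
            else self.observer_hazard
        )


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _dump(payload, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=1, default=_jsonable, sort_keys=True))


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """simulate -> forecast -> fit -> fit-alt -> compare -> stats.

    Writes machine-readable JSON twins of the five headline result tables
    (model suite, cross-validation, per-subject estimates with bootstrap
    CIs, median-split ANOVAs, alternative models) plus a run log of every
    seed and flag.  Returns the bundle as a dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        if config.input_csv:
            data = read_dataset(config.input_csv)
            log.info("loaded %d records from %s", data.n_records, config.input_csv)
        else:
            data = generate_cohort(config.task, config.profiles, seed=config.seed)
            write_dataset(data, outdir / "dataset.csv")
            log.info("simulated %d records", data.n_records)

        stage = "forecast"
        bayes = observer.forecast_dataset(data, hazard=config.hazard)
        sample = llo.extract_adjustments(data, bayes)
        log.info(
            "N=%d (unconditional), N=%d (conditional on adjustment), hazard=%g",
            len(sample), int(sample["adjusted"].sum()), config.hazard,
        )

        stage = "fit"
        table1 = {}
        for cond in ("all", "adjust"):
            results = llo.table1_suite(sample, conditioning=cond)
            table1[cond] = llo.suite_table(results)
        full = llo.LinearLogOddsModel.from_sample(
            sample, llo.ModelSpec(conditioning=config.conditioning)
        ).fit()
        table3 = stability.bootstrap_ci(
            sample, b=config.bootstrap_b, seed=config.seed + 1
        )

        stage = "fit-alt"
        table5 = (
            alternatives.fit_alt_suite(data, config.hazard, sample=sample)
            if config.fit_alternatives
            else None
        )

        stage = "compare"
        cv = compare.cv_compare(
            sample,
            [
                llo.ModelSpec("subject", "subject", "subject", config.conditioning),
                llo.ModelSpec("shared", "subject", "subject", config.conditioning),
                llo.ModelSpec("subject", "shared", "subject", config.conditioning),
            ],
            folds=config.folds,
            seed=config.seed + 2,
        )

        stage = "stats"
        sess = stability.sessionwise_fits(sample)
        table4 = pd.concat(
            [stability.median_split_anova(sess, p) for p in stability.PARAMS],
            ignore_index=True,
        )
        decomp = [asdict(d) for d in stability.variance_decomposition(
            sess, seed=config.seed + 3
        )]
        corr = stability.early_late_correlation(sess)
        timing = stability.timing_summary(data, sample)
        subj_fits = full.params_frame().reset_index(names="subject_id")
        timing_corr = stability.bias_timing_correlation(subj_fits, timing)
        wilcoxon = {}
        for name, values, null in (
            ("alpha_vs_0", full.alpha_by_subject.to_numpy(), 0.0),
            ("beta_vs_1", full.beta_by_subject.to_numpy(), 1.0),
        ):
            try:
                wilcoxon[name] = stability.wilcoxon_signed_rank(values, null)
            except DataError as exc:  # < 5 subjects, or all tied
                log.warning("wilcoxon %s skipped: %s", name, exc)
                wilcoxon[name] = None
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    bundle = {
        "table1_model_suite": {k: v for k, v in table1.items()},
        "table2_cross_validation": cv.table,
        "table3_subject_estimates": table3,
        "table4_median_split_anova": table4,
        "table5_alternative_models": table5,
        "sessionwise_fits": sess,
        "variance_decomposition": decomp,
        "early_late_correlation": corr,
        "timing_correlations": timing_corr,
        "wilcoxon": wilcoxon,
        "run_log": {
            "seed": config.seed,
            "hazard": config.hazard,
            "conditioning": config.conditioning,
            "folds": config.folds,
            "bootstrap_b": config.bootstrap_b,
            "n_records": data.n_records,
            "n_conditional": int(sample["adjusted"].sum()),
            "provenance": data.provenance,
        },
    }
    _dump(bundle["table1_model_suite"], outdir / "table1_model_suite.json")
    _dump(cv.table, outdir / "table2_cross_validation.json")
    _dump(table3, outdir / "table3_subject_estimates.json")
    _dump(table4, outdir / "table4_median_split_anova.json")
    if table5 is not None:
        _dump(table5, outdir / "table5_alternative_models.json")
    _dump(
        {
            k: bundle[k]
            for k in (
                "variance_decomposition", "early_late_correlation",
                "timing_correlations", "wilcoxon", "run_log",
            )
        },
        outdir / "stability_stats.json",
    )
    return bundle
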