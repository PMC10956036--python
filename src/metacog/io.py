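"""CSV/YAML I/O and the end-to-end analysis pipeline.

The pipeline orders the stages the way the analysis is meant to run:
single-subject meta-d' fits → exclusion filtering → questionnaire scoring →
standardized regressions; every output carries the seed and a hash of the
configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import exclusions as excl
from .instruments import CATCH_ITEM, FACTOR_NAMES
from .metad import fit_metad
from .regression import standardized_ols
from .scoring import FactorWeights, questionnaire_totals, score_factors
from .sdt import counts_from_trials
from .synthetic import Cohort, CohortSpec, simulate_cohort

logger = logging.getLogger("metacog")

__all__ = [
    "PipelineConfig",
    "read_trials",
    "write_trials",
    "read_questionnaires",
    "fit_participants",
    "run_pipeline",
]

TRIAL_COLUMNS = ["participant_id", "task", "block", "evidence_level",
                 "stimulus_side", "response_side", "confidence", "responded"]


def read_trials(path, K: int = 6) -> pd.DataFrame:
    """Read and validate a trial CSV (schema: one row per trial)."""
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df["responded"] = df["responded"].astype(bool)
    conf = pd.to_numeric(df["confidence"], errors="coerce")
    resp = df["responded"]
    bad = resp & (conf.isna() | (conf < 1) | (conf > K) | (conf != conf.round()))
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(f"{path}: invalid confidence at row {row} "
                         f"(value {df['confidence'].iloc[row]!r})")
    if (~resp & conf.notna()).any():
        row = int(np.flatnonzero(~resp & conf.notna())[0])
        raise ValueError(f"{path}: confidence present on non-responded row {row}")
    df["confidence"] = conf
    for col in ("stimulus_side", "response_side"):
        vals = set(df.loc[df[col].notna(), col].unique()) - {"left", "right"}
        if vals:
            raise ValueError(f"{path}: invalid {col} values {sorted(vals)}")
    if len(df) == 0:
        logger.warning("%s: empty trial table", path)
    logger.info("%s: read %d trials, %d participants", path, len(df),
                df["participant_id"].nunique())
    return df


def write_trials(df: pd.DataFrame, path) -> None:
    out = df[TRIAL_COLUMNS].copy()
    out.to_csv(path, index=False, float_format="%.10g")


def read_questionnaires(path) -> pd.DataFrame:
    """Read a long-format questionnaire CSV and pivot to participants x items."""
    df = pd.read_csv(path)
    required = {"participant_id", "item_id", "response"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    wide = df.pivot(index="participant_id", columns="item_id", values="response")
    return wide


def fit_participants(trials: pd.DataFrame, K: int = 6,
                     method: str = "mle") -> pd.DataFrame:
    """Single-subject meta-d' fits for every participant x task in a table.

    Returns one row per fit with the type-1 and type-2 measures used by the
    regression analyses.
    """
    rows = []
    for (pid, task), sub in trials.groupby(["participant_id", "task"], sort=False):
        counts = counts_from_trials(sub, K)
        fit = fit_metad(counts, method=method)
        rows.append({
            "participant_id": pid, "task": task,
            "d_prime": fit.type1.d_prime, "c": fit.type1.c,
            "c_rel": fit.type1.c_rel, "meta_d": fit.meta_d,
            "m_ratio": fit.m_ratio, "log_efficiency": fit.log_efficiency,
            "confidence_criterion": fit.confidence_criterion,
            "loglik": fit.loglik, "degenerate": fit.degenerate,
        })
    return pd.DataFrame(rows)


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "pipeline_out"
    experiment: str = "exp1"            # which exclusion rule set
    K: int = 6
    apply_exclusions: bool = True
    cohort: dict = field(default_factory=dict)   # CohortSpec overrides
    trials_csv: str | None = None       # load instead of simulating
    questionnaire_csv: str | None = None
    weights_csv: str | None = None
    measures: tuple = ("d_prime", "meta_d", "log_efficiency", "confidence_criterion")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _cohort_from_config(config: PipelineConfig) -> Cohort:
    spec = CohortSpec(seed=config.seed, **config.cohort)
    if config.experiment == "exp2" and "tasks" not in config.cohort:
        spec.tasks = ("perception", "knowledge")
    return simulate_cohort(spec)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run fits → exclusions → scoring → regressions; write the output bundle.

    Returns the in-memory artifacts; CSV/JSON copies and a timing log are
    written under ``config.outdir``.
    """
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {"seed": config.seed, "config_hash": config.config_hash()}
    timings = {}

    def tick(stage):
        timings[stage] = round(time.time() - t0, 2)
        logger.info("stage %s done at %.2fs", stage, timings[stage])

    cohort = _cohort_from_config(config)
    tasks = list(cohort.trials)
    tick("simulate")

    fits = pd.concat([fit_participants(cohort.trials[t], K=config.K)
                      for t in tasks], ignore_index=True)
    tick("fits")

    demo = cohort.demographics.set_index("participant_id")
    metrics = demo.copy()
    metrics["catch_ok"] = (cohort.catch.set_index("participant_id")["response"]
                           == CATCH_ITEM["required_response"])
    for t in tasks:
        tm = excl.task_metrics(cohort.trials[t])
        metrics[f"accuracy_{t}"] = tm["accuracy"]
        metrics[f"constant_confidence_{t}"] = tm["constant_confidence"]
        metrics[f"n_nonresponse_{t}"] = tm["n_nonresponse"]
        mr = fits[fits["task"] == t].set_index("participant_id")["m_ratio"]
        metrics[f"m_ratio_{t}"] = mr
    if config.apply_exclusions:
        retained, report = excl.apply_exclusions(metrics, config.experiment)
    else:
        retained = metrics.index
        report = excl.ExclusionReport(len(metrics), 0, {}, {})
    tick("exclusions")

    items = cohort.items.loc[retained]
    scores = score_factors(items, cohort.weights)
    totals = questionnaire_totals(items, big5_items=None if cohort.big5_items is None
                                  else cohort.big5_items.loc[retained])
    scores = scores.join(totals).join(demo.loc[retained])
    tick("scoring")

    results = []
    for t in tasks:
        wide = fits[fits["task"] == t].set_index("participant_id").loc[retained]
        predictors = scores[list(FACTOR_NAMES) + ["age", "gender"]]
        for measure in config.measures:
            y = wide[measure]
            if y.isna().any():   # e.g. log efficiency of negative-Mratio survivors
                keep = y.notna()
                res = standardized_ols(y[keep], predictors.loc[keep[keep].index],
                                       model_id=f"symptom_dimensions_{t}",
                                       outcome_name=measure,
                                       n_dependent_tests=len(config.measures))
            else:
                res = standardized_ols(y, predictors,
                                       model_id=f"symptom_dimensions_{t}",
                                       outcome_name=measure,
                                       n_dependent_tests=len(config.measures))
            results.append(res)
    tidy = pd.concat([r.to_tidy() for r in results], ignore_index=True)
    tick("regressions")

    # --- outputs -----------------------------------------------------------
    fits.to_csv(outdir / "fits.csv", index=False, float_format="%.10g")
    scores.to_csv(outdir / "scores.csv", float_format="%.10g")
    tidy.to_csv(outdir / "regressions.csv", index=False, float_format="%.10g")
    with open(outdir / "exclusion_report.json", "w") as fh:
        json.dump({"n_input": report.n_input, "n_excluded": report.n_excluded,
                   "n_retained": report.n_retained, "per_rule": report.per_rule,
                   **stamp}, fh, indent=2, default=str)
    with open(outdir / "run_log.json", "w") as fh:
        json.dump({**stamp, "timings_s": timings}, fh, indent=2)
    return {"fits": fits, "metrics": metrics, "retained": retained,
            "exclusion_report": report, "scores": scores, "regressions": tidy,
            "cohort": cohort, **stamp}


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig(**data)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
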