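"""Predefined data-quality exclusion rules and per-rule reporting.

A participant is excluded when they violate *any* rule; the headline count
deduplicates participants while the per-rule counts credit every rule a
participant violates.  Experiment 1 applies six rules on the perceptual
task; experiment 2 adds four knowledge-task rules:

* missing gender information
* age below 18
* below- or near-chance accuracy (< 55%), per task
* failed attention-check ("catch") questionnaire item
* a single constant confidence rating across all of a task's trials
* metacognitive efficiency (meta-d'/d') below 0, per task
* more than 4 unanswered knowledge-task trials

Accuracy is computed over responded trials excluding the identical
(zero-evidence) condition, where correctness is undefined.  The Mratio
screen uses the non-hierarchical single-subject fit, matching the workflow
order (exclusion precedes the hierarchical analyses).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExclusionConfig",
    "ExclusionReport",
    "task_metrics",
    "apply_exclusions",
    "EXP1_RULES",
    "EXP2_RULES",
]

EXP1_RULES = (
    "missing_gender",
    "accuracy_perception",
    "age_under_18",
    "catch_item",
    "constant_confidence_perception",
    "negative_mratio_perception",
)
EXP2_RULES = EXP1_RULES + (
    "accuracy_knowledge",
    "constant_confidence_knowledge",
    "negative_mratio_knowledge",
    "nonresponse_knowledge",
)


@dataclass
class ExclusionConfig:
    accuracy_threshold: float = 0.55       # strict <
    min_age: int = 18
    max_nonresponses: int = 4              # strict >
    include_zero_evidence_in_accuracy: bool = False
    rules: tuple | None = None             # override the experiment's rule set


@dataclass
class ExclusionReport:
    n_input: int
    n_excluded: int
    per_rule: dict
    per_participant: dict  # participant -> list of violated rules

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_excluded

    def to_text(self) -> str:
        lines = [f"input: {self.n_input}  excluded: {self.n_excluded} "
                 f"({100 * self.n_excluded / max(self.n_input, 1):.1f}%)  "
                 f"retained: {self.n_retained}"]
        for rule, cnt in self.per_rule.items():
            lines.append(f"  {rule}: {cnt}")
        return "\n".join(lines)


def task_metrics(trials: pd.DataFrame,
                 include_zero_evidence: bool = False) -> pd.DataFrame:
    """Per-participant summary of one task's trial table.

    Returns accuracy over responded (and, by default, non-zero-evidence)
    trials, whether a single confidence rating was used throughout, and the
    non-response count.
    """
    rows = []
    for pid, sub in trials.groupby("participant_id", sort=False):
        resp = sub[sub["responded"].astype(bool)]
        scored = resp if include_zero_evidence else \
            resp[resp["evidence_level"].astype(float) != 0]
        acc = float((scored["response_side"] == scored["stimulus_side"]).mean()) \
            if len(scored) else float("nan")
        conf = resp["confidence"].to_numpy(dtype=float)
        rows.append({
            "participant_id": pid,
            "accuracy": acc,
            "constant_confidence": bool(len(conf) > 0 and np.nanstd(conf) == 0),
            "n_nonresponse": int(len(sub) - len(resp)),
        })
    return pd.DataFrame(rows).set_index("participant_id")


def _metric(metrics: pd.DataFrame, col: str, rule: str) -> pd.Series:
    if col not in metrics.columns:
        raise ValueError(f"metrics table lacks column {col!r} required by rule {rule!r}")
    s = metrics[col]
    if s.isna().any():
        missing = metrics.index[s.isna()].tolist()
        raise ValueError(f"missing {col!r} for participants {missing[:5]} "
                         f"(rule {rule!r})")
    return s


def apply_exclusions(metrics: pd.DataFrame, experiment: str = "exp2",
                     config: ExclusionConfig | None = None
                     ) -> tuple[pd.Index, ExclusionReport]:
    """Apply an experiment's rule set to a participant-metrics table.

    ``metrics`` is indexed by participant id with columns ``age``, ``gender``,
    ``catch_ok``, ``accuracy_<task>``, ``constant_confidence_<task>``,
    ``m_ratio_<task>`` and (experiment 2) ``n_nonresponse_knowledge``.
    Returns the retained index and a report; the retained set is independent
    of rule order and re-application excludes no one.
    """
    cfg = config or ExclusionConfig()
    if experiment not in ("exp1", "exp2"):
        raise ValueError("experiment must be 'exp1' or 'exp2'")
    rules = cfg.rules if cfg.rules is not None else \
        (EXP1_RULES if experiment == "exp1" else EXP2_RULES)

    violators: dict[str, pd.Index] = {}
    for rule in rules:
        if rule == "missing_gender":
            mask = metrics["gender"].isna() | (metrics["gender"].astype(object) == "")
        elif rule == "age_under_18":
            mask = _metric(metrics, "age", rule) < cfg.min_age
        elif rule == "catch_item":
            mask = ~_metric(metrics, "catch_ok", rule).astype(bool)
        elif rule.startswith("accuracy_"):
            task = rule.split("_", 1)[1]
            mask = _metric(metrics, f"accuracy_{task}", rule) < cfg.accuracy_threshold
        elif rule.startswith("constant_confidence_"):
            task = rule.split("constant_confidence_")[1]
            mask = _metric(metrics, f"constant_confidence_{task}", rule).astype(bool)
        elif rule.startswith("negative_mratio_"):
            task = rule.split("negative_mratio_")[1]
            mask = _metric(metrics, f"m_ratio_{task}", rule) < 0
        elif rule == "nonresponse_knowledge":
            mask = _metric(metrics, "n_nonresponse_knowledge", rule) > cfg.max_nonresponses
        else:
            raise ValueError(f"unknown rule {rule!r}")
        violators[rule] = metrics.index[np.asarray(mask, dtype=bool)]

    excluded: set = set()
    per_participant: dict = {}
    for rule, idx in violators.items():
        for pid in idx:
            per_participant.setdefault(pid, []).append(rule)
            excluded.add(pid)
    retained = metrics.index[~metrics.index.isin(excluded)]
    report = ExclusionReport(
        n_input=len(metrics),
        n_excluded=len(excluded),
        per_rule={rule: len(idx) for rule, idx in violators.items()},
        per_participant=per_participant,
    )
    return retained, report
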