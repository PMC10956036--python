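"""Exclusion rules: union semantics, idempotence, order independence."""

import numpy as np
import pandas as pd
import pytest

from metacog.exclusions import (EXP1_RULES, EXP2_RULES, ExclusionConfig,
                                apply_exclusions, task_metrics)
from metacog.io import PipelineConfig, run_pipeline
from metacog.synthetic import CohortSpec, simulate_cohort


def metrics_frame(n, rng=None, **overrides):
    """Hand-built participant metrics, clean by default."""
    rng = rng or np.random.default_rng(0)
    df = pd.DataFrame({
        "age": np.full(n, 25),
        "gender": ["female", "male"] * (n // 2) + ["female"] * (n % 2),
        "catch_ok": True,
        "accuracy_perception": 0.75,
        "constant_confidence_perception": False,
        "m_ratio_perception": 0.9,
        "accuracy_knowledge": 0.7,
        "constant_confidence_knowledge": False,
        "m_ratio_knowledge": 0.8,
        "n_nonresponse_knowledge": 0,
    }, index=pd.Index([f"p{i}" for i in range(n)], name="participant_id"))
    for col, (idx, val) in overrides.items():
        df.loc[[f"p{i}" for i in idx], col] = val
    return df


class TestRuleSemantics:
    def test_clean_table_retains_everyone(self):
        m = metrics_frame(20)
        retained, rep = apply_exclusions(m, "exp2")
        assert rep.n_excluded == 0
        assert len(retained) == 20

    def test_multi_rule_violator_counted_once(self):
        m = metrics_frame(10,
                          age=([0], 16),
                          accuracy_perception=([0, 1], 0.4))
        retained, rep = apply_exclusions(m, "exp1")
        assert rep.n_excluded == 2              # p0 (two rules) + p1
        assert rep.per_rule["age_under_18"] == 1
        assert rep.per_rule["accuracy_perception"] == 2
        assert sorted(rep.per_participant["p0"]) == ["accuracy_perception",
                                                     "age_under_18"]
        assert rep.n_retained == 8

    def test_exp1_ignores_knowledge_columns(self):
        m = metrics_frame(6, accuracy_knowledge=([2], 0.2),
                          n_nonresponse_knowledge=([3], 10))
        _, rep = apply_exclusions(m, "exp1")
        assert rep.n_excluded == 0
        _, rep2 = apply_exclusions(m, "exp2")
        assert rep2.n_excluded == 2

    def test_accuracy_threshold_is_strict(self):
        m = metrics_frame(4, accuracy_perception=([0], 0.55))
        _, rep = apply_exclusions(m, "exp1")
        assert rep.n_excluded == 0              # exactly 55% is retained
        m2 = metrics_frame(4, accuracy_perception=([0], 0.5499))
        _, rep2 = apply_exclusions(m2, "exp1")
        assert rep2.n_excluded == 1

    def test_negative_mratio_rule(self):
        m = metrics_frame(5, m_ratio_perception=([1], -0.2))
        retained, rep = apply_exclusions(m, "exp1")
        assert rep.per_rule["negative_mratio_perception"] == 1
        assert "p1" not in retained

    def test_idempotent_and_order_independent_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(5, 25))
            m = metrics_frame(n)
            # randomly violate rules
            m["age"] = rng.choice([16, 25], n, p=[0.15, 0.85])
            m["accuracy_perception"] = rng.uniform(0.4, 0.9, n)
            m["m_ratio_perception"] = rng.normal(0.7, 0.5, n)
            m["catch_ok"] = rng.random(n) > 0.1
            m["n_nonresponse_knowledge"] = rng.integers(0, 8, n)
            retained, rep = apply_exclusions(m, "exp2")
            # idempotence
            retained2, rep2 = apply_exclusions(m.loc[retained], "exp2")
            assert rep2.n_excluded == 0
            assert list(retained2) == list(retained)
            # order independence
            shuffled = ExclusionConfig(rules=tuple(rng.permutation(EXP2_RULES)))
            retained3, _ = apply_exclusions(m, "exp2", shuffled)
            assert set(retained3) == set(retained)

    def test_missing_required_column_names_rule(self):
        m = metrics_frame(4).drop(columns=["m_ratio_knowledge"])
        with pytest.raises(ValueError, match="negative_mratio_knowledge"):
            apply_exclusions(m, "exp2")


class TestTaskMetrics:
    def test_zero_evidence_trials_outside_accuracy_denominator(self):
        trials = pd.DataFrame({
            "participant_id": "p0",
            "evidence_level": [8, 8, 0, 0],
            "stimulus_side": ["right", "right", "left", "left"],
            "response_side": ["right", "left", "left", "left"],
            "confidence": [5, 2, 3, 3],
            "responded": True,
        })
        tm = task_metrics(trials)
        assert tm.loc["p0", "accuracy"] == 0.5    # 1 of 2 scored trials
        tm2 = task_metrics(trials, include_zero_evidence=True)
        assert tm2.loc["p0", "accuracy"] == 0.75

    def test_constant_confidence_detection(self):
        trials = pd.DataFrame({
            "participant_id": ["a"] * 3 + ["b"] * 3,
            "evidence_level": 8,
            "stimulus_side": "right",
            "response_side": "right",
            "confidence": [4, 4, 4, 4, 5, 4],
            "responded": True,
        })
        tm = task_metrics(trials)
        assert bool(tm.loc["a", "constant_confidence"])
        assert not bool(tm.loc["b", "constant_confidence"])


class TestPlantedCohort:
    def test_planted_violators_reported_exactly(self, tmp_path):
        cfg = PipelineConfig(
            seed=17, outdir=str(tmp_path / "excl"), experiment="exp1",
            cohort={"n": 40, "include_big5": False,
                    "base_meta_noise": 0.05, "meta_noise_sd_between": 0.02,
                    "violators": {"under_18": 2, "chance_performer": 3,
                                  "constant_confidence": 1}})
        out = run_pipeline(cfg)
        rep = out["exclusion_report"]
        assert rep.per_rule["age_under_18"] == 2
        assert rep.per_rule["accuracy_perception"] == 3
        assert rep.per_rule["constant_confidence_perception"] == 1
        assert rep.n_excluded == 6
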