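"""Designs, observers and cohort generation."""

import numpy as np
import pandas as pd
import pytest

from metacog.instruments import PSYCHIATRIC_INSTRUMENTS, all_item_ids
from metacog.scoring import score_factors
from metacog.sdt import counts_from_trials, type1_fit
from metacog.synthetic import (CohortSpec, ObserverParams, generate_design,
                               generate_stimulus_spec, simulate_cohort,
                               simulate_model_counts, simulate_observer,
                               synthetic_factor_weights)


class TestDesigns:
    def test_perception_design_totals(self):
        spec, trials = generate_design("perception", seed=0)
        assert len(trials) == 136
        assert len(spec.conditions) == 17
        assert spec.reference_magnitude == 272
        assert set(trials["block"]) == {1, 2}
        assert (trials["block"] == 1).sum() == 68

    def test_knowledge_design_totals(self):
        spec, trials = generate_design("knowledge", seed=0)
        assert len(trials) == 144
        assert len(spec.conditions) == 16
        assert len(spec.bin_edges) == 9
        assert spec.bin_edges[1] == pytest.approx(0.225)
        assert (trials["block"] == 1).sum() == 72

    def test_reference_side_counterbalanced_within_condition(self):
        _, trials = generate_design("perception", seed=5)
        for delta, sub in trials.groupby("condition"):
            sides = (sub["reference_side"] == "right").sum()
            assert sides == len(sub) // 2

    def test_odd_repetitions_rejected(self):
        with pytest.raises(ValueError, match="counterbalancing"):
            generate_design("perception", trials_per_condition=7)

    def test_block_division_enforced(self):
        with pytest.raises(ValueError, match="blocks"):
            generate_design("perception", trials_per_condition=2, blocks=5)

    def test_same_seed_identical_order(self):
        _, a = generate_design("perception", seed=9)
        _, b = generate_design("perception", seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_stimulus_spec_arithmetic(self):
        spec, trials = generate_design("perception", seed=1)
        row = trials[trials["condition"] == 64].index[0]
        s = generate_stimulus_spec(spec, trials, row)
        assert s["reference_count"] == 272
        assert s["comparison_count"] == 336
        assert s["reference_side"] != s["comparison_side"]
        zero = trials[trials["condition"] == 0].index[0]
        s0 = generate_stimulus_spec(spec, trials, zero)
        assert s0["comparison_count"] == s0["reference_count"] == 272


class TestObserver:
    def test_zero_sensitivity_is_chance(self):
        spec, trials = generate_design("perception", conditions=(-48, 48),
                                       trials_per_condition=3000, seed=2)
        tt = simulate_observer(trials, ObserverParams(0.0), seed=3)
        acc = (tt["response_side"] == tt["stimulus_side"]).mean()
        assert acc == pytest.approx(0.5, abs=0.03)

    def test_same_seed_byte_identical(self):
        _, trials = generate_design("perception", seed=4)
        p = ObserverParams(0.045, 0.1, 0.3, 0.1)
        a = simulate_observer(trials, p, seed=6)
        b = simulate_observer(trials, p, seed=6)
        pd.testing.assert_frame_equal(a, b)

    def test_constant_confidence_override(self):
        _, trials = generate_design("perception", seed=4)
        p = ObserverParams(0.045, constant_confidence=4)
        tt = simulate_observer(trials, p, seed=6)
        assert set(tt["confidence"]) == {4.0}

    def test_knowledge_nonresponses(self):
        _, trials = generate_design("knowledge", seed=4)
        p = ObserverParams(1.6, nonresponse_rate=0.1)
        tt = simulate_observer(trials, p, seed=6, task="knowledge")
        dropped = ~tt["responded"]
        assert dropped.any()
        assert tt.loc[dropped, "confidence"].isna().all()

    def test_model_counts_match_requested_total(self):
        counts = simulate_model_counts(777, 1.5, 0.9, seed=1)
        assert counts.total == 777


class TestCohort:
    @pytest.fixture(scope="class")
    def cohort(self):
        return simulate_cohort(CohortSpec(n=500, seed=7, include_big5=True))

    def test_item_table_shape(self, cohort):
        assert cohort.items.shape == (500, 209)
        assert list(cohort.items.columns) == all_item_ids()
        assert cohort.big5_items.shape == (500, 44)

    def test_item_responses_within_instrument_ranges(self, cohort):
        col = 0
        for name, cfg in PSYCHIATRIC_INSTRUMENTS.items():
            block = cohort.items.iloc[:, col:col + cfg["n_items"]]
            assert block.min().min() >= cfg["min"]
            assert block.max().max() <= cfg["max"]
            col += cfg["n_items"]

    def test_factor_scores_recover_planted_latents(self, cohort):
        scores = score_factors(cohort.items, cohort.weights)
        gt = cohort.ground_truth.set_index("participant_id")
        for f in ("AD", "CIT", "SW"):
            r = np.corrcoef(scores[f], gt[f])[0, 1]
            assert r > 0.9, f"{f}: r={r:.3f}"

    def test_ground_truth_records_planted_parameters(self, cohort):
        gt = cohort.ground_truth
        for col in ("AD", "CIT", "SW", "confidence_shift", "criterion",
                    "meta_noise_sd", "sensitivity_perception"):
            assert col in gt.columns
        assert len(gt) == 500

    def test_same_seed_reproducible(self):
        a = simulate_cohort(CohortSpec(n=40, seed=3, include_big5=False))
        b = simulate_cohort(CohortSpec(n=40, seed=3, include_big5=False))
        pd.testing.assert_frame_equal(a.items, b.items)
        pd.testing.assert_frame_equal(a.trials["perception"], b.trials["perception"])
        pd.testing.assert_frame_equal(a.ground_truth, b.ground_truth)

    def test_lsas_items_are_fear_avoidance_means(self, cohort):
        lsas_cols = [c for c in cohort.items.columns if c.startswith("lsas")]
        expected = (cohort.lsas_fear.to_numpy()
                    + cohort.lsas_avoidance.to_numpy()) / 2
        np.testing.assert_allclose(cohort.items[lsas_cols].to_numpy(), expected)

    def test_planted_violators_behave_as_planted(self):
        spec = CohortSpec(n=60, seed=5, tasks=("perception", "knowledge"),
                          base_meta_noise=0.05, meta_noise_sd_between=0.02,
                          include_big5=False,
                          violators={"under_18": 2, "chance_performer": 2,
                                     "constant_confidence": 1,
                                     "knowledge_nonresponse": 1,
                                     "catch_fail": 1, "missing_gender": 1})
        coh = simulate_cohort(spec)
        gt = coh.ground_truth
        assert gt["violates_under_18"].sum() == 2
        under = gt[gt["violates_under_18"]]
        assert (under["age"] < 18).all()
        assert gt.loc[gt["violates_missing_gender"], "gender"].isna().all()
        # chance performers really score below the accuracy cut-off
        for pid in gt.loc[gt["violates_chance_performer"], "participant_id"]:
            sub = coh.trials["perception"]
            sub = sub[(sub["participant_id"] == pid) & sub["responded"]
                      & (sub["evidence_level"] != 0)]
            assert (sub["response_side"] == sub["stimulus_side"]).mean() < 0.55
        # the knowledge non-responder misses more than 4 trials
        pid = gt.loc[gt["violates_knowledge_nonresponse"], "participant_id"].iloc[0]
        sub = coh.trials["knowledge"]
        assert (~sub[sub["participant_id"] == pid]["responded"]).sum() > 4
        bad = coh.catch.set_index("participant_id").loc[
            gt.loc[gt["violates_catch_fail"], "participant_id"], "response"]
        assert (bad != "Good part of the time").all()

    def test_synthetic_weights_shape_and_determinism(self):
        w1 = synthetic_factor_weights(1)
        w2 = synthetic_factor_weights(1)
        pd.testing.assert_frame_equal(w1.weights, w2.weights)
        assert w1.weights.shape == (209, 3)
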