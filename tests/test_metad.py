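"""The meta-d' model: predicted type-2 probabilities, fitting, efficiency."""

import numpy as np
import pytest

from metacog.metad import (McmcParams, confidence_criterion, efficiency,
                           fit_metad, predict_type2_probs, type2_loglik)
from metacog.sdt import RatingCounts, counts_from_trials
from metacog.synthetic import (ObserverParams, generate_design,
                               simulate_model_counts, simulate_observer)


class TestPredictType2Probs:
    def test_conditional_distributions_normalise(self):
        off = np.array([0.3, 0.7, 1.0, 1.6, 2.0])
        p = predict_type2_probs(1.4, 0.2, 0.2 - off, 0.2 + off, 6)
        np.testing.assert_allclose(p.sum(axis=2), 1.0, atol=1e-12)

    def test_zero_sensitivity_carries_no_stimulus_information(self):
        off = np.array([0.4, 0.8])
        p = predict_type2_probs(0.0, 0.0, -off, off, 3)
        np.testing.assert_allclose(p[0], p[1], atol=1e-12)

    def test_closed_form_upper_band(self):
        # P(conf=2 | S2, right) = [1 - PHI(1-1)] / [1 - PHI(0-1)]
        p = predict_type2_probs(2.0, 0.0, np.array([-1.0]), np.array([1.0]), 2)
        assert p[1, 1, 1] == pytest.approx(0.5 / 0.8413447, abs=1e-6)

    def test_distant_criteria_force_lowest_confidence(self):
        off = np.array([50.0, 60.0])
        p = predict_type2_probs(1.0, 0.0, -off, off, 3)
        np.testing.assert_allclose(p[:, :, 0], 1.0, atol=1e-10)

    def test_validation_errors(self):
        with pytest.raises(ValueError, match="meta_d"):
            predict_type2_probs(-1.0, 0.0, np.array([-1.0]), np.array([1.0]), 2)
        with pytest.raises(ValueError, match="non-decreasing"):
            predict_type2_probs(1.0, 0.0, np.array([-1.0, -2.0]),
                                np.array([2.0, 1.0]), 3)


class TestFitMetad:
    def test_parameter_recovery_from_model_counts(self):
        counts = simulate_model_counts(50000, 1.5, 1.2 / 1.5, c=0.1, seed=21)
        fit = fit_metad(counts)
        assert fit.meta_d == pytest.approx(1.2, abs=0.05)

    def test_ideal_observer_mratio_is_one(self):
        spec, trials = generate_design("perception", conditions=(-48, 48),
                                       trials_per_condition=25000, seed=2)
        tt = simulate_observer(trials, ObserverParams(1.5 / 48), seed=3)
        fit = fit_metad(counts_from_trials(tt, 6))
        assert fit.m_ratio == pytest.approx(1.0, abs=0.05)
        assert efficiency(fit) == pytest.approx(0.0, abs=0.05)

    def test_meta_d_invariant_to_count_scaling(self):
        counts = simulate_model_counts(800, 1.5, 0.8, seed=5)
        f1 = fit_metad(counts)
        f5 = fit_metad(counts.scaled(5))
        assert f5.meta_d == pytest.approx(f1.meta_d, abs=0.05)

    def test_degenerate_confidence_flagged(self):
        c = np.zeros((2, 2, 6))
        c[:, :, 3] = [[30, 10], [10, 30]]
        fit = fit_metad(RatingCounts(c, 6))
        assert fit.degenerate

    def test_negative_meta_d_representable(self):
        """Confidence anti-correlated with accuracy drives meta-d below zero."""
        rng = np.random.default_rng(7)
        n = 4000
        x = np.where(rng.random(n) < 0.5, 0.75, -0.75) + rng.standard_normal(n)
        stim = np.zeros((2, 2, 6))
        # high confidence exactly when the response is wrong
        for s, mu in ((0, -0.75), (1, 0.75)):
            xs = mu + rng.standard_normal(n)
            r = (xs > 0).astype(int)
            correct = r == s
            conf = np.where(correct, 1, 5)
            for ri, ci in zip(r, conf):
                stim[s, ri, ci] += 1
        fit = fit_metad(RatingCounts(stim, 6))
        assert fit.m_ratio < 0
        with pytest.raises(ValueError, match="exclusion"):
            efficiency(fit)

    def test_mle_mcmc_agreement(self):
        """Point estimates from both methods agree on 1,000-trial sessions."""
        diffs = []
        light = McmcParams(nchains=1, nburnin=300, nsamples=700, seed=0)
        for s in range(20):
            counts = simulate_model_counts(1000, 1.6, 0.9, c=0.1, seed=300 + s)
            mle = fit_metad(counts, method="mle")
            mc = fit_metad(counts, method="mcmc", mcmc=light)
            diffs.append(abs(mle.meta_d - mc.meta_d))
        assert np.mean(diffs) < 0.1

    def test_mcmc_reports_convergence_diagnostics(self):
        counts = simulate_model_counts(600, 1.5, 0.9, seed=9)
        fit = fit_metad(counts, method="mcmc",
                        mcmc=McmcParams(nchains=1, nburnin=500, nsamples=1500, seed=1))
        assert fit.posterior is not None
        assert fit.posterior["ess"] > 100
        assert 0.9 < fit.posterior["rhat"] < 1.2

    def test_fitted_mratio_decreases_with_meta_noise(self):
        spec, trials = generate_design("perception", conditions=(-48, 48),
                                       trials_per_condition=500, seed=2)
        means = []
        for noise in (0.0, 1.0, 2.0):
            ms = []
            for s in range(10):
                tt = simulate_observer(trials, ObserverParams(1.5 / 48,
                                                              meta_noise_sd=noise),
                                       seed=500 + s)
                ms.append(fit_metad(counts_from_trials(tt, 6)).m_ratio)
            means.append(np.mean(ms))
        assert means[0] > means[1] > means[2]


class TestDerivedStatistics:
    def _fit_with_criteria(self, t2c_left, t2c_right, meta_c=0.0):
        counts = simulate_model_counts(2000, 1.5, 0.9, seed=3)
        fit = fit_metad(counts)
        fit.meta_c = meta_c
        fit.t2c_left = np.asarray(t2c_left, float)
        fit.t2c_right = np.asarray(t2c_right, float)
        return fit

    def test_coincident_criteria_give_zero(self):
        fit = self._fit_with_criteria(np.zeros(5), np.zeros(5))
        assert confidence_criterion(fit) == 0.0

    def test_symmetric_ladder_mean_offset(self):
        off = np.array([0.2, 0.4, 0.6, 0.8, 1.0])
        fit = self._fit_with_criteria(-off, off)
        assert confidence_criterion(fit) == pytest.approx(0.6, abs=1e-12)

    def test_raw_c_reference_option(self):
        off = np.array([0.5, 1.0])
        fit = self._fit_with_criteria(0.3 - off, 0.3 + off, meta_c=0.3)
        assert confidence_criterion(fit) == pytest.approx(0.75, abs=1e-12)
        c = fit.type1.c
        expected_raw = 0.5 * (np.mean(np.abs(fit.t2c_left - c))
                              + np.mean(np.abs(fit.t2c_right - c)))
        assert confidence_criterion(fit, reference="c") == pytest.approx(
            expected_raw, abs=1e-12)

    def test_efficiency_log_identity(self):
        counts = simulate_model_counts(5000, 1.5, 1.0, seed=11)
        fit = fit_metad(counts)
        assert efficiency(fit) == pytest.approx(np.log(fit.m_ratio), abs=1e-12)

    def test_confidence_criterion_tracks_mean_confidence_inversely(self):
        """Across observers differing only in confidence bias, the criterion
        statistic is strongly anti-correlated with mean raw confidence."""
        spec, trials = generate_design("perception", conditions=(-48, 48),
                                       trials_per_condition=200, seed=4)
        rng = np.random.default_rng(0)
        crits, mean_conf = [], []
        for i in range(60):
            shift = rng.uniform(-0.35, 0.8)
            tt = simulate_observer(trials, ObserverParams(1.5 / 48,
                                                          confidence_shift=shift),
                                   seed=700 + i)
            fit = fit_metad(counts_from_trials(tt, 6))
            crits.append(fit.confidence_criterion)
            mean_conf.append(tt["confidence"].mean())
        r = np.corrcoef(crits, mean_conf)[0, 1]
        assert r < -0.8
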