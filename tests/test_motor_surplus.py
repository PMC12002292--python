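"""Trace surplus, MSI, SM selection, motor enhancement, held-out decoding."""

import numpy as np
import pandas as pd
import pytest

from visuomotor.data import STIMULUS_OF_BEHAVIOR
from visuomotor.motor_surplus import (
    holdout_predict,
    motor_enhancement,
    motor_surplus_index,
    select_sm,
    trace_surplus,
)
from visuomotor.regressors import make_kernel, visuomotor_regressor
from visuomotor.sensory_index import trial_average
from visuomotor.synthetic_data import SimConfig, generate_population

W = 10
STARTS8 = np.arange(8) * 30


class TestTraceSurplus:
    def test_periodic_trace_zero_surplus_in_windows(self):
        seg = np.sin(np.arange(W))
        trace = np.zeros(8 * 30)
        for s in STARTS8:
            trace[s : s + W] = seg
        surplus = trace_surplus(trace, STARTS8, W)
        for s in STARTS8:
            np.testing.assert_allclose(surplus[s : s + W], 0.0, atol=1e-12)

    def test_single_responding_trial_mean_subtraction_algebra(self):
        # responding only in trial 2 of 8 leaves 7/8 of the response
        # there and -1/8 of it in every other window
        resp = np.ones(W)
        trace = np.zeros(8 * 30)
        trace[STARTS8[2] : STARTS8[2] + W] = resp
        surplus = trace_surplus(trace, STARTS8, W)
        np.testing.assert_allclose(surplus[STARTS8[2] : STARTS8[2] + W], 7 / 8 * resp)
        np.testing.assert_allclose(surplus[STARTS8[0] : STARTS8[0] + W], -1 / 8 * resp)

    def test_window_sum_zero_at_each_timepoint(self, rng):
        trace = rng.normal(0, 1, 8 * 30)
        surplus = trace_surplus(trace, STARTS8, W)
        total = sum(surplus[s : s + W] for s in STARTS8)
        np.testing.assert_allclose(total, 0.0, atol=1e-12)

    def test_surplus_then_trial_average_is_zero(self, rng):
        trace = rng.normal(0, 1, 8 * 30)
        surplus = trace_surplus(trace, STARTS8, W)
        np.testing.assert_allclose(trial_average(surplus, STARTS8, W), 0.0, atol=1e-12)


def freezing_context(noise_sd=0.0, seed=11, n_fish=1):
    """A dataset guaranteed to contain >=2 freezing and >=2 none sweep trials."""
    for s in range(seed, seed + 50):
        cfg = SimConfig(
            n_fish=n_fish,
            n_sensory_per_stimulus=4,
            n_sm_per_behavior=4,
            n_mixed=0,
            n_background=20,
            noise_sd=noise_sd,
            amp_spread_sd=0.0,
            trial_jitter_sd=0.0,
            seed=s,
        )
        recs, sched, behs, truth = generate_population(cfg)
        labels = behs[0].labels_for(sched, "sweep")
        if (labels == "freezing").sum() >= 2 and (labels == "none").sum() >= 2:
            return cfg, recs, sched, behs, truth
    raise RuntimeError("no suitable seed found")


class TestMotorSurplusIndex:
    def test_planted_sm_neuron_matches_mean_subtraction_oracle(self):
        # With a matched kernel and no noise, the surplus of a neuron
        # gated on n_b of n trials is (1 - n_b/n)*r in behavior windows
        # and -(n_b/n)*r elsewhere, so its correlation with the
        # visuomotor regressor is sqrt(1 - n_b/n) (up to small
        # mean-centering and kernel-truncation corrections).
        cfg, recs, sched, behs, _ = freezing_context(noise_sd=0.0)
        rec = recs[0]
        labels = behs[0].labels_for(sched, "sweep")
        n_b = (labels == "freezing").sum()
        oracle = np.sqrt(1 - n_b / len(labels))
        kernel = make_kernel(cfg.kernel_tau_s, cfg.frame_rate_hz)
        vm = visuomotor_regressor(sched, behs[0], "freezing", kernel, rec.n_frames)
        starts = sched.windows("sweep", cfg.window_frames)
        sm_ids = rec.neurons.index[rec.neurons["true_class"] == "sm:freezing"]
        for nid in sm_ids:
            surplus = trace_surplus(rec.dff[nid], starts, cfg.window_frames)
            assert motor_surplus_index(surplus, vm) == pytest.approx(oracle, abs=0.05)

    def test_sensory_neurons_score_near_zero(self):
        cfg, recs, sched, behs, _ = freezing_context(noise_sd=0.1)
        rec = recs[0]
        kernel = make_kernel(cfg.kernel_tau_s, cfg.frame_rate_hz)
        vm = visuomotor_regressor(sched, behs[0], "freezing", kernel, rec.n_frames)
        starts = sched.windows("sweep", cfg.window_frames)
        ids = rec.neurons.index[rec.neurons["true_class"] == "sensory:sweep"]
        msis = []
        for nid in ids:
            surplus = trace_surplus(rec.dff[nid], starts, cfg.window_frames)
            msis.append(motor_surplus_index(surplus, vm))
        assert abs(np.mean(msis)) < 0.15

    def test_zero_variance_surplus_flagged_zero(self):
        vm = np.sin(np.arange(100))
        with pytest.warns(UserWarning):
            assert motor_surplus_index(np.zeros(100), vm) == 0.0

    def test_constant_regressor_rejected(self):
        with pytest.raises(ValueError):
            motor_surplus_index(np.ones(10), np.ones(10))


class TestSelectSm:
    def make_scores(self, msi, fish=0):
        return pd.DataFrame(
            {
                "neuron_id": np.arange(len(msi)),
                "fish": fish,
                "behavior": "freezing",
                "msi": msi,
            }
        )

    def test_percentile_threshold_count(self, rng):
        out = select_sm(self.make_scores(rng.normal(0, 1, 1000)), pct=97)
        assert out["selected"].sum() == 30

    def test_stricter_threshold_nested(self, rng):
        scores = self.make_scores(rng.normal(0, 1, 500))
        s97 = select_sm(scores, pct=97)
        s99 = select_sm(scores, pct=99)
        sel97 = set(s97.loc[s97["selected"], "neuron_id"])
        sel99 = set(s99.loc[s99["selected"], "neuron_id"])
        assert sel99 <= sel97

    def test_msi_separates_planted_sm_from_sensory(self):
        cfg, recs, sched, behs, _ = freezing_context(noise_sd=0.1)
        rec = recs[0]
        kernel = make_kernel(cfg.kernel_tau_s, cfg.frame_rate_hz)
        vm = visuomotor_regressor(sched, behs[0], "freezing", kernel, rec.n_frames)
        starts = sched.windows("sweep", cfg.window_frames)

        def msi_of(cls):
            ids = rec.neurons.index[rec.neurons["true_class"] == cls]
            return [
                motor_surplus_index(
                    trace_surplus(rec.dff[n], starts, cfg.window_frames), vm
                )
                for n in ids
            ]

        assert min(msi_of("sm:freezing")) > max(msi_of("sensory:sweep"))


class TestMotorEnhancement:
    def test_gated_population_monotone_and_elbow(self, rng):
        # population whose behavior-trial gain rises with MSI rank, with
        # a planted kink at the 97th percentile
        n = 300
        msi = np.sort(rng.random(n))
        ranks = (np.arange(n) + 1) / n * 100
        # hockey-stick: shallow slope below the 97th percentile, steep above
        gain = np.where(ranks >= 97, 0.01 * 97 + 1.0 * (ranks - 97), 0.01 * ranks)
        beh_starts = np.array([0, 50])
        nr_starts = np.array([100, 150])
        dff = rng.normal(0, 0.01, (n, 200))
        for s in beh_starts:
            dff[:, s : s + 10] += gain[:, None]
        curve = motor_enhancement(dff, beh_starts, nr_starts, 10, msi)
        diffs = np.diff(curve.enhancement)
        assert (diffs >= -0.05).all()
        assert curve.elbow == 97.0

    def test_background_population_flat(self, rng):
        dff = rng.normal(0, 0.1, (200, 200))
        curve = motor_enhancement(
            dff, np.array([0, 50]), np.array([100, 150]), 10, rng.random(200)
        )
        assert np.nanmax(np.abs(curve.enhancement)) < 0.2

    def test_missing_trial_class_rejected(self, rng):
        with pytest.raises(ValueError):
            motor_enhancement(
                rng.normal(0, 1, (10, 100)), np.array([]), np.array([0]), 10,
                rng.random(10),
            )


class TestHoldoutPredict:
    def test_noiseless_gating_perfect_accuracy(self):
        cfg, recs, sched, behs, _ = freezing_context(noise_sd=0.0)
        kernel = make_kernel(cfg.kernel_tau_s, cfg.frame_rate_hz)
        res = holdout_predict(
            recs[0], sched, behs[0], "freezing", kernel, cfg.window_frames,
            n_null=10, seed=0,
        )
        assert res.accuracy == 1.0

    def test_null_accuracy_near_chance_on_background(self, rng):
        cfg, recs, sched, behs, _ = freezing_context(noise_sd=0.0)
        rec = recs[0]
        noise_rec = type(rec)(rng.normal(0, 1, rec.dff.shape), 2.0, 0)
        kernel = make_kernel(cfg.kernel_tau_s, cfg.frame_rate_hz)
        res = holdout_predict(
            noise_rec, sched, behs[0], "freezing", kernel, cfg.window_frames,
            n_null=40, seed=1,
        )
        assert abs(res.null_accuracies.mean() - 0.5) < 0.15

    def test_real_beats_null_at_moderate_noise(self):
        cfg, recs, sched, behs, _ = freezing_context(noise_sd=0.2)
        kernel = make_kernel(cfg.kernel_tau_s, cfg.frame_rate_hz)
        res = holdout_predict(
            recs[0], sched, behs[0], "freezing", kernel, cfg.window_frames,
            n_null=40, seed=2,
        )
        assert res.accuracy > np.percentile(res.null_accuracies, 95)

    def test_insufficient_trials_rejected(self):
        cfg, recs, sched, behs, _ = freezing_context(noise_sd=0.0)
        bt = behs[0]
        trials = bt.trials.copy()
        stim = STIMULUS_OF_BEHAVIOR["freezing"]
        mask = trials["stimulus"] == stim
        trials.loc[mask, "label"] = "none"
        trials.loc[trials.index[mask][:1], "label"] = "freezing"
        kernel = make_kernel(cfg.kernel_tau_s, cfg.frame_rate_hz)
        with pytest.raises(ValueError, match="freezing"):
            holdout_predict(
                recs[0], sched, type(bt)(trials), "freezing", kernel,
                cfg.window_frames, n_null=5, seed=0,
            )

    def test_seeded_null_reproducible(self):
        cfg, recs, sched, behs, _ = freezing_context(noise_sd=0.1)
        kernel = make_kernel(cfg.kernel_tau_s, cfg.frame_rate_hz)
        kw = dict(pct=97.0, n_null=10, seed=5)
        a = holdout_predict(recs[0], sched, behs[0], "freezing", kernel, cfg.window_frames, **kw)
        b = holdout_predict(recs[0], sched, behs[0], "freezing", kernel, cfg.window_frames, **kw)
        np.testing.assert_array_equal(a.null_accuracies, b.null_accuracies)
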