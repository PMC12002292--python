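"""Behavior-conditioned partial correlation: residuals, statistic, null, FDR."""

import warnings

import numpy as np
import pandas as pd
import pytest

from visuomotor.partial_correlation import (
    area_fraction_significant,
    behavior_templates,
    empirical_p,
    partial_corr,
    pc_statistic,
    pc_test_population,
    residual,
    trial_shuffle_null,
)
from visuomotor.synthetic_data import SimConfig, generate_population

W = 20
N_TRIALS = 8
STARTS = np.arange(N_TRIALS) * 50
IS_BEH = np.array([True, False, True, False, True, False, False, False])


def build_trace(segments):
    trace = np.zeros(N_TRIALS * 50)
    for s, seg in zip(STARTS, segments):
        trace[s : s + W] = seg
    return trace


class TestTemplatesAndResidual:
    def test_identical_trials_yield_common_template(self):
        seg = np.sin(np.arange(W))
        trace = build_trace([seg] * N_TRIALS)
        beh_t, non_t = behavior_templates(trace, STARTS, W, IS_BEH)
        np.testing.assert_allclose(beh_t, seg)
        np.testing.assert_allclose(non_t, seg)

    def test_gated_neuron_behavior_template_dominates(self, rng):
        segs = [np.full(W, 3.0) if b else np.zeros(W) for b in IS_BEH]
        trace = build_trace(segs)
        beh_t, non_t = behavior_templates(trace, STARTS, W, IS_BEH)
        assert beh_t.mean() > non_t.mean() + 2.5

    def test_noise_template_variance_shrinks_with_class_size(self, rng):
        n_mc, var_b = 300, []
        for _ in range(n_mc):
            trace = rng.normal(0, 1, N_TRIALS * 50)
            beh_t, _ = behavior_templates(trace, STARTS, W, IS_BEH)
            var_b.append(beh_t.var())
        assert np.mean(var_b) == pytest.approx(1 / IS_BEH.sum(), rel=0.2)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            behavior_templates(np.zeros(400), STARTS, W, np.zeros(8, bool))

    def test_residual_class_means_exactly_zero(self, rng):
        trace = rng.normal(0, 1, N_TRIALS * 50)
        res = residual(trace, STARTS, W, IS_BEH)
        np.testing.assert_allclose(res[IS_BEH].mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(res[~IS_BEH].mean(axis=0), 0.0, atol=1e-12)

    def test_noiseless_gated_neuron_zero_residual(self):
        segs = [np.full(W, 3.0) if b else np.zeros(W) for b in IS_BEH]
        res = residual(build_trace(segs), STARTS, W, IS_BEH)
        np.testing.assert_allclose(res, 0.0, atol=1e-12)


class TestPartialCorr:
    def test_self_correlation_is_one(self, rng):
        res = residual(rng.normal(0, 1, 400), STARTS, W, IS_BEH)
        assert partial_corr(res, res) == pytest.approx(1.0)

    def test_matches_closed_form_on_confounded_gaussians(self, rng):
        # binary class-shift confound z; the residual method must agree
        # with the textbook formula r_xy.z computed on the same samples
        n_tr, L = 50, 200
        z_trial = rng.random(n_tr) < 0.5
        z = np.repeat(z_trial, L).astype(float)
        u = rng.normal(0, 1, n_tr * L)
        x = 1.5 * z + u + rng.normal(0, 0.5, n_tr * L)
        y = -0.8 * z + 0.7 * u + rng.normal(0, 0.5, n_tr * L)
        starts = np.arange(n_tr) * L
        rx = residual(x, starts, L, z_trial)
        ry = residual(y, starts, L, z_trial)
        r = np.corrcoef(np.stack([x, y, z]))
        closed = (r[0, 1] - r[0, 2] * r[1, 2]) / np.sqrt(
            (1 - r[0, 2] ** 2) * (1 - r[1, 2] ** 2)
        )
        assert partial_corr(rx, ry) == pytest.approx(closed, abs=0.02)

    def test_independent_residual_null_spread(self, rng):
        # r between independent N(0,1) series of length n has sd ~ 1/sqrt(n)
        n = 2000
        starts = np.arange(10) * 200
        flags = np.arange(10) < 5
        rs = [
            partial_corr(
                residual(rng.normal(0, 1, n), starts, 200, flags),
                residual(rng.normal(0, 1, n), starts, 200, flags),
            )
            for _ in range(200)
        ]
        assert np.std(rs) == pytest.approx(1 / np.sqrt(n), rel=0.25)

    def test_zero_variance_flagged_zero(self):
        res = residual(np.zeros(400), STARTS, W, IS_BEH)
        with pytest.warns(UserWarning):
            assert partial_corr(res, res) == 0.0


class TestPcStatistic:
    def test_interpolated_percentile_of_sparse_correlations(self):
        # 10 correlations, one at 0.9 and nine at 0: the sorted vector's
        # 90th percentile (linear interpolation) is 0.9*0.1 = 0.09
        sm = residual(np.zeros(400) + 1e-9, STARTS, W, IS_BEH)
        # construct directly through the percentile path with stubbed pcs
        from visuomotor._stats import percentile_linear

        pcs = np.array([0.9] + [0.0] * 9)
        assert percentile_linear(pcs, 90) == pytest.approx(0.09)

    def test_equal_correlations_return_common_value(self, rng):
        sm_trace = rng.normal(0, 1, 400)
        res = residual(sm_trace, STARTS, W, IS_BEH)
        sens = np.stack([res] * 12)
        assert pc_statistic(res, sens) == pytest.approx(1.0)

    def test_small_population_warns(self, rng):
        res = residual(rng.normal(0, 1, 400), STARTS, W, IS_BEH)
        with pytest.warns(UserWarning):
            stat = pc_statistic(res, res[None])
        assert stat == pytest.approx(1.0)

    def test_empty_population_rejected(self, rng):
        res = residual(rng.normal(0, 1, 400), STARTS, W, IS_BEH)
        with pytest.raises(ValueError):
            pc_statistic(res, np.empty((0, N_TRIALS, W)))


class TestTrialShuffleNull:
    def sensory_stack(self, rng, n=12):
        return np.stack(
            [residual(rng.normal(0, 1, 400), STARTS, W, IS_BEH) for _ in range(n)]
        )

    def test_seeded_null_reproducible(self, rng):
        sm = residual(rng.normal(0, 1, 400), STARTS, W, IS_BEH)
        sens = self.sensory_stack(rng)
        a = trial_shuffle_null(sm, sens, IS_BEH, n_perm=100, seed=3)
        b = trial_shuffle_null(sm, sens, IS_BEH, n_perm=100, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_identity_only_permutation_space_rejected(self, rng):
        sm = residual(rng.normal(0, 1, 150), np.arange(3) * 50, W,
                      np.array([True, False, True]))
        with pytest.raises(ValueError):
            trial_shuffle_null(
                sm[:1], sm[None, :1], np.array([True]), n_perm=100, seed=0
            )

    def test_strong_connection_exceeds_all_nulls(self, rng):
        shared = rng.normal(0, 1, 400)
        sm_trace = 0.9 * shared + rng.normal(0, 0.2, 400)
        sens_traces = [shared + rng.normal(0, 0.2, 400) for _ in range(12)]
        sm = residual(sm_trace, STARTS, W, IS_BEH)
        sens = np.stack([residual(t, STARTS, W, IS_BEH) for t in sens_traces])
        stat = pc_statistic(sm, sens)
        null = trial_shuffle_null(sm, sens, IS_BEH, n_perm=199, seed=0)
        assert stat > null.max()

    def test_empirical_p_formula(self):
        null = np.linspace(0, 1, 999)
        assert empirical_p(2.0, null) == pytest.approx(1 / 1000)
        assert empirical_p(-1.0, null) == pytest.approx(1.0)
        assert empirical_p(0.5, null) == pytest.approx(0.5, abs=0.01)


class TestAreaFractions:
    def make_results(self, p_by_fish, area="tectum", behavior="freezing"):
        rows = []
        for fish, ps in p_by_fish.items():
            for i, p in enumerate(ps):
                rows.append(
                    {"fish": fish, "area": area, "behavior": behavior,
                     "sm_index": i, "p_empirical": p}
                )
        return pd.DataFrame(rows)

    def test_bh_within_fish_and_pooled_fraction(self):
        res = self.make_results(
            {0: [0.001] * 8 + [0.8] * 2, 1: [0.001] * 6 + [0.9] * 4}
        )
        out = area_fraction_significant(res, "tectum", "freezing")
        assert out.fraction == pytest.approx(14 / 20)
        assert out.per_fish[0] == pytest.approx(0.8)
        assert out.per_fish[1] == pytest.approx(0.6)

    def test_empty_area_rejected(self):
        res = self.make_results({0: [0.5]})
        with pytest.raises(ValueError):
            area_fraction_significant(res, "NI", "freezing")

    def test_adjusted_p_not_below_raw(self, rng):
        res = self.make_results({0: rng.random(30).tolist()})
        out = area_fraction_significant(res, "tectum", "freezing", alpha=0.05)
        assert 0.0 <= out.fraction <= 1.0


class TestSubtractionArtifactControl:
    def test_template_plus_noise_traces_not_flagged(self, rng):
        # traces built as trial-averaged templates plus independent
        # noise share no within-trial fluctuations, so correlations
        # between residuals must not be manufactured by the template
        # subtraction itself
        beh_template = rng.normal(0, 1, W)
        non_template = rng.normal(0, 1, W)

        def synth():
            segs = [
                (beh_template if b else non_template) + rng.normal(0, 0.3, W)
                for b in IS_BEH
            ]
            return build_trace(segs)

        sens = np.stack([residual(synth(), STARTS, W, IS_BEH) for _ in range(15)])
        sm = np.stack([residual(synth(), STARTS, W, IS_BEH) for _ in range(20)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            df = pc_test_population(sm, sens, IS_BEH, n_perm=199, seed=1)
        df["fish"] = 0
        df["area"] = "tectum"
        df["behavior"] = "freezing"
        out = area_fraction_significant(df, "tectum", "freezing")
        assert out.fraction <= 0.10


class TestScenarioCalibration:
    @staticmethod
    @pytest.fixture(scope="class")
    def h2_pvalues():
        cfg = SimConfig(
            scenario="H2", n_fish=2, n_sensory_per_stimulus=12,
            n_sm_per_behavior=10, n_mixed=0, n_background=10, seed=21,
        )
        recs, sched, behs, _ = generate_population(cfg)
        wf = cfg.window_frames
        starts = sched.windows("sweep", wf)
        ps = []
        for rec, beh in zip(recs, behs):
            labels = beh.labels_for(sched, "sweep")
            is_beh = labels == "freezing"
            if is_beh.sum() < 1 or (~is_beh).sum() < 2:
                continue
            nt = rec.neurons
            s_ids = nt.index[nt["true_class"] == "sensory:sweep"]
            sm_ids = nt.index[nt["true_class"] == "sm:freezing"]
            s_res = np.stack([residual(rec.dff[n], starts, wf, is_beh) for n in s_ids])
            m_res = np.stack([residual(rec.dff[n], starts, wf, is_beh) for n in sm_ids])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                df = pc_test_population(m_res, s_res, is_beh, n_perm=199, seed=5)
            ps.extend(df["p_empirical"])
        return np.array(ps)

    def test_h2_pvalues_not_anticonservative(self, h2_pvalues):
        # under the behavior-only hypothesis the test must not produce
        # an excess of small p-values
        assert (h2_pvalues < 0.05).mean() <= 0.10
        assert h2_pvalues.mean() > 0.35
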