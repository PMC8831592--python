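"""Labeling rule, splits, metrics, survival statistics and PDA maps."""

from __future__ import annotations

import numpy as np
import pytest

from qusresponse.evaluation import (
    MetricsSummary,
    MrGradeInput,
    SplitSpec,
    SurvivalRecord,
    compute_metrics,
    km_curve,
    log_rank,
    mr_grade,
    pda_maps,
    stratified_split,
)
from qusresponse.feature_net import BackboneConfig, FeatureNet
from qusresponse.parametric_mapping import NetworkInput
from qusresponse.patient_predictor import PredictorNet
from qusresponse.synthetic_rf import SurvivalParams, simulate_survival


class TestMrGrade:
    @pytest.mark.parametrize(
        "initial,residual,score,label",
        [
            (5.0, 5.0, 1, "non-responder"),   # zero reduction
            (5.0, 6.0, 1, "non-responder"),   # growth is still MR1
            (5.0, 4.0, 2, "non-responder"),   # 20% reduction
            (5.0, 3.0, 3, "responder"),       # 40% reduction
            (5.0, 0.5, 3, "responder"),       # exactly 90%
            (5.0, 0.3, 4, "responder"),       # 94% reduction
        ],
    )
    def test_size_reduction_grades(self, initial, residual, score, label):
        s, lab = mr_grade(MrGradeInput(initial, residual))
        assert (s, lab) == (score, label)

    def test_very_low_cellularity_upgrades_to_responder(self):
        s, lab = mr_grade(MrGradeInput(5.0, 4.5, very_low_cellularity=True))
        assert (s, lab) == (3, "responder")

    def test_no_malignant_cells_is_mr5(self):
        s, lab = mr_grade(MrGradeInput(5.0, 0.0, no_malignant_cells=True))
        assert (s, lab) == (5, "responder")

    def test_negative_sizes_rejected(self):
        with pytest.raises(ValueError):
            MrGradeInput(-1.0, 0.5)

    def test_zero_initial_with_malignant_cells_rejected(self):
        with pytest.raises(ValueError):
            mr_grade(MrGradeInput(0.0, 0.0))


class TestStratifiedSplit:
    def _cohort_labels(self):
        return ["responder"] * 138 + ["non-responder"] * 43

    def test_clinical_cohort_partition_sizes(self):
        labels = self._cohort_labels()
        spec = SplitSpec(test_fraction=50 / 181,
                         validation_fraction_of_train=31 / 131, seed=0)
        tr, va, te = stratified_split(labels, spec)
        assert (len(tr), len(va), len(te)) == (100, 31, 50)

    def test_partition_disjoint_and_exhaustive(self):
        labels = self._cohort_labels()
        tr, va, te = stratified_split(labels, SplitSpec(seed=3))
        allidx = np.concatenate([tr, va, te])
        assert len(np.unique(allidx)) == 181
        assert len(allidx) == 181

    def test_class_proportions_preserved_within_rounding(self):
        labels = self._cohort_labels()
        tr, va, te = stratified_split(labels, SplitSpec(seed=1))
        overall = 43 / 181
        for part in (tr, va, te):
            frac = np.mean([labels[i] == "non-responder" for i in part])
            assert frac == pytest.approx(overall, abs=0.05)

    def test_same_seed_identical_partition(self):
        labels = self._cohort_labels()
        a = stratified_split(labels, SplitSpec(seed=7))
        b = stratified_split(labels, SplitSpec(seed=7))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(["responder"] * 10 + ["non-responder"], SplitSpec())


class TestMetrics:
    def test_perfect_predictions(self):
        y = ["non-responder"] * 5 + ["responder"] * 5
        p = np.array([0.9] * 5 + [0.1] * 5)
        m = compute_metrics(p, y)
        assert (m.accuracy, m.sensitivity, m.specificity, m.auc) == (1, 1, 1, 1)

    def test_degenerate_all_responder_classifier(self):
        y = ["responder"] * 40 + ["non-responder"] * 10
        p = np.zeros(50)
        m = compute_metrics(p, y)
        assert m.specificity == 1.0
        assert m.sensitivity == 0.0
        assert m.accuracy == pytest.approx(0.8)

    def test_accuracy_identity_with_per_class_rates(self):
        """accuracy = (spec*n_resp + sens*n_nonresp) / n, exactly."""
        rng = np.random.default_rng(0)
        y = ["responder"] * 37 + ["non-responder"] * 13
        p = rng.random(50)
        m = compute_metrics(p, y)
        assert m.accuracy == pytest.approx(
            (m.specificity * 37 + m.sensitivity * 13) / 50, abs=1e-12
        )

    def test_auc_matches_rank_sum_oracle(self):
        rng = np.random.default_rng(1)
        y = np.array([0] * 12 + [1] * 8)
        p = rng.random(20)
        m = compute_metrics(p, ["non-responder" if v else "responder" for v in y])
        pos, neg = p[y == 1], p[y == 0]
        cmp_matrix = (pos[:, None] > neg[None, :]).sum() + 0.5 * (
            pos[:, None] == neg[None, :]
        ).sum()
        assert m.auc == pytest.approx(cmp_matrix / (len(pos) * len(neg)))

    def test_single_class_flagged_not_zeroed(self):
        m = compute_metrics(np.array([0.2, 0.4]), ["responder", "responder"])
        assert np.isnan(m.sensitivity) and np.isnan(m.auc)
        assert m.flags


class TestKaplanMeier:
    def test_all_censored_curve_stays_at_one(self):
        recs = [SurvivalRecord(f"p{i}", 10.0 + i, False) for i in range(5)]
        _, s = km_curve(recs)
        assert np.all(s == 1.0)

    def test_single_event_drops_by_one_over_n(self):
        recs = [SurvivalRecord(f"p{i}", 10.0 + i, i == 0) for i in range(4)]
        t, s = km_curve(recs)
        assert s[-1] == pytest.approx(3 / 4)

    def test_matches_brute_force_product_limit(self):
        rng = np.random.default_rng(2)
        times = rng.exponential(20, 20).round(1) + 0.1
        events = rng.random(20) < 0.7
        recs = [SurvivalRecord(f"p{i}", times[i], bool(events[i]))
                for i in range(20)]
        t_grid, s = km_curve(recs)
        # independent brute-force product over distinct event times
        def brute(t_eval):
            out = 1.0
            for et in np.unique(times[events]):
                if et <= t_eval:
                    at_risk = np.sum(times >= et)
                    d = np.sum((times == et) & events)
                    out *= 1 - d / at_risk
            return out
        for te, se in zip(t_grid, s):
            assert se == pytest.approx(brute(te), abs=1e-10)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            SurvivalRecord("p", 0.0, True)


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        recs = [SurvivalRecord(f"p{i}", 5.0 + i, i % 2 == 0) for i in range(10)]
        stat, p = log_rank(recs, list(recs))
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_power_against_threefold_hazard_ratio(self):
        """HR = 3, n = 25 + 25: rejection rate at alpha 0.05 above 0.8."""
        pa = SurvivalParams(hazard_responder=0.01, hazard_non_responder=0.03)
        labels = ["responder"] * 25 + ["non-responder"] * 25
        rng = np.random.default_rng(11)
        rejections = 0
        n_sims = 200
        for _ in range(n_sims):
            t, e = simulate_survival(labels, pa, rng)
            recs = [SurvivalRecord(f"p{i}", t[i], bool(e[i]))
                    for i in range(50)]
            _, p = log_rank(recs[:25], recs[25:])
            rejections += p < 0.05
        assert rejections / n_sims > 0.8

    def test_zero_events_rejected(self):
        a = [SurvivalRecord("a", 1.0, False)]
        b = [SurvivalRecord("b", 2.0, False)]
        with pytest.raises(ValueError):
            log_rank(a, b)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            log_rank([], [SurvivalRecord("b", 2.0, True)])


class _ChannelMeanFeatureNet:
    """Synthetic feature extractor that reads only channel 0."""

    def features(self, x, train=False):
        return np.tile(x[:, 0].mean(axis=(1, 2))[:, None], (1, 256))


def _linear_predictor(scale=20.0):
    net = PredictorNet(rng=np.random.default_rng(0))
    for p in net.params():
        p.value[...] = 0.0
    d1, d2 = net.net.layers[1], net.net.layers[4]
    d1.w.value[...] = 1.0 / 256.0
    d2.w.value[1, :] = scale / 100.0
    d2.b.value[...] = np.array([scale * 0.25, 0.0])
    return net


class TestPda:
    def _planes(self, seed=0, n=3, size=32):
        rng = np.random.default_rng(seed)
        planes = []
        for i in range(n):
            t = np.zeros((4, size, size))
            t[:, 8:24, 8:24] = rng.random((4, 16, 16))
            planes.append(NetworkInput(t, mode="core+margin", plane_id=f"pl{i}"))
        return planes

    def test_background_occlusion_has_zero_impact(self):
        planes = self._planes()
        maps = pda_maps(_ChannelMeanFeatureNet(), _linear_predictor(),
                        planes, target_plane=0)
        # patches fully outside the 8:24 content square are no-ops
        assert maps.channel_maps[:, 0, 0] == pytest.approx(0.0)
        assert maps.channel_maps[:, -1, -1] == pytest.approx(0.0)

    def test_maps_nonnegative(self):
        planes = self._planes()
        maps = pda_maps(_ChannelMeanFeatureNet(), _linear_predictor(),
                        planes, target_plane=1)
        assert np.all(maps.channel_maps >= 0.0)

    def test_planted_single_channel_sensitivity_dominates(self):
        """A model reading only channel 0 yields a channel-0 map that
        dwarfs the other channels' maps."""
        planes = self._planes()
        maps = pda_maps(_ChannelMeanFeatureNet(), _linear_predictor(),
                        planes, target_plane=0)
        totals = maps.channel_maps.reshape(4, -1).sum(axis=1)
        assert totals[0] > 10 * max(totals[1:].max(), 1e-12)

    def test_constant_model_yields_identically_zero_maps(self):
        class ConstantFeatures:
            def features(self, x, train=False):
                return np.ones((x.shape[0], 256))

        planes = self._planes()
        maps = pda_maps(ConstantFeatures(), _linear_predictor(), planes, 0)
        assert np.all(maps.channel_maps == 0.0)

    def test_patch_larger_than_image_rejected(self):
        planes = [NetworkInput(np.ones((4, 4, 4)), mode="core")]
        with pytest.raises(ValueError):
            pda_maps(_ChannelMeanFeatureNet(), _linear_predictor(),
                     planes, 0, patch=8)

    def test_real_feature_net_maps_nonnegative_and_shaped(self):
        net = FeatureNet(BackboneConfig("ran", "small"),
                         rng=np.random.default_rng(0))
        predictor = PredictorNet(rng=np.random.default_rng(1))
        planes = self._planes(size=32)
        maps = pda_maps(net, predictor, planes, target_plane=0)
        n_pos = (32 - 8) // 4 + 1
        assert maps.channel_maps.shape == (4, n_pos, n_pos)
        assert np.all(maps.channel_maps >= 0.0)
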