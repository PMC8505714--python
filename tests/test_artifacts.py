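import numpy as np
import pytest
from scipy import stats

from mrcpdecode.artifacts import (
    reject_by_amplitude,
    reject_high_rt,
    reject_statistical_outliers,
    remove_ocular_components,
)
from mrcpdecode.io import ContinuousRecording, EpochSet
from mrcpdecode.synthetic import BehaviorModel


def _epochs(data, fs=100.0, labels=None):
    data = np.asarray(data, dtype=float)
    ch = [f"ch{i}" for i in range(data.shape[1])]
    t = np.arange(data.shape[2]) / fs
    return EpochSet(data, t, ch, fs, labels=labels)


class TestRejectHighRT:
    def test_strict_threshold(self):
        rep = reject_high_rt(np.arange(3), np.array([0.4, 2.0, 2.1]))
        assert list(rep.kept_mask) == [True, True, False]
        assert rep.table.loc[2, "reasons"] == "rt_gt_2s"

    def test_all_fast_kept(self):
        rep = reject_high_rt(np.arange(5), np.full(5, 0.5))
        assert rep.kept_mask.all()

    def test_no_movement_passes_vacuously(self):
        rep = reject_high_rt(np.arange(2), np.array([np.nan, 3.0]))
        assert list(rep.kept_mask) == [True, False]

    def test_negative_rt_is_data_error(self):
        rep = reject_high_rt(np.arange(1), np.array([-0.2]))
        assert rep.table.loc[0, "reasons"] == "channel_noise"

    def test_slow_trial_count_matches_generator_tail(self):
        # expected rejections from the two-component truncated-normal RT model
        model = BehaviorModel(slow_prob=0.1)
        rng = np.random.default_rng(17)
        rts = np.array([model.draw_rt(rng)[0] for _ in range(480)])
        rep = reject_high_rt(np.arange(480), rts)
        p = model.slow_prob * stats.norm.sf(2.0, model.slow_rt_mean_s,
                                            model.slow_rt_sd_s)
        p += (1 - model.slow_prob) * stats.norm.sf(2.0, model.rt_mean_s,
                                                   model.rt_sd_s)
        mean, sd = 480 * p, np.sqrt(480 * p * (1 - p))
        assert abs(rep.n_rejected - mean) < 3 * sd


class TestRejectByAmplitude:
    def test_single_sample_over_limit(self, rng):
        data = rng.normal(0, 10, (3, 2, 100))
        data[1, 0, 50] = 201.0
        rep = reject_by_amplitude(_epochs(data))
        assert list(rep.kept_mask) == [True, False, True]

    def test_boundary_inclusive(self):
        data = np.full((1, 1, 10), 200.0)
        assert reject_by_amplitude(_epochs(data)).kept_mask.all()

    def test_exactly_injected_trials_rejected(self, rng):
        # bursts in known trials, nothing else near the limit
        data = rng.normal(0, 5, (20, 4, 200))
        bad = [3, 11, 17]
        for i in bad:
            data[i, rng.integers(4), 100:120] += 300.0
        rep = reject_by_amplitude(_epochs(data))
        assert sorted(np.flatnonzero(~rep.kept_mask)) == bad

    def test_conservation(self, rng):
        rep = reject_by_amplitude(_epochs(rng.normal(0, 80, (30, 2, 50))))
        assert rep.n_rejected + rep.kept_mask.sum() == rep.n_total


class TestStatisticalOutliers:
    def test_gaussian_false_positive_rate(self):
        # 3-SD rule on clean single-channel Gaussian trials: ≤ 5% rejected
        # in at least 95% of seeded runs
        ok = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            rep, _ = reject_statistical_outliers(
                _epochs(rng.normal(size=(200, 1, 400)))
            )
            ok += rep.fraction_rejected <= 0.05
        assert ok >= 48

    def test_high_amplitude_trial_caught(self, rng):
        data = rng.normal(size=(60, 2, 300))
        data[13] *= 10.0
        rep, detail = reject_statistical_outliers(_epochs(data))
        assert not rep.kept_mask[13]
        assert detail.loc[13, "max_abs_z_joint_probability"] > 3.0

    def test_identical_trials_get_identical_scores(self, rng):
        data = rng.normal(size=(40, 1, 200))
        data[5] = data[21]
        _, detail = reject_statistical_outliers(_epochs(data))
        for col in ("max_abs_z_joint_probability", "max_abs_z_kurtosis"):
            assert detail.loc[5, col] == pytest.approx(detail.loc[21, col])

    def test_too_few_trials_warns_and_keeps(self, rng):
        with pytest.warns(UserWarning, match="skipped"):
            rep, _ = reject_statistical_outliers(_epochs(rng.normal(size=(5, 1, 50))))
        assert rep.kept_mask.all()

    def test_rejection_monotone_under_dominating_artifact(self, rng):
        # an added artifact that dominates the statistics must not rescue
        # an already-rejected trial
        data = rng.normal(size=(50, 1, 200))
        data[7] *= 12.0
        rep1, _ = reject_statistical_outliers(_epochs(data))
        assert not rep1.kept_mask[7]
        data2 = data.copy()
        data2[30] *= 15.0
        rep2, _ = reject_statistical_outliers(_epochs(data2))
        assert not rep2.kept_mask[7] and not rep2.kept_mask[30]


class TestReportMerge:
    def test_union_of_reasons_and_conservation(self):
        a = reject_high_rt(np.arange(3), np.array([2.5, 0.3, 0.4]))
        b = reject_by_amplitude(_epochs(np.concatenate([
            np.zeros((2, 1, 10)), np.full((1, 1, 10), 300.0)
        ])))
        m = a.merge(b)
        assert list(m.kept_mask) == [False, True, False]
        assert m.table.loc[0, "reasons"] == "rt_gt_2s"
        assert m.table.loc[2, "reasons"] == "amplitude"
        assert m.n_rejected + m.kept_mask.sum() == m.n_total


class TestOcularRemoval:
    def _blinky_recording(self, rng, n_samp=6000, blink_amp=60.0):
        fs = 100.0
        labels = ["F1", "F2", "FC1", "C1", "Cz", "C2", "CP1", "P1"]
        profile = np.array([1.0, 0.9, 0.35, 0.1, 0.08, 0.08, 0.04, 0.02])
        t = np.arange(n_samp) / fs
        blink_src = np.zeros(n_samp)
        for s in range(300, n_samp - 100, 700):
            blink_src[s:s + 40] += np.hanning(40)
        mrcp = np.sin(2 * np.pi * 1.1 * t)
        mrcp_profile = np.array([0.1, 0.1, 0.5, 0.8, 1.0, 0.7, 0.5, 0.2])
        noise = rng.normal(0, 1.0, (8, n_samp))
        data = (
            blink_amp * profile[:, None] * blink_src[None, :]
            + 8.0 * mrcp_profile[:, None] * mrcp[None, :]
            + noise
        )
        rec = ContinuousRecording(data, labels, fs)
        return rec, blink_src, mrcp

    def test_blinks_removed_signal_preserved(self, rng):
        rec, blink_src, mrcp = self._blinky_recording(rng)
        eog = rec.data[0]  # frontal channel as EOG reference
        cleaned, decomp = remove_ocular_components(rec, eog, seed=0)
        assert decomp.eye_flags.sum() >= 1
        f1 = cleaned.data[0]
        assert abs(np.corrcoef(f1, blink_src)[0, 1]) < 0.2
        cz = cleaned.data[rec.channel_labels.index("Cz")]
        assert np.corrcoef(cz, mrcp)[0, 1] > 0.9

    def test_no_blinks_no_flags(self):
        # calibration: clean data should flag nothing in ≥ 90% of runs
        ok = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            rec, _, _ = self._blinky_recording(rng, blink_amp=0.0)
            _, decomp = remove_ocular_components(rec, rec.data[0], seed=seed,
                                                 strict_convergence=False)
            ok += decomp.eye_flags.sum() == 0
        assert ok >= 9

    def test_forced_empty_flags_identity(self, rng):
        rec, _, _ = self._blinky_recording(rng)
        cleaned, decomp = remove_ocular_components(
            rec, rec.data[0], corr_threshold=2.0, frontal_threshold=2.0, seed=0
        )
        assert decomp.eye_flags.sum() == 0
        np.testing.assert_allclose(cleaned.data, rec.data, atol=1e-6)

    def test_mixing_unmixing_near_identity(self, rng):
        rec, _, _ = self._blinky_recording(rng)
        _, decomp = remove_ocular_components(rec, rec.data[0], seed=0)
        ident = decomp.mixing @ decomp.unmixing
        resid = rec.data - ident @ rec.data
        assert np.abs(resid).max() / np.abs(rec.data).max() < 1e-6

    def test_needs_enough_samples(self, rng):
        rec = ContinuousRecording(rng.normal(size=(8, 10)),
                                  [f"c{i}" for i in range(8)], 100.0)
        with pytest.raises(ValueError, match="samples"):
            remove_ocular_components(rec, np.zeros(10))
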