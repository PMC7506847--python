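"""Synthetic generator: phase structure, signal statistics, determinism."""

import numpy as np
import pytest

import fallcam as fc


def svm_of(trace):
    return fc.compute_svm(trace).values


def gyro_of(trace):
    return fc.compute_gyro_magnitude(trace).values


def max_run(mask):
    best = run = 0
    for v in mask:
        run = run + 1 if v else 0
        best = max(best, run)
    return best


class TestSimulateFall:
    def test_same_seed_is_bit_identical(self):
        a = fc.simulate_fall(fc.FallProfile(), fs=50.0, seed=42)
        b = fc.simulate_fall(fc.FallProfile(), fs=50.0, seed=42)
        assert np.array_equal(a.acc, b.acc)
        assert np.array_equal(a.gyro, b.gyro)
        assert a.fall_start_frame == b.fall_start_frame

    def test_phase_structure_and_fall_start(self, default_fall):
        tr = default_fall
        labels = np.asarray(tr.phase_labels)
        assert tr.trial_label == "fall"
        assert labels[0] == "standing"
        assert labels[-1] == "recovery"
        # fall start is the first frame of the early-fall phase
        ef = np.flatnonzero(labels == "early_fall")
        assert ef[0] == tr.fall_start_frame
        assert np.all(np.diff(ef) == 1), "early fall span is contiguous"

    @pytest.mark.parametrize("seed", range(5))
    def test_early_fall_span_covers_weightless_duration(self, seed):
        rng = np.random.default_rng(seed)
        prof = fc.sample_fall_profile(rng)
        tr = fc.simulate_fall(prof, fs=50.0, seed=seed)
        n_ef = int(np.sum(np.asarray(tr.phase_labels) == "early_fall"))
        assert 7 <= n_ef <= 12  # 0.14-0.24 s at 50 Hz

    def test_early_fall_gyro_below_threshold(self, default_fall):
        ef = np.asarray(default_fall.phase_labels) == "early_fall"
        assert gyro_of(default_fall)[ef].max() < 100.0

    def test_min_svm_over_early_fall_near_plateau(self):
        for seed in range(10):
            prof = fc.sample_fall_profile(np.random.default_rng(seed))
            tr = fc.simulate_fall(prof, fs=50.0, seed=seed)
            ef = np.asarray(tr.phase_labels) == "early_fall"
            lo = prof.plateau_g - prof.fluctuation_amp_g - 3 * prof.noise_acc_g
            hi = prof.plateau_g + prof.fluctuation_amp_g + 3 * prof.noise_acc_g
            assert lo <= svm_of(tr)[ef].min() <= hi

    def test_early_fall_mostly_inside_detection_band(self):
        """The weightless core is detectable by construction: most of its
        frames satisfy the joint SVM-band + gyro condition."""
        for seed in range(10):
            prof = fc.sample_fall_profile(np.random.default_rng(100 + seed))
            tr = fc.simulate_fall(prof, fs=50.0, seed=seed)
            ef = np.asarray(tr.phase_labels) == "early_fall"
            svm, gyro = svm_of(tr)[ef], gyro_of(tr)[ef]
            frac = np.mean((svm >= 0.6) & (svm <= 0.9) & (gyro < 100))
            assert frac > 0.5

    def test_impact_spike_dominates_trace(self, default_fall):
        prof = fc.FallProfile()
        peak = svm_of(default_fall).max()
        assert peak > 2.0
        assert peak == pytest.approx(prof.impact_peak_g, rel=0.1)

    def test_invalid_plateau_rejected(self):
        with pytest.raises(ValueError, match="plateau_g"):
            fc.simulate_fall(fc.FallProfile(plateau_g=1.0), fs=50.0, seed=0)

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError, match="fs"):
            fc.simulate_fall(fc.FallProfile(), fs=10.0, seed=0)


class TestSimulateAdl:
    def test_walk_dips_shorter_than_tenth_second(self):
        for seed in range(10):
            prof = fc.sample_adl_profile("walk", np.random.default_rng(seed))
            tr = fc.simulate_adl(prof, fs=50.0, seed=seed)
            assert max_run(svm_of(tr) < 0.95) < 5  # < 0.1 s at 50 Hz

    def test_walk_never_dwells_in_fall_band(self):
        for seed in range(10):
            prof = fc.sample_adl_profile("walk", np.random.default_rng(seed))
            tr = fc.simulate_adl(prof, fs=50.0, seed=seed)
            svm = svm_of(tr)
            assert max_run((svm >= 0.6) & (svm <= 0.9)) < 10

    def test_lie_down_has_high_angular_velocity(self):
        prof = fc.sample_adl_profile("lie_down", np.random.default_rng(0))
        tr = fc.simulate_adl(prof, fs=50.0, seed=0)
        assert gyro_of(tr).max() > 100.0

    def test_lie_down_band_frames_are_gyro_vetoed(self):
        """Lying declines through the fall SVM band, but with the trunk
        rotating above 100 deg/s, so band frames do not qualify."""
        prof = fc.sample_adl_profile("lie_down", np.random.default_rng(1))
        tr = fc.simulate_adl(prof, fs=50.0, seed=1)
        svm, gyro = svm_of(tr), gyro_of(tr)
        in_band = (svm >= 0.6) & (svm <= 0.9)
        assert in_band.sum() > 5  # the ambiguity is real...
        assert np.mean(gyro[in_band] >= 100.0) > 0.9  # ...and vetoed

    def test_jump_flight_below_band(self):
        prof = fc.sample_adl_profile("jump", np.random.default_rng(2))
        tr = fc.simulate_adl(prof, fs=50.0, seed=2)
        assert svm_of(tr).min() < 0.6

    def test_stand_up_never_leaves_point_nine(self):
        for seed in range(5):
            prof = fc.sample_adl_profile(
                "stand_up", np.random.default_rng(seed)
            )
            tr = fc.simulate_adl(prof, fs=50.0, seed=seed)
            assert max_run(svm_of(tr) < 0.9) <= 2

    def test_zero_noise_stand_is_exactly_one_g(self):
        prof = fc.AdlProfile(kind="stand", noise_acc_g=0.0, noise_gyro_dps=0.0)
        tr = fc.simulate_adl(prof, fs=50.0, seed=0)
        np.testing.assert_allclose(svm_of(tr), 1.0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            fc.simulate_adl(fc.AdlProfile(kind="cartwheel"), fs=50.0, seed=0)

    def test_same_seed_is_deterministic(self):
        prof = fc.sample_adl_profile("jog", np.random.default_rng(9))
        a = fc.simulate_adl(prof, fs=50.0, seed=9)
        b = fc.simulate_adl(prof, fs=50.0, seed=9)
        assert np.array_equal(a.acc, b.acc)


class TestGenerateDataset:
    def test_empty_counts_give_empty_manifest(self, tmp_path):
        manifest = fc.generate_dataset(0, 0, out_dir=tmp_path)
        assert len(manifest) == 0

    def test_corpus_shape_and_labels(self, tmp_path):
        manifest = fc.generate_dataset(6, 4, fs=50.0, seed=1, out_dir=tmp_path)
        assert len(manifest) == 10
        assert (manifest.trial_label == "fall").sum() == 6
        assert all((tmp_path / p).exists() for p in manifest.path)

    def test_regeneration_is_byte_identical(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        fc.generate_dataset(3, 3, fs=50.0, seed=7, out_dir=d1)
        fc.generate_dataset(3, 3, fs=50.0, seed=7, out_dir=d2)
        for f1 in sorted(d1.iterdir()):
            assert f1.read_bytes() == (d2 / f1.name).read_bytes()


def test_training_windows_have_classifier_shape():
    windows = fc.make_training_windows(3, 3, seed=0)
    assert len(windows) == 6
    assert all(w.data.shape == (6, 100) for w in windows)
    assert sum(w.label == "fall" for w in windows) == 3
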