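"""Core trace types, derived signals, windowing and I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fallcam as fc
from fallcam.imu import G_TO_MS2

from conftest import make_trace

finite = st.floats(-10, 10, allow_nan=False)


class TestDerivedSignals:
    @pytest.mark.parametrize(
        "frame, expected",
        [
            ((0, 1, 0), 1.0),      # pure-gravity rest
            ((0, 0, 0), 0.0),      # free fall
            ((0.6, 0.8, 0), 1.0),  # 3-4-5 identity
        ],
    )
    def test_svm_known_values(self, frame, expected):
        tr = make_trace([frame])
        assert fc.compute_svm(tr).values[0] == pytest.approx(expected)

    @pytest.mark.parametrize(
        "frame, expected", [((0, 0, 0), 0.0), ((100, 0, 0), 100.0)]
    )
    def test_gyro_magnitude_known_values(self, frame, expected):
        tr = make_trace([(0, 1, 0)], gyro=[frame])
        assert fc.compute_gyro_magnitude(tr).values[0] == pytest.approx(
            expected
        )

    @given(
        rows=st.lists(
            st.tuples(finite, finite, finite), min_size=1, max_size=20
        )
    )
    @settings(deadline=None)
    def test_norms_match_summation_oracle(self, rows):
        """Both magnitudes equal an independently coded sum-of-squares."""
        arr = np.array(rows, dtype=float)
        tr = make_trace(arr, gyro=arr)
        for series in (fc.compute_svm(tr), fc.compute_gyro_magnitude(tr)):
            for i, (x, y, z) in enumerate(rows):
                oracle = (x * x + y * y + z * z) ** 0.5
                assert abs(series.values[i] - oracle) < 1e-12

    @given(
        frame=st.tuples(finite, finite, finite),
        scale=st.floats(-5, 5, allow_nan=False),
    )
    @settings(deadline=None)
    def test_permutation_invariance_and_scale_equivariance(self, frame, scale):
        base = fc.compute_svm(make_trace([frame])).values[0]
        perm = fc.compute_svm(make_trace([frame[::-1]])).values[0]
        scaled = fc.compute_svm(
            make_trace([tuple(scale * v for v in frame)])
        ).values[0]
        assert perm == pytest.approx(base, abs=1e-12)
        assert scaled == pytest.approx(abs(scale) * base, rel=1e-9, abs=1e-9)

    def test_empty_trace_rejected(self):
        tr = make_trace(np.empty((0, 3)))
        with pytest.raises(ValueError, match="empty"):
            fc.compute_svm(tr)
        with pytest.raises(ValueError, match="empty"):
            fc.compute_gyro_magnitude(tr)


class TestWindowing:
    @pytest.mark.parametrize(
        "fs, duration, expected",
        [(200.0, 1.0, 200), (50.0, 0.4, 20), (50.0, 0.0, 0)],
    )
    def test_extract_window_lengths(self, fs, duration, expected):
        tr = make_trace(np.zeros((300, 3)), fs=fs)
        assert len(fc.extract_window(tr, 10, duration)) == expected

    def test_extract_window_overrun_is_an_error(self):
        tr = make_trace(np.zeros((30, 3)))
        with pytest.raises(ValueError, match="insufficient"):
            fc.extract_window(tr, 20, 0.4)

    def test_nested_extraction_equals_direct(self, default_fall):
        outer = fc.extract_window(default_fall, 10, 1.0)
        nested = fc.extract_window(outer, 0, 0.4)
        direct = fc.extract_window(default_fall, 10, 0.4)
        np.testing.assert_allclose(nested.acc, direct.acc)
        np.testing.assert_allclose(nested.gyro, direct.gyro)

    def test_resample_decimates_exact_multiples(self):
        acc = np.column_stack([np.arange(200.0)] * 3)
        tr = make_trace(acc, fs=200.0)
        win = fc.resample_to_window(tr, 100)
        np.testing.assert_allclose(win.data[0], np.arange(0.0, 200.0, 2.0))

    def test_resample_is_identity_at_target_length(self):
        acc = np.random.default_rng(0).normal(size=(100, 3))
        tr = make_trace(acc)
        win = fc.resample_to_window(tr, 100)
        np.testing.assert_allclose(win.data[:3], acc.T)

    def test_resample_interpolation_preserves_constants(self):
        tr = make_trace(np.full((50, 3), 0.7))
        win = fc.resample_to_window(tr, 100)
        np.testing.assert_allclose(win.data[:3], 0.7)

    def test_decimation_preserves_min_max_bounds(self):
        rng = np.random.default_rng(1)
        acc = rng.normal(size=(300, 3))
        tr = make_trace(acc, fs=150.0)
        win = fc.resample_to_window(tr, 100)
        assert win.data.min() >= tr.channels.min()
        assert win.data.max() <= tr.channels.max()

    def test_resample_rejects_empty_segment(self):
        tr = make_trace(np.empty((0, 3)))
        with pytest.raises(ValueError, match="empty"):
            fc.resample_to_window(tr, 100)


class TestTraceValidation:
    def test_nonuniform_timestamps_rejected(self):
        with pytest.raises(ValueError, match="uniform"):
            fc.ImuTrace(
                t=np.array([0.0, 0.02, 0.06]),
                acc=np.zeros((3, 3)),
                gyro=np.zeros((3, 3)),
                fs=50.0,
            )

    def test_fall_start_frame_must_index_a_frame(self):
        with pytest.raises(ValueError, match="fall_start_frame"):
            make_trace(np.zeros((10, 3)), fall_start_frame=10)


class TestIO:
    def test_trace_csv_roundtrip(self, tmp_path, default_fall):
        path = tmp_path / "fall.csv"
        fc.write_trace_csv(default_fall, path)
        back = fc.read_trace_csv(
            path, trial_label="fall",
            fall_start_frame=default_fall.fall_start_frame,
        )
        np.testing.assert_allclose(back.acc, default_fall.acc, atol=1e-6)
        np.testing.assert_allclose(back.gyro, default_fall.gyro, atol=1e-6)
        assert back.fs == pytest.approx(50.0, rel=1e-3)
        assert list(back.phase_labels) == list(default_fall.phase_labels)

    def test_si_units_converted_on_read(self, tmp_path):
        tr = make_trace(
            np.full((10, 3), G_TO_MS2), gyro=np.full((10, 3), np.pi)
        )
        path = tmp_path / "si.csv"
        fc.write_trace_csv(tr, path)
        back = fc.read_trace_csv(path, acc_unit="m/s2", gyro_unit="rad/s")
        np.testing.assert_allclose(back.acc, 1.0, atol=1e-5)
        np.testing.assert_allclose(back.gyro, 180.0, atol=1e-3)

    def test_manifest_roundtrip_and_loading(self, tmp_path):
        fc.generate_dataset(2, 2, fs=50.0, seed=3, out_dir=tmp_path)
        traces = fc.load_dataset(tmp_path / "manifest.csv")
        assert len(traces) == 4
        labels = sorted(tr.trial_label for tr in traces)
        assert labels == ["fall", "fall", "non_fall", "non_fall"]
        assert all(
            tr.fall_start_frame is not None
            for tr in traces
            if tr.trial_label == "fall"
        )


def test_kalman_smoothing_reduces_noise_variance():
    rng = np.random.default_rng(5)
    acc = np.tile([0.0, 1.0, 0.0], (400, 1)) + rng.normal(0, 0.05, (400, 3))
    tr = make_trace(acc)
    sm = fc.kalman_smooth(tr)
    assert np.var(sm.acc[:, 1]) < 0.5 * np.var(tr.acc[:, 1])
    # steady-state estimate stays near the true signal
    assert abs(sm.acc[100:, 1].mean() - 1.0) < 0.02
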