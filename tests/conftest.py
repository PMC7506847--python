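import numpy as np
import pytest

import fallcam as fc


def make_trace(acc, gyro=None, fs=50.0, **kw):
    """Build a trace from raw (n, 3) arrays with a uniform time base."""
    acc = np.asarray(acc, dtype=float)
    if acc.ndim == 1:
        acc = acc[None, :]
    n = len(acc)
    gyro = np.zeros((n, 3)) if gyro is None else np.asarray(gyro, dtype=float)
    return fc.ImuTrace(t=np.arange(n) / fs, acc=acc, gyro=gyro, fs=fs, **kw)


def svm_trace(svm, gyro_mag=None, fs=50.0, **kw):
    """Trace whose per-frame SVM equals the given series (ay carries it)."""
    svm = np.asarray(svm, dtype=float)
    acc = np.column_stack([np.zeros_like(svm), svm, np.zeros_like(svm)])
    gyro = None
    if gyro_mag is not None:
        g = np.asarray(gyro_mag, dtype=float)
        gyro = np.column_stack([g, np.zeros_like(g), np.zeros_like(g)])
    return make_trace(acc, gyro, fs=fs, **kw)


@pytest.fixture(scope="session")
def default_fall():
    return fc.simulate_fall(fc.FallProfile(), fs=50.0, seed=7)


@pytest.fixture(scope="session")
def trained_model():
    """A small but genuinely trained classifier shared across tests."""
    windows = fc.make_training_windows(40, 40, seed=11)
    train_w, test_w = fc.split_windows(windows, ratio=2.3, seed=11)
    model = fc.build_classifier(seed=11)
    model = fc.train(
        model, train_w, fc.TrainSpec(epochs=8, seed=11), val_windows=test_w
    )
    return model, train_w, test_w
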