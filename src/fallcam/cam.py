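"""Class activation mapping for the 1D classifier.

The GAP head makes the network's evidence localizable: with ``S_k(x)`` the
last conv layer's output on channel k and ``w_kc`` the head weight of
channel k for class c, the class activation map

    M_c(x) = sum_k w_kc * S_k(x)

indicates how important temporal location x is for classifying the window
as class c, and its temporal mean equals the class logit minus the head
bias.  For visualization the map is min-max normalized to integers in
[0, 255] and upsampled to the input length, giving the familiar
purple-to-yellow hot map over the raw signals.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cnn import FeatureMaps, TrainedClassifier, forward
from .imu import ClassifierWindow


@dataclass
class ActivationMap:
    raw: np.ndarray          # M_c(x), length L
    normalized: np.ndarray   # ints in [0, 255], length L
    upsampled: np.ndarray    # ints in [0, 255], input length
    class_index: int


def compute_cam(
    model: TrainedClassifier,
    window: ClassifierWindow | np.ndarray,
    class_index: int,
    feature_maps: FeatureMaps | None = None,
) -> np.ndarray:
    """Raw class activation map ``M_c(x) = sum_k w_kc S_k(x)``.

    ``feature_maps`` may be passed to reuse a previous forward pass.
    """
    if not 0 <= class_index < model.config.n_classes:
        raise ValueError(f"class_index {class_index} out of range")
    if feature_maps is None:
        feature_maps, _ = forward(model, window)
    return model.fc_weights[class_index] @ feature_maps.S


def normalize_map(raw: np.ndarray) -> np.ndarray:
    """Affine min-max map to integers 0..255 (round half up).

    A constant map carries no localization signal and maps to all zeros.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValueError("cannot normalize an empty map")
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.zeros(raw.shape, dtype=int)
    scaled = 255.0 * (raw - lo) / (hi - lo)
    return np.floor(scaled + 0.5).astype(int)


def upsample_map(
    normalized: np.ndarray, target_len: int = 100, mode: str = "linear"
) -> np.ndarray:
    """Stretch a length-L map onto ``target_len`` positions.

    Linear interpolation on uniformly spaced positions spanning
    ``[0, target_len - 1]`` (endpoints preserved), re-rounded to 0..255.
    ``mode="nearest"`` reproduces exact step plots instead.
    """
    normalized = np.asarray(normalized, dtype=float)
    if normalized.size == 0:
        raise ValueError("cannot upsample an empty map")
    if target_len < 1:
        raise ValueError("target_len must be >= 1")
    L = len(normalized)
    x = np.arange(target_len)
    xp = np.linspace(0.0, target_len - 1.0, L) if L > 1 else np.array([0.0])
    if mode == "linear":
        vals = np.interp(x, xp, normalized)
    elif mode == "nearest":
        nearest = np.abs(x[:, None] - xp[None, :]).argmin(axis=1)
        vals = normalized[nearest]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return np.floor(vals + 0.5).astype(int)


def activation_map(
    model: TrainedClassifier,
    window: ClassifierWindow | np.ndarray,
    class_index: int,
    target_len: int | None = None,
) -> ActivationMap:
    """Full raw -> normalized -> upsampled pipeline for one window."""
    raw = compute_cam(model, window, class_index)
    normalized = normalize_map(raw)
    upsampled = upsample_map(
        normalized, target_len or model.config.input_len
    )
    return ActivationMap(
        raw=raw,
        normalized=normalized,
        upsampled=upsampled,
        class_index=class_index,
    )


def contiguous_highlight(
    upsampled: np.ndarray, intensity_threshold: int = 200
) -> list[tuple[int, int]]:
    """Maximal runs of frames at or above an intensity, as [start, stop).

    The run lengths over fall windows are what calibrates the weightless
    duration statistic (7-12 highlighted frames at 50 Hz).
    """
    if not 0 <= intensity_threshold <= 255:
        raise ValueError("intensity_threshold must lie in [0, 255]")
    mask = np.asarray(upsampled) >= intensity_threshold
    edges = np.flatnonzero(np.diff(np.r_[0, mask.astype(int), 0]))
    return [
        (int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)
    ]


def export_hotmap_csv(
    amap: ActivationMap, path: str | Path
) -> pd.DataFrame:
    """Write the upsampled map as a ``frame,intensity`` CSV."""
    df = pd.DataFrame(
        {"frame": np.arange(len(amap.upsampled)), "intensity": amap.upsampled}
    )
    df.to_csv(path, index=False)
    return df


def render_hotmap(
    window: ClassifierWindow,
    amap: ActivationMap,
    path: str | Path,
) -> None:
    """Render the six channels colored by CAM intensity (PNG convenience)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = ["ax", "ay", "az", "gx", "gy", "gz"]
    fig, axes = plt.subplots(6, 1, sharex=True, figsize=(8, 9))
    x = np.arange(window.data.shape[1])
    colors = plt.cm.viridis(amap.upsampled / 255.0)
    for ch, (ax_, name) in enumerate(zip(axes, names)):
        ax_.scatter(x, window.data[ch], c=colors, s=6)
        ax_.plot(x, window.data[ch], color="0.8", lw=0.5, zorder=0)
        ax_.set_ylabel(name)
    axes[-1].set_xlabel("frame")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
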