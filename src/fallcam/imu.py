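"""Core IMU domain types, derived signals, windowing and trace I/O.

Conventions
-----------
* Acceleration is expressed in units of ``g`` (1 g = 9.80665 m/s^2) and
  angular velocity in degrees per second.  Inputs recorded in m/s^2 or
  rad/s are converted at the reading boundary, never downstream.
* The sensor is waist-mounted with the y-axis along gravity, so a subject
  standing still reads ``(ax, ay, az) ~ (0, 1, 0) g``.
* Frame indices are 0-based and windows are half-open ``[start, start+n)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

G_TO_MS2 = 9.80665
RAD_TO_DEG = 180.0 / math.pi

#: Phase vocabulary used by per-frame labels.
PHASE_STANDING = "standing"
PHASE_EARLY_FALL = "early_fall"
PHASE_IMPACT = "impact"
PHASE_RECOVERY = "recovery"
ADL_PHASES = ("adl_walk", "adl_jog", "adl_stand_up", "adl_lie_down", "adl_jump")
ALL_PHASES = (
    PHASE_STANDING,
    PHASE_EARLY_FALL,
    PHASE_IMPACT,
    PHASE_RECOVERY,
) + ADL_PHASES

LABEL_FALL = "fall"
LABEL_NON_FALL = "non_fall"

TRACE_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz"]


class ImuFrame(NamedTuple):
    """A single timestamped 6-channel inertial sample."""

    t: float
    ax: float
    ay: float
    az: float
    gx: float
    gy: float
    gz: float
    phase_label: str | None = None


@dataclass
class ImuTrace:
    """A uniformly sampled 6-channel inertial recording.

    Parameters
    ----------
    t
        Seconds from trace start, strictly increasing, spaced ``1/fs``.
    acc
        ``(n, 3)`` tri-axial acceleration in g.
    gyro
        ``(n, 3)`` tri-axial angular velocity in deg/s.
    fs
        Sampling rate in Hz.
    trial_label
        ``"fall"`` or ``"non_fall"`` for the whole trial.
    fall_start_frame
        Index of the first frame whose acceleration magnitude drops below
        the fall-start level; defined for fall trials only.
    phase_labels
        Optional per-frame phase annotation (see :data:`ALL_PHASES`).
    """

    t: np.ndarray
    acc: np.ndarray
    gyro: np.ndarray
    fs: float
    trial_label: str = LABEL_NON_FALL
    fall_start_frame: int | None = None
    phase_labels: np.ndarray | None = None
    trial_id: str | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.phase_labels is not None:
            self.phase_labels = np.asarray(self.phase_labels, dtype=object)
        self.validate()

    def validate(self) -> None:
        n = len(self.t)
        if self.acc.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise ValueError(
                f"acc/gyro must be (n, 3) with n={n}; "
                f"got {self.acc.shape} and {self.gyro.shape}"
            )
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if n > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if not np.allclose(dt, 1.0 / self.fs, rtol=1e-3, atol=1e-6):
                raise ValueError("timestamps must be uniformly spaced at 1/fs")
        if self.trial_label not in (LABEL_FALL, LABEL_NON_FALL):
            raise ValueError(f"unknown trial_label {self.trial_label!r}")
        if self.fall_start_frame is not None and not (
            0 <= self.fall_start_frame < n
        ):
            raise ValueError(
                f"fall_start_frame {self.fall_start_frame} outside [0, {n})"
            )
        if self.phase_labels is not None and len(self.phase_labels) != n:
            raise ValueError("phase_labels must match trace length")

    def __len__(self) -> int:
        return len(self.t)

    def frame(self, i: int) -> ImuFrame:
        label = None if self.phase_labels is None else self.phase_labels[i]
        return ImuFrame(
            self.t[i], *self.acc[i], *self.gyro[i], phase_label=label
        )

    @property
    def channels(self) -> np.ndarray:
        """``(6, n)`` array ordered (ax, ay, az, gx, gy, gz)."""
        return np.vstack([self.acc.T, self.gyro.T])

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs


@dataclass
class DerivedSeries:
    """A per-frame scalar series derived from a trace (non-negative)."""

    values: np.ndarray
    kind: str  # {"svm_g", "gyro_mag_dps"}

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ClassifierWindow:
    """A fixed-length resampled segment: the classifier's input tensor.

    ``data`` is a ``(6, target_len)`` array ordered (ax, ay, az, gx, gy, gz).
    """

    data: np.ndarray
    source_fs: float
    origin_frame: int = 0
    label: str = LABEL_NON_FALL

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != 6:
            raise ValueError(f"window must be (6, n), got {self.data.shape}")


def compute_svm(trace: ImuTrace) -> DerivedSeries:
    """Sum vector magnitude of the tri-axial acceleration, in g.

    The SVM reads ~1 g at rest, dips below 1 g during weightlessness and
    spikes far above 1 g at ground impact, which makes it the primary
    fall-phase feature.
    """
    if len(trace) == 0:
        raise ValueError("cannot compute SVM of an empty trace")
    return DerivedSeries(np.linalg.norm(trace.acc, axis=1), "svm_g")


def compute_gyro_magnitude(trace: ImuTrace) -> DerivedSeries:
    """Euclidean norm of the tri-axial angular velocity, in deg/s.

    The norm is rotation-invariant, so the feature does not depend on how
    the sensor happens to be oriented around the gravity axis.
    """
    if len(trace) == 0:
        raise ValueError("cannot compute gyro magnitude of an empty trace")
    return DerivedSeries(np.linalg.norm(trace.gyro, axis=1), "gyro_mag_dps")


def extract_window(
    trace: ImuTrace, start_frame: int, duration_s: float
) -> ImuTrace:
    """Cut ``round(duration_s * fs)`` frames starting at ``start_frame``.

    The returned trace is rebased so its timestamps start at 0; the
    fall-start index is carried over when it lies inside the window.
    """
    if not 0 <= start_frame <= len(trace):
        raise IndexError(f"start_frame {start_frame} outside trace")
    n = round(duration_s * trace.fs)
    stop = start_frame + n
    if stop > len(trace):
        raise ValueError(
            f"window [{start_frame}, {stop}) overruns trace of length "
            f"{len(trace)}: insufficient data"
        )
    fsf = trace.fall_start_frame
    if fsf is not None and start_frame <= fsf < stop:
        fsf = fsf - start_frame
    else:
        fsf = None
    labels = (
        None
        if trace.phase_labels is None
        else trace.phase_labels[start_frame:stop]
    )
    t = trace.t[start_frame:stop]
    return ImuTrace(
        t=t - (t[0] if n else 0.0),
        acc=trace.acc[start_frame:stop],
        gyro=trace.gyro[start_frame:stop],
        fs=trace.fs,
        trial_label=trace.trial_label,
        fall_start_frame=fsf,
        phase_labels=labels,
        trial_id=trace.trial_id,
    )


def resample_to_window(
    segment: ImuTrace, target_len: int = 100, origin_frame: int = 0
) -> ClassifierWindow:
    """Resample a segment to the classifier's fixed input length.

    When the source length is an exact integer multiple ``k * target_len``
    the output is pure decimation (every k-th sample, starting at index 0),
    matching the 200-to-100 subsampling used on 1 s snippets recorded at
    200 Hz.  Otherwise each channel is linearly interpolated on a uniform
    index grid.
    """
    m = len(segment)
    if m == 0:
        raise ValueError("cannot resample an empty segment")
    if target_len < 1:
        raise ValueError("target_len must be >= 1")
    chans = segment.channels
    if m % target_len == 0:
        k = m // target_len
        data = chans[:, ::k]
    else:
        x = np.linspace(0.0, m - 1, target_len)
        xp = np.arange(m)
        data = np.vstack([np.interp(x, xp, c) for c in chans])
    return ClassifierWindow(
        data=data,
        source_fs=segment.fs,
        origin_frame=origin_frame,
        label=segment.trial_label,
    )


def kalman_smooth(
    trace: ImuTrace,
    process_var: float = 1e-4,
    measurement_var: float = 4e-4,
) -> ImuTrace:
    """Optional per-channel scalar Kalman filter (constant-signal model).

    Disabled by default throughout the package: the synthetic generator
    already emulates the band-limited stream a filtered sensor produces.
    Exposed for users feeding raw, unfiltered recordings.
    """
    if len(trace) == 0:
        return trace

    def _filter(col: np.ndarray) -> np.ndarray:
        out = np.empty_like(col)
        x, p = col[0], measurement_var
        out[0] = x
        for i in range(1, len(col)):
            p = p + process_var
            k = p / (p + measurement_var)
            x = x + k * (col[i] - x)
            p = (1.0 - k) * p
            out[i] = x
        return out

    acc = np.column_stack([_filter(trace.acc[:, j]) for j in range(3)])
    gyro = np.column_stack([_filter(trace.gyro[:, j]) for j in range(3)])
    return replace(trace, acc=acc, gyro=gyro)


# ---------------------------------------------------------------------------
# Trace and manifest I/O
# ---------------------------------------------------------------------------

def write_trace_csv(trace: ImuTrace, path: str | Path) -> None:
    """Write ``t,ax,ay,az,gx,gy,gz[,phase_label]`` (units: s, g, deg/s)."""
    df = pd.DataFrame(
        np.column_stack([trace.t, trace.acc, trace.gyro]),
        columns=TRACE_COLUMNS,
    )
    if trace.phase_labels is not None:
        df["phase_label"] = trace.phase_labels
    df.to_csv(path, index=False, float_format="%.6f")


def read_trace_csv(
    path: str | Path,
    fs: float | None = None,
    trial_label: str = LABEL_NON_FALL,
    fall_start_frame: int | None = None,
    acc_unit: str = "g",
    gyro_unit: str = "dps",
    trial_id: str | None = None,
) -> ImuTrace:
    """Read a trace CSV, converting units at the boundary.

    ``acc_unit`` may be ``"g"`` or ``"m/s2"``; ``gyro_unit`` may be
    ``"dps"`` or ``"rad/s"``.  The sampling rate is inferred from the
    timestamp spacing when not given.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace CSV {path} lacks columns {missing}")
    acc = df[["ax", "ay", "az"]].to_numpy(dtype=float)
    gyro = df[["gx", "gy", "gz"]].to_numpy(dtype=float)
    if acc_unit == "m/s2":
        acc = acc / G_TO_MS2
    elif acc_unit != "g":
        raise ValueError(f"unknown acc_unit {acc_unit!r}")
    if gyro_unit == "rad/s":
        gyro = gyro * RAD_TO_DEG
    elif gyro_unit != "dps":
        raise ValueError(f"unknown gyro_unit {gyro_unit!r}")
    t = df["t"].to_numpy(dtype=float)
    if fs is None:
        if len(t) < 2:
            raise ValueError("cannot infer fs from a single-frame trace")
        fs = 1.0 / float(np.median(np.diff(t)))
    labels = (
        df["phase_label"].to_numpy(dtype=object)
        if "phase_label" in df.columns
        else None
    )
    return ImuTrace(
        t=t,
        acc=acc,
        gyro=gyro,
        fs=fs,
        trial_label=trial_label,
        fall_start_frame=fall_start_frame,
        phase_labels=labels,
        trial_id=trial_id,
    )


MANIFEST_COLUMNS = ["trial_id", "path", "trial_label", "fall_start_frame", "fs"]


def write_manifest(rows: Iterable[dict], path: str | Path) -> pd.DataFrame:
    """Write the dataset manifest CSV (one row per trace file)."""
    df = pd.DataFrame(list(rows), columns=MANIFEST_COLUMNS)
    df.to_csv(path, index=False)
    return df


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} lacks columns {missing}")
    return df


def load_dataset(manifest_path: str | Path) -> list[ImuTrace]:
    """Load every trace referenced by a manifest, resolving relative paths."""
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    traces = []
    for row in df.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = manifest_path.parent / p
        fsf = None if pd.isna(row.fall_start_frame) else int(row.fall_start_frame)
        traces.append(
            read_trace_csv(
                p,
                fs=float(row.fs),
                trial_label=str(row.trial_label),
                fall_start_frame=fsf,
                trial_id=str(row.trial_id),
            )
        )
    return traces
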