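"""Offline adapter stub for MobiAct-style recordings.

The public MobiAct corpus distributes one CSV per trial with columns

    timestamp, rel_time, acc_x, acc_y, acc_z, gyro_x, gyro_y, gyro_z,
    azimuth, pitch, roll, label

sampled at 200 Hz, acceleration in m/s^2 and angular velocity in rad/s,
with a per-frame activity label (e.g. STD, WAL, FOL, FKL, ...).  This
module only documents that layout and converts a single such file into the
package's native units; it performs no download and is not required by any
other component.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .imu import G_TO_MS2, LABEL_FALL, LABEL_NON_FALL, RAD_TO_DEG, ImuTrace

#: MobiAct activity codes that denote falls
FALL_CODES = frozenset({"FOL", "FKL", "BSC", "SDL"})

COLUMNS = [
    "timestamp", "rel_time", "acc_x", "acc_y", "acc_z",
    "gyro_x", "gyro_y", "gyro_z", "azimuth", "pitch", "roll", "label",
]


def load_mobiact_trial(path: str | Path, fs: float = 200.0) -> ImuTrace:
    """Read one MobiAct-layout CSV into an :class:`ImuTrace`.

    Units are converted at the boundary (m/s^2 -> g, rad/s -> deg/s); the
    trial label is ``fall`` when any frame carries a fall activity code,
    and the fall start is the first such frame.
    """
    df = pd.read_csv(path)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path} is not MobiAct-layout: missing {missing}")
    labels = df["label"].astype(str).to_numpy()
    is_fall = [lab in FALL_CODES for lab in labels]
    n = len(df)
    return ImuTrace(
        t=(df["rel_time"] - df["rel_time"].iloc[0]).to_numpy(dtype=float),
        acc=df[["acc_x", "acc_y", "acc_z"]].to_numpy(dtype=float) / G_TO_MS2,
        gyro=df[["gyro_x", "gyro_y", "gyro_z"]].to_numpy(dtype=float)
        * RAD_TO_DEG,
        fs=fs,
        trial_label=LABEL_FALL if any(is_fall) else LABEL_NON_FALL,
        fall_start_frame=is_fall.index(True) if any(is_fall) else None,
        phase_labels=None,
        trial_id=Path(path).stem,
    )
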