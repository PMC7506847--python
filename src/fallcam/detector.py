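"""Streaming pre-impact threshold detector.

The detector watches the acceleration sum vector magnitude (SVM) and the
angular-velocity magnitude frame by frame.  When the SVM crosses from at
or above 0.95 g to below it (a candidate fall start), the next 0.4 s of
frames are evaluated against a joint per-frame condition — SVM within
0.6-0.9 g (inclusive) and gyro magnitude below 100 deg/s (exclusive) — and
the candidate is declared a fall when at least half the window qualifies.
The verdict lands exactly ``round(0.4 * fs)`` frames after the start
frame: 400 ms at any sampling rate.  After a verdict the detector re-arms
only once the SVM has returned to at least 0.95 g, so each contiguous
sub-threshold excursion raises at most one alarm.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .imu import ImuTrace, compute_gyro_magnitude, compute_svm

VERDICT_FALL = "fall"
VERDICT_REJECTED = "rejected"


@dataclass(frozen=True)
class DetectorConfig:
    """Thresholds of the windowed detector (defaults are the calibrated
    values: 0.95 g start, 0.6-0.9 g band, 100 deg/s gyro, 0.4 s window,
    half-rule decision)."""

    svm_start_g: float = 0.95
    svm_band_g: tuple[float, float] = (0.6, 0.9)
    gyro_max_dps: float = 100.0
    window_s: float = 0.4
    decision_fraction: float = 0.5
    fs: float = 50.0

    @property
    def n_window(self) -> int:
        return round(self.window_s * self.fs)

    def validate(self) -> None:
        lo, hi = self.svm_band_g
        if not lo < hi < self.svm_start_g:
            raise ValueError(
                "band must satisfy lower < upper < svm_start_g"
            )
        if self.n_window < 1:
            raise ValueError("window must span at least one frame")
        if not 0.0 < self.decision_fraction <= 1.0:
            raise ValueError("decision_fraction must lie in (0, 1]")
        if self.fs <= 0:
            raise ValueError("fs must be positive")


@dataclass
class DetectionEvent:
    start_frame: int
    decision_frame: int
    qualifying_count: int
    latency_ms: float
    verdict: str


def frame_qualifies(
    svm_g: float, gyro_dps: float, config: DetectorConfig | None = None
) -> bool:
    """Joint per-frame early-fall condition.

    SVM band inclusive on both edges, gyro threshold exclusive.
    """
    config = config or DetectorConfig()
    lo, hi = config.svm_band_g
    return bool(lo <= svm_g <= hi) and bool(gyro_dps < config.gyro_max_dps)


def decision_rule(
    qualifying_count: int, n: int, decision_fraction: float = 0.5
) -> str:
    """Half-rule verdict: fall iff count >= ceil(decision_fraction * n)."""
    if not 0 <= qualifying_count <= n:
        raise ValueError("qualifying_count must lie in [0, n]")
    needed = math.ceil(decision_fraction * n)
    return VERDICT_FALL if qualifying_count >= needed else VERDICT_REJECTED


class StreamingDetector:
    """Frame-by-frame detector; feed() returns an event at decision frames.

    The state machine has three modes: waiting for the SVM to reach the
    start level (initial, and after every verdict), armed-and-idle (ready
    to trigger on a falling edge), and evaluating a candidate window.
    Each frame is processed exactly once; a verdict becomes available when
    the last window frame has been consumed, i.e. at ``decision_frame =
    start_frame + n_window``, never earlier or later.
    """

    def __init__(self, config: DetectorConfig | None = None):
        self.config = config or DetectorConfig()
        self.config.validate()
        self._i = -1
        self._ready = False  # an SVM >= start level has been seen
        self._start: int | None = None
        self._count = 0

    def feed(self, svm_g: float, gyro_dps: float) -> DetectionEvent | None:
        cfg = self.config
        self._i += 1
        i = self._i

        if self._start is not None:
            if frame_qualifies(svm_g, gyro_dps, cfg):
                self._count += 1
            if i - self._start + 1 == cfg.n_window:
                event = DetectionEvent(
                    start_frame=self._start,
                    decision_frame=self._start + cfg.n_window,
                    qualifying_count=self._count,
                    latency_ms=cfg.n_window / cfg.fs * 1000.0,
                    verdict=decision_rule(
                        self._count, cfg.n_window, cfg.decision_fraction
                    ),
                )
                self._start = None
                self._count = 0
                self._ready = False  # re-arm only above the start level
                return event
            return None

        if svm_g >= cfg.svm_start_g:
            self._ready = True
        elif self._ready:
            # falling-edge crossing of the start threshold: arm and begin
            # the evaluation window at this frame.
            self._start = i
            self._count = 1 if frame_qualifies(svm_g, gyro_dps, cfg) else 0
            self._ready = False
        return None


def run_detector(
    trace: ImuTrace, config: DetectorConfig | None = None
) -> list[DetectionEvent]:
    """Scan a whole trace; equivalent to feeding it frame by frame."""
    config = config or DetectorConfig()
    config.validate()
    if not math.isclose(trace.fs, config.fs, rel_tol=1e-6):
        raise ValueError(
            f"trace fs {trace.fs} does not match detector fs {config.fs}"
        )
    if len(trace) < config.n_window:
        warnings.warn(
            "trace shorter than the evaluation window; no detection "
            "possible",
            stacklevel=2,
        )
        return []
    svm = compute_svm(trace).values
    gyro = compute_gyro_magnitude(trace).values
    det = StreamingDetector(config)
    events = []
    for s, g in zip(svm, gyro):
        ev = det.feed(float(s), float(g))
        if ev is not None:
            events.append(ev)
    return events


def events_to_frame(
    events: list[DetectionEvent], trial_id: str | None = None
) -> pd.DataFrame:
    """Events as the CSV schema
    ``trial_id,start_frame,decision_frame,qualifying_count,latency_ms,verdict``."""
    return pd.DataFrame(
        [
            {
                "trial_id": trial_id,
                "start_frame": e.start_frame,
                "decision_frame": e.decision_frame,
                "qualifying_count": e.qualifying_count,
                "latency_ms": e.latency_ms,
                "verdict": e.verdict,
            }
            for e in events
        ],
        columns=[
            "trial_id",
            "start_frame",
            "decision_frame",
            "qualifying_count",
            "latency_ms",
            "verdict",
        ],
    )
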