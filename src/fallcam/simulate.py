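"""Seeded synthetic IMU generators for falls and activities of daily living.

The generators emulate the waist-mounted, 50 Hz recording protocol used for
threshold calibration: the y-axis lies along gravity, fall trials move from
quiet standing through a short weightless phase into ground impact, and ADL
trials reproduce the signal features that make each activity separable from
a fall:

* a fall's acceleration magnitude (SVM) crosses 0.95 g at fall start and
  dwells in the 0.6-0.9 g band with low (< 100 deg/s) angular velocity for
  a 0.14-0.24 s weightless core before the pre-impact plunge and spike;
* walking/jogging produce periodic sub-0.95 g dips each shorter than 0.1 s;
* a jump's flight phase drops the SVM below 0.6 g;
* lying down declines through the same SVM band as a fall but with angular
  velocity above 100 deg/s throughout the movement;
* standing up never leaves 0.9 g for more than a couple of frames.

Signals are piecewise-smooth envelopes (cosine ramps between phase levels)
decomposed onto axes by a seeded tilt/azimuth model, plus Gaussian
measurement noise.  The noise is band-limited with a 3-tap average to
emulate the on-device filtering present in the recording chain a threshold
detector actually sees; unfiltered white noise at the same amplitude would
produce spurious single-frame 0.95 g crossings that filtered hardware
streams do not exhibit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .imu import (
    ADL_PHASES,
    LABEL_FALL,
    LABEL_NON_FALL,
    PHASE_EARLY_FALL,
    PHASE_IMPACT,
    PHASE_RECOVERY,
    PHASE_STANDING,
    ClassifierWindow,
    ImuTrace,
    extract_window,
    resample_to_window,
    write_manifest,
    write_trace_csv,
)

ADL_KINDS = ("walk", "jog", "jump", "stand_up", "lie_down", "stand")
#: Kinds cycled by default corpora: the four staged ADL types of the
#: self-collected protocol (walking, jogging, standing up, lying down).
DEFAULT_ADL_MIX = ("walk", "jog", "stand_up", "lie_down")
FALL_DIRECTIONS = ("forward", "backward", "lateral_left", "lateral_right")


@dataclass
class FallProfile:
    """Shape parameters of one simulated fall.

    ``plateau_g`` is the SVM level of the weightless core (0.6-0.9 g by
    default sampling), ``weightless_s`` its duration (0.14-0.24 s), and
    ``gyro_peak_dps`` the angular-velocity envelope peak reached at ground
    contact (kept below 100 deg/s through the early fall).  The impact
    spike amplitude only needs to be far above 1 g; the detector never
    inspects the impact phase.
    """

    pre_fall_s: float = 1.5
    plateau_g: float = 0.75
    weightless_s: float = 0.18
    fluctuation_amp_g: float = 0.02
    gyro_peak_dps: float = 50.0
    impact_peak_g: float = 4.5
    impact_s: float = 0.06
    noise_acc_g: float = 0.02
    noise_gyro_dps: float = 5.0
    # pre-impact plunge: continued decline from the plateau to the floor
    # level reached just before ground contact.
    plunge_s: float = 0.24
    plunge_floor_g: float = 0.52
    recovery_s: float = 1.2
    direction: str = "forward"

    def validate(self) -> None:
        if not 0.0 < self.plateau_g < 0.95:
            raise ValueError(
                f"plateau_g must lie in (0, 0.95) g, got {self.plateau_g}"
            )
        if self.weightless_s <= 0:
            raise ValueError("weightless_s must be positive")
        if self.impact_peak_g <= 1.0:
            raise ValueError("impact_peak_g must exceed 1 g")
        if self.noise_acc_g < 0 or self.noise_gyro_dps < 0:
            raise ValueError("noise levels must be non-negative")
        if self.direction not in FALL_DIRECTIONS:
            raise ValueError(f"unknown fall direction {self.direction!r}")


@dataclass
class AdlProfile:
    """Shape parameters of one simulated activity of daily living."""

    kind: str = "walk"
    dip_depth_g: float = 0.25
    dip_duration_s: float = 0.05
    cadence_hz: float = 2.0
    gyro_peak_dps: float = 40.0
    duration_s: float = 6.0
    noise_acc_g: float = 0.02
    noise_gyro_dps: float = 5.0
    # jump-specific
    flight_g: float = 0.35
    flight_s: float = 0.35
    # lie-down-specific
    lie_level_g: float = 0.78

    def validate(self) -> None:
        if self.kind not in ADL_KINDS:
            raise ValueError(f"unknown ADL kind {self.kind!r}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.kind in ("walk", "jog") and self.dip_duration_s >= 0.1:
            raise ValueError("walk/jog dips must last < 0.1 s")
        if self.kind == "lie_down" and self.gyro_peak_dps <= 100:
            raise ValueError("lie_down requires gyro_peak_dps > 100")
        if self.kind == "jump" and not self.flight_g < 0.6:
            raise ValueError("jump flight SVM must be < 0.6 g")


def sample_fall_profile(rng: np.random.Generator) -> FallProfile:
    """Draw a fall profile from the documented default ranges."""
    return FallProfile(
        pre_fall_s=float(rng.uniform(1.2, 2.0)),
        plateau_g=float(rng.uniform(0.6, 0.9)),
        weightless_s=float(rng.uniform(0.14, 0.24)),
        fluctuation_amp_g=float(rng.uniform(0.01, 0.03)),
        gyro_peak_dps=float(rng.uniform(20.0, 80.0)),
        impact_peak_g=float(rng.uniform(3.0, 6.0)),
        direction=FALL_DIRECTIONS[int(rng.integers(len(FALL_DIRECTIONS)))],
    )


def sample_adl_profile(kind: str, rng: np.random.Generator) -> AdlProfile:
    """Draw an ADL profile of the given kind from realistic ranges."""
    if kind == "walk":
        return AdlProfile(
            kind="walk",
            dip_depth_g=float(rng.uniform(0.15, 0.3)),
            dip_duration_s=0.05,
            cadence_hz=float(rng.uniform(1.6, 2.4)),
            gyro_peak_dps=float(rng.uniform(20.0, 60.0)),
            duration_s=6.0,
        )
    if kind == "jog":
        return AdlProfile(
            kind="jog",
            dip_depth_g=float(rng.uniform(0.3, 0.45)),
            dip_duration_s=0.04,
            cadence_hz=float(rng.uniform(2.4, 3.2)),
            gyro_peak_dps=float(rng.uniform(40.0, 90.0)),
            duration_s=6.0,
        )
    if kind == "jump":
        return AdlProfile(
            kind="jump",
            flight_g=float(rng.uniform(0.2, 0.45)),
            flight_s=float(rng.uniform(0.28, 0.4)),
            gyro_peak_dps=float(rng.uniform(30.0, 80.0)),
            duration_s=4.0,
        )
    if kind == "stand_up":
        return AdlProfile(
            kind="stand_up",
            gyro_peak_dps=float(rng.uniform(40.0, 80.0)),
            duration_s=4.0,
        )
    if kind == "lie_down":
        return AdlProfile(
            kind="lie_down",
            lie_level_g=float(rng.uniform(0.7, 0.82)),
            gyro_peak_dps=float(rng.uniform(130.0, 260.0)),
            duration_s=4.0,
        )
    if kind == "stand":
        return AdlProfile(kind="stand", gyro_peak_dps=0.0, duration_s=4.0)
    raise ValueError(f"unknown ADL kind {kind!r}")


# ---------------------------------------------------------------------------
# envelope building blocks
# ---------------------------------------------------------------------------

def _cos_ramp(a: float, b: float, n: int) -> np.ndarray:
    """Smooth half-cosine transition from a to b over n frames (excl. a)."""
    if n <= 0:
        return np.empty(0)
    phase = np.linspace(0.0, math.pi, n + 1)[1:]
    return a + (b - a) * (1.0 - np.cos(phase)) / 2.0


def _smooth_noise(
    rng: np.random.Generator, n: int, sigma: float, ncols: int = 3
) -> np.ndarray:
    """Band-limited Gaussian noise: white draws put through a 3-tap mean."""
    if sigma == 0.0 or n == 0:
        return np.zeros((n, ncols))
    w = rng.normal(0.0, sigma, size=(n + 2, ncols))
    return (w[:-2] + w[1:-1] + w[2:]) / 3.0


def _decompose(
    svm_env: np.ndarray,
    tilt_rad: np.ndarray,
    azimuth_rad: float,
) -> np.ndarray:
    """Distribute an SVM envelope onto axes given body tilt from vertical."""
    ay = svm_env * np.cos(tilt_rad)
    horiz = svm_env * np.sin(tilt_rad)
    ax = horiz * math.cos(azimuth_rad)
    az = horiz * math.sin(azimuth_rad)
    return np.column_stack([ax, ay, az])


def _gyro_axes(
    env: np.ndarray, rng: np.random.Generator, sigma: float
) -> np.ndarray:
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    return env[:, None] * u[None, :] + _smooth_noise(rng, len(env), sigma)


_AZIMUTH = {
    "forward": 0.0,
    "backward": math.pi,
    "lateral_left": math.pi / 2,
    "lateral_right": -math.pi / 2,
}


def simulate_fall(
    profile: FallProfile, fs: float = 50.0, seed: int = 0
) -> ImuTrace:
    """Generate one labeled fall trial.

    Phase structure (SVM envelope): quiet standing at 1 g, a short trigger
    ramp crossing 0.95 g (the first sub-0.95 g frame becomes
    ``fall_start_frame``), the weightless core declining into the
    0.6-0.9 g band for ``weightless_s`` (labeled ``early_fall``), the
    pre-impact plunge toward ``plunge_floor_g``, the impact spike to
    ``impact_peak_g``, and recovery at 1 g.  The angular-velocity envelope
    ramps from rest to ``gyro_peak_dps`` at ground contact, then spikes
    during impact.  Identical ``(profile, fs, seed)`` reproduce the trace
    bit-for-bit.
    """
    profile.validate()
    if fs < 20:
        raise ValueError(f"fs must be >= 20 Hz, got {fs}")
    rng = np.random.default_rng(seed)
    p = profile.plateau_g

    n_pre = round(profile.pre_fall_s * fs)
    k_span = round(profile.weightless_s * fs)
    n_ramp = max(2, round(0.06 * fs))
    n_plunge = round(profile.plunge_s * fs)
    n_rise = max(1, round(profile.impact_s * fs / 2))
    n_decay = max(2, round(0.12 * fs))
    n_rec = round(profile.recovery_s * fs)

    # weightless core: decline from just inside the band toward the
    # plateau, with a slow fluctuation; the envelope floor sits at 0.615 g
    # so the core straddles the lower band edge only through noise.
    hi = min(0.88, p + 0.08)
    span = _cos_ramp(hi, p, k_span)
    t_span = np.arange(k_span) / fs
    f_w = rng.uniform(4.0, 8.0)
    span = span + profile.fluctuation_amp_g * np.sin(
        2 * math.pi * f_w * t_span + rng.uniform(0, 2 * math.pi)
    )
    span = np.maximum(span, 0.615)

    env = np.concatenate(
        [
            np.full(n_pre, 1.0),
            _cos_ramp(1.0, hi, n_ramp),  # trigger ramp through 0.95 g
            span,
            _cos_ramp(span[-1], profile.plunge_floor_g, n_plunge),
            _cos_ramp(profile.plunge_floor_g, profile.impact_peak_g, n_rise),
            _cos_ramp(profile.impact_peak_g, 1.0, n_decay),
            np.full(n_rec, 1.0),
        ]
    )
    n = len(env)

    # the first envelope frame below the 0.95 g start threshold
    fall_start = int(np.argmax(env < 0.95))
    span_start = n_pre + n_ramp
    contact = span_start + k_span + n_plunge + n_rise  # spike peak

    labels = np.empty(n, dtype=object)
    labels[:fall_start] = PHASE_STANDING
    labels[fall_start:span_start] = PHASE_EARLY_FALL
    labels[span_start : span_start + k_span] = PHASE_EARLY_FALL
    labels[span_start + k_span : contact + n_decay] = PHASE_IMPACT
    labels[contact + n_decay :] = PHASE_RECOVERY
    # keep the early_fall-labeled span at exactly the weightless core
    # length: the trigger-ramp tail below 0.95 g belongs to the core.
    early = np.flatnonzero(labels == PHASE_EARLY_FALL)
    if len(early) > k_span:
        labels[early[k_span:]] = PHASE_IMPACT
        # shift the core boundary, not the physical envelope

    # tilt from vertical: 0 while standing, ramping to a lying posture
    # between fall start and ground contact.
    tilt_end = math.radians(rng.uniform(60.0, 85.0))
    tilt = np.zeros(n)
    n_tilt = contact - fall_start
    tilt[fall_start:contact] = _cos_ramp(0.0, tilt_end, n_tilt)
    tilt[contact:] = tilt_end
    azimuth = _AZIMUTH[profile.direction] + rng.uniform(-0.3, 0.3)

    acc = _decompose(env, tilt, azimuth)
    acc += _smooth_noise(rng, n, profile.noise_acc_g)

    gyro_env = np.zeros(n)
    gyro_env[fall_start:contact] = _cos_ramp(
        0.0, profile.gyro_peak_dps, contact - fall_start
    )
    g_imp = profile.gyro_peak_dps + rng.uniform(80.0, 200.0)
    gyro_env[contact : contact + n_decay] = _cos_ramp(
        g_imp, 0.0, n_decay
    )
    gyro = _gyro_axes(gyro_env, rng, profile.noise_gyro_dps)

    return ImuTrace(
        t=np.arange(n) / fs,
        acc=acc,
        gyro=gyro,
        fs=fs,
        trial_label=LABEL_FALL,
        fall_start_frame=fall_start,
        phase_labels=labels,
    )


# ---------------------------------------------------------------------------
# ADL builders
# ---------------------------------------------------------------------------

def _dip_kernel(depth: float, width: int) -> np.ndarray:
    """A short sub-1 g notch whose shoulders return exactly to 1 g."""
    j = np.arange(1, width + 1)
    return 1.0 - depth * np.sin(math.pi * j / (width + 1))


def _build_walk_like(
    profile: AdlProfile, fs: float, rng: np.random.Generator, phase: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = round(profile.duration_s * fs)
    t = np.arange(n) / fs
    env = 1.0 + 0.015 * np.sin(
        2 * math.pi * profile.cadence_hz * t + rng.uniform(0, 2 * math.pi)
    )
    width = max(2, round(profile.dip_duration_s * fs))
    step = 1.0 / profile.cadence_hz
    kernel = None
    pos = rng.uniform(0.3, 0.3 + step)
    while pos * fs + width + 1 < n:
        i = int(pos * fs)
        depth = profile.dip_depth_g * rng.uniform(0.85, 1.15)
        kernel = _dip_kernel(min(depth, 0.38), width)
        env[i : i + width] = kernel
        if phase == "adl_jog":  # landing rebound above 1 g
            reb = min(i + width + 2, n)
            env[i + width : reb] = 1.0 + depth * 1.5
        pos += step * rng.uniform(0.95, 1.05)
    gyro_env = np.abs(
        profile.gyro_peak_dps
        * np.sin(2 * math.pi * profile.cadence_hz * t + rng.uniform(0, 6.28))
    )
    labels = np.full(n, phase, dtype=object)
    return env, gyro_env, labels


def simulate_adl(
    profile: AdlProfile, fs: float = 50.0, seed: int = 0
) -> ImuTrace:
    """Generate one labeled non-fall trial of the profile's kind.

    Deterministic given ``(profile, fs, seed)``.  See the module docstring
    for the per-kind signal structure.
    """
    profile.validate()
    if fs < 20:
        raise ValueError(f"fs must be >= 20 Hz, got {fs}")
    rng = np.random.default_rng(seed)
    kind = profile.kind
    tilt = None

    if kind in ("walk", "jog"):
        env, gyro_env, labels = _build_walk_like(
            profile, fs, rng, f"adl_{kind}"
        )
    elif kind == "stand":
        n = round(profile.duration_s * fs)
        env = np.ones(n)
        gyro_env = np.zeros(n)
        labels = np.full(n, PHASE_STANDING, dtype=object)
    elif kind == "stand_up":
        n_pre = round(1.0 * fs)
        n_rise = round(0.3 * fs)
        n_post = round(profile.duration_s * fs) - n_pre - n_rise - 2
        env = np.concatenate(
            [
                np.full(n_pre, 1.0),
                [0.93, 0.93],  # brief unweighting, never below 0.9 g
                _cos_ramp(0.93, 1.15, n_rise // 2),
                _cos_ramp(1.15, 1.0, n_rise - n_rise // 2),
                np.full(max(n_post, 0), 1.0),
            ]
        )
        n = len(env)
        t = np.arange(n) / fs
        gyro_env = np.zeros(n)
        bump = slice(n_pre - round(0.1 * fs), n_pre + n_rise)
        m = bump.stop - bump.start
        gyro_env[bump] = profile.gyro_peak_dps * np.sin(
            math.pi * np.arange(m) / max(m - 1, 1)
        )
        labels = np.full(n, "adl_stand_up", dtype=object)
    elif kind == "lie_down":
        n_pre = round(1.0 * fs)
        n_dec = round(0.5 * fs)
        n_hold = round(0.24 * fs)
        n_rise = round(0.4 * fs)
        n_post = max(round(profile.duration_s * fs) - n_pre - n_dec - n_hold - n_rise, 0)
        env = np.concatenate(
            [
                np.full(n_pre, 1.0),
                _cos_ramp(1.0, profile.lie_level_g, n_dec),
                np.full(n_hold, profile.lie_level_g),
                _cos_ramp(profile.lie_level_g, 1.0, n_rise),
                np.full(n_post, 1.0),
            ]
        )
        n = len(env)
        # trunk rotation: angular velocity exceeds 100 deg/s over the whole
        # sub-0.95 g excursion, which is what vetoes the SVM-band match.
        sub = np.flatnonzero(env < 0.95)
        m0, m1 = int(sub[0]), int(sub[-1])
        lead, tail = round(0.16 * fs), round(0.24 * fs)
        gyro_env = np.zeros(n)
        r0 = max(m0 - lead, 0)
        gyro_env[r0:m0] = _cos_ramp(0.0, profile.gyro_peak_dps, m0 - r0)
        gyro_env[m0 : m1 + 1] = profile.gyro_peak_dps
        r1 = min(m1 + 1 + tail, n)
        gyro_env[m1 + 1 : r1] = _cos_ramp(
            profile.gyro_peak_dps, 0.0, r1 - m1 - 1
        )
        labels = np.full(n, "adl_lie_down", dtype=object)
        tilt_end = math.radians(rng.uniform(70.0, 88.0))
        tilt = np.zeros(n)
        tilt[m0 : m1 + 1] = _cos_ramp(0.0, tilt_end, m1 + 1 - m0)
        tilt[m1 + 1 :] = tilt_end
    elif kind == "jump":
        n_pre = round(1.0 * fs)
        n_crouch = round(0.08 * fs)
        n_push = round(0.16 * fs)
        n_flight = round(profile.flight_s * fs)
        n_land = max(2, round(0.06 * fs))
        n_settle = round(0.2 * fs)
        push_peak = rng.uniform(1.6, 2.2)
        land_peak = rng.uniform(2.5, 4.0)
        env = np.concatenate(
            [
                np.full(n_pre, 1.0),
                _dip_kernel(0.15, n_crouch),
                _cos_ramp(0.85, push_peak, n_push // 2),
                _cos_ramp(push_peak, profile.flight_g, n_push - n_push // 2),
                np.full(n_flight, profile.flight_g),
                _cos_ramp(profile.flight_g, land_peak, n_land // 2),
                _cos_ramp(land_peak, 1.0, n_land - n_land // 2 + n_settle),
            ]
        )
        pad = round(profile.duration_s * fs) - len(env)
        if pad > 0:
            env = np.concatenate([env, np.full(pad, 1.0)])
        n = len(env)
        t = np.arange(n) / fs
        gyro_env = np.abs(
            profile.gyro_peak_dps * np.sin(2 * math.pi * 1.2 * t)
        )
        labels = np.full(n, "adl_jump", dtype=object)
    else:  # pragma: no cover - guarded by validate()
        raise ValueError(f"unknown ADL kind {kind!r}")

    n = len(env)
    if tilt is None:
        tilt = np.zeros(n)
    acc = _decompose(env, tilt, rng.uniform(0, 2 * math.pi))
    acc += _smooth_noise(rng, n, profile.noise_acc_g)
    gyro = _gyro_axes(gyro_env, rng, profile.noise_gyro_dps)
    return ImuTrace(
        t=np.arange(n) / fs,
        acc=acc,
        gyro=gyro,
        fs=fs,
        trial_label=LABEL_NON_FALL,
        phase_labels=labels,
    )


# ---------------------------------------------------------------------------
# corpus generation
# ---------------------------------------------------------------------------

def _child_seeds(seed: int, count: int) -> list[int]:
    """Stable per-trace seeds below 2**31 derived from one corpus seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(count) % (2**31)]


def simulate_corpus(
    n_falls: int,
    n_adls: int,
    fs: float = 50.0,
    seed: int = 0,
    adl_kinds: tuple[str, ...] = DEFAULT_ADL_MIX,
) -> list[ImuTrace]:
    """Generate a labeled in-memory corpus of fall and ADL trials.

    Fall directions and ADL kinds are cycled round-robin; per-trial
    profiles are drawn from the documented default ranges with a seeded
    RNG, so the same seed reproduces the corpus exactly.
    """
    if n_falls < 0 or n_adls < 0:
        raise ValueError("counts must be >= 0")
    seeds = _child_seeds(seed, 2 * (n_falls + n_adls))
    traces: list[ImuTrace] = []
    for i in range(n_falls):
        prof = sample_fall_profile(np.random.default_rng(seeds[2 * i]))
        prof.direction = FALL_DIRECTIONS[i % len(FALL_DIRECTIONS)]
        tr = simulate_fall(prof, fs=fs, seed=seeds[2 * i + 1])
        tr.trial_id = f"fall_{i:04d}"
        traces.append(tr)
    base = 2 * n_falls
    for j in range(n_adls):
        kind = adl_kinds[j % len(adl_kinds)]
        prof = sample_adl_profile(
            kind, np.random.default_rng(seeds[base + 2 * j])
        )
        tr = simulate_adl(prof, fs=fs, seed=seeds[base + 2 * j + 1])
        tr.trial_id = f"adl_{kind}_{j:04d}"
        traces.append(tr)
    return traces


def generate_dataset(
    n_falls: int,
    n_adls: int,
    fs: float = 50.0,
    seed: int = 0,
    out_dir: str | Path = ".",
    adl_kinds: tuple[str, ...] = DEFAULT_ADL_MIX,
):
    """Write a corpus as trace CSVs plus a manifest; returns the manifest.

    Regenerating with the same arguments reproduces every file
    byte-identically.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    traces = simulate_corpus(n_falls, n_adls, fs=fs, seed=seed, adl_kinds=adl_kinds)
    rows = []
    for tr in traces:
        fname = f"{tr.trial_id}.csv"
        write_trace_csv(tr, out_dir / fname)
        rows.append(
            {
                "trial_id": tr.trial_id,
                "path": fname,
                "trial_label": tr.trial_label,
                "fall_start_frame": tr.fall_start_frame,
                "fs": fs,
            }
        )
    return write_manifest(rows, out_dir / "manifest.csv")


def make_training_windows(
    n_falls: int,
    n_adls: int,
    fs: float = 50.0,
    seed: int = 0,
    window_s: float = 1.0,
    target_len: int = 100,
    adl_kinds: tuple[str, ...] = DEFAULT_ADL_MIX,
) -> list[ClassifierWindow]:
    """Build classifier windows from a synthetic corpus.

    Mirrors the windowing applied to frame-labeled datasets: a one-second
    snippet starting at the activity-start frame (the fall start for fall
    trials, motion onset for ADLs), resampled to the classifier's input
    length.
    """
    traces = simulate_corpus(n_falls, n_adls, fs=fs, seed=seed, adl_kinds=adl_kinds)
    windows = []
    for tr in traces:
        if tr.trial_label == LABEL_FALL:
            start = tr.fall_start_frame or 0
        else:
            start = round(0.8 * fs)  # staged ADL motion begins at ~1 s
        start = min(start, max(len(tr) - round(window_s * fs), 0))
        seg = extract_window(tr, start, window_s)
        windows.append(resample_to_window(seg, target_len, origin_frame=start))
    return windows
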