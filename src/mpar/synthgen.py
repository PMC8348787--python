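"""Seeded synthetic generator of wrist-IMU activity recordings.

The study population this emulates — pregnant women wearing a single
wrist module — cannot be redistributed, so every pipeline stage is
exercised on synthetic bouts instead.  The signal model is deliberately
simple: each activity class is a gravity projection (wrist orientation)
plus up to three sinusoidal movement harmonics plus Gaussian sensor
noise, with per-bout jitter of amplitudes, frequencies and phases playing
the role of subject-to-subject and bout-to-bout variability.  That is
enough structure for the 43 window features (moments, zero crossings,
spectral bins, entropy) to separate classes, while three engineered
near-collisions mirror the confusion structure reported for the real
cohort:

* stair walking (MPA1) is close to level walking (MPA7) — cautious stair
  gait looks like a slow walk at the wrist;
* side bending (MPA9) and standing (MPA10) sit near hands exercise
  (MPA4) in wrist-motion energy — all three move the instrumented wrist
  very little;
* laying (MPA6) and front bending (MPA8) are strongly distinct from
  everything else (near-zero energy versus large slow swings).

Accelerometer units are g, gyroscope degrees/second, temperature °C.
All randomness flows from explicit integer seeds: the same seed always
reproduces the same bout or cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .signal_io import (
    ACTIVITY_LABELS,
    IMU_SAMPLING_RATE,
    SensorRecording,
)

__all__ = [
    "ActivityProfile",
    "CohortSpec",
    "default_profiles",
    "generate_bout",
    "generate_cohort",
]

NYQUIST = IMU_SAMPLING_RATE / 2.0


@dataclass(frozen=True)
class ActivityProfile:
    """Statistical signature of one activity class at the wrist.

    Parameters
    ----------
    label
        Activity class, ``MPA1`` .. ``MPA10``.
    gravity
        Mean gravity projection onto the sensor axes, in g.  Encodes the
        typical wrist orientation during the activity.
    acc_components
        Sinusoidal movement components ``(frequency_hz, (ax, ay, az))``
        with per-axis amplitudes in g.
    acc_noise
        Standard deviation of white accelerometer noise, g.
    gyro_components
        Sinusoidal angular-rate components ``(frequency_hz, (gx, gy, gz))``
        with amplitudes in degrees/second.
    gyro_noise
        Standard deviation of white gyroscope noise, dps.
    temp_base
        Mean skin temperature, °C.
    temp_drift
        Linear temperature drift, °C per minute (activity warms the wrist).
    duration_range
        (min, max) bout duration in seconds; bouts last 2-5 minutes.
    amp_jitter, freq_jitter
        Relative per-bout lognormal-ish jitter of amplitudes and
        frequencies (subject and bout variability).
    """

    label: str
    gravity: tuple[float, float, float]
    acc_components: tuple[tuple[float, tuple[float, float, float]], ...]
    acc_noise: float
    gyro_components: tuple[tuple[float, tuple[float, float, float]], ...]
    gyro_noise: float
    temp_base: float = 33.0
    temp_drift: float = 0.0
    duration_range: tuple[float, float] = (120.0, 300.0)
    amp_jitter: float = 0.18
    freq_jitter: float = 0.06

    def __post_init__(self) -> None:
        if self.label not in ACTIVITY_LABELS:
            raise ValueError(f"unknown activity label {self.label!r}")
        for freq, _ in self.acc_components + self.gyro_components:
            if not 0 < freq < NYQUIST:
                raise ValueError(
                    f"component frequency {freq} Hz outside (0, {NYQUIST}) Hz"
                )
        if self.acc_noise <= 0 or self.gyro_noise <= 0:
            raise ValueError("noise scales must be positive")
        lo, hi = self.duration_range
        if not 0 < lo <= hi:
            raise ValueError("invalid duration range")


def default_profiles() -> tuple[ActivityProfile, ...]:
    """Built-in profiles for the ten activity classes, MPA1..MPA10.

    Amplitudes, frequencies and noise scales are desk-calibrated wrist
    plausibilities; the deliberate near-collisions described in the
    module docstring are encoded here.
    """
    return (
        # stairs up/down: cautious gait, slightly slower and rockier than walking
        ActivityProfile(
            "MPA1",
            gravity=(0.10, -0.96, 0.22),
            acc_components=((1.65, (0.30, 0.38, 0.22)), (3.3, (0.10, 0.12, 0.07))),
            acc_noise=0.10,
            gyro_components=((1.65, (38.0, 46.0, 28.0)), (3.3, (12.0, 15.0, 9.0))),
            gyro_noise=12.0,
            temp_base=33.2,
            temp_drift=0.04,
        ),
        # cooking: irregular mid-energy hand work, noisy
        ActivityProfile(
            "MPA2",
            gravity=(0.30, -0.88, 0.30),
            acc_components=((0.9, (0.12, 0.18, 0.15)), (2.6, (0.06, 0.08, 0.07))),
            acc_noise=0.14,
            gyro_components=((0.9, (25.0, 35.0, 30.0)),),
            gyro_noise=20.0,
            temp_base=33.4,
        ),
        # eating: slow hand-to-mouth cycle, large wrist rotation
        ActivityProfile(
            "MPA3",
            gravity=(0.20, -0.94, 0.20),
            acc_components=((0.55, (0.15, 0.22, 0.10)),),
            acc_noise=0.06,
            gyro_components=((0.55, (30.0, 45.0, 18.0)),),
            gyro_noise=8.0,
        ),
        # hands exercise: small regular arm movement — low-energy cluster seed
        ActivityProfile(
            "MPA4",
            gravity=(0.00, -0.99, 0.08),
            acc_components=((1.1, (0.08, 0.10, 0.06)),),
            acc_noise=0.05,
            gyro_components=((1.1, (15.0, 18.0, 10.0)),),
            gyro_noise=6.0,
        ),
        # laundry: vigorous scrubbing/wringing, broadband
        ActivityProfile(
            "MPA5",
            gravity=(0.25, -0.90, 0.25),
            acc_components=((1.3, (0.20, 0.28, 0.24)), (2.6, (0.08, 0.10, 0.09))),
            acc_noise=0.12,
            gyro_components=((1.3, (45.0, 60.0, 50.0)),),
            gyro_noise=15.0,
            temp_base=33.3,
            temp_drift=0.03,
        ),
        # laying: near-static, distinct supine wrist orientation, lowest noise
        ActivityProfile(
            "MPA6",
            gravity=(0.88, 0.12, -0.42),
            acc_components=((0.25, (0.012, 0.010, 0.012)),),
            acc_noise=0.008,
            gyro_components=((0.25, (0.6, 0.5, 0.6)),),
            gyro_noise=0.5,
            temp_base=34.3,
        ),
        # walking: level gait, close to MPA1 by design
        ActivityProfile(
            "MPA7",
            gravity=(0.08, -0.97, 0.18),
            acc_components=((1.9, (0.27, 0.34, 0.20)), (3.8, (0.09, 0.11, 0.06))),
            acc_noise=0.10,
            gyro_components=((1.9, (34.0, 42.0, 25.0)), (3.8, (11.0, 13.0, 8.0))),
            gyro_noise=12.0,
            temp_base=33.2,
            temp_drift=0.05,
        ),
        # front bending: slow, very large trunk+arm swings — highly distinct
        ActivityProfile(
            "MPA8",
            gravity=(0.00, -0.68, 0.70),
            acc_components=((0.28, (0.45, 0.55, 0.50)),),
            acc_noise=0.07,
            gyro_components=((0.28, (60.0, 75.0, 70.0)),),
            gyro_noise=8.0,
        ),
        # side bending: small slow sway, near MPA4 in energy
        ActivityProfile(
            "MPA9",
            gravity=(0.16, -0.97, 0.05),
            acc_components=((0.35, (0.09, 0.11, 0.07)),),
            acc_noise=0.05,
            gyro_components=((0.35, (14.0, 16.0, 9.0)),),
            gyro_noise=6.0,
        ),
        # standing: postural sway and tremor only, near MPA4/MPA9 in energy
        ActivityProfile(
            "MPA10",
            gravity=(0.05, -0.99, 0.06),
            acc_components=((0.9, (0.06, 0.07, 0.05)),),
            acc_noise=0.05,
            gyro_components=((0.9, (10.0, 12.0, 7.0)),),
            gyro_noise=6.0,
        ),
    )


def profiles_by_label(
    profiles: Sequence[ActivityProfile] | None = None,
) -> dict[str, ActivityProfile]:
    """Map label -> profile (defaults if none given)."""
    profs = tuple(profiles) if profiles is not None else default_profiles()
    return {p.label: p for p in profs}


# Fig. 2-style metadata category vocabularies with plausible proportions;
# metadata is carried through the pipeline but never influences signals.
METADATA_DISTRIBUTIONS: Mapping[str, tuple[tuple[object, ...], tuple[float, ...]]] = {
    "trimester": ((1, 2, 3), (0.25, 0.34, 0.41)),
    "age_band": (("18-25", "26-30", "31-35", "36-40"), (0.30, 0.35, 0.25, 0.10)),
    "occupation": (("housewife", "working", "student"), (0.62, 0.28, 0.10)),
    "anemia": ((False, True), (0.67, 0.33)),
}


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic data-collection campaign.

    Defaults mirror the emulated study: 61 subjects, about six activity
    bouts each, 2-5 minutes per bout.
    """

    n_subjects: int = 61
    activities_per_subject: int = 6
    seed: int = 0
    duration_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 1 <= self.activities_per_subject <= len(ACTIVITY_LABELS):
            raise ValueError("activities_per_subject must be in 1..10")


def _draw_metadata(rng: np.random.Generator) -> dict:
    meta = {}
    for key, (cats, probs) in METADATA_DISTRIBUTIONS.items():
        meta[key] = cats[rng.choice(len(cats), p=probs)]
    return meta


def generate_bout(
    profile: ActivityProfile,
    duration: float,
    seed: int,
    subject_id: str = "S00",
    metadata: dict | None = None,
) -> SensorRecording:
    """Synthesise one labelled activity bout.

    50 Hz IMU ticks are the profile's gravity projection plus jittered
    sinusoidal components plus Gaussian noise; the 1 Hz temperature track
    is forward-filled onto the tick grid.  Deterministic given ``seed``.
    """
    if duration < 1.0:
        raise ValueError(f"bout duration must be >= 1 s, got {duration}")
    rng = np.random.default_rng(seed)
    n = int(round(duration * IMU_SAMPLING_RATE))
    t = np.arange(n) / IMU_SAMPLING_RATE

    def synth(components, noise_sd, base):
        out = np.tile(np.asarray(base, dtype=float), (n, 1))
        for freq, amps in components:
            f = freq * (1.0 + profile.freq_jitter * rng.standard_normal())
            f = float(np.clip(f, 0.05, NYQUIST - 0.5))
            for axis, amp in enumerate(amps):
                a = amp * (1.0 + profile.amp_jitter * rng.standard_normal())
                phase = rng.uniform(0.0, 2.0 * np.pi)
                out[:, axis] += a * np.sin(2.0 * np.pi * f * t + phase)
        out += rng.normal(0.0, noise_sd, size=(n, 3))
        return out

    acc = synth(profile.acc_components, profile.acc_noise, profile.gravity)
    gyro = synth(profile.gyro_components, profile.gyro_noise, (0.0, 0.0, 0.0))

    n_seconds = -(-n // int(IMU_SAMPLING_RATE))  # ceil
    seconds = np.arange(n_seconds)
    temp_1hz = (
        profile.temp_base
        + profile.temp_drift * seconds / 60.0
        + rng.normal(0.0, 0.03, size=n_seconds)
    )
    temp = np.repeat(temp_1hz, int(IMU_SAMPLING_RATE))[:n]

    rec = SensorRecording(
        subject_id=subject_id,
        activity_label=profile.label,
        t=t,
        acc=acc,
        gyro=gyro,
        temp=temp,
        metadata=dict(metadata or {}),
    )
    return rec.validate()


def generate_cohort(
    spec: CohortSpec = CohortSpec(),
    profiles: Sequence[ActivityProfile] | None = None,
) -> list[SensorRecording]:
    """Synthesise a full cohort of labelled bouts.

    Each subject gets a random subset of ``activities_per_subject``
    classes, a metadata draw, and one bout per class with duration drawn
    from the profile's range.  Per-bout seeds derive from the master seed,
    so the whole cohort is reproducible bit for bit.
    """
    by_label = profiles_by_label(profiles)
    rng = np.random.default_rng(spec.seed)
    recordings: list[SensorRecording] = []
    width = max(2, len(str(spec.n_subjects)))
    for i in range(spec.n_subjects):
        subject_id = f"S{i + 1:0{width}d}"
        meta = _draw_metadata(rng)
        labels = rng.choice(
            len(ACTIVITY_LABELS), size=spec.activities_per_subject, replace=False
        )
        for j in sorted(labels):
            profile = by_label[ACTIVITY_LABELS[j]]
            lo, hi = spec.duration_range or profile.duration_range
            duration = float(rng.uniform(lo, hi))
            bout_seed = int(rng.integers(0, 2**31 - 1))
            recordings.append(
                generate_bout(profile, duration, bout_seed, subject_id, meta)
            )
    return recordings
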