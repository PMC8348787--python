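"""Sensor-stream data model and delimited-text I/O.

A recording is one labelled activity bout from one subject: a 50 Hz
six-channel IMU stream (3-axis accelerometer in g, 3-axis gyroscope in
degrees/second) plus a 1 Hz skin-temperature channel forward-filled onto
the 50 Hz tick grid so a single flat file holds all channels.  Files are
plain comma-delimited text with ``#``-prefixed metadata lines, so they are
self-describing and diffable.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ACTIVITY_LABELS",
    "ACTIVITY_NAMES",
    "CANONICAL_FEATURE_NAMES",
    "ChannelSpec",
    "SensorRecording",
    "FeatureTable",
    "FormatError",
    "ValidationError",
    "VocabularyError",
    "read_recording",
    "write_recording",
    "read_feature_table",
    "write_feature_table",
]

#: The ten maternal physical activity (MPA) classes.
ACTIVITY_LABELS: tuple[str, ...] = tuple(f"MPA{i}" for i in range(1, 11))

ACTIVITY_NAMES: dict[str, str] = {
    "MPA1": "stairs up/down",
    "MPA2": "cooking",
    "MPA3": "eating",
    "MPA4": "hands exercise",
    "MPA5": "laundry",
    "MPA6": "laying",
    "MPA7": "walking",
    "MPA8": "front bending",
    "MPA9": "side bending",
    "MPA10": "standing",
}

IMU_SAMPLING_RATE = 50.0  # Hz
TEMP_SAMPLING_RATE = 1.0  # Hz
QUANTIZATION_BITS = 16

RAW_COLUMNS = ("t", "acc_x", "acc_y", "acc_z", "gyro_x", "gyro_y", "gyro_z", "temp")

# Canonical 43-feature schema, in family order:
# mean x4, std x3, cosine similarity x3, gyro RMS x3, skewness x3,
# kurtosis x3, max x3, min x3, zero crossings x3, FFT x6, entropy x3,
# grouped Q1 x3, peak time-difference x3.
CANONICAL_FEATURE_NAMES: tuple[str, ...] = (
    "mean_acc_x", "mean_acc_y", "mean_acc_z", "mean_temp",
    "std_acc_x", "std_acc_y", "std_acc_z",
    "cos_acc_xy", "cos_acc_xz", "cos_acc_yz",
    "rms_gyro_x", "rms_gyro_y", "rms_gyro_z",
    "skew_acc_x", "skew_acc_y", "skew_acc_z",
    "kurt_acc_x", "kurt_acc_y", "kurt_acc_z",
    "max_acc_x", "max_acc_y", "max_acc_z",
    "min_acc_x", "min_acc_y", "min_acc_z",
    "zc_acc_x", "zc_acc_y", "zc_acc_z",
    "fft_peakf", "fft_lowf1", "fft_lowf2", "fft_lowf3", "fft_medf", "fft_highf",
    "entropy_acc_x", "entropy_acc_y", "entropy_acc_z",
    "q1_acc_x", "q1_acc_y", "q1_acc_z",
    "peak_dt_acc_x", "peak_dt_acc_y", "peak_dt_acc_z",
)

FEATURE_FAMILY_SIZES = (4, 3, 3, 3, 3, 3, 3, 3, 3, 6, 3, 3, 3)
assert sum(FEATURE_FAMILY_SIZES) == 43 == len(CANONICAL_FEATURE_NAMES)


class FormatError(ValueError):
    """File does not match the expected delimited-text dialect."""


class ValidationError(ValueError):
    """Parsed content violates a recording invariant."""


class VocabularyError(ValidationError):
    """Activity label outside the MPA1..MPA10 vocabulary."""


@dataclass(frozen=True)
class ChannelSpec:
    """One sensor channel: name, sampling rate in Hz, quantization bits."""

    name: str
    sampling_rate: float
    quantization_bits: int = QUANTIZATION_BITS

    def __post_init__(self) -> None:
        if self.name not in RAW_COLUMNS[1:]:
            raise ValueError(f"unknown channel {self.name!r}")
        expected = TEMP_SAMPLING_RATE if self.name == "temp" else IMU_SAMPLING_RATE
        if self.sampling_rate != expected:
            raise ValueError(
                f"channel {self.name!r} must sample at {expected:g} Hz, "
                f"got {self.sampling_rate:g}"
            )


#: The module's fixed channel complement.
DEFAULT_CHANNELS: tuple[ChannelSpec, ...] = tuple(
    ChannelSpec(name, TEMP_SAMPLING_RATE if name == "temp" else IMU_SAMPLING_RATE)
    for name in RAW_COLUMNS[1:]
)


@dataclass
class SensorRecording:
    """A labelled multichannel time series for one subject/activity bout.

    Parameters
    ----------
    subject_id
        Opaque subject identifier.
    activity_label
        One of ``MPA1`` .. ``MPA10``.
    t
        Seconds from bout start, strictly increasing, nominal 1/50 s spacing.
    acc
        ``(n, 3)`` accelerometer samples in g (x, y, z columns).
    gyro
        ``(n, 3)`` gyroscope samples in degrees/second.
    temp
        ``(n,)`` temperature in °C, constant within each 1 s span
        (forward-filled from the 1 Hz sensor).
    metadata
        Subject metadata: ``trimester`` (1-3), ``age_band``, ``occupation``,
        ``anemia`` (bool-ish).
    """

    subject_id: str
    activity_label: str
    t: np.ndarray
    acc: np.ndarray
    gyro: np.ndarray
    temp: np.ndarray
    metadata: dict = field(default_factory=dict)
    sampling_rate: float = IMU_SAMPLING_RATE

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float).reshape(-1, 3)
        self.gyro = np.asarray(self.gyro, dtype=float).reshape(-1, 3)
        self.temp = np.asarray(self.temp, dtype=float).reshape(-1)

    @property
    def n_samples(self) -> int:
        return self.t.shape[0]

    @property
    def duration(self) -> float:
        """Bout duration in seconds (tick count over the tick rate)."""
        return self.n_samples / self.sampling_rate

    def validate(self) -> "SensorRecording":
        """Check all recording invariants; raise on violation."""
        if self.activity_label not in ACTIVITY_LABELS:
            raise VocabularyError(
                f"unknown activity label {self.activity_label!r}; "
                f"expected one of {', '.join(ACTIVITY_LABELS)}"
            )
        n = self.n_samples
        if not (self.acc.shape[0] == self.gyro.shape[0] == self.temp.shape[0] == n):
            raise ValidationError("channel lengths disagree")
        if n > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValidationError("timestamps are not strictly increasing")
        if n:
            # temp forward-filled from 1 Hz: constant within each second
            sec = np.floor(self.t + 1e-9).astype(int)
            first = np.r_[True, sec[1:] != sec[:-1]]
            ref = self.temp[np.maximum.accumulate(np.where(first, np.arange(n), 0))]
            if np.any(np.abs(self.temp - ref) > 1e-9):
                raise ValidationError("temperature changes within a 1 s span")
        return self


def _metadata_header(rec: SensorRecording) -> list[str]:
    lines = [
        f"# subject={rec.subject_id}",
        f"# activity={rec.activity_label}",
        "# units_acc=g",
        "# units_gyro=dps",
    ]
    for key, val in rec.metadata.items():
        lines.append(f"# {key}={val}")
    return lines


def write_recording(rec: SensorRecording, path: str | os.PathLike) -> str:
    """Write ``rec`` in the canonical raw-recording dialect; returns the path."""
    rec.validate()
    frame = pd.DataFrame(
        {
            "t": rec.t,
            "acc_x": rec.acc[:, 0], "acc_y": rec.acc[:, 1], "acc_z": rec.acc[:, 2],
            "gyro_x": rec.gyro[:, 0], "gyro_y": rec.gyro[:, 1], "gyro_z": rec.gyro[:, 2],
            "temp": rec.temp,
        }
    )
    buf = io.StringIO()
    frame.to_csv(buf, index=False, float_format="%.12g")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(_metadata_header(rec)) + "\n")
        fh.write(buf.getvalue())
    return os.fspath(path)


_META_KEYS = {"trimester", "age_band", "occupation", "anemia"}


def read_recording(path: str | os.PathLike) -> SensorRecording:
    """Parse a raw-recording file and return a validated :class:`SensorRecording`."""
    meta: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        header = line.strip()
        if header.split(",") != list(RAW_COLUMNS):
            raise FormatError(
                f"{path}: bad header {header!r}; expected {','.join(RAW_COLUMNS)!r}"
            )
        fh.seek(pos)
        frame = pd.read_csv(fh)
    subject = meta.pop("subject", "unknown")
    activity = meta.pop("activity", "")
    meta.pop("units_acc", None)
    meta.pop("units_gyro", None)
    metadata: dict = {}
    for key, raw in meta.items():
        if key == "trimester":
            metadata[key] = int(raw)
        elif key == "anemia":
            metadata[key] = raw.lower() in ("1", "true", "yes")
        else:
            metadata[key] = raw
    rec = SensorRecording(
        subject_id=subject,
        activity_label=activity,
        t=frame["t"].to_numpy(),
        acc=frame[["acc_x", "acc_y", "acc_z"]].to_numpy(),
        gyro=frame[["gyro_x", "gyro_y", "gyro_z"]].to_numpy(),
        temp=frame["temp"].to_numpy(),
        metadata=metadata,
    )
    return rec.validate()


@dataclass
class FeatureTable:
    """Per-window feature rows: ``subject_id``, ``activity_label`` + 43 features.

    Backed by a :class:`pandas.DataFrame` whose column order is the canonical
    feature order; ``X``/``y`` views feed the evaluation harness directly.
    """

    frame: pd.DataFrame
    feature_names: tuple[str, ...] = CANONICAL_FEATURE_NAMES

    KEY_COLUMNS = ("subject_id", "activity_label")

    def __post_init__(self) -> None:
        expected = list(self.KEY_COLUMNS) + list(self.feature_names)
        got = list(self.frame.columns)
        if got != expected:
            raise FormatError(
                f"feature table has {len(got)} columns, expected "
                f"{len(expected)} ({len(self.feature_names)} features)"
            )
        values = self.frame[list(self.feature_names)].to_numpy(dtype=float)
        if values.size and not np.all(np.isfinite(values)):
            raise ValidationError("feature table contains non-finite values")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def X(self) -> np.ndarray:
        """``(n_rows, 43)`` feature matrix."""
        return self.frame[list(self.feature_names)].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        """``(n_rows,)`` activity labels."""
        return self.frame["activity_label"].to_numpy()

    def select(self, index: Sequence[int]) -> "FeatureTable":
        return FeatureTable(
            self.frame.iloc[list(index)].reset_index(drop=True), self.feature_names
        )

    @classmethod
    def from_rows(
        cls,
        rows: Iterable[tuple[str, str, Sequence[float]]],
        feature_names: tuple[str, ...] = CANONICAL_FEATURE_NAMES,
    ) -> "FeatureTable":
        records = []
        for subject_id, label, values in rows:
            values = np.asarray(values, dtype=float)
            if values.shape != (len(feature_names),):
                raise ValidationError(
                    f"row has {values.size} features, expected {len(feature_names)}"
                )
            records.append((subject_id, label, *values))
        frame = pd.DataFrame(
            records, columns=list(cls.KEY_COLUMNS) + list(feature_names)
        )
        return cls(frame, feature_names)


def write_feature_table(table: FeatureTable, path: str | os.PathLike) -> str:
    """Write a feature table as comma-delimited text; returns the path."""
    table.frame.to_csv(path, index=False, float_format="%.12g")
    return os.fspath(path)


def read_feature_table(
    path: str | os.PathLike,
    feature_names: tuple[str, ...] = CANONICAL_FEATURE_NAMES,
) -> FeatureTable:
    """Read a feature table, checking the 2 + 43 column schema."""
    frame = pd.read_csv(path)
    expected = list(FeatureTable.KEY_COLUMNS) + list(feature_names)
    if list(frame.columns) != expected:
        raise FormatError(
            f"{path}: expected columns {expected[:2]} + {len(feature_names)} "
            f"features, got {len(frame.columns)} columns"
        )
    return FeatureTable(frame, feature_names)
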