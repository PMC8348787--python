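"""Sliding-window segmentation of sensor recordings.

Windows are fixed-duration slices of all channels, cut either back-to-back
(non-overlapped, stride = N samples) or with 50% overlap (stride = N/2).
At the 50 Hz IMU rate a 1 s window holds N = 50 samples and a 2 s window
N = 100; consecutive overlapped windows share exactly N/2 samples (0.5 s
and 1 s respectively).  Trailing samples that do not fill a whole window
are dropped so every window feeds the feature formulas exactly N samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .signal_io import IMU_SAMPLING_RATE, SensorRecording

__all__ = ["WindowingConfig", "Window", "segment", "window_count"]


@dataclass(frozen=True)
class WindowingConfig:
    """Window duration, overlap mode and sampling rate.

    ``window_seconds`` is 1 or 2; ``overlapped`` selects 50% overlap
    (stride N/2) versus abutting windows (stride N).
    """

    window_seconds: float = 1.0
    overlapped: bool = False
    sampling_rate: float = IMU_SAMPLING_RATE

    def __post_init__(self) -> None:
        if self.window_seconds not in (1, 2):
            raise ValueError(f"window_seconds must be 1 or 2, got {self.window_seconds}")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        n = self.window_seconds * self.sampling_rate
        if abs(n - round(n)) > 1e-9 or round(n) % 2:
            raise ValueError("window must span an even integer number of samples")

    @property
    def n_samples(self) -> int:
        """Window length N in samples."""
        return int(round(self.window_seconds * self.sampling_rate))

    @property
    def stride(self) -> int:
        """Hop between consecutive window starts, in samples."""
        return self.n_samples // 2 if self.overlapped else self.n_samples


@dataclass
class Window:
    """One fixed-length segment of all channels, inheriting the bout's label."""

    start_time: float
    acc: np.ndarray  # (N, 3)
    gyro: np.ndarray  # (N, 3)
    temp: np.ndarray  # (N,) forward-filled
    activity_label: str
    subject_id: str
    sampling_rate: float = IMU_SAMPLING_RATE

    @property
    def n(self) -> int:
        return self.acc.shape[0]


def window_count(t_samples: int, cfg: WindowingConfig) -> int:
    """Number of windows a recording of ``t_samples`` IMU ticks yields.

    Closed form of :func:`segment`'s output length:
    ``floor((T - N) / stride) + 1`` when T >= N, else 0.
    """
    if t_samples < 0:
        raise ValueError("t_samples must be non-negative")
    n, stride = cfg.n_samples, cfg.stride
    if t_samples < n:
        return 0
    return (t_samples - n) // stride + 1


def segment(rec: SensorRecording, cfg: WindowingConfig) -> list[Window]:
    """Cut ``rec`` into ordered fixed-length windows.

    Returns windows ordered by start time, each carrying the recording's
    label and subject id.  A recording shorter than one window yields an
    empty list with a warning (not an error: short bouts are legal input).
    """
    count = window_count(rec.n_samples, cfg)
    if count == 0:
        warnings.warn(
            f"recording of {rec.n_samples} samples is shorter than one "
            f"{cfg.n_samples}-sample window; no windows emitted",
            stacklevel=2,
        )
        return []
    n, stride = cfg.n_samples, cfg.stride
    windows = []
    for i in range(count):
        lo = i * stride
        hi = lo + n
        windows.append(
            Window(
                start_time=float(rec.t[lo]),
                acc=rec.acc[lo:hi],
                gyro=rec.gyro[lo:hi],
                temp=rec.temp[lo:hi],
                activity_label=rec.activity_label,
                subject_id=rec.subject_id,
                sampling_rate=cfg.sampling_rate,
            )
        )
    return windows
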