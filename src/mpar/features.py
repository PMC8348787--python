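"""The 43-dimension window feature vector.

Thirteen feature families computed per window, in canonical order:

====================  =====  ==========================================
family                count  channels
====================  =====  ==========================================
mean                      4  acc x/y/z, temperature
standard deviation        3  acc axes (population form)
cosine similarity         3  acc axis pairs (x,y), (x,z), (y,z)
root mean square          3  gyro axes
skewness                  3  acc axes
kurtosis                  3  acc axes
maximum                   3  acc axes
minimum                   3  acc axes
zero crossings            3  acc axes (strict sign changes)
FFT magnitude             6  mean-removed acceleration magnitude
entropy                   3  acc axes (binned Shannon entropy)
first quartile Q1         3  acc axes (grouped-data estimate)
peak time difference      3  acc axes, |t(max) - t(min)| seconds
====================  =====  ==========================================

The six spectral features come from the one-sided DFT magnitude of the
mean-removed acceleration magnitude sqrt(ax^2+ay^2+az^2): the peak
magnitude (``peakf``), the first three non-DC bin magnitudes
(``lowf1..lowf3``), and band-mean magnitudes over (5, 15] Hz (``medf``)
and (15, 25] Hz (``highf``).  Acceleration magnitude keeps the spectral
family orientation-invariant and the feature count at exactly six.

Degenerate windows (zero variance, zero vector norm) are legal — a subject
laying still produces them — and map to finite values: skewness, kurtosis,
entropy and cosine similarity of a zero-norm pair become 0, the grouped Q1
of a constant window is that constant.

All public single-feature operations accept 1-D sample sequences; the
extraction entry points operate on :class:`~mpar.segmentation.Window`
objects and use vectorised batch kernels internally, so extracting a
feature table over tens of thousands of windows costs seconds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .segmentation import Window
from .signal_io import CANONICAL_FEATURE_NAMES, FEATURE_FAMILY_SIZES, FeatureTable

__all__ = [
    "FeatureSpec",
    "FeatureVector",
    "f_mean",
    "f_std",
    "f_cosine_similarity",
    "f_rms",
    "f_skewness",
    "f_kurtosis",
    "f_minmax",
    "f_zero_crossings",
    "f_fft_features",
    "f_entropy",
    "f_quartile_q1",
    "f_peak_time_diff",
    "fft_peak_frequency",
    "extract_feature_vector",
    "extract_feature_table",
]

FFT_FEATURE_NAMES = ("peakf", "lowf1", "lowf2", "lowf3", "medf", "highf")


@dataclass(frozen=True)
class FeatureSpec:
    """Tunable knobs of the 43-feature schema.

    entropy_bins
        Equal-width histogram bins for the entropy features (default 16).
    q1_bins
        Equal-width classes for the grouped first-quartile estimate
        (default 10).
    entropy_literal
        Apply the extra 1/N scaling some formulations print; off by
        default because it makes entropy window-length dependent.
    skew_literal
        Drop the 1/N moment normalisation from skewness (the unnormalised
        third-moment sum); off by default for consistency with kurtosis.
    med_band, high_band
        (lo, hi] frequency bands in Hz averaged for ``medf``/``highf``.
    """

    entropy_bins: int = 16
    q1_bins: int = 10
    entropy_literal: bool = False
    skew_literal: bool = False
    med_band: tuple[float, float] = (5.0, 15.0)
    high_band: tuple[float, float] = (15.0, 25.0)

    feature_names: tuple[str, ...] = CANONICAL_FEATURE_NAMES
    family_sizes: tuple[int, ...] = FEATURE_FAMILY_SIZES

    @property
    def n_features(self) -> int:
        return len(self.feature_names)


DEFAULT_SPEC = FeatureSpec()


@dataclass
class FeatureVector:
    """43 ordered feature values plus label and provenance."""

    values: np.ndarray
    label: str
    subject_id: str
    start_time: float
    feature_names: tuple[str, ...] = CANONICAL_FEATURE_NAMES

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.feature_names, self.values))


# ---------------------------------------------------------------------------
# batch kernels: each takes a (n_windows, N) array, returns (n_windows,)

def _as_batch(samples) -> np.ndarray:
    x = np.asarray(samples, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    return x


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


def _b_mean(x: np.ndarray) -> np.ndarray:
    return x.mean(axis=1)


def _b_std(x: np.ndarray) -> np.ndarray:
    # population form: sqrt((1/N) sum (S_i - mu)^2)
    return x.std(axis=1, ddof=0)


def _b_cos(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    num = np.einsum("ij,ij->i", a, b)
    den = np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
    out = np.zeros(a.shape[0])
    np.divide(num, den, out=out, where=den > 0)
    return np.clip(out, -1.0, 1.0)


def _b_rms(x: np.ndarray) -> np.ndarray:
    return np.sqrt(np.mean(x * x, axis=1))


def _sigma_floor(mu: np.ndarray) -> np.ndarray:
    # spreads below float rounding noise count as zero (constant window)
    return 64 * np.finfo(float).eps * np.maximum(1.0, np.abs(mu[:, 0]))


def _b_skew(x: np.ndarray, literal: bool = False) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    d = x - mu
    sigma = np.sqrt(np.mean(d * d, axis=1))
    m3 = np.mean(d**3, axis=1)
    out = np.zeros(x.shape[0])
    np.divide(m3, sigma**3, out=out, where=sigma > _sigma_floor(mu))
    if literal:
        out *= x.shape[1]
    return out


def _b_kurt(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    d = x - mu
    sigma = np.sqrt(np.mean(d * d, axis=1))
    m4 = np.mean(d**4, axis=1)
    out = np.zeros(x.shape[0])
    np.divide(m4, sigma**4, out=out, where=sigma > _sigma_floor(mu))
    return out


def _b_zc(x: np.ndarray) -> np.ndarray:
    a, b = x[:, :-1], x[:, 1:]
    return np.sum(((a < 0) & (b > 0)) | ((a > 0) & (b < 0)), axis=1).astype(float)


def _bin_indices(x: np.ndarray, bins: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-row equal-width bin index over [row min, row max]; returns
    (indices, row range, row min).  Constant rows collapse into bin 0."""
    lo = x.min(axis=1, keepdims=True)
    rng = x.max(axis=1, keepdims=True) - lo
    scaled = np.zeros_like(x)
    np.divide(x - lo, rng, out=scaled, where=rng > 0)
    idx = np.minimum((scaled * bins).astype(int), bins - 1)
    return idx, rng[:, 0], lo[:, 0]


def _row_bincount(idx: np.ndarray, bins: int) -> np.ndarray:
    n_rows = idx.shape[0]
    offsets = np.arange(n_rows)[:, None] * bins
    flat = np.bincount((idx + offsets).ravel(), minlength=n_rows * bins)
    return flat.reshape(n_rows, bins)


def _b_entropy(x: np.ndarray, bins: int, literal: bool = False) -> np.ndarray:
    idx, _, _ = _bin_indices(x, bins)
    counts = _row_bincount(idx, bins)
    p = counts / x.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    h = -terms.sum(axis=1)
    if literal:
        h = h / x.shape[1]
    return h


def _b_q1(x: np.ndarray, bins: int) -> np.ndarray:
    """Grouped-data first quartile: Q1 = l + (h/f)(N/4 - C) over B
    equal-width classes of [min, max]; l/f/C taken at the class holding
    the ceil(N/4)-th ordered sample.  Constant rows return the constant."""
    n = x.shape[1]
    idx, rng, lo = _bin_indices(x, bins)
    counts = _row_bincount(idx, bins)
    cum = counts.cumsum(axis=1)
    k = -(-n // 4)  # ceil(N/4)
    cls = (cum >= k).argmax(axis=1)
    rows = np.arange(x.shape[0])
    f = counts[rows, cls].astype(float)
    c_below = cum[rows, cls] - counts[rows, cls]
    h = rng / bins
    l = lo + cls * h
    q1 = l + np.divide(h, f, out=np.zeros_like(f), where=f > 0) * (n / 4.0 - c_below)
    return np.where(rng > 0, q1, lo)


def _b_peak_dt(x: np.ndarray, fs: float) -> np.ndarray:
    # first-occurrence ties, as argmax/argmin give
    return np.abs(x.argmax(axis=1) - x.argmin(axis=1)) / fs


def _b_fft(acc: np.ndarray, fs: float, spec: FeatureSpec) -> np.ndarray:
    """Six spectral features per window from (n_windows, N, 3) acceleration."""
    n = acc.shape[1]
    _require(n >= 4, f"FFT features need at least 4 samples, got {n}")
    mag = np.linalg.norm(acc, axis=2)
    mag = mag - mag.mean(axis=1, keepdims=True)
    spectrum = np.abs(np.fft.rfft(mag, axis=1))  # k = 0 .. N//2
    half = spectrum[:, 1 : n // 2 + 1]  # one-sided, DC excluded
    freqs = np.arange(1, n // 2 + 1) * fs / n
    peakf = half.max(axis=1)
    low = half[:, 0:3]
    med_mask = (freqs > spec.med_band[0]) & (freqs <= spec.med_band[1])
    high_mask = (freqs > spec.high_band[0]) & (freqs <= spec.high_band[1])
    medf = half[:, med_mask].mean(axis=1) if med_mask.any() else np.zeros(len(half))
    highf = half[:, high_mask].mean(axis=1) if high_mask.any() else np.zeros(len(half))
    return np.column_stack([peakf, low, medf, highf])


# ---------------------------------------------------------------------------
# public single-window operations

def f_mean(samples: Sequence[float]) -> float:
    """Arithmetic mean (1/N) sum S_i."""
    x = _as_batch(samples)
    _require(x.shape[1] >= 1, "mean of empty window")
    return float(_b_mean(x)[0])


def f_std(samples: Sequence[float]) -> float:
    """Population standard deviation sqrt((1/N) sum (S_i - mu)^2)."""
    x = _as_batch(samples)
    _require(x.shape[1] >= 1, "std of empty window")
    return float(_b_std(x)[0])


def f_cosine_similarity(a: Sequence[float], b: Sequence[float]) -> float:
    """Cosine of the angle between two axis sample vectors, in [-1, 1].

    A zero-norm input has no direction; the similarity is defined as 0.
    """
    xa, xb = _as_batch(a), _as_batch(b)
    _require(xa.shape == xb.shape, "cosine similarity needs equal lengths")
    return float(_b_cos(xa, xb)[0])


def f_rms(gyro_samples: Sequence[float]) -> float:
    """Root mean square sqrt((1/N) sum G_i^2) — angular-movement energy."""
    x = _as_batch(gyro_samples)
    _require(x.shape[1] >= 1, "RMS of empty window")
    return float(_b_rms(x)[0])


def f_skewness(samples: Sequence[float], literal: bool = False) -> float:
    """Third standardised moment (1/N) sum ((S_i - mu)/sigma)^3; 0 when sigma = 0.

    ``literal=True`` drops the 1/N normalisation (unnormalised sum form).
    """
    x = _as_batch(samples)
    _require(x.shape[1] >= 2, "skewness needs at least 2 samples")
    return float(_b_skew(x, literal)[0])


def f_kurtosis(samples: Sequence[float]) -> float:
    """Fourth moment ratio sum (S_i - mu)^4 / (N sigma^4); 0 when sigma = 0."""
    x = _as_batch(samples)
    _require(x.shape[1] >= 2, "kurtosis needs at least 2 samples")
    return float(_b_kurt(x)[0])


def f_minmax(samples: Sequence[float]) -> tuple[float, float]:
    """(min, max) of the window."""
    x = np.asarray(samples, dtype=float)
    _require(x.size >= 1, "extrema of empty window")
    return float(x.min()), float(x.max())


def f_zero_crossings(samples: Sequence[float]) -> int:
    """Count of adjacent strict sign changes; exact zeros never cross."""
    x = _as_batch(samples)
    _require(x.shape[1] >= 2, "zero crossings need at least 2 samples")
    return int(_b_zc(x)[0])


def f_fft_features(window: Window, spec: FeatureSpec = DEFAULT_SPEC) -> np.ndarray:
    """(peakf, lowf1, lowf2, lowf3, medf, highf) of one window.

    Computed from the one-sided DFT magnitude of the window's mean-removed
    acceleration magnitude signal.
    """
    return _b_fft(window.acc[None, :, :], window.sampling_rate, spec)[0]


def fft_peak_frequency(window: Window, spec: FeatureSpec = DEFAULT_SPEC) -> float:
    """Frequency (Hz) of the dominant non-DC spectral bin — a diagnostic
    companion to ``peakf`` (which reports the peak magnitude)."""
    n = window.n
    mag = np.linalg.norm(window.acc, axis=1)
    spectrum = np.abs(np.fft.rfft(mag - mag.mean()))
    half = spectrum[1 : n // 2 + 1]
    return float((int(half.argmax()) + 1) * window.sampling_rate / n)


def f_entropy(samples: Sequence[float], spec: FeatureSpec = DEFAULT_SPEC) -> float:
    """Shannon entropy (bits) of a B-bin equal-width histogram of the window.

    Separates static windows (one occupied bin, entropy 0) from dynamic
    ones (mass spread over bins).  ``spec.entropy_literal`` applies an
    extra 1/N scaling.
    """
    x = _as_batch(samples)
    _require(x.shape[1] >= 1, "entropy of empty window")
    return float(_b_entropy(x, spec.entropy_bins, spec.entropy_literal)[0])


def f_quartile_q1(samples: Sequence[float], spec: FeatureSpec = DEFAULT_SPEC) -> float:
    """Grouped-data first quartile Q1 = l + (h/f)(N/4 - C).

    The window is binned into B equal-width classes over [min, max]; l is
    the lower bound of the class containing the ceil(N/4)-th ordered
    sample, h the class width, f its frequency and C the cumulative
    frequency below it.  A constant window returns the constant.
    """
    x = _as_batch(samples)
    _require(x.shape[1] >= 4, "grouped Q1 needs at least 4 samples")
    return float(_b_q1(x, spec.q1_bins)[0])


def f_peak_time_diff(samples: Sequence[float], sampling_rate: float = 50.0) -> float:
    """|t(argmax) - t(argmin)| in seconds, first occurrence breaking ties."""
    x = _as_batch(samples)
    _require(x.shape[1] >= 1, "peak time difference of empty window")
    return float(_b_peak_dt(x, sampling_rate)[0])


# ---------------------------------------------------------------------------
# extraction

def _batch_features(
    acc: np.ndarray, gyro: np.ndarray, temp: np.ndarray, fs: float, spec: FeatureSpec
) -> np.ndarray:
    """Compute the (n_windows, 43) feature matrix from stacked channels."""
    ax, ay, az = acc[:, :, 0], acc[:, :, 1], acc[:, :, 2]
    cols: list[np.ndarray] = []
    cols += [_b_mean(ax), _b_mean(ay), _b_mean(az), _b_mean(temp)]
    cols += [_b_std(a) for a in (ax, ay, az)]
    cols += [_b_cos(ax, ay), _b_cos(ax, az), _b_cos(ay, az)]
    cols += [_b_rms(gyro[:, :, i]) for i in range(3)]
    cols += [_b_skew(a, spec.skew_literal) for a in (ax, ay, az)]
    cols += [_b_kurt(a) for a in (ax, ay, az)]
    cols += [a.max(axis=1) for a in (ax, ay, az)]
    cols += [a.min(axis=1) for a in (ax, ay, az)]
    cols += [_b_zc(a) for a in (ax, ay, az)]
    fft = _b_fft(acc, fs, spec)
    cols += [fft[:, i] for i in range(6)]
    cols += [_b_entropy(a, spec.entropy_bins, spec.entropy_literal) for a in (ax, ay, az)]
    cols += [_b_q1(a, spec.q1_bins) for a in (ax, ay, az)]
    cols += [_b_peak_dt(a, fs) for a in (ax, ay, az)]
    return np.column_stack(cols)


def _check_window(window: Window) -> None:
    for name in ("acc", "gyro", "temp"):
        arr = getattr(window, name, None)
        if arr is None or np.asarray(arr).size == 0:
            raise KeyError(f"window is missing channel data: {name}")


def extract_feature_vector(
    window: Window, spec: FeatureSpec = DEFAULT_SPEC
) -> FeatureVector:
    """Compute the full 43-value feature vector of one window."""
    _check_window(window)
    values = _batch_features(
        window.acc[None], window.gyro[None], window.temp[None],
        window.sampling_rate, spec,
    )[0]
    return FeatureVector(
        values=values,
        label=window.activity_label,
        subject_id=window.subject_id,
        start_time=window.start_time,
        feature_names=spec.feature_names,
    )


def extract_feature_table(
    windows: Iterable[Window], spec: FeatureSpec = DEFAULT_SPEC
) -> FeatureTable:
    """One feature row per window, preserving window order.

    Equivalent to mapping :func:`extract_feature_vector` over the windows,
    but computed with vectorised kernels over the stacked channel arrays.
    """
    windows = list(windows)
    if not windows:
        import pandas as pd

        frame = pd.DataFrame(
            columns=list(FeatureTable.KEY_COLUMNS) + list(spec.feature_names)
        )
        return FeatureTable(frame, spec.feature_names)
    for w in windows:
        _check_window(w)
    acc = np.stack([w.acc for w in windows])
    gyro = np.stack([w.gyro for w in windows])
    temp = np.stack([w.temp for w in windows])
    values = _batch_features(acc, gyro, temp, windows[0].sampling_rate, spec)
    rows = (
        (w.subject_id, w.activity_label, values[i])
        for i, w in enumerate(windows)
    )
    return FeatureTable.from_rows(rows, spec.feature_names)
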