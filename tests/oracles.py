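"""Independent brute-force oracles for the window-feature formulas.

Every oracle evaluates its formula with plain Python loops and ``math``,
sharing no code with the implementation under test.
"""

from __future__ import annotations

import cmath
import math
from typing import Sequence


def o_mean(xs: Sequence[float]) -> float:
    total = 0.0
    for x in xs:
        total += x
    return total / len(xs)


def o_std(xs: Sequence[float]) -> float:
    mu = o_mean(xs)
    acc = 0.0
    for x in xs:
        acc += (x - mu) ** 2
    return math.sqrt(acc / len(xs))


def o_cosine(a: Sequence[float], b: Sequence[float]) -> float:
    dot = na = nb = 0.0
    for x, y in zip(a, b):
        dot += x * y
        na += x * x
        nb += y * y
    if na == 0.0 or nb == 0.0:
        return 0.0
    return dot / (math.sqrt(na) * math.sqrt(nb))


def o_rms(xs: Sequence[float]) -> float:
    acc = 0.0
    for x in xs:
        acc += x * x
    return math.sqrt(acc / len(xs))


def o_skewness(xs: Sequence[float]) -> float:
    mu = o_mean(xs)
    sigma = o_std(xs)
    if sigma == 0.0:
        return 0.0
    acc = 0.0
    for x in xs:
        acc += ((x - mu) / sigma) ** 3
    return acc / len(xs)


def o_kurtosis(xs: Sequence[float]) -> float:
    mu = o_mean(xs)
    sigma = o_std(xs)
    if sigma == 0.0:
        return 0.0
    acc = 0.0
    for x in xs:
        acc += (x - mu) ** 4
    return acc / (len(xs) * sigma**4)


def o_minmax(xs: Sequence[float]) -> tuple[float, float]:
    ordered = sorted(xs)
    return ordered[0], ordered[-1]


def o_zero_crossings(xs: Sequence[float]) -> int:
    count = 0
    for prev, cur in zip(xs, xs[1:]):
        if (prev < 0 and cur > 0) or (prev > 0 and cur < 0):
            count += 1
    return count


def o_entropy(xs: Sequence[float], bins: int = 16, literal: bool = False) -> float:
    lo, hi = o_minmax(xs)
    width = hi - lo
    counts = [0] * bins
    for x in xs:
        if width == 0.0:
            counts[0] += 1
        else:
            idx = int((x - lo) / width * bins)
            counts[min(idx, bins - 1)] += 1
    n = len(xs)
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / n
            h -= p * math.log2(p)
    return h / n if literal else h


def o_quartile_q1(xs: Sequence[float], bins: int = 10) -> float:
    lo, hi = o_minmax(xs)
    width = hi - lo
    if width == 0.0:
        return lo
    n = len(xs)
    counts = [0] * bins
    for x in xs:
        idx = int((x - lo) / width * bins)
        counts[min(idx, bins - 1)] += 1
    k = math.ceil(n / 4)  # rank of the sample whose class we use
    cum = 0
    for cls, c in enumerate(counts):
        if cum + c >= k:
            h = width / bins
            l = lo + cls * h
            return l + h / c * (n / 4 - cum)
        cum += c
    raise AssertionError("unreachable: ranks exhaust the classes")


def o_peak_time_diff(xs: Sequence[float], fs: float = 50.0) -> float:
    i_max = i_min = 0
    for i, x in enumerate(xs):
        if x > xs[i_max]:
            i_max = i
        if x < xs[i_min]:
            i_min = i
    return abs(i_max - i_min) / fs


def o_naive_dft_magnitudes(xs: Sequence[float]) -> list[float]:
    """One-sided |H(k)|, k = 1 .. N//2, by the O(N^2) definition."""
    n = len(xs)
    out = []
    for k in range(1, n // 2 + 1):
        h = 0j
        for i, x in enumerate(xs):
            h += x * cmath.exp(-2j * cmath.pi * k * i / n)
        out.append(abs(h))
    return out


def o_fft_features(
    acc_rows: Sequence[Sequence[float]],
    fs: float = 50.0,
    med_band: tuple[float, float] = (5.0, 15.0),
    high_band: tuple[float, float] = (15.0, 25.0),
) -> list[float]:
    """(peakf, lowf1..3, medf, highf) from (N, 3) acceleration rows."""
    mag = [math.sqrt(x * x + y * y + z * z) for x, y, z in acc_rows]
    mu = o_mean(mag)
    mag = [m - mu for m in mag]
    half = o_naive_dft_magnitudes(mag)
    n = len(mag)
    freqs = [k * fs / n for k in range(1, n // 2 + 1)]
    med = [h for h, f in zip(half, freqs) if med_band[0] < f <= med_band[1]]
    high = [h for h, f in zip(half, freqs) if high_band[0] < f <= high_band[1]]
    return [
        max(half),
        half[0],
        half[1],
        half[2],
        o_mean(med) if med else 0.0,
        o_mean(high) if high else 0.0,
    ]


def o_alert_schedule(
    runs: Sequence[tuple[float, int, bool]],
    sustain: float,
    cooldown: float,
    window_seconds: float,
) -> list[float]:
    """Expected alert emission times from maximal same-label runs.

    ``runs`` are (start_time, n_windows, proscribed) triples of maximal
    constant-label runs.  Coverage is known only at window ends
    start + k*w: the first alert fires once coverage reaches ``sustain``
    (back-dated to start+sustain); a re-alert fires at each later window
    end at least ``cooldown`` after the previous emission.
    """
    emissions: list[float] = []
    for start, n_windows, proscribed in runs:
        if not proscribed:
            continue
        covered = n_windows * window_seconds
        if covered < sustain:
            continue
        last = start + sustain
        emissions.append(last)
        k_first = math.ceil(sustain / window_seconds - 1e-9)
        for k in range(k_first + 1, n_windows + 1):
            g = start + k * window_seconds
            if g - last >= cooldown - 1e-9:
                emissions.append(g)
                last = g
    return emissions
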