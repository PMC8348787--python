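"""Feature formulas against independent brute-force oracles, plus the
shift/scale invariances the statistics must satisfy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import oracles
from conftest import random_window_samples
from mpar import FeatureSpec, Window, extract_feature_table, extract_feature_vector
from mpar import features as F
from mpar.signal_io import CANONICAL_FEATURE_NAMES, FEATURE_FAMILY_SIZES


def make_window(acc, gyro=None, temp=None, fs=50.0, label="MPA1", subject="S01"):
    acc = np.asarray(acc, dtype=float)
    n = acc.shape[0]
    gyro = np.zeros((n, 3)) if gyro is None else np.asarray(gyro, dtype=float)
    temp = np.full(n, 33.0) if temp is None else np.asarray(temp, dtype=float)
    return Window(0.0, acc, gyro, temp, label, subject, fs)


def random_window(rng, n=50):
    acc = np.column_stack([random_window_samples(rng, n) for _ in range(3)])
    gyro = np.column_stack([random_window_samples(rng, n, scale=30.0) for _ in range(3)])
    temp = np.full(n, 33.0 + rng.normal(0, 0.5))
    return make_window(acc, gyro, temp)


class TestScalarExamples:
    def test_documented_values(self):
        assert F.f_mean([1, 2, 3, 4]) == pytest.approx(2.5)
        assert F.f_mean([7.0] * 10) == pytest.approx(7.0)
        assert F.f_std([5.0] * 8) == 0.0
        assert F.f_std([1, 2, 3, 4]) == pytest.approx(np.sqrt(1.25))
        assert F.f_cosine_similarity([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert F.f_cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)
        assert F.f_rms([3, 4]) == pytest.approx(np.sqrt(12.5))
        assert F.f_rms([-2.0] * 5) == pytest.approx(2.0)
        assert F.f_skewness([1, 2, 3]) == pytest.approx(0.0)
        assert F.f_skewness([4.0] * 6) == 0.0
        assert F.f_kurtosis([4.0] * 6) == 0.0
        assert F.f_kurtosis([-1, 1, -1, 1]) == pytest.approx(1.0)
        assert F.f_minmax([3, -1, 7]) == (-1.0, 7.0)
        assert F.f_minmax([2.0, 2.0]) == (2.0, 2.0)
        assert F.f_zero_crossings([1, -1, 1]) == 2
        assert F.f_zero_crossings([1, 2, 3]) == 0
        assert F.f_zero_crossings([1, 0, 1]) == 0  # exact zero never crosses
        assert F.f_entropy(np.full(50, 2.0)) == 0.0
        assert F.f_quartile_q1(np.full(50, 3.3)) == pytest.approx(3.3)
        x = np.zeros(50)
        x[10], x[40] = 5.0, -5.0
        assert F.f_peak_time_diff(x, 50.0) == pytest.approx(0.6)
        assert F.f_peak_time_diff(np.full(50, 1.0)) == 0.0

    def test_entropy_uniform_spread_hits_log2_bins(self):
        spec = FeatureSpec(entropy_bins=16)
        # 32 samples spread evenly over 16 bins -> maximal entropy log2(16)
        x = np.repeat(np.linspace(0.0, 1.0, 16), 2) + np.tile([0.0, 0.001], 16)
        assert F.f_entropy(np.sort(x), spec) == pytest.approx(4.0)

    def test_q1_near_order_statistic_quartile(self):
        x = np.arange(1.0, 101.0)
        spec = FeatureSpec(q1_bins=10)
        q1 = F.f_quartile_q1(x, spec)
        assert abs(q1 - 25.5) <= (x.max() - x.min()) / spec.q1_bins

    def test_empty_and_short_inputs_raise(self):
        for fn in (F.f_mean, F.f_std, F.f_rms):
            with pytest.raises(ValueError):
                fn([])
        with pytest.raises(ValueError):
            F.f_skewness([1.0])
        with pytest.raises(ValueError):
            F.f_quartile_q1([1.0, 2.0])

    def test_cosine_zero_norm_defined_as_zero(self):
        assert F.f_cosine_similarity([0, 0, 0], [1, 2, 3]) == 0.0


N_ORACLE_WINDOWS = 1000


@pytest.fixture(scope="module")
def windows():
    rng = np.random.default_rng(991)
    return [
        random_window_samples(rng, n)
        for n in rng.choice([50, 100], size=N_ORACLE_WINDOWS)
    ]


class TestBruteForceOracles:
    """Each family matches an independent loop evaluation of its formula
    on 1000 random windows (1e-9; exact for the integer-valued family)."""

    @pytest.mark.parametrize(
        "impl,oracle",
        [
            (F.f_mean, oracles.o_mean),
            (F.f_std, oracles.o_std),
            (F.f_rms, oracles.o_rms),
            (F.f_skewness, oracles.o_skewness),
            (F.f_kurtosis, oracles.o_kurtosis),
            (F.f_minmax, oracles.o_minmax),
            (F.f_entropy, lambda x: oracles.o_entropy(x, bins=16)),
            (F.f_quartile_q1, lambda x: oracles.o_quartile_q1(x, bins=10)),
            (F.f_peak_time_diff, oracles.o_peak_time_diff),
        ],
        ids=["mean", "std", "rms", "skew", "kurt", "minmax", "entropy", "q1", "peak_dt"],
    )
    def test_scalar_families(self, windows, impl, oracle):
        for x in windows:
            np.testing.assert_allclose(
                np.atleast_1d(impl(x)), np.atleast_1d(oracle(list(x))), atol=1e-9
            )

    def test_zero_crossings_exact(self, windows):
        rng = np.random.default_rng(5)
        for x in windows[:500]:
            assert F.f_zero_crossings(x) == oracles.o_zero_crossings(list(x))
        for _ in range(500):  # dense-crossing stress: random +-1 sequences
            x = rng.choice([-1.0, 1.0], size=50)
            assert F.f_zero_crossings(x) == oracles.o_zero_crossings(list(x))

    def test_cosine_similarity_pairs(self, windows):
        for a, b in zip(windows[:500], windows[500:]):
            m = min(len(a), len(b))
            np.testing.assert_allclose(
                F.f_cosine_similarity(a[:m], b[:m]),
                oracles.o_cosine(list(a[:m]), list(b[:m])),
                atol=1e-9,
            )

    def test_fft_features_match_naive_dft(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            w = random_window(rng, n=int(rng.choice([50, 100])))
            np.testing.assert_allclose(
                F.f_fft_features(w),
                oracles.o_fft_features(w.acc.tolist()),
                atol=1e-9,
            )

    def test_fft_constant_window_is_all_zero(self):
        w = make_window(np.ones((50, 3)))
        np.testing.assert_allclose(F.f_fft_features(w), np.zeros(6), atol=1e-12)

    def test_fft_pure_tone_peaks_at_its_bin(self):
        t = np.arange(50) / 50.0
        tone = np.sin(2 * np.pi * 5.0 * t)
        # orient the tone along x so the magnitude signal carries it
        acc = np.column_stack([10.0 + tone, np.zeros(50), np.zeros(50)])
        w = make_window(acc)
        peakf, lowf1, lowf2, lowf3, _, _ = F.f_fft_features(w)
        mag = np.linalg.norm(acc, axis=1)
        spectrum = np.abs(np.fft.rfft(mag - mag.mean()))
        assert peakf == pytest.approx(spectrum[5], abs=1e-9)
        assert spectrum[1:26].argmax() == 4  # 5 Hz bin (index 4 past DC)
        for low in (lowf1, lowf2, lowf3):
            assert low < 0.05 * peakf

    def test_peak_frequency_companion(self):
        t = np.arange(100) / 50.0
        acc = np.column_stack(
            [1.0 + np.sin(2 * np.pi * 7.0 * t), np.zeros(100), np.zeros(100)]
        )
        assert F.fft_peak_frequency(make_window(acc)) == pytest.approx(7.0)


class TestExtraction:
    def test_vector_has_43_canonically_ordered_values(self, rng):
        fv = extract_feature_vector(random_window(rng))
        assert fv.values.shape == (43,)
        assert fv.feature_names == CANONICAL_FEATURE_NAMES
        assert sum(FEATURE_FAMILY_SIZES) == 43
        assert FEATURE_FAMILY_SIZES == (4, 3, 3, 3, 3, 3, 3, 3, 3, 6, 3, 3, 3)

    def test_constant_window_degenerates_cleanly(self):
        acc = np.tile([0.3, -0.5, 0.81], (50, 1))
        w = make_window(acc, temp=np.full(50, 34.0))
        d = extract_feature_vector(w).as_dict()
        assert d["mean_acc_x"] == pytest.approx(0.3)
        assert d["mean_acc_y"] == pytest.approx(-0.5)
        assert d["mean_temp"] == pytest.approx(34.0)
        for name in ("std_acc_x", "zc_acc_y", "entropy_acc_z", "skew_acc_x",
                     "kurt_acc_y", "peak_dt_acc_z", "fft_peakf"):
            assert d[name] == pytest.approx(0.0)
        assert d["q1_acc_x"] == pytest.approx(0.3)
        assert d["max_acc_z"] == d["min_acc_z"] == pytest.approx(0.81)

    def test_vector_composes_the_individual_operations(self, rng):
        spec = FeatureSpec()
        for _ in range(25):
            w = random_window(rng, n=int(rng.choice([50, 100])))
            d = extract_feature_vector(w, spec).as_dict()
            ax, ay, az = w.acc[:, 0], w.acc[:, 1], w.acc[:, 2]
            expected = {
                "mean_acc_x": F.f_mean(ax),
                "mean_temp": F.f_mean(w.temp),
                "std_acc_y": F.f_std(ay),
                "cos_acc_xz": F.f_cosine_similarity(ax, az),
                "rms_gyro_y": F.f_rms(w.gyro[:, 1]),
                "skew_acc_z": F.f_skewness(az),
                "kurt_acc_x": F.f_kurtosis(ax),
                "max_acc_y": F.f_minmax(ay)[1],
                "min_acc_x": F.f_minmax(ax)[0],
                "zc_acc_z": float(F.f_zero_crossings(az)),
                "entropy_acc_x": F.f_entropy(ax, spec),
                "q1_acc_y": F.f_quartile_q1(ay, spec),
                "peak_dt_acc_x": F.f_peak_time_diff(ax, w.sampling_rate),
            }
            for k, v in expected.items():
                assert d[k] == pytest.approx(v, abs=1e-9), k
            np.testing.assert_allclose(
                [d[f"fft_{n}"] for n in F.FFT_FEATURE_NAMES],
                F.f_fft_features(w, spec),
                atol=1e-9,
            )

    def test_table_equals_mapped_vectors_and_preserves_order(self, rng):
        windows = [random_window(rng) for _ in range(19)]
        table = extract_feature_table(windows)
        assert len(table) == 19
        expected = np.stack([extract_feature_vector(w).values for w in windows])
        np.testing.assert_allclose(table.X, expected, atol=1e-12)
        assert list(table.y) == [w.activity_label for w in windows]

    def test_empty_window_sequence_gives_empty_table_with_header(self):
        table = extract_feature_table([])
        assert len(table) == 0
        assert tuple(table.frame.columns[2:]) == CANONICAL_FEATURE_NAMES

    def test_literal_modes_rescale_as_printed(self, rng):
        w = random_window(rng)
        x = w.acc[:, 0]
        assert F.f_skewness(x, literal=True) == pytest.approx(
            50 * F.f_skewness(x), rel=1e-12
        )
        lit = FeatureSpec(entropy_literal=True)
        assert F.f_entropy(x, lit) == pytest.approx(F.f_entropy(x) / 50, rel=1e-12)


# windows on a 0.1 grid in [-50, 50]: spreads are either 0 or >= 0.1, so
# shift/scale identities are numerically exact-ish and never degenerate
grid_windows = hnp.arrays(
    np.float64, st.integers(8, 64), elements=st.integers(-500, 500)
).map(lambda a: a / 10.0)


class TestInvariances:
    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(x=grid_windows, c=st.integers(-100, 100).map(lambda v: v / 10.0))
    def test_shift_moves_location_not_shape(self, x, c):
        shifted = x + c
        assert F.f_std(shifted) == pytest.approx(F.f_std(x), abs=1e-8)
        assert F.f_skewness(shifted) == pytest.approx(F.f_skewness(x), abs=1e-6)
        assert F.f_kurtosis(shifted) == pytest.approx(F.f_kurtosis(x), abs=1e-5)
        assert F.f_peak_time_diff(shifted) == F.f_peak_time_diff(x)
        assert F.f_mean(shifted) == pytest.approx(F.f_mean(x) + c, abs=1e-9)
        lo, hi = F.f_minmax(x)
        assert F.f_minmax(shifted) == (pytest.approx(lo + c), pytest.approx(hi + c))

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(x=grid_windows, c=st.integers(1, 200).map(lambda v: v / 10.0))
    def test_positive_scaling_covariance(self, x, c):
        scaled = c * x
        assert F.f_std(scaled) == pytest.approx(c * F.f_std(x), rel=1e-9, abs=1e-9)
        assert F.f_rms(scaled) == pytest.approx(c * F.f_rms(x), rel=1e-9, abs=1e-9)
        lo, hi = F.f_minmax(x)
        assert F.f_minmax(scaled) == (
            pytest.approx(c * lo, rel=1e-12),
            pytest.approx(c * hi, rel=1e-12),
        )
        assert F.f_skewness(scaled) == pytest.approx(F.f_skewness(x), abs=1e-6)
        assert F.f_kurtosis(scaled) == pytest.approx(F.f_kurtosis(x), abs=1e-5)
        assert F.f_zero_crossings(scaled) == F.f_zero_crossings(x)
        assert F.f_cosine_similarity(scaled, scaled) == pytest.approx(
            F.f_cosine_similarity(x, x), abs=1e-9
        )
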