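"""Feature definitions against hand calculations and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from liftsafe import features as ft
from liftsafe.errors import DataError


class TestTimeDomainExamples:
    @pytest.mark.parametrize(
        "x, expected",
        [([1, 1, 1, 1], 0.0), ([0, 2], 1.41421), ([1, 2, 3, 4, 5], 1.58114)],
    )
    def test_std(self, x, expected):
        assert ft.std(x) == pytest.approx(expected, abs=1e-5)

    @pytest.mark.parametrize("x, expected", [([1, -1, 1, -1], 1.0), ([-3, 0, 3], 2.0)])
    def test_mav(self, x, expected):
        assert ft.mav(x) == pytest.approx(expected)

    @pytest.mark.parametrize("x, expected", [([5, 5, 5], 0.0), ([-2, 5], 7.0)])
    def test_pp(self, x, expected):
        assert ft.pp(x) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "x, expected",
        [
            ([1, -1, 1, -1], 3),
            ([1, 2, 3], 0),
            # strict inequalities: an exact zero breaks both clauses
            ([1, 0, -1], 0),
        ],
    )
    def test_zcr(self, x, expected):
        assert ft.zcr(x) == expected

    @pytest.mark.parametrize(
        "x, expected",
        [([1, 2, 3, 4], 0), ([0, 1, 0, 1, 0], 3), ([2, 2, 2, 2], 0)],
    )
    def test_ssc(self, x, expected):
        assert ft.ssc(x) == expected

    def test_std_needs_two_samples(self):
        with pytest.raises(DataError):
            ft.std([1.0])


class TestSpectralExamples:
    def test_spectrum_of_constant(self):
        s = ft.power_spectrum([1, 1, 1, 1, 1, 1, 1, 1])
        assert s[0] == pytest.approx(64.0)
        assert np.allclose(s[1:], 0.0, atol=1e-9)

    def test_total_power_is_energy(self):
        # P = mean(S) equals sum of squared samples by Parseval
        x = np.arange(8, dtype=float)
        assert ft.total_power(ft.power_spectrum(x)) == pytest.approx(np.sum(x**2))

    def test_parseval(self, rng):
        x = rng.normal(size=200)
        s = ft.power_spectrum(x)
        assert np.sum(s) == pytest.approx(len(x) * np.sum(x**2), rel=1e-8)

    def test_entropy_degenerate_and_flat(self):
        single = np.array([0.0, 5.0, 0.0, 0.0])
        assert ft.spectral_entropy(single) == pytest.approx(0.0)
        flat = np.ones(16)
        assert ft.spectral_entropy(flat) == pytest.approx(1.0)
        assert ft.spectral_entropy(flat, normalized=False) == pytest.approx(4.0)

    def test_entropy_two_equal_bins_of_four(self):
        s = np.array([3.0, 0.0, 3.0, 0.0])
        assert ft.spectral_entropy(s, normalized=False) == pytest.approx(1.0)
        assert ft.spectral_entropy(s, normalized=True) == pytest.approx(0.5)

    def test_entropy_all_zero_raises(self):
        with pytest.raises(DataError):
            ft.spectral_entropy(np.zeros(8))

    def test_kurtosis_two_point_distribution(self):
        # symmetric two-point distribution has standardized 4th moment 1
        assert ft.spectral_kurtosis(np.array([1.0, 9.0, 1.0, 9.0])) == pytest.approx(-2.0)

    def test_kurtosis_of_gaussian_values(self):
        values = np.random.default_rng(7).normal(size=100_000)
        assert abs(ft.spectral_kurtosis(values)) < 0.1

    def test_kurtosis_affine_invariance(self, rng):
        s = rng.exponential(size=64)
        assert ft.spectral_kurtosis(3.5 * s + 2.0) == pytest.approx(
            ft.spectral_kurtosis(s), rel=1e-9
        )

    def test_skewness_hand_value(self):
        # {0,0,0,1}: mean 1/4, population sd sqrt(3)/4 -> skew = 2/sqrt(3)
        assert ft.spectral_skewness(np.array([0.0, 0.0, 0.0, 1.0])) == pytest.approx(
            1.1547, abs=1e-4
        )

    def test_skewness_symmetric_and_reflection(self, rng):
        sym = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert ft.spectral_skewness(sym) == pytest.approx(0.0, abs=1e-8)
        s = rng.exponential(size=64)
        reflected = 2 * s.mean() - s
        assert ft.spectral_skewness(reflected) == pytest.approx(
            -ft.spectral_skewness(s), rel=1e-9
        )

    def test_flat_spectrum_moments_raise(self):
        with pytest.raises(DataError):
            ft.spectral_kurtosis(np.ones(8))
        with pytest.raises(DataError):
            ft.spectral_skewness(np.ones(8))


def _random_segments(n_segments, rng):
    """Random segments including exact zeros and plateaus (via rounding)."""
    for _ in range(n_segments):
        n = int(rng.integers(8, 64))
        x = rng.normal(0, 1, n)
        if rng.random() < 0.3:
            x = np.round(x, 1)  # introduces ties and exact zeros
        yield x


def test_all_features_match_bruteforce_oracle(rng):
    """Implementation vs naive loop transcription, 1e-8 relative, 1000 segments."""
    for x in _random_segments(1000, rng):
        xs = list(map(float, x))
        assert ft.std(x) == pytest.approx(oracles.oracle_std(xs), rel=1e-8)
        assert ft.mav(x) == pytest.approx(oracles.oracle_mav(xs), rel=1e-8)
        assert ft.pp(x) == pytest.approx(oracles.oracle_pp(xs), rel=1e-8)
        assert ft.zcr(x) == oracles.oracle_zcr(xs)
        assert ft.ssc(x) == oracles.oracle_ssc(xs)
        s = ft.power_spectrum(x)
        assert ft.total_power(s) == pytest.approx(oracles.oracle_total_power(list(s)), rel=1e-8)
        assert ft.spectral_entropy(s) == pytest.approx(
            oracles.oracle_spectral_entropy(list(s)), rel=1e-8
        )
        assert ft.spectral_kurtosis(s) == pytest.approx(
            oracles.oracle_spectral_kurtosis(list(s)), rel=1e-8, abs=1e-8
        )
        assert ft.spectral_skewness(s) == pytest.approx(
            oracles.oracle_spectral_skewness(list(s)), rel=1e-8
        )


def test_spectrum_matches_dft_definition(rng):
    """FFT-based spectrum equals the defining double sum on short segments."""
    for _ in range(20):
        x = rng.normal(size=int(rng.integers(8, 24)))
        expected = oracles.oracle_spectrum(list(map(float, x)))
        assert np.allclose(ft.power_spectrum(x), expected, rtol=1e-7, atol=1e-7)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    data=st.lists(
        st.floats(min_value=-50, max_value=50, allow_nan=False), min_size=8, max_size=40
    ),
    c=st.floats(min_value=0.01, max_value=100.0),
)
def test_scaling_laws(data, c):
    """STD/MAV/PP/sqrt(P) are 1-homogeneous; counts and shape stats scale-free."""
    x = np.asarray(data)
    if np.all(x == x[0]):
        x = x + np.arange(len(x))  # avoid fully degenerate segments
    scaled = c * x
    assert ft.std(scaled) == pytest.approx(c * ft.std(x), rel=1e-9)
    assert ft.mav(scaled) == pytest.approx(c * ft.mav(x), rel=1e-9)
    assert ft.pp(scaled) == pytest.approx(c * ft.pp(x), rel=1e-9)
    ps, ps_scaled = ft.power_spectrum(x), ft.power_spectrum(scaled)
    assert np.sqrt(ft.total_power(ps_scaled)) == pytest.approx(
        c * np.sqrt(ft.total_power(ps)), rel=1e-6
    )
    assert ft.zcr(scaled) == ft.zcr(x)
    assert ft.ssc(scaled) == ft.ssc(x)
    if ps.sum() > 0:
        assert ft.spectral_entropy(ps_scaled) == pytest.approx(
            ft.spectral_entropy(ps), rel=1e-6
        )
    if np.std(ps) > 1e-12 * np.mean(ps):
        assert ft.spectral_kurtosis(ps_scaled) == pytest.approx(
            ft.spectral_kurtosis(ps), rel=1e-5, abs=1e-6
        )
        assert ft.spectral_skewness(ps_scaled) == pytest.approx(
            ft.spectral_skewness(ps), rel=1e-5, abs=1e-6
        )


class TestAssembly:
    def test_single_segment_row(self, rng):
        seg = rng.normal(size=(100, 6))
        df = ft.extract_features([seg], [3], ["safe"])
        assert df.shape == (1, 3 + 54)
        assert list(df.columns[:3]) == ["subject", "lifting_id", "label"]
        # composition: table cells equal the individual operations channel-wise
        assert df.loc[0, "STD_ax"] == pytest.approx(ft.std(seg[:, 0]))
        assert df.loc[0, "SE_vz"] == pytest.approx(
            ft.spectral_entropy(ft.power_spectrum(seg[:, 5]))
        )
        assert df.loc[0, "ZCR_vy"] == ft.zcr(seg[:, 4])

    def test_error_carries_segment_identity(self, rng):
        good = rng.normal(size=(100, 6))
        short = rng.normal(size=(4, 6))
        with pytest.raises(DataError, match="subject 9, lifting 1"):
            ft.extract_features([good, short], [9, 9], ["safe", "safe"], [0, 1])

    def test_counts_bounded_by_length(self, rng):
        seg = rng.normal(size=(50, 6))
        df = ft.extract_features([seg], [0], ["unsafe"])
        for ch in ft.CHANNEL_NAMES:
            assert 0 <= df.loc[0, f"ZCR_{ch}"] <= 50
            assert 0 <= df.loc[0, f"SSC_{ch}"] <= 50
            assert float(df.loc[0, f"ZCR_{ch}"]).is_integer()
            assert float(df.loc[0, f"SSC_{ch}"]).is_integer()
            assert 0.0 <= df.loc[0, f"SE_{ch}"] <= 1.0
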