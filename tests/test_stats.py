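"""Curve statistics: mean, kurtosis, peak/valley metrics, FDHs."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mmoblique import (
    MMImage,
    AzimuthalCurve,
    compute_fdh,
    curve_kurtosis,
    curve_mean,
    find_peaks_valleys,
)


def make_curve(values):
    values = np.asarray(values, dtype=float)
    az = np.arange(len(values)) * (360.0 / len(values))
    return AzimuthalCurve(element_index=(2, 2), azimuths_deg=az, values=values)


# --- mean -------------------------------------------------------------------

@pytest.mark.parametrize(
    "values,expected",
    [([1.0, 1.0, 1.0], 1.0), ([0.0, 2.0], 1.0), ([1.0, np.nan, 3.0], 2.0)],
)
def test_curve_mean(values, expected):
    assert curve_mean(values) == pytest.approx(expected)


def test_mean_of_empty_input_raises():
    with pytest.raises(ValueError, match="empty"):
        curve_mean([np.nan, np.nan])


# --- kurtosis ---------------------------------------------------------------

def test_kurtosis_two_point_symmetric_is_one():
    assert curve_kurtosis([-1.0, 1.0] * 50) == pytest.approx(1.0)


def test_kurtosis_of_normal_sample_is_three(rng):
    sample = rng.standard_normal(400_000)
    assert curve_kurtosis(sample) == pytest.approx(3.0, abs=0.03)


def test_kurtosis_of_sinusoid_matches_moment_integral_oracle():
    # oracle: population kurtosis of cos via dense numerical quadrature
    t = np.linspace(0, 2 * np.pi, 200_001)
    x = np.cos(t[:-1])
    m2 = np.mean(x**2)
    m4 = np.mean(x**4)
    oracle = m4 / m2**2
    assert oracle == pytest.approx(1.5, abs=1e-4)
    dense = np.cos(np.deg2rad(np.arange(0, 360, 0.25)))
    assert curve_kurtosis(dense) == pytest.approx(oracle, abs=1e-6)


def test_kurtosis_of_constant_raises_distinct_error():
    with pytest.raises(ValueError, match="constant"):
        curve_kurtosis(np.full(100, 0.3))


@given(
    a=st.floats(min_value=0.1, max_value=50).filter(lambda v: abs(v) > 1e-3),
    b=st.floats(min_value=-100, max_value=100),
    sign=st.sampled_from([-1.0, 1.0]),
)
def test_kurtosis_affine_invariance(a, b, sign):
    base = np.sin(np.linspace(0, 11, 400)) ** 3 + 0.2
    assert curve_kurtosis(sign * a * base + b) == pytest.approx(
        curve_kurtosis(base), rel=1e-8
    )


def test_kurtosis_lower_bound_property(rng):
    for _ in range(20):
        sample = rng.uniform(-1, 1, 50)
        assert curve_kurtosis(sample) >= 1.0


# --- peaks / valleys --------------------------------------------------------

def test_pure_four_period_cosine_peak_structure():
    az = np.arange(0.0, 360.0)
    amp = 0.4
    curve = make_curve(amp * np.cos(4 * np.deg2rad(az)))
    ps = find_peaks_valleys(curve)
    assert ps.n_peaks == 4
    assert ps.n_valleys == 4
    np.testing.assert_allclose(ps.peak_azimuths_deg, [0, 90, 180, 270], atol=1.0)
    np.testing.assert_allclose(ps.pp_values, 0.0, atol=1e-9)
    np.testing.assert_allclose(ps.pv_values, 2 * amp, rtol=5e-3)


def test_unequal_twin_peaks_pp_value_is_height_difference():
    az = np.arange(0.0, 360.0)

    def bump(center, height, width=12.0):
        d = np.minimum(np.abs(az - center), 360 - np.abs(az - center))
        return height * np.exp(-0.5 * (d / width) ** 2)

    curve = make_curve(bump(50, 1.0) + bump(130, 0.6))
    ps = find_peaks_valleys(curve)
    assert ps.n_peaks == 2
    assert len(ps.pp_values) == 1
    assert ps.pp_values[0] == pytest.approx(0.4, abs=0.02)


def test_peaks_and_valleys_interleave_on_circle(rng):
    az = np.arange(0.0, 360.0)
    curve = make_curve(
        np.cos(2 * np.deg2rad(az)) + 0.3 * np.cos(np.deg2rad(3 * az + 70))
    )
    ps = find_peaks_valleys(curve)
    merged = sorted(
        [(a, "p") for a in ps.peak_azimuths_deg]
        + [(a, "v") for a in ps.valley_azimuths_deg]
    )
    kinds = [k for _, k in merged]
    assert all(kinds[i] != kinds[i + 1] for i in range(len(kinds) - 1))


def test_flat_curve_returns_empty_peakset_with_warning():
    curve = make_curve(np.full(360, 0.2))
    with pytest.warns(UserWarning, match="no extrema"):
        ps = find_peaks_valleys(curve)
    assert ps.n_peaks == 0 and np.isnan(ps.pp_gap)


def test_twin_peak_gap_in_normalized_period_units():
    az = np.arange(0.0, 360.0)

    def bumps(centers, width=8.0):
        out = np.zeros_like(az)
        for c in centers:
            d = np.minimum(np.abs(az - c), 360 - np.abs(az - c))
            out += np.exp(-0.5 * (d / width) ** 2)
        return out

    # twin peaks 30 deg apart inside each 90 deg window
    curve = make_curve(bumps([30, 60, 120, 150, 210, 240, 300, 330]))
    ps = find_peaks_valleys(curve)
    assert ps.pp_gap == pytest.approx(30.0 / 180.0, abs=0.01)


# --- FDH --------------------------------------------------------------------

def test_fdh_constant_image_single_bin():
    mm = MMImage(np.full((4, 4, 10, 10), 0.5))
    fdh = compute_fdh(mm, (2, 2), n_bins=8, value_range=(-1, 1))
    assert fdh.counts.sum() == 100
    assert np.count_nonzero(fdh.counts) == 1


def test_fdh_two_half_planes_equal_counts():
    elements = np.zeros((4, 4, 10, 10))
    elements[1, 1, :5] = -0.5
    elements[1, 1, 5:] = 0.5
    fdh = compute_fdh(MMImage(elements), (2, 2), n_bins=4, value_range=(-1, 1))
    assert fdh.counts.tolist() == [0, 50, 0, 50] or fdh.counts.tolist() == [50, 0, 50, 0]


def test_fdh_conserves_pixel_count_with_mask_and_outliers(rng):
    elements = rng.uniform(-2, 2, (4, 4, 20, 20))  # some values outside range
    elements[1, 1, 0, :5] = np.nan
    mm = MMImage(elements)
    roi = np.zeros((20, 20), dtype=bool)
    roi[:10] = True
    fdh = compute_fdh(mm, (2, 2), roi_mask=roi, n_bins=32)
    assert fdh.counts.sum() == fdh.n_pixels == 200 - 5


def test_fdh_centroid_tracks_baseline_shift():
    base = np.zeros((4, 4, 30, 30))
    base[1, 1] = 0.2
    shifted = base.copy()
    shifted[1, 1] -= 0.15
    f0 = compute_fdh(MMImage(base), (2, 2), n_bins=256)
    f1 = compute_fdh(MMImage(shifted), (2, 2), n_bins=256)
    assert f1.centroid - f0.centroid == pytest.approx(-0.15, abs=2 / 256)


def test_fdh_empty_roi_raises():
    mm = MMImage(np.zeros((4, 4, 5, 5)))
    with pytest.raises(ValueError, match="empty ROI"):
        compute_fdh(mm, (2, 2), roi_mask=np.zeros((5, 5), dtype=bool))
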