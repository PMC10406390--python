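"""DRR forward model and inversion against independent Mueller-calculus oracles."""

import logging

import numpy as np
import pytest

from mmoblique import (
    AcquisitionConfig,
    MMImage,
    design_matrix,
    fit_fourier_coefficients,
    measurement_row,
    normalize_by_m11,
    reconstruct_mm,
    render_frames,
)


# --- independent oracle: textbook element-wise Mueller matrices -------------

def oracle_retarder(delta_deg, axis_deg):
    d = np.deg2rad(delta_deg)
    c, s = np.cos(2 * np.deg2rad(axis_deg)), np.sin(2 * np.deg2rad(axis_deg))
    cd, sd = np.cos(d), np.sin(d)
    return np.array(
        [
            [1, 0, 0, 0],
            [0, c**2 + s**2 * cd, c * s * (1 - cd), -s * sd],
            [0, c * s * (1 - cd), s**2 + c**2 * cd, c * sd],
            [0, s * sd, -c * sd, cd],
        ]
    )


def oracle_polarizer(axis_deg):
    c, s = np.cos(2 * np.deg2rad(axis_deg)), np.sin(2 * np.deg2rad(axis_deg))
    return 0.5 * np.array(
        [
            [1, c, s, 0],
            [c, c**2, c * s, 0],
            [s, c * s, s**2, 0],
            [0, 0, 0, 0],
        ]
    )


def oracle_intensity(mueller, r1, r2, config):
    """Intensity via full matrix products, independent of measurement_row."""
    s_in = (
        oracle_retarder(config.retardance_deg, r1)
        @ oracle_polarizer(config.polarizer_angle_deg)
        @ np.array([1.0, 0, 0, 0])
    )
    s_out = (
        oracle_polarizer(config.polarizer_angle_deg)
        @ oracle_retarder(config.retardance_deg, r2)
        @ mueller
        @ s_in
    )
    return s_out[0]


def random_physical_mm(rng):
    m = rng.uniform(-0.5, 0.5, (4, 4))
    m[0, 0] = 1.0
    return m


# --- measurement_row --------------------------------------------------------

def test_measurement_row_matches_matrix_product_oracle(acq, rng):
    for _ in range(20):
        r1, r2 = rng.uniform(0, 360, 2)
        m = random_physical_mm(rng)
        w = measurement_row(r1, r2, acq)
        assert w @ m.ravel() == pytest.approx(oracle_intensity(m, r1, r2, acq), abs=1e-12)


def test_measurement_row_aligned_elements_hand_computed(acq):
    # r1 = r2 = 0, quarter-wave plates with fast axis along the polarizers:
    # generator Stokes (0.5, 0.5, 0, 0), analyzer row 0.5*(1, 1, 0, 0)
    w = measurement_row(0.0, 0.0, acq).reshape(4, 4)
    expected = np.outer([0.5, 0.5, 0, 0], [0.5, 0.5, 0, 0])
    np.testing.assert_allclose(w, expected, atol=1e-12)


def test_zero_retardance_design_is_rank_deficient():
    cfg = AcquisitionConfig(retardance_deg=0.0)
    rank = np.linalg.matrix_rank(design_matrix(cfg), tol=1e-10)
    assert rank <= 4


def test_default_design_has_full_rank(acq):
    assert np.linalg.matrix_rank(design_matrix(acq), tol=1e-10) == 16


# --- render / reconstruct ---------------------------------------------------

def test_render_zero_mm_gives_zero_frames(acq):
    mm = MMImage(np.zeros((4, 4, 3, 3)))
    frames = render_frames(mm, acq)
    assert np.all(frames.frames == 0)
    assert np.allclose(frames.r2_angles_deg, 5 * frames.r1_angles_deg)


def test_render_is_linear(acq, rng):
    m1 = MMImage(rng.uniform(-1, 1, (4, 4, 2, 2)))
    m2 = MMImage(rng.uniform(-1, 1, (4, 4, 2, 2)))
    combo = MMImage(2.0 * m1.elements + 3.0 * m2.elements)
    np.testing.assert_allclose(
        render_frames(combo, acq).frames,
        2.0 * render_frames(m1, acq).frames + 3.0 * render_frames(m2, acq).frames,
        atol=1e-12,
    )


def test_render_identity_matches_oracle_air_calibration(acq):
    mm = MMImage.from_matrix(np.eye(4), (2, 2))
    frames = render_frames(mm, acq)
    for k, (r1, r2) in enumerate(zip(frames.r1_angles_deg, frames.r2_angles_deg)):
        assert frames.frames[k, 0, 0] == pytest.approx(
            oracle_intensity(np.eye(4), r1, r2, acq), abs=1e-12
        )


def test_rank_deficient_render_raises(rng):
    cfg = AcquisitionConfig(retardance_deg=0.0)
    mm = MMImage(rng.uniform(-1, 1, (4, 4, 2, 2)))
    with pytest.raises(ValueError, match="r1_step_deg"):
        render_frames(mm, cfg)


def test_round_trip_recovers_random_mms(acq, rng):
    mats = np.stack([random_physical_mm(rng) for _ in range(25)])
    mm = MMImage(mats.reshape(5, 5, 4, 4).transpose(2, 3, 0, 1))
    recovered = reconstruct_mm(render_frames(mm, acq))
    assert np.max(np.abs(recovered.elements - mm.elements)) < 1e-10


def test_reconstruct_identity_exactly(acq):
    mm = MMImage.from_matrix(np.eye(4), (3, 3))
    recovered = reconstruct_mm(render_frames(mm, acq))
    assert np.max(np.abs(recovered.elements - mm.elements)) < 1e-10
    assert np.max(recovered.metadata["residual_map"]) < 1e-12


def test_reconstruct_warns_on_negative_intensity(acq, caplog):
    mm = MMImage.from_matrix(np.eye(4), (2, 2))
    frames = render_frames(mm, acq)
    frames.frames[0, 0, 0] = -0.5
    with caplog.at_level(logging.WARNING, logger="mmoblique.drr"):
        reconstruct_mm(frames)
    assert any("negative" in r.message for r in caplog.records)


def test_intensity_scale_round_trips(rng):
    cfg = AcquisitionConfig(intensity_scale=4096.0)
    mm = MMImage.from_matrix(random_physical_mm(rng), (2, 2))
    recovered = reconstruct_mm(render_frames(mm, cfg))
    assert np.max(np.abs(recovered.elements - mm.elements)) < 1e-9


# --- Fourier diagnostic surface ---------------------------------------------

def test_fourier_fit_constant_series(acq):
    coeffs = fit_fourier_coefficients(np.full(30, 3.25), config=acq)
    assert coeffs.alpha0 == pytest.approx(3.25, abs=1e-10)
    assert np.max(np.abs(coeffs.alpha)) < 1e-10
    assert np.max(np.abs(coeffs.beta)) < 1e-10


def test_fourier_fit_third_harmonic(acq):
    phase = 2.0 * np.deg2rad(acq.r1_angles_deg)
    coeffs = fit_fourier_coefficients(np.cos(3 * phase), phase_rad=phase)
    assert coeffs.alpha[2] == pytest.approx(1.0, abs=1e-10)
    others = np.delete(np.concatenate([coeffs.alpha, coeffs.beta, [coeffs.alpha0]]), 2)
    assert np.max(np.abs(others)) < 1e-10


def test_fourier_fit_underdetermined_raises():
    with pytest.raises(ValueError, match="underdetermined"):
        fit_fourier_coefficients(np.ones(20), phase_rad=np.linspace(0, 6, 20), n_max=12)


def test_fourier_fit_matches_dense_grid_dft_oracle(acq, rng):
    """The 30-sample fit equals the DFT of the densely sampled continuous signal."""
    m = random_physical_mm(rng)
    series = np.array(
        [
            oracle_intensity(m, r1, r2, acq)
            for r1, r2 in zip(acq.r1_angles_deg, acq.r2_angles_deg)
        ]
    )
    fitted = fit_fourier_coefficients(series, config=acq)
    # dense sampling: r1 spans 180 deg, so the phase x = 2*r1 spans 360 deg
    t = np.linspace(0, 180, 3600, endpoint=False)
    dense = np.array([oracle_intensity(m, r1, 5 * r1, acq) for r1 in t])
    spectrum = np.fft.rfft(dense)
    alpha0 = spectrum[0].real / len(dense)
    alpha = 2 * spectrum[1:13].real / len(dense)
    beta = -2 * spectrum[1:13].imag / len(dense)
    assert fitted.alpha0 == pytest.approx(alpha0, abs=1e-10)
    np.testing.assert_allclose(fitted.alpha, alpha, atol=1e-10)
    np.testing.assert_allclose(fitted.beta, beta, atol=1e-10)
    assert fitted.residual < 1e-12


# --- normalization ----------------------------------------------------------

def test_normalize_scaled_identity():
    mm = MMImage.from_matrix(2.5 * np.eye(4), (3, 3))
    normalized = normalize_by_m11(mm)
    assert normalized.normalized
    for idx, channel in normalized.iter_channels():
        expected = 1.0 if idx[0] == idx[1] else 0.0
        np.testing.assert_allclose(channel, expected, atol=1e-12)


def test_normalize_masks_zero_m11_region(caplog):
    mm = MMImage.from_matrix(np.eye(4), (4, 4))
    mm.elements[0, 0, :2, :] = 0.0
    with caplog.at_level(logging.WARNING, logger="mmoblique.drr"):
        normalized = normalize_by_m11(mm)
    assert normalized.metadata["masked_pixels"] == 8
    assert np.all(np.isnan(normalized.channel((2, 2))[:2, :]))
    assert np.all(np.isfinite(normalized.channel((2, 2))[2:, :]))
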