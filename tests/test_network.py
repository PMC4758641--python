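"""Network-core tests: closed forms, brute-force oracles, and invariants.

The oracles re-implement the layer equations as direct summation loops
over space and orientation with the same truncated-kernel definitions,
independent of the separable/matrix convolution path they check.
"""

import numpy as np
import pytest

from attnnet import (AttentionField, ModelParameters, no_attention,
                     run_to_equilibrium, spatial_attention)
from attnnet.network import (CalibrationError, bottom_excitation, bottom_pass,
                             calibrate_constants, default_calibration_stimulus,
                             divisive_normalize, feedback_field,
                             feedforward_drive, gabor_filter_bank, top_pass)
from attnnet.params import N_ORIENTATIONS, ORI_STEP
from attnnet.stimuli import GaborSpec, semi_rectified_gabor_patch


# ---------------------------------------------------------------------------
# Brute-force oracle helpers (direct sums, truncated kernels)


def oracle_gauss_kernel(sigma):
    r = int(np.ceil(3 * sigma))
    x = np.arange(-r, r + 1)
    k = np.exp(-x.astype(float) ** 2 / (2 * sigma ** 2))
    return k / k.sum(), r


def oracle_blur2d(m, sigma):
    """Zero-padded separable Gaussian blur by direct summation."""
    k, r = oracle_gauss_kernel(sigma)
    h, w = m.shape[:2]
    out = np.zeros_like(m)
    for i in range(h):
        for j in range(w):
            acc = 0.0 if m.ndim == 2 else np.zeros(m.shape[2])
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < h and 0 <= jj < w:
                        acc = acc + k[di + r] * k[dj + r] * m[ii, jj]
            out[i, j] = acc
    return out


def oracle_orientation_conv(m, sigma_ori):
    """Circular orientation-axis convolution by direct summation."""
    sig = sigma_ori / ORI_STEP
    r = int(np.ceil(3 * sig))
    off = np.arange(-r, r + 1)
    k = np.exp(-off.astype(float) ** 2 / (2 * sig ** 2))
    k /= k.sum()
    out = np.zeros_like(m)
    for t in range(N_ORIENTATIONS):
        for o, w in zip(off, k):
            out[..., (t + o) % N_ORIENTATIONS] += w * m[..., t]
    return out


def oracle_normalize(e, sigma_inh, c):
    inh = oracle_blur2d(e.sum(axis=2), sigma_inh)
    return e / (inh[:, :, None] + c)


def oracle_conv2d(image, kernel):
    """Zero-padded 'same' correlation by a quadruple loop."""
    h, w = image.shape
    kh, kw = kernel.shape
    rh, rw = kh // 2, kw // 2
    out = np.zeros_like(image)
    for i in range(h):
        for j in range(w):
            acc = 0.0
            for a in range(kh):
                for b in range(kw):
                    ii, jj = i + a - rh, j + b - rw
                    if 0 <= ii < h and 0 <= jj < w:
                        acc += kernel[a, b] * image[ii, jj]
            out[i, j] = acc
    return out


# ---------------------------------------------------------------------------
# Filter bank


class TestGaborFilterBank:
    def test_eight_kernels_at_channel_orientations(self):
        kernels = gabor_filter_bank(ModelParameters())
        assert len(kernels) == N_ORIENTATIONS

    def test_horizontal_kernel_is_transpose_of_vertical(self):
        kernels = gabor_filter_bank(ModelParameters())
        np.testing.assert_allclose(kernels[4], kernels[0].T, atol=1e-12)

    def test_kernels_are_zero_dc_and_unit_energy(self):
        for k in gabor_filter_bank(ModelParameters()):
            assert abs(k.sum()) < 1e-12
            assert np.linalg.norm(k) == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# Feedforward drive


class TestFeedforwardDrive:
    def test_zero_image_gives_zero_drive(self, small_params):
        drive = feedforward_drive(np.zeros(small_params.canvas), small_params)
        assert np.all(drive == 0)

    def test_impulse_reproduces_rectified_kernels(self, small_params):
        img = np.zeros(small_params.canvas)
        img[4, 4] = 1.0
        drive = feedforward_drive(img, small_params)
        kernels = gabor_filter_bank(small_params)
        r = kernels[0].shape[0] // 2
        for k, kern in enumerate(kernels):
            expected = np.zeros(small_params.canvas)
            expected[4 - r:4 + r + 1, 4 - r:4 + r + 1] = np.maximum(kern, 0)
            np.testing.assert_allclose(drive[:, :, k], expected, atol=1e-12)

    def test_matches_brute_force_convolution(self, small_params, rng):
        img = rng.random(small_params.canvas)
        drive = feedforward_drive(img, small_params)
        kernels = gabor_filter_bank(small_params)
        for k, kern in enumerate(kernels):
            expected = np.maximum(oracle_conv2d(img, kern), 0)
            np.testing.assert_allclose(drive[:, :, k], expected, atol=1e-10)

    def test_negative_image_rejected(self, small_params):
        img = np.full(small_params.canvas, -0.1)
        with pytest.raises(ValueError):
            feedforward_drive(img, small_params)


# ---------------------------------------------------------------------------
# Divisive normalization


class TestDivisiveNormalize:
    def test_zero_excitation_gives_zero_response(self):
        e = np.zeros((5, 5, 8))
        assert np.all(divisive_normalize(e, 1.0, 0.3) == 0)

    def test_uniform_single_channel_closed_form(self):
        e = np.zeros((7, 9, 8))
        e[:, :, 2] = 0.8
        r = divisive_normalize(e, 1.0, 0.3, pad_mode="wrap")
        # blur of a constant is the constant (unit-sum kernel, periodic)
        np.testing.assert_allclose(r[:, :, 2], 0.8 / (0.8 + 0.3), atol=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        e = rng.random((5, 5, 8))
        r = divisive_normalize(e, 1.0, 0.25)
        np.testing.assert_allclose(r, oracle_normalize(e, 1.0, 0.25),
                                   rtol=1e-10)

    def test_nonpositive_constant_rejected(self):
        with pytest.raises(ValueError):
            divisive_normalize(np.ones((3, 3, 8)), 1.0, 0.0)

    def test_non_negativity_and_boundedness(self, rng):
        e = rng.random((6, 6, 8)) * 5
        c = 0.4
        r = divisive_normalize(e, 1.0, c)
        assert r.min() >= 0
        assert np.all(r <= e / c + 1e-12)


# ---------------------------------------------------------------------------
# Layer passes


class TestBottomPass:
    def test_zero_feedback_squares_the_drive(self, small_params, rng):
        drive = rng.random((9, 9, 8))
        fb = np.zeros_like(drive)
        expected = divisive_normalize(drive ** 2, small_params.sigma_inh,
                                      small_params.c_bottom)
        np.testing.assert_allclose(bottom_pass(drive, fb, small_params),
                                   expected, rtol=1e-12)

    def test_zero_drive_silences_any_feedback(self, small_params, rng):
        drive = np.zeros((9, 9, 8))
        fb = rng.random((9, 9, 8))
        assert np.all(bottom_pass(drive, fb, small_params) == 0)

    def test_uniform_closed_form(self):
        p = ModelParameters(canvas=(7, 7), c_bottom=0.2)
        d, f = 0.5, 0.3
        drive = np.zeros((7, 7, 8))
        drive[:, :, 0] = d
        fb = np.full((7, 7, 8), f)
        r = divisive_normalize(bottom_excitation(drive, fb), p.sigma_inh,
                               p.c_bottom, pad_mode="wrap")
        e = ((1 + f) * d) ** 2
        np.testing.assert_allclose(r[:, :, 0], e / (e + 0.2), atol=1e-12)

    def test_negative_feedback_rejected(self, small_params):
        drive = np.ones((9, 9, 8))
        fb = np.full_like(drive, -0.01)
        with pytest.raises(ValueError):
            bottom_pass(drive, fb, small_params)


class TestTopPass:
    def test_matches_brute_force_oracle(self, small_params, rng):
        m = rng.random((9, 9, 8))
        att = no_attention(small_params)
        got = top_pass(m, att, small_params)
        pool = oracle_orientation_conv(
            oracle_blur2d(m, small_params.sigma_top), small_params.sigma_ori)
        expected = oracle_normalize(pool ** 2, small_params.sigma_inh,
                                    small_params.c_top)
        np.testing.assert_allclose(got, expected, rtol=1e-10)

    def test_orientation_wraparound_is_symmetric(self, small_params, rng):
        m = np.zeros((9, 9, 8))
        m[:, :, 7] = rng.random((9, 9))
        att = no_attention(small_params)
        r = top_pass(m, att, small_params)
        # channel 7 leaks equally into channels 6 and 0 (circular axis)
        np.testing.assert_allclose(r[:, :, 0], r[:, :, 6], rtol=1e-12)

    def test_negative_attention_rejected(self):
        with pytest.raises(ValueError):
            AttentionField(-np.ones((9, 9, 8)))


class TestFeedbackField:
    def test_zero_top_response_gives_zero_feedback(self, small_params):
        fb = feedback_field(np.zeros((9, 9, 8)), small_params)
        assert np.all(fb == 0)

    def test_linearity(self, small_params, rng):
        m = rng.random((9, 9, 8))
        np.testing.assert_allclose(feedback_field(2 * m, small_params),
                                   2 * feedback_field(m, small_params),
                                   rtol=1e-12)

    def test_matches_brute_force_oracle(self, small_params, rng):
        m = rng.random((9, 9, 8))
        expected = small_params.alpha_fb * oracle_orientation_conv(
            oracle_blur2d(m, small_params.sigma_top), small_params.sigma_ori)
        np.testing.assert_allclose(feedback_field(m, small_params), expected,
                                   rtol=1e-10)


# ---------------------------------------------------------------------------
# Fixed-point iteration


class TestRunToEquilibrium:
    def test_zero_image_is_a_zero_fixed_point(self, params):
        probes = [(50, 50, 0, "top"), (50, 50, 0, "bottom")]
        state = run_to_equilibrium(np.zeros(params.canvas),
                                   no_attention(params), params,
                                   probes=probes)
        assert np.all(state.top_response == 0)
        assert np.all(state.bottom_response == 0)
        assert np.all(state.traces == 0)

    def test_responses_always_non_negative(self, params):
        img = default_calibration_stimulus(params)
        state = run_to_equilibrium(img, spatial_attention((50, 50), params),
                                   params)
        assert state.bottom_response.min() >= 0
        assert state.top_response.min() >= 0
        assert state.feedback.min() >= 0

    def test_attended_run_equilibrates_by_iteration_30(self, params):
        img = default_calibration_stimulus(params)
        att = spatial_attention((50, 50), params)
        s29 = run_to_equilibrium(img, att, params, n_iterations=29)
        s30 = run_to_equilibrium(img, att, params, n_iterations=30)
        delta = np.abs(s30.top_response - s29.top_response).max()
        assert delta < 1e-6 * s30.top_response.max()

    def test_translation_equivariance_under_periodic_padding(self):
        p = ModelParameters(canvas=(40, 40), c_bottom=1.0, c_top=1e-3,
                            n_iterations=5)
        img = semi_rectified_gabor_patch(
            GaborSpec(center=(20, 20), orientation=0.0), p.canvas)
        att = spatial_attention((20, 20), p)
        base = run_to_equilibrium(img, att, p, pad_mode="wrap")
        dy, dx = 3, -5
        shifted_att = AttentionField(np.roll(att.values, (dy, dx),
                                             axis=(0, 1)), mode="spatial")
        shifted = run_to_equilibrium(np.roll(img, (dy, dx), axis=(0, 1)),
                                     shifted_att, p, pad_mode="wrap")
        np.testing.assert_allclose(
            shifted.top_response,
            np.roll(base.top_response, (dy, dx), axis=(0, 1)), atol=1e-12)

    def test_mirror_symmetric_display_gives_mirrored_responses(self, params):
        # stimuli at mirror columns x and (W-1)-x; channel k maps to
        # channel (8-k) % 8 under a left-right flip
        left = GaborSpec(center=(40, 50), orientation=0.0)
        right = GaborSpec(center=(59, 50), orientation=np.pi / 2)
        img = (semi_rectified_gabor_patch(left, params.canvas)
               + semi_rectified_gabor_patch(right, params.canvas))
        att = spatial_attention((40, 50), params)
        state = run_to_equilibrium(img, att, params)
        m_left = GaborSpec(center=(40, 50), orientation=np.pi / 2)
        m_right = GaborSpec(center=(59, 50), orientation=0.0)
        m_img = (semi_rectified_gabor_patch(m_left, params.canvas)
                 + semi_rectified_gabor_patch(m_right, params.canvas))
        m_att = spatial_attention((59, 50), params)
        m_state = run_to_equilibrium(m_img, m_att, params)
        chan_map = [(8 - k) % 8 for k in range(8)]
        np.testing.assert_allclose(
            m_state.top_response[:, ::-1, :][:, :, chan_map],
            state.top_response, rtol=1e-9, atol=1e-14)


# ---------------------------------------------------------------------------
# Calibration


class TestCalibration:
    def test_converged_constants_are_a_fixed_point(self, params):
        c_bottom, c_top = calibrate_constants(params)
        assert c_bottom == pytest.approx(params.c_bottom, rel=1e-5)
        assert c_top == pytest.approx(params.c_top, rel=1e-5)

    def test_first_iteration_scales_with_amplitude_squared(self, params):
        # with FB = 0 the pre-inhibition excitation is the squared drive,
        # and the rectified drive is linear in stimulus amplitude
        img = default_calibration_stimulus(params)
        e1 = bottom_excitation(feedforward_drive(img, params),
                               np.zeros(params.canvas + (8,)))
        e2 = bottom_excitation(feedforward_drive(1.7 * img, params),
                               np.zeros(params.canvas + (8,)))
        assert e2.max() == pytest.approx(1.7 ** 2 * e1.max(), rel=1e-12)

    def test_blank_calibration_stimulus_rejected(self, params):
        with pytest.raises(CalibrationError):
            calibrate_constants(params,
                                calibration_stimulus=np.zeros(params.canvas))
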