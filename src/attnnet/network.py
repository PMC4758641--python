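"""The two-layer feedback network.

Bottom layer ("V1"): the input image is filtered by a bank of Gabor filters
at 8 orientations; the resulting drive is multiplied by ``(1 + FB)`` (the
modulatory feedback from the top layer, strictly excitatory), squared
(power-law transfer), and divisively normalized by short-range pooled
activity.

Top layer ("V4/MT"): bottom responses are pooled by a Gaussian over space
(sd sigma_top, giving RFs four times the bottom-layer size) and a circular
Gaussian over the orientation axis (sd sigma_ori), multiplied by
``(1 + A)`` (the attention field), squared, and normalized identically.

Feedback mirrors the feedforward pooling: the top response passed through
the same spatial-then-orientation kernels and scaled by alpha_fb.  The
whole bottom -> top -> feedback loop is iterated a fixed 30 times, which
suffices to equilibrate responses; feedback starts at zero, so the first
iteration is purely feedforward in the bottom layer.

Conventions (fixed across the package): Gaussian pooling/inhibition
kernels are normalized to unit sum and truncated at radius ceil(3 sd);
spatial padding is zero ("constant") by default with a periodic ("wrap")
option; the orientation axis always wraps.  The Gabor filters are zero-DC
(mean subtracted) and unit L2 norm, truncated at the same radius.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, signal

from .attention import AttentionField
from .params import N_ORIENTATIONS, ORI_STEP, ModelParameters
from .stimuli import gabor

__all__ = [
    "DivergenceError",
    "CalibrationError",
    "NetworkState",
    "gabor_filter_bank",
    "feedforward_drive",
    "divisive_normalize",
    "bottom_excitation",
    "top_excitation",
    "bottom_pass",
    "top_pass",
    "feedback_field",
    "run_to_equilibrium",
    "calibrate_constants",
    "calibrate",
]


class DivergenceError(RuntimeError):
    """Raised when the fixed-point iteration produces non-finite values."""


class CalibrationError(RuntimeError):
    """Raised when the normalization-constant calibration fails to converge."""


# ---------------------------------------------------------------------------
# Kernels


def _gaussian_kernel_1d(sigma: float) -> np.ndarray:
    """Unit-sum 1-D Gaussian, truncated at radius ceil(3 sigma)."""
    radius = int(np.ceil(3.0 * sigma))
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-x ** 2 / (2.0 * sigma ** 2))
    return k / k.sum()


@functools.lru_cache(maxsize=256)
def _blur_matrix(sigma: float, n: int, pad_mode: str) -> np.ndarray:
    """Dense n x n matrix applying the truncated Gaussian along one axis.

    Banded for zero padding ("constant"), circulant for periodic ("wrap").
    Applying the blur as a matrix product is several times faster than a
    direct moving-window correlation at these sizes.
    """
    k = _gaussian_kernel_1d(sigma)
    radius = len(k) // 2
    m = np.zeros((n, n))
    for i in range(n):
        for j, w in enumerate(k):
            col = i + j - radius
            if pad_mode == "wrap":
                m[i, col % n] += w
            elif 0 <= col < n:
                m[i, col] += w
    return m


def _orientation_matrix(sigma_ori: float) -> np.ndarray:
    """8x8 circular-convolution matrix for the orientation axis.

    The kernel is a unit-sum Gaussian with sd ``sigma_ori`` radians,
    sampled at the pi/8 channel spacing and wrapped onto the 8 circular
    channels (``out = map @ M``).
    """
    sigma_ch = sigma_ori / ORI_STEP
    radius = int(np.ceil(3.0 * sigma_ch))
    offsets = np.arange(-radius, radius + 1)
    weights = np.exp(-offsets.astype(float) ** 2 / (2.0 * sigma_ch ** 2))
    weights /= weights.sum()
    m = np.zeros((N_ORIENTATIONS, N_ORIENTATIONS))
    for off, wt in zip(offsets, weights):
        for k in range(N_ORIENTATIONS):
            m[(k + off) % N_ORIENTATIONS, k] += wt
    return m


@functools.lru_cache(maxsize=32)
def gabor_filter_bank(params: ModelParameters) -> tuple[np.ndarray, ...]:
    """One 2-D Gabor kernel per orientation channel theta_k = k*pi/8.

    Kernels have envelope sd sigma_bottom, carrier wavelength
    ``params.wavelength``, cosine phase, and are truncated at radius
    ceil(3 sd).  Each is made zero-DC by mean subtraction and scaled to
    unit L2 norm (the unit-energy convention), so the filter output is a
    matched-filter correlation independent of kernel support size.
    """
    radius = int(np.ceil(3.0 * params.sigma_bottom))
    coords = np.arange(-radius, radius + 1, dtype=float)
    xg, yg = np.meshgrid(coords, coords)
    kernels = []
    for k in range(N_ORIENTATIONS):
        g = gabor(xg, yg, k * ORI_STEP, params.sigma_bottom,
                  params.wavelength)
        g = g - g.mean()
        kernels.append(g / np.linalg.norm(g))
    return tuple(kernels)


# ---------------------------------------------------------------------------
# Elementary passes


def _blur_spatial(m: np.ndarray, sigma: float, pad_mode: str) -> np.ndarray:
    """Separable Gaussian blur over the two spatial axes of a 2-D/3-D map."""
    m0 = _blur_matrix(sigma, m.shape[0], pad_mode)
    m1 = _blur_matrix(sigma, m.shape[1], pad_mode)
    out = np.tensordot(m0, m, axes=(1, 0))
    if m.ndim == 2:
        return out @ m1  # symmetric kernel: M.T == M
    return np.tensordot(out, m1, axes=(1, 0)).transpose(0, 2, 1)


def feedforward_drive(image: np.ndarray, params: ModelParameters,
                      pad_mode: str = "constant") -> np.ndarray:
    """Gabor-bank filtering of the image; one channel per orientation.

    Negative filter outputs are floored at zero: the drive is an input
    rate, and squaring a negative response would otherwise turn
    suppression into excitation.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if image.shape != tuple(params.canvas):
        raise ValueError(f"image shape {image.shape} does not match "
                         f"canvas {params.canvas}")
    if not np.all(image >= 0):
        raise ValueError("image must be non-negative")
    return np.maximum(gabor_responses(image, params, pad_mode), 0.0)


def gabor_responses(image: np.ndarray, params: ModelParameters,
                    pad_mode: str = "constant") -> np.ndarray:
    """Raw (signed) Gabor-bank filter outputs, before rectification.

    Linear in the image, unlike :func:`feedforward_drive`; the
    receptive-field mapping protocol exploits this to assemble displays
    from precomputed per-stimulus responses.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != tuple(params.canvas):
        raise ValueError(f"image shape {image.shape} does not match "
                         f"canvas {params.canvas}")
    kernels = gabor_filter_bank(params)
    drive = np.empty(image.shape + (N_ORIENTATIONS,))
    for k, kern in enumerate(kernels):
        if pad_mode == "constant":
            # even-symmetric kernels: convolution == correlation
            drive[:, :, k] = signal.fftconvolve(image, kern, mode="same")
        else:
            drive[:, :, k] = ndimage.correlate(image, kern, mode=pad_mode)
    return drive


def divisive_normalize(excitation: np.ndarray, sigma_inh: float, c: float,
                       pad_mode: str = "constant") -> np.ndarray:
    """R = E / (Inh + c), Inh = Gaussian blur of the orientation-summed E.

    The inhibition pool is untuned (summed over channels) and short-range
    (sd sigma_inh), implementing divisive normalization by neighbouring
    activity.
    """
    if c <= 0:
        raise ValueError("normalization constant c must be > 0")
    pooled = excitation.sum(axis=2)
    inh = _blur_spatial(pooled, sigma_inh, pad_mode)
    return excitation / (inh[:, :, None] + c)


def bottom_excitation(drive: np.ndarray, feedback: np.ndarray) -> np.ndarray:
    """Pre-inhibition bottom excitation: ((1 + FB) * drive)^2."""
    if np.min(feedback) < 0:
        raise ValueError("feedback must be non-negative (strictly excitatory)")
    return ((1.0 + feedback) * drive) ** 2


def bottom_pass(drive: np.ndarray, feedback: np.ndarray,
                params: ModelParameters,
                pad_mode: str = "constant") -> np.ndarray:
    return divisive_normalize(bottom_excitation(drive, feedback),
                              params.sigma_inh, params.c_bottom, pad_mode)


def _pool_to_top(m: np.ndarray, params: ModelParameters,
                 pad_mode: str) -> np.ndarray:
    """Spatial (sd sigma_top) then circular orientation (sd sigma_ori) pooling."""
    pooled = _blur_spatial(m, params.sigma_top, pad_mode)
    return pooled @ _orientation_matrix_cached(params.sigma_ori)


@functools.lru_cache(maxsize=32)
def _orientation_matrix_cached(sigma_ori: float) -> np.ndarray:
    return _orientation_matrix(sigma_ori)


def top_excitation(bottom_response: np.ndarray, attention: AttentionField,
                   params: ModelParameters,
                   pad_mode: str = "constant") -> np.ndarray:
    """Pre-inhibition top excitation: ((1 + A) * pooled bottom response)^2."""
    pool = _pool_to_top(bottom_response, params, pad_mode)
    return ((1.0 + attention.values) * pool) ** 2


def top_pass(bottom_response: np.ndarray, attention: AttentionField,
             params: ModelParameters,
             pad_mode: str = "constant") -> np.ndarray:
    return divisive_normalize(
        top_excitation(bottom_response, attention, params, pad_mode),
        params.sigma_inh, params.c_top, pad_mode)


def feedback_field(top_response: np.ndarray, params: ModelParameters,
                   pad_mode: str = "constant") -> np.ndarray:
    """FB = alpha_fb times the top response pooled by the feedforward kernels.

    Feedback weights are proportional to the feedforward weights, so the
    operator is the same spatial-then-orientation Gaussian pooling.
    """
    return params.alpha_fb * _pool_to_top(top_response, params, pad_mode)


# ---------------------------------------------------------------------------
# Fixed-point iteration


@dataclass
class NetworkState:
    """Converged network responses plus per-iteration probe traces.

    ``probes`` lists (x, y, channel, layer) tuples; ``traces[i]`` is the
    i-th probe's activation after each iteration.
    """

    bottom_response: np.ndarray
    top_response: np.ndarray
    feedback: np.ndarray
    probes: list = field(default_factory=list)
    traces: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    iterations_run: int = 0

    def trace(self, probe_index: int) -> np.ndarray:
        return self.traces[probe_index]

    @property
    def trace_bottom(self) -> list[np.ndarray]:
        return [self.traces[i] for i, p in enumerate(self.probes)
                if p[3] == "bottom"]

    @property
    def trace_top(self) -> list[np.ndarray]:
        return [self.traces[i] for i, p in enumerate(self.probes)
                if p[3] == "top"]

    def save_csv(self, directory, prefix: str = "state") -> None:
        """Write each layer's response, one CSV per orientation channel."""
        from pathlib import Path
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, m in (("bottom", self.bottom_response),
                        ("top", self.top_response),
                        ("feedback", self.feedback)):
            for k in range(m.shape[2]):
                np.savetxt(directory / f"{prefix}_{name}_ch{k}.csv",
                           m[:, :, k], delimiter=",")


def _read_probe(probe, bottom: np.ndarray, top: np.ndarray) -> float:
    x, y, channel, layer = probe
    m = bottom if layer == "bottom" else top
    return float(m[int(y), int(x), int(channel)])


def run_to_equilibrium(image: np.ndarray, attention: AttentionField,
                       params: ModelParameters,
                       probes: Sequence[tuple] = (),
                       pad_mode: str = "constant",
                       n_iterations: int | None = None,
                       drive: np.ndarray | None = None) -> NetworkState:
    """Iterate bottom -> top -> feedback for a fixed number of passes.

    Feedback is initialized to zero.  ``probes`` are (x, y, channel,
    layer) cells whose activation is recorded after every iteration (the
    timecourse readout).  ``drive`` may supply a precomputed feedforward
    drive for the image (they must correspond; no check is possible).
    """
    if drive is None:
        drive = feedforward_drive(image, params, pad_mode)
    n_iter = params.n_iterations if n_iterations is None else int(n_iterations)
    fb = np.zeros_like(drive)
    traces = np.zeros((len(probes), n_iter))
    bottom = top = np.zeros_like(drive)
    for it in range(n_iter):
        bottom = bottom_pass(drive, fb, params, pad_mode)
        top = top_pass(bottom, attention, params, pad_mode)
        fb = feedback_field(top, params, pad_mode)
        if not np.all(np.isfinite(top)) or not np.all(np.isfinite(bottom)):
            raise DivergenceError(f"non-finite activation at iteration {it + 1}")
        for i, probe in enumerate(probes):
            traces[i, it] = _read_probe(probe, bottom, top)
    return NetworkState(bottom_response=bottom, top_response=top, feedback=fb,
                        probes=list(probes), traces=traces,
                        iterations_run=n_iter)


# ---------------------------------------------------------------------------
# Normalization-constant calibration


def default_calibration_stimulus(params: ModelParameters) -> np.ndarray:
    """Single vertical semi-rectified Gabor at the canvas center, amplitude 1.

    The same patch shape the biased-competition protocol uses.
    """
    from .stimuli import GaborSpec, semi_rectified_gabor_patch
    h, w = params.canvas
    spec = GaborSpec(center=(w // 2, h // 2), orientation=0.0, amplitude=1.0,
                     envelope_sd=params.sigma_bottom,
                     wavelength=params.wavelength)
    return semi_rectified_gabor_patch(spec, params.canvas)


def calibrate_constants(params: ModelParameters,
                        calibration_stimulus: np.ndarray | None = None,
                        rel_tol: float = 1e-6,
                        max_iterations: int = 500,
                        pad_mode: str = "constant") -> tuple[float, float]:
    """Converge the two normalization constants on a bare single-Gabor input.

    Runs the equilibrium loop with attention off, resetting each layer's
    constant to ``sigma_norm`` times that layer's maximum pre-inhibition
    excitation after every iteration, until both constants change by less
    than ``rel_tol`` relative between iterations.  The converged values
    are then frozen for all experiments.
    """
    from .attention import no_attention

    if calibration_stimulus is None:
        calibration_stimulus = default_calibration_stimulus(params)
    drive = feedforward_drive(calibration_stimulus, params, pad_mode)
    att = no_attention(params)
    fb = np.zeros_like(drive)
    c_bottom = params.c_bottom
    c_top = params.c_top
    for it in range(max_iterations):
        e_bottom = bottom_excitation(drive, fb)
        new_c_bottom = params.sigma_norm * float(e_bottom.max())
        if new_c_bottom <= 0:
            raise CalibrationError("calibration stimulus drives no activity")
        bottom = divisive_normalize(e_bottom, params.sigma_inh, new_c_bottom,
                                    pad_mode)
        e_top = top_excitation(bottom, att, params, pad_mode)
        new_c_top = params.sigma_norm * float(e_top.max())
        if new_c_top <= 0:
            raise CalibrationError("no activity reaches the top layer")
        top = divisive_normalize(e_top, params.sigma_inh, new_c_top, pad_mode)
        fb = feedback_field(top, params, pad_mode)
        db = abs(new_c_bottom - c_bottom) / new_c_bottom
        dt = abs(new_c_top - c_top) / new_c_top
        c_bottom, c_top = new_c_bottom, new_c_top
        if it > 0 and db < rel_tol and dt < rel_tol:
            return c_bottom, c_top
    raise CalibrationError(
        f"normalization constants did not converge within {max_iterations} "
        f"iterations (last relative changes {db:.2e}, {dt:.2e})")


def calibrate(params: ModelParameters, **kwargs) -> ModelParameters:
    """Return a copy of ``params`` with calibrated c_bottom / c_top."""
    c_bottom, c_top = calibrate_constants(params, **kwargs)
    return params.replace(c_bottom=c_bottom, c_top=c_top)
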