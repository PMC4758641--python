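"""Stimulus generation.

All visual inputs are program-generated grayscale images: semi-rectified
Gabor patches (single-polarity bar-like stimuli, the luminance analogue of
a half-wave rectified grating), compositions of several patches, and
spectrally flat noise patches used for spectral receptive-field mapping.

Convention: an image is a 2-D non-negative float array indexed
``[row, column]``; positions are given as ``(x, y) = (column, row)`` in
pixels.  Orientation ``theta`` is the bar orientation in radians on the
pi-periodic axis, with ``theta = 0`` a vertical bar (carrier varying along
x) and ``theta = pi/2`` a horizontal bar.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from PIL.PngImagePlugin import PngInfo

__all__ = [
    "GaborSpec",
    "gabor",
    "semi_rectified_gabor_patch",
    "compose_display",
    "whitened_noise_patches",
    "write_csv",
    "read_csv",
    "write_png",
    "read_png",
]


@dataclass(frozen=True)
class GaborSpec:
    """Parameters of one semi-rectified Gabor patch.

    amplitude 1.0 is "full intensity"; 0.85 the reduced intensity used for
    the receptive-field mapping targets.
    """

    center: tuple[float, float]  # (x, y) px
    orientation: float           # radians in [0, pi)
    amplitude: float = 1.0
    envelope_sd: float = 3.0
    wavelength: float = 6.0
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.envelope_sd <= 0:
            raise ValueError("envelope_sd must be > 0")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be > 0")


def gabor(x: np.ndarray, y: np.ndarray, orientation: float,
          envelope_sd: float, wavelength: float, phase: float = 0.0
          ) -> np.ndarray:
    """Unrectified Gabor: Gaussian envelope times a cosine carrier.

    ``x``/``y`` are offsets from the Gabor center in pixels.  With
    ``orientation = 0`` the carrier varies along x, giving vertical bars.
    """
    envelope = np.exp(-(x ** 2 + y ** 2) / (2.0 * envelope_sd ** 2))
    carrier = np.cos(2.0 * np.pi * (x * np.cos(orientation)
                                    + y * np.sin(orientation)) / wavelength
                     + phase)
    return envelope * carrier


def semi_rectified_gabor_patch(spec: GaborSpec,
                               canvas: tuple[int, int]) -> np.ndarray:
    """Render ``max(0, amplitude * Gabor)`` on a zero background.

    ``canvas`` is (height, width).  The patch center must lie on the
    canvas; if the +-3 sd support does not fit it is clipped with a
    warning.
    """
    h, w = canvas
    cx, cy = spec.center
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError(f"center {spec.center} outside canvas {canvas}")
    support = 3.0 * spec.envelope_sd
    if cx - support < 0 or cx + support > w - 1 \
            or cy - support < 0 or cy + support > h - 1:
        warnings.warn("Gabor support extends beyond canvas; patch clipped",
                      stacklevel=2)
    xs = np.arange(w, dtype=float) - cx
    ys = np.arange(h, dtype=float) - cy
    xg, yg = np.meshgrid(xs, ys)
    g = spec.amplitude * gabor(xg, yg, spec.orientation, spec.envelope_sd,
                               spec.wavelength, spec.phase)
    return np.maximum(g, 0.0)


def compose_display(specs: Sequence[GaborSpec],
                    canvas: tuple[int, int]) -> np.ndarray:
    """Pixelwise sum of the rendered patches (no clipping where they overlap)."""
    if len(specs) == 0:
        raise ValueError("compose_display requires at least one GaborSpec")
    out = np.zeros(canvas, dtype=float)
    for spec in specs:
        out += semi_rectified_gabor_patch(spec, canvas)
    return out


def whitened_noise_patches(n: int, size: int, seed: int) -> list[np.ndarray]:
    """Reproducible spectrally flat noise patches, half-wave rectified.

    Gaussian white noise has a flat expected power spectrum by
    construction, emulating whitened natural images (the output of retinal
    decorrelation); rectification yields the non-negative luminance the
    network expects.  Same ``(n, size, seed)`` gives bitwise-identical
    patches.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if size < 1:
        raise ValueError("size must be >= 1")
    rng = np.random.default_rng(seed)
    return [np.maximum(rng.standard_normal((size, size)), 0.0)
            for _ in range(n)]


# ---------------------------------------------------------------------------
# Plain-text and PNG image I/O


def write_csv(image: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, image, delimiter=",")


def read_csv(path: str | Path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter=","))


def write_png(image: np.ndarray, path: str | Path) -> float:
    """8-bit PNG with the scale factor recorded in the metadata.

    Returns the factor by which pixel values were divided; ``read_png``
    uses the stored value to restore the original scale (to 8-bit
    quantization accuracy).
    """
    peak = float(image.max())
    scale = peak if peak > 0 else 1.0
    quantized = np.round(image / scale * 255.0).astype(np.uint8)
    meta = PngInfo()
    meta.add_text("attnnet_scale", repr(scale))
    Image.fromarray(quantized, mode="L").save(Path(path), pnginfo=meta)
    return scale


def read_png(path: str | Path) -> np.ndarray:
    with Image.open(Path(path)) as im:
        scale = float(im.info.get("attnnet_scale", 1.0))
        arr = np.asarray(im, dtype=float)
    return arr / 255.0 * scale
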