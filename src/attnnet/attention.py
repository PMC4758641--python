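"""Attention fields.

The top layer receives a multiplicative modulation ``(1 + A)`` where A is a
unit-peak Gaussian profile scaled by the mode's gain: over retinotopic
space for spatial attention (peak alpha_spatial_att at the attended
location), or over the pi-periodic orientation axis for feature-based
attention (peak alpha_feature_att at the attended orientation, spread
sigma_ori — the same spread as the orientation pooling, so feature
attention respects the network's own orientation selectivity).

The two modes are mutually exclusive in every protocol here; a product
combination is exposed as :func:`combined_attention` but is experimental.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .params import N_ORIENTATIONS, ModelParameters

__all__ = [
    "AttentionField",
    "no_attention",
    "spatial_attention",
    "feature_attention",
    "combined_attention",
    "circular_orientation_distance",
]


def circular_orientation_distance(a: float | np.ndarray,
                                  b: float | np.ndarray) -> np.ndarray:
    """Distance on the pi-periodic orientation axis: min(|d|, pi - |d|)."""
    d = np.abs(np.asarray(a, dtype=float) - b) % np.pi
    return np.minimum(d, np.pi - d)


@dataclass(frozen=True)
class AttentionField:
    """Multiplicative attentional modulation A(x, theta) >= 0.

    ``values`` has the oriented-map shape (height, width, 8).  ``mode`` is
    one of "none", "spatial", "feature" (or "combined"); ``focus`` records
    the attended location (spatial) or orientation in radians (feature).
    """

    values: np.ndarray
    mode: str = "none"
    focus: Optional[tuple] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3 or v.shape[2] != N_ORIENTATIONS:
            raise ValueError(f"attention field must be (H, W, {N_ORIENTATIONS})")
        if not np.all(np.isfinite(v)) or v.min() < 0:
            raise ValueError("attention field values must be finite and >= 0")
        object.__setattr__(self, "values", v)


def no_attention(params: ModelParameters) -> AttentionField:
    h, w = params.canvas
    return AttentionField(np.zeros((h, w, N_ORIENTATIONS)), mode="none")


def spatial_attention(focus: tuple[float, float], params: ModelParameters,
                      sigma: float | None = None,
                      alpha: float | None = None) -> AttentionField:
    """Isotropic 2-D Gaussian attention field centered on ``focus`` (x, y).

    Unit-peak: the value at the focus is alpha_spatial_att.  ``sigma``
    overrides sigma_att_spat (the attention-field-size manipulation of the
    contrast-response protocol).  Constant across orientation channels.
    """
    h, w = params.canvas
    fx, fy = focus
    if not (0 <= fx < w and 0 <= fy < h):
        raise ValueError(f"attention focus {focus} outside canvas {params.canvas}")
    sigma = params.sigma_att_spat if sigma is None else float(sigma)
    alpha = params.alpha_spatial_att if alpha is None else float(alpha)
    if sigma <= 0:
        raise ValueError("attention sigma must be > 0")
    xs = np.arange(w, dtype=float) - fx
    ys = np.arange(h, dtype=float) - fy
    d2 = ys[:, None] ** 2 + xs[None, :] ** 2
    field = alpha * np.exp(-d2 / (2.0 * sigma ** 2))
    values = np.repeat(field[:, :, None], N_ORIENTATIONS, axis=2)
    return AttentionField(values, mode="spatial", focus=(fx, fy))


def feature_attention(theta_att: float, params: ModelParameters,
                      alpha: float | None = None) -> AttentionField:
    """Orientation-domain Gaussian attention field, constant over space.

    Unit-peak: the channel matching ``theta_att`` receives
    alpha_feature_att; the spread is sigma_ori on the circular
    (pi-periodic) orientation axis.
    """
    h, w = params.canvas
    alpha = params.alpha_feature_att if alpha is None else float(alpha)
    thetas = np.arange(N_ORIENTATIONS) * (np.pi / N_ORIENTATIONS)
    d = circular_orientation_distance(thetas, theta_att % np.pi)
    profile = alpha * np.exp(-d ** 2 / (2.0 * params.sigma_ori ** 2))
    values = np.broadcast_to(profile, (h, w, N_ORIENTATIONS)).copy()
    return AttentionField(values, mode="feature", focus=(theta_att % np.pi,))


def combined_attention(focus: tuple[float, float], theta_att: float,
                       params: ModelParameters) -> AttentionField:
    """Experimental product of the spatial and feature fields.

    No protocol here uses it; exposed for exploration only.
    """
    spat = spatial_attention(focus, params).values
    feat = feature_attention(theta_att, params).values
    return AttentionField(spat * feat, mode="combined",
                          focus=(focus[0], focus[1], theta_att % np.pi))
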