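"""Curve fitting and map statistics quantifying experiment outputs.

Gaussian fits summarize orientation tuning curves (width = tuning
sharpness); Naka-Rushton fits summarize contrast-response curves and
support a quantitative response-gain vs contrast-gain classification;
half-max centroid/area statistics quantify receptive-field maps; the
normalized difference map compares spectral receptive fields between
attention conditions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "FitError",
    "GaussianFit",
    "NakaRushtonFit",
    "fit_gaussian",
    "fit_naka_rushton",
    "classify_gain",
    "rf_statistics",
    "normalized_difference",
]


class FitError(RuntimeError):
    """Raised when a curve fit is degenerate or fails to converge."""


@dataclass(frozen=True)
class GaussianFit:
    amplitude: float
    center: float
    width: float
    baseline: float
    rms_residual: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


@dataclass(frozen=True)
class NakaRushtonFit:
    r_max: float
    c50: float
    exponent: float
    baseline: float
    rms_residual: float

    def __call__(self, c):
        c = np.asarray(c, dtype=float)
        cn = c ** self.exponent
        return self.baseline + self.r_max * cn / (cn + self.c50 ** self.exponent)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _circ_d(x, center):
    d = np.abs(x - center) % np.pi
    return np.minimum(d, np.pi - d)


def fit_gaussian(x, y, circular: bool = False) -> GaussianFit:
    """Least-squares fit of ``y = baseline + A exp(-d(x, mu)^2 / 2 w^2)``.

    With ``circular=True`` the x axis is treated as pi-periodic
    orientation and d is the circular orientation distance.
    Initialization is data-driven (peak position/height, half-width at
    half height, minimum as baseline), so the fit is deterministic.
    The width is bounded below by half the smallest sample spacing:
    narrower widths are not identifiable from the samples and the
    unbounded fit can collapse onto a single point.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise FitError("need at least 4 points for a Gaussian fit")
    span = float(y.max() - y.min())
    if span <= 0 or span < 1e-12 * max(abs(float(y.max())), 1.0):
        raise FitError("degenerate (constant) curve")
    baseline0 = float(y.min())
    amp0 = span
    center0 = float(x[int(np.argmax(y))])
    dist = _circ_d(x, center0) if circular else np.abs(x - center0)
    above = dist[y - baseline0 >= 0.5 * amp0]
    width0 = max(float(above.max()) / 1.177, 1e-3 * (x.max() - x.min() + 1e-9)) \
        if above.size else float(np.median(dist))

    if circular:
        def model(xx, a, mu, w, b):
            return b + a * np.exp(-_circ_d(xx, mu) ** 2 / (2.0 * w ** 2))
    else:
        def model(xx, a, mu, w, b):
            return b + a * np.exp(-(xx - mu) ** 2 / (2.0 * w ** 2))

    spacing = np.diff(np.sort(np.unique(x)))
    min_width = 0.5 * float(spacing.min()) if spacing.size else 1e-9
    x_span = np.pi if circular else float(x.max() - x.min())
    try:
        popt, _ = curve_fit(
            model, x, y, p0=[amp0, center0, max(width0, min_width), baseline0],
            bounds=([-np.inf, -np.inf, min_width, -np.inf],
                    [np.inf, np.inf, 10 * x_span, np.inf]),
            maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - scipy failure path
        raise FitError(f"Gaussian fit did not converge: {exc}") from exc
    a, mu, w, b = popt
    resid = y - model(x, *popt)
    if circular:
        mu = mu % np.pi
    return GaussianFit(amplitude=float(a), center=float(mu), width=abs(float(w)),
                       baseline=float(b),
                       rms_residual=float(np.sqrt(np.mean(resid ** 2))))


def fit_naka_rushton(contrast, response,
                     monotone_tol: float = 0.05) -> NakaRushtonFit:
    """Fit ``r = baseline + r_max c^n / (c^n + c50^n)`` to a contrast curve.

    Requires at least 5 points spanning sub-saturation to saturation and
    an (approximately) non-decreasing curve: any decrease larger than
    ``monotone_tol`` times the response range is a fit failure.
    """
    c = np.asarray(contrast, dtype=float)
    y = np.asarray(response, dtype=float)
    if c.size < 5:
        raise FitError("need at least 5 points for a Naka-Rushton fit")
    order = np.argsort(c)
    c, y = c[order], y[order]
    span = float(y.max() - y.min())
    if span <= 0:
        raise FitError("degenerate (constant) curve")
    drops = np.diff(y)
    if drops.min() < -monotone_tol * span:
        raise FitError("curve is non-monotone beyond tolerance")
    baseline0 = float(y.min())
    rmax0 = span
    half = baseline0 + 0.5 * rmax0
    above = np.nonzero(y >= half)[0]
    c50_0 = float(c[above[0]]) if above.size and c[above[0]] > 0 \
        else float(np.median(c[c > 0]))

    def model(cc, rmax, c50, n, b):
        cn = np.power(np.maximum(cc, 0.0), n)
        return b + rmax * cn / (cn + c50 ** n)

    cmax = float(c.max())
    try:
        popt, _ = curve_fit(
            model, c, y, p0=[rmax0, c50_0, 3.0, baseline0],
            bounds=([1e-12, 1e-6 * cmax, 0.3, 0.0],
                    [10 * rmax0 + 1e-9, 10 * cmax, 60.0, max(y.max(), 1e-9)]),
            maxfev=40000)
    except RuntimeError as exc:  # pragma: no cover
        raise FitError(f"Naka-Rushton fit did not converge: {exc}") from exc
    rmax, c50, n, b = popt
    resid = y - model(c, *popt)
    return NakaRushtonFit(r_max=float(rmax), c50=float(c50), exponent=float(n),
                          baseline=float(b),
                          rms_residual=float(np.sqrt(np.mean(resid ** 2))))


def classify_gain(attended: NakaRushtonFit, reference: NakaRushtonFit,
                  dominance: float = 2.0) -> str:
    """Classify an attentional effect as response gain, contrast gain or mixed.

    Response gain: the relative r_max change dominates the relative c50
    change by at least ``dominance``; contrast gain: the reverse; mixed
    otherwise.  The factor-2 dominance criterion makes the qualitative
    distinction testable.
    """
    d_rmax = abs(attended.r_max - reference.r_max) / reference.r_max
    d_c50 = abs(attended.c50 - reference.c50) / reference.c50
    if d_rmax > dominance * d_c50:
        return "response"
    if d_c50 > dominance * d_rmax:
        return "contrast"
    return "mixed"


def rf_statistics(rf_map: np.ndarray,
                  grid_spacing: float = 1.0,
                  grid_center: tuple[float, float] = (0.0, 0.0)
                  ) -> tuple[tuple[float, float], int, float]:
    """Half-max receptive-field statistics of a probe-grid response map.

    Returns ``(centroid (x, y), area, peak)``: the response-weighted
    center of mass of grid points at or above half the peak (in the same
    pixel coordinates as ``grid_center``), the count of such points (RF
    area in grid cells), and the peak response.
    """
    m = np.asarray(rf_map, dtype=float)
    peak = float(m.max())
    if peak <= 0:
        raise ValueError("all-zero receptive-field map")
    mask = m >= 0.5 * peak
    rows, cols = np.nonzero(mask)
    weights = m[rows, cols]
    half = (np.array(m.shape, dtype=float) - 1) / 2.0
    cx = grid_center[0] + float(np.average(cols - half[1], weights=weights)) * grid_spacing
    cy = grid_center[1] + float(np.average(rows - half[0], weights=weights)) * grid_spacing
    return (cx, cy), int(mask.sum()), peak


def normalized_difference(a: np.ndarray, b: np.ndarray) -> np.ma.MaskedArray:
    """Pointwise ``(a - b) / (a + b)``, masked where ``a + b == 0``.

    Bounded in [-1, 1] wherever defined for non-negative inputs; exactly
    antisymmetric under swapping the two conditions.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    total = a + b
    mask = total == 0
    safe = np.where(mask, 1.0, total)
    return np.ma.MaskedArray((a - b) / safe, mask=mask)
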