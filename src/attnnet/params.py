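"""Model parameters.

A single global parameter set is used for every experiment: the model's
point is that one configuration reproduces all attentional effects at once,
so nothing here is tuned per protocol.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import yaml

N_ORIENTATIONS = 8
#: Orientation channel spacing on the pi-periodic orientation axis (radians).
ORI_STEP = math.pi / N_ORIENTATIONS


@dataclass(frozen=True)
class ModelParameters:
    """All constants of the two-layer attention network.

    Spatial scales are in pixels, orientation scales in radians. The
    defaults are the single global set used across every experiment.

    Attributes
    ----------
    sigma_bottom : float
        Envelope sd of the bottom-layer Gabor filters (V1 RF size), px.
    sigma_top : float
        Sd of the spatial Gaussian pooling from bottom to top layer
        (V4/MT RF size), px.  Feedback uses the same kernel.
    sigma_inh : float
        Sd of the short-range inhibition Gaussian pooling the divisive
        normalization signal, px.  Identical in both layers.
    sigma_att_spat : float
        Sd of the spatial attention field, px.
    sigma_ori : float
        Sd of the orientation-domain Gaussian, radians; used both for
        bottom-to-top orientation pooling and for the feature-attention
        field.
    alpha_spatial_att : float
        Peak gain of the spatial attention field (modulation factor at
        the focus is 1 + alpha).
    alpha_feature_att : float
        Peak gain of the feature attention field.
    alpha_fb : float
        Strength of the modulatory feedback from top to bottom layer.
    sigma_norm : float
        Calibration multiplier: each layer's normalization constant is
        sigma_norm times that layer's maximum pre-inhibition excitation.
    c_bottom, c_top : float
        Semi-saturation constants of the divisive normalization in each
        layer.  The defaults are the values the calibration loop
        converges to under this implementation's filter conventions
        (see ``attnnet.network.calibrate_constants``).
    n_iterations : int
        Fixed number of bottom->top->feedback passes; 30 suffices to
        equilibrate responses.
    wavelength : float
        Carrier wavelength of the bottom-layer Gabor filters, px.
    canvas : tuple[int, int]
        Default (height, width) of the stimulus canvas, px.
    """

    sigma_bottom: float = 3.0
    sigma_top: float = 12.0
    sigma_inh: float = 1.0
    sigma_att_spat: float = 3.0
    sigma_ori: float = 1.1 * ORI_STEP
    alpha_spatial_att: float = 2.0
    alpha_feature_att: float = 0.2
    alpha_fb: float = 18.0
    sigma_norm: float = 0.6
    c_bottom: float = 1.0
    c_top: float = 1.0
    n_iterations: int = 30
    wavelength: float = 6.0
    canvas: tuple[int, int] = (100, 100)

    def __post_init__(self) -> None:
        for name in ("sigma_bottom", "sigma_top", "sigma_inh",
                     "sigma_att_spat", "sigma_ori", "sigma_norm",
                     "c_bottom", "c_top", "wavelength"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("alpha_spatial_att", "alpha_feature_att", "alpha_fb"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")

    # The nine free parameters the sensitivity sweep rescales (the two c
    # constants are recalibrated, not scaled, and n_iterations is fixed).
    FREE_PARAMETERS = ("sigma_bottom", "sigma_top", "sigma_inh",
                       "sigma_att_spat", "sigma_ori", "alpha_spatial_att",
                       "alpha_feature_att", "alpha_fb", "sigma_norm")

    def replace(self, **kwargs) -> "ModelParameters":
        return dataclasses.replace(self, **kwargs)

    def scaled(self, factor: float) -> "ModelParameters":
        """All nine free parameters multiplied by a common factor."""
        if factor <= 0:
            raise ValueError("scale factor must be > 0")
        return self.replace(**{k: getattr(self, k) * factor
                               for k in self.FREE_PARAMETERS})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["canvas"] = list(self.canvas)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        d = dict(d)
        if "canvas" in d:
            d["canvas"] = tuple(d["canvas"])
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - valid
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (json.dumps(self.to_dict(), indent=2)
                if path.suffix == ".json"
                else yaml.safe_dump(self.to_dict(), sort_keys=False))
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "ModelParameters":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)


def orientation_channels() -> "list[float]":
    """The 8 channel orientations theta_k = k*pi/8, k = 0..7 (radians)."""
    return [k * ORI_STEP for k in range(N_ORIENTATIONS)]
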