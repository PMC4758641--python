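# Methods

## Model

Two reciprocally connected retinotopic sheets, one cell per pixel per
orientation channel (8 channels at θ_k = k·π/8 on the π-periodic
orientation axis). All state is held in non-negative arrays of shape
(height, width, 8).

**Bottom layer.** The input image (non-negative luminance, "full
intensity" = 1) is filtered by a bank of 8 Gabor kernels; the resulting
drive is multiplied by (1 + FB), squared, and divisively normalized:

    E = ((1 + FB) · drive)²,   R = E / (Inh + c_bottom),
    Inh = Gauss(σ_inh) ⊗ Σ_θ E.

Squaring implements a power-law transfer; the unit constant in (1 + FB)
makes feedback strictly excitatory (FB ≥ 0 is enforced). The drive is
floored at zero after filtering: a negative filter response is not a
physical rate, and squaring it would turn suppression into excitation.

**Top layer.** Bottom responses are pooled by a separable spatial Gaussian
(sd σ_top) followed by a circular 1-D Gaussian over the orientation axis
(sd σ_ori), multiplied by (1 + A) where A is the attention field, squared,
and normalized with c_top. Top-layer orientation selectivity therefore
arises purely from selective pooling.

**Feedback.** FB = α_fb times the top response passed through the same
spatial-then-orientation pooling (feedback weights proportional to
feedforward weights). The loop bottom → top → feedback is iterated a fixed
30 times with FB initialized to zero, so iteration 1 is purely feedforward
in the bottom layer. A fixed count (rather than a convergence test) keeps
traces bit-for-bit reproducible; an equilibration check is part of the
test suite (see Limitations).

## Parameters

One global set, used unchanged by every protocol:

| parameter | value | meaning |
|---|---|---|
| σ_bottom | 3 px | Gabor envelope sd; "V1" RF size |
| σ_top | 12 px | bottom→top pooling sd; "V4/MT" RF size (4× bottom) |
| σ_inh | 1 px | normalization pool sd (both layers; short-range) |
| σ_att_spat | 3 px | spatial attention field sd |
| σ_ori | 1.1·π/8 rad | orientation pooling sd = feature-attention spread |
| α_spatial_att | 2 | peak spatial attention gain |
| α_feature_att | 0.2 | peak feature attention gain |
| α_fb | 18 | feedback strength |
| σ_norm | 0.6 | calibration multiplier for c_bottom, c_top |
| n_iterations | 30 | fixed relaxation passes |
| wavelength | 6 px | Gabor carrier wavelength (filters and stimuli) |
| canvas | 100×100 px | default sheet size (≥3σ_top margin at the center) |

## Conventions the equations do not fix

These choices are documented because the results' absolute scales depend
on them.

* **Kernel normalization.** All Gaussian kernels (pooling, feedback,
  inhibition, orientation) are unit-sum and truncated at radius
  ceil(3σ) (<0.3% mass lost, deterministic footprint). The attention
  Gaussians are unit-peak, so the maximum modulation factor is 1 + α —
  a sum-normalized attention field (peak ≈ 0.03) could not produce
  attentional effects of the observed tens-of-percent magnitude.
* **Gabor filters** are cosine-phase, zero-DC (mean-subtracted) and unit
  L2 norm (the unit-energy convention); stimuli are semi-rectified
  (max(0, ·)) cosine Gabors with envelope sd σ_bottom and the model
  wavelength, so a full-intensity stimulus is the matched input of one
  bottom-layer filter.
* **Padding.** Spatial convolutions use zero padding (a periodic option
  exists and is used by the exact translation-equivariance tests); the
  orientation axis always wraps. The default canvas keeps all measured
  activity ≥3σ_top from the borders.
* **Normalization-constant calibration** runs on a bare, unattended
  single Gabor at the canvas center: after every iteration each layer's
  constant is reset to σ_norm times that layer's maximum pre-inhibition
  excitation, until both change by <1e-6 relative (hard cap 500
  iterations). With the conventions above this converges to
  c_bottom = 29.56 and c_top = 2.97e-5. These values are a *gauge*: the
  divisive normalization makes every downstream response invariant to a
  common rescaling of the filter bank, so only the ratio of c to the
  operating excitation matters, and that ratio is pinned by σ_norm. The
  feedforward (first-iteration) bottom-layer maximum corresponds to
  c = 2.75 under the same conventions.

## Protocols

All protocols read out the top-layer, vertical-preferring cell at the
canvas center (probe responses are single-cell values, no spatial
averaging), and all modulation percentages are 100·(R_att − R_noatt)/R_noatt
at equilibrium.

* **Biased competition.** Preferred (vertical) and anti-preferred
  (horizontal) Gabors at ±10 px from the cell; five conditions (each
  alone, pair unattended, pair attending either stimulus).
* **Layer modulation.** Peak modulation across channels at the cell under
  the attentional focus, per layer. Default display: a single preferred
  Gabor at the cell's RF center (the two-stimulus display is available
  via `display="pair"`; it yields larger values in both layers).
* **Timecourse.** Per-iteration traces of matched top/bottom probes with
  attention on/off; onset latency is summarized as the first iteration
  where |modulation| reaches half its final value (scale-free and robust
  on 30-point traces).
* **Orientation tuning.** Stimulus takes the 8 channel orientations;
  feature attention tracks the stimulus orientation. Tuning width is the
  sd of a circular Gaussian fit.
* **Contrast response.** Stimulus amplitude sweeps linearly from 0 to the
  saturation amplitude (found on a 1.5× ladder: the level where the
  unattended response changes <1% over the last grid step). 16 levels are
  used: the response curve has a steep ignition knee near the calibration
  amplitude — an inevitable consequence of σ_norm placing the
  normalization constants at 0.6× the amplitude-1 excitation — and a
  coarser grid under-resolves the knee, destabilizing the c50 of the
  Naka-Rushton fits. The size sweep uses attention fields of σ = 1.5 and
  24 px (well below/above the σ_top = 12 RF scale); the offset sweep uses
  focus offsets of 0, 6 and 10 px at σ = 3. Gain regimes are classified
  from Naka-Rushton fits (r = b + r_max·cⁿ/(cⁿ + c50ⁿ)): "response" if
  the relative r_max change dominates the relative c50 change by ≥2×,
  "contrast" for the reverse, "mixed" otherwise.
* **RF mapping.** Two horizontal targets at 85% intensity flank the cell
  at 2/3·σ_top ("inside", 8 px at defaults) or 2·σ_top ("edge", 24 px);
  a full-intensity vertical probe visits a 15×15 grid with 2 px spacing.
  Offsets are RF-relative so the layouts keep their meaning when
  parameters are rescaled. RF centroid = response-weighted center of mass
  of grid points at ≥ half the map's peak; RF area = the count of such
  points. The probe's filter response is computed once and shifted
  (the filter bank is linear; rectification is applied to the summed
  display response), so each grid point costs only the 30-pass loop.
* **Spectral RF.** ≥500 half-wave-rectified Gaussian white-noise patches
  (spectrally flat by construction, standing in for whitened natural
  images) are shown on a 48×48 canvas under feature attention to 45° or
  135° — orientations equidistant from both probe cells' preferences.
  SRF = Σ_i r_i·|FFT2(patch_i)| / Σ_i r_i (amplitude spectrum; a power
  option exists). Conditions are compared with the normalized difference
  (a−b)/(a+b), masked where a+b = 0.
* **Sensitivity.** All nine free parameters are multiplied by a common
  factor (0.8, 1.0, 1.2), constants recalibrated per scale, and four
  qualitative conclusions re-checked: biased competition (signs correct
  and ≥5% each way — smaller is counted as eliminated), feature-gain
  sharpening, RF shift direction, and the shrink/expand pattern.

## Numerical choices

* Separable Gaussian blurs are applied as precomputed banded (or
  circulant) matrix products — several times faster than moving-window
  correlation at these sizes and exactly equal to it (oracle-tested to
  1e-10 against direct summation).
* Gaussian fits: data-driven initialization (peak location/height,
  half-width at half height, min as baseline), width bounded below by
  half the sample spacing — on 8-point tuning curves the attended curve
  is peakier than any Gaussian and an unbounded width collapses to ~0.
* Naka-Rushton fits: exponent bounded to [0.3, 60] (the knee is steep),
  curves required non-decreasing within 5% of their range.
* Calibration fails loudly (CalibrationError) on blank stimuli or
  non-convergence; the fixed-point loop raises DivergenceError naming the
  iteration if responses become non-finite.

## What the synthetic stimuli do and do not show

All inputs are program-generated: rectified Gabors and rectified white
noise. They probe the network mechanism under the exact conditions the
protocols define; they contain no natural-image statistics, no noise in
the responses (the model is deterministic), no temporal structure. Passing
tests therefore demonstrate the circuit-level claims (which effects emerge
from feedback plus normalization) — not quantitative agreement with any
physiological dataset, and nothing about trial-to-trial variability,
synchrony, or response timing within an iteration.

## Known limitations

* Within-RF competition only: no outside-RF surround suppression, no
  spiking dynamics, no learning; the source of the top-down signal is not
  modelled (spatial and feature attention fields are given).
* The absolute values of c_bottom/c_top (and every raw response value)
  depend on the documented filter-normalization gauge; percent
  modulations, gain classifications and RF statistics do not.
* At exactly the calibration amplitude the unattended network sits at the
  ignition knee of the feedback loop and equilibrates slowly (probe
  change ~7e-4 between iterations 30 and 60, vs <1e-6 for attended runs).
  The fixed 30-iteration protocol is kept for reproducibility; the
  residual drift is orders of magnitude below every effect reported.
* The spatial attention Gaussian is 2-D isotropic; the field itself does
  not wrap under periodic padding (equivariance tests shift the field
  array explicitly).
* The spectral-RF estimator omits any correction for stimulus spectral
  autocorrelation; with rectified white noise the raw SRF anisotropy is
  real but small, and the attention effect is read from the normalized
  difference map.
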