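# Methods

`micropress` models and analyses single-cell mechanics measured by two-plate
(parallel-plate) compression: a suspended cell is squeezed between two flat
end-effectors at constant speed while the reaction force and a micrograph
sequence are recorded. The package contains both the analysis chain used on
such recordings and a virtual instrument that generates the same data types
from known ground truth, so every stage can be validated quantitatively
without hardware.

## Force-sensor calibration

The force sensor is calibrated gravimetrically: a steel ball of known mass m
(default 3.27 × 10⁻⁵ g) rests on the sensor tip while the assembly is rotated
through one full revolution in `n_steps` equal increments (50 steps → 7.2°
per step). The axial load at angle θ is m·g·cos(θ − φ), with g = 9.80665 m/s²
throughout, so the ADC output traces

    ADC(θ) = baseline + m·g·cos(θ − φ) / k,

where k is the force-to-signal conversion coefficient (nN/ADU) and φ the
phase of the sensitive axis. The fit is ordinary least squares of ADC on
{cos θ, sin θ, 1}: amplitude R = √(A² + B²) gives k = m·g/R, φ = atan2(B, A),
and the constant term is the baseline. Because the model class contains the
noise-free signal exactly, noise-free sweeps are recovered to machine
precision, and the recovered phase shifts one-for-one under a rigid rotation
of all sweep angles while k, RMSE and resolution are invariant.

A free baseline term is always included: real ADCs have offsets and the
constant is identifiable from a full revolution.

Error metrics are reported in force units: residuals (predicted − measured
ADC) are converted through k, RMSE is their root mean square and the maximum
error their largest magnitude. **Resolution** is defined operationally as the
standard deviation of the force-converted fit residuals — the smallest force
change distinguishable from calibration scatter. This is this package's
working definition; other instruments define resolution differently (e.g.
noise-floor spectral density), so absolute resolution values are only
comparable within this convention. It requires ≥ 5 residuals and scales
linearly with the ADC noise at fixed k.

## Geometry from micrographs

Frames show two dark plate bands with inner edges perpendicular to the
compression axis (horizontal by default) and a darker cell between them.

* Plate inner edges: strongest rising/falling gradients of the transverse-
  averaged intensity profile, reported at pixel boundaries. Gradient argmax
  and Otsu segmentation make all measurements invariant to affine intensity
  rescaling.
* Cell mask: Otsu threshold on the inter-plate region, largest connected
  component.
* Width L_t: plate inner-edge separation while the cell touches both plates;
  before contact, the axial extent of the cell mask.
* Contact length D_t: transverse extent of the mask within a tolerance band
  (default 2 px, configurable) inside each plate edge, averaged over the two
  plates. An empty band returns D_t = 0 with a no-contact flag. Contact below
  the pixel scale is not resolvable in bright field, hence the band.
* Contact area: S_t = π·D_t²/4 (circular patch), exact on any input.

Coordinates are 0-based pixel indices with intensities sampled at pixel
centres; µm values come from `pixel_size`. Round-trip accuracy against the
renderer is within one pixel for both D_t and L_t over L_t ∈ [4, 15] µm,
D_t ∈ [0, 12] µm and pixel sizes {0.05, 0.1, 0.2} µm/px. A manual-override
path (pre-measured geometry CSV) is supported, since bench measurements of
D_t/L_t are often made by hand.

## Stress, strain, and the elastic modulus

Engineering strain ε_t = (L₀ − L_t)/L₀ and contact stress σ_t = F_t/S_t.
Forces are in nN and areas in µm², so stress is in kPa identically
(1 nN/µm² = 1 kPa); the generator and the analysers share this convention
bit-for-bit. L₀ is the undeformed cell width measured from an approach frame
(the cell imaged just before plate contact), read from the segmented cell
mask. Taking L₀ from the first *contact* frame instead under-reads it by one
frame-period of plate travel and biases every modulus down by
speed/(rate·L₀) ≈ 1–2% at the defaults; with the approach-frame convention
the image path's residual modulus bias is below 1% (pixel-quantization
effects only). Points without contact (S_t = 0) carry no stress information
and are excluded (counted, not interpolated); points with L_t > L₀ trigger a
negative-strain warning and are likewise excluded.

The curve is split into loading/unloading at the index of maximum strain.
The elastic modulus is the OLS slope of σ on ε over the **high-strain
region** of the loading branch — by default the top 30% of achieved strain,
where the stress–strain plot of compressed cells is linear. The cutoff is
scale-free and configurable; on exactly linear data the estimate moves by
< 2% when the window shrinks from 30% to 10%. The regression keeps an
intercept (contact-onset offsets are common; the slope is the modulus either
way on linear data). At least three window points are required.

## Power-law rheology

Cells are viscoelastic; the apparent modulus falls with indentation time
according to the structural-damping power law

    E(t) = E₀ (t/t_ref)^(−β),  t_ref = 1 s,

with β = 0 a purely elastic solid and β = 1 a Newtonian liquid. Apparent
moduli are sampled one per compression run as the secant σ/ε at a fixed
strain checkpoint (linear interpolation between bracketing loading points);
the indentation time to the checkpoint is ε*·L₀/speed for a constant-speed
ramp. Sweeping the plate speed over 2.5–15 µm/s varies t by the same 6×
factor, conditioning the fit. Two checkpoints probe depth regimes: 0.15
(shallow — cytoplasm-dominated) and 0.45 (deep — nucleus engaged); both
defaults are configurable and are this package's choice of how to form
E(t) samples from runs, since several constructions are possible.

The fit is OLS of ln E on ln(t/t_ref) (the model is exactly linear in log
space): β = −slope, E₀ = exp(intercept). Nonlinear least squares on the
original scale is available as a cross-check (`method="nls"`). Noise-free
samples are recovered to ≤ 10⁻⁶ relative error over E₀ ∈ [1, 10] kPa,
β ∈ [0, 1]; changing t_ref to t_ref′ rescales E₀ by (t_ref′/t_ref)^(−β) and
leaves β unchanged (tested analytic identity). The regime comparison reports
the deep/shallow E₀ ratio and the β difference and flags whether the dataset
shows the expected compartment picture (stiffer and more solid-like at
depth); the flags describe the data and are not enforced as invariants.

## The virtual instrument

The simulator emulates what the analysis assumes, with known ground truth:

* **Geometry.** A rigid truncated sphere of diameter L₀: at strain ε the
  plate separation is L₀(1 − ε) and the contact chord is
  D(ε) = L₀·√(2ε − ε²) (D(0) = 0, strictly increasing, ≤ L₀). Lateral
  bulging and volume conservation are *not* modelled; the truncated sphere
  is a transparent, testable stand-in, not a contact-mechanics solution —
  Hertzian or finite-element contact is out of scope.
* **Two compartments.** The nucleus (diameter fraction 0.6 of L₀ by default)
  engages at ε* = 1 − nucleus_fraction. Below ε* the apparent modulus is the
  cytoplasm power law; above, the compartments are stacked in series along
  the compression axis and the modulus is the strain-weighted harmonic mean
  of the two power laws. This is the simplest model that makes deep
  indentation read out the stiffer, more solid nucleus.
* **Forces.** σ(t) = E_app(ε, t)·ε, F = σ·πD²/4, plus additive Gaussian
  force noise (default 2 nN, of the order of the sensor resolution).
  Unloading retraces strain with stress scaled by `unload_retention`
  (default 0.7): observed hysteresis loops motivate the factor, but its
  magnitude is a free parameter, not a fitted quantity.
* **Micrographs.** Bright-field-like frames: dark plates (0.2), darker cell
  (0.5), bright background (0.9) on pixel-centre sampling. The cell
  silhouette is a circular barrel with flat contact pads so the chord equals
  D_t exactly within the measurement band (a compressed cell is flat against
  the plate over the patch). D_t = 0 renders a pre-contact frame with the
  plates opened a few pixels wider than the cell. No optics (blur, shading,
  shot noise) are modelled, so image tests validate the measurement
  geometry, not robustness to real microscope artefacts.
* **Populations.** Condition presets are normal mixtures over whole-cell
  moduli, truncated below at 0.1 kPa. Single-component presets carry the
  studied conditions' mean ± SD and per-condition sample sizes (cell-type
  panel, Cytochalasin D and Trichostatin A dose series, trypsinization
  comparison). The progerin-overexpression preset is the two-component
  mixture 0.6·N(3.0, 0.8²) + 0.4·N(7.0, 0.8²) kPa, reproducing its
  characteristic stiffness peaks in the 2–4 and 6–8 kPa bands; the lamin-A
  preset 0.7·N(3.2, 1.0²) + 0.3·N(4.6, 2.0²) is right-skewed but unimodal.
  Mixture weights and component SDs for these two are this package's
  choices (only the peak bands are constrained by the reported
  distributions). Sampled cells are converted to *elastic* virtual cells
  (β = 0, both compartments at the drawn modulus): the presets encode
  distributions of measured stiffness, so the measurement must return the
  drawn value; rheology scenarios exercise viscoelastic cells separately.
* **End effectors.** The plate scenario is the standard simulator. The
  needle scenario keeps the whole-cell reaction force (a displacement-
  controlled compression transmits its reaction through the cell body
  regardless of tip footprint) and models the unstable engagement of the
  small fixed tip as multiplicative log-normal slip noise (unit mean,
  CV 0.5), which widens the max-force distribution relative to the plate at
  equal cell parameters.

All randomness sits behind explicit integer seeds (numpy `default_rng`); the
pipeline derives per-cell sub-seeds from one master seed via `SeedSequence`,
so whole-scenario reruns are byte-identical.

## Population statistics

Summaries are mean ± sample SD (n − 1) with SEM. The two-sample test is the
classic pooled-variance Student's t (two-tailed, df = n_a + n_b − 2), with
Welch's variant behind a flag; no multiple-comparison correction is applied
(a known limitation of the underlying protocol this mirrors). Density
histograms report the fraction of cells per bin (default 1 kPa), normalised
so density × width sums to 1. Modes are local maxima of a Gaussian KDE
(Silverman bandwidth) exceeding 10% of the global peak; a population is
flagged bimodal when two modes are separated by > 2 kPa, the separation of
the 2–4 and 6–8 kPa stiffness bands. KDE modes are used instead of raw
histogram peaks because bin-edge tie-breaking is ill-posed. Dose-response
checks report whether condition means are non-increasing in dose order plus
the total relative decrease.

Measured moduli that regress to ≤ 0 kPa (possible for cells drawn near the
truncation bound, whose stress signal is below the force-noise floor) are
excluded from condition populations as below-detection measurements.

## Numerical and design choices

* Angles are degrees at every interface and radians internally (conversion
  centralised in the calibration module).
* Checkpoint/curve interpolation is linear in strain; against a 10× refined
  time grid the interpolated apparent modulus agrees within 0.5%.
* The rheology speed-sweep scenario samples at 200 Hz with L₀ = 15 µm so
  both checkpoints land exactly on sample times for all four speeds, keeping
  the noise-free regime fits exact.
* Degenerate inputs are errors, not silent results: < 4 calibration angles,
  all-equal angles, < 3 contact points, unreached checkpoints, all-equal
  indentation times, empty masks, non-positive apparent moduli.
* Population pipeline problem sizes: condition runs use the per-condition
  studied sample sizes (e.g. 57 HEK293A cells) at 50 Hz sampling with
  loading-only ramps; image-based geometry (the default) renders one frame
  per sample at 0.1 µm/px.

## What passing tests do and do not show

The virtual instrument shares its geometric model with the analysis chain,
so round trips validate internal consistency, parameter identifiability and
implementation correctness — not the truncated-sphere approximation itself,
nor robustness to optical artefacts, cell adhesion, plate misalignment or
off-axis contact, none of which are modelled. Population recovery tests show
the pipeline is statistically faithful to the generator's distributions at
the studied sample sizes; they cannot validate the biological values of the
presets, which are taken as given.
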