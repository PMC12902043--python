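# Methods

## Wave propagation

All field transport uses the angular spectrum method with the exact
(non-paraxial) kernel: a field sampled at pitch p on an n_y×n_x grid is
Fourier-decomposed into plane waves at spatial frequencies spaced
1/(n·p) per axis, each component is multiplied by

    exp(+i 2π d √(1/λ² − f_x² − f_y²)),

and the field is recomposed.  The square-root form is retained rather
than the Fresnel expansion because at the target geometry (d ≈ 2.5 mm
over a 7.7 mm sensor) the marginal plane waves are not deeply paraxial.
Frequencies with f_x² + f_y² > 1/λ² are evanescent; their kernel is set
to exactly zero, which keeps backpropagation stable (the same components
would otherwise grow exponentially).  Note that at the study's sampling
(p = 2.0 μm, λ = 0.658 μm) the representable band lies entirely inside
the propagating region, so the cut-off never removes energy there.

Sign convention: forward propagation (object → sensor, positive d) uses
the +i exponent; `transfer(−d)` is the complex conjugate of
`transfer(+d)`.  Lengths are μm throughout.

**Padding.** Before transforming, a field is embedded in a grid enlarged
by `pad_factor` (default 2) per axis and cropped back afterwards.  The
border is filled with the mean modulus of the field's outer frame
(nominally 8 px wide, shrunk to min(8, min(n)/4) on tiny grids) rather
than zeros: a normalised hologram has background ≈ 1, and zero-padding
would introduce a spurious hard aperture edge that diffracts into the
reconstruction.  Padding costs 4× per FFT at factor 2; for interior
objects on grids ≥ 512 px the wrap-around error without padding is
negligible, which is why the bundled test scenes run at `pad_factor=1`.

## Reconstruction

A raw frame is first normalised by a background estimate
(`frame_mean` by default — grains are sparse, so the frame mean tracks
the background; `border_mean` and pixelwise `reference_frame` division
are available, the latter guarded against divisor values below 1% of the
reference mean).  The sensor-plane field is initialised as Ũ = √H with
zero phase.

**Phase reference.** √H carries no propagation phase, so a literal
backpropagation would leave the plane-wave carrier phase exp(−i2πh/λ) on
the background, making "clip to 1 and reset the phase to zero"
internally inconsistent.  The reconstruction module therefore uses
carrier-removed kernels (the on-axis phase divided out), i.e. all phases
are referenced to the illuminating wave — precisely the convention in
which the transmission of an empty scene is 1 + 0i.  Amplitudes are
unaffected.

**GS loop.** One iteration = backpropagate by h, then enforce passivity
(|T̃| ≤ clip level, default 1.0; offending pixels become
`clip_level + 0i`, i.e. amplitude clipped and phase reset at those
pixels only — a global phase reset would destroy the retrieved phase and
defeat the algorithm).  Between iterations the field returns to the
sensor plane, where its modulus is replaced by √H (zero-modulus pixels,
whose phase is undefined, adopt phase 0).  The result is read off the
object plane of the final pass, so one iteration coincides with a single
backpropagation plus clipping, and `n_iterations = 0` is special-cased
to the same degenerate output.  The iteration count is fixed at 200 with
no early-stopping tolerance; on the synthetic scenes the sensor-plane
misfit plateaus well before that.  When requested, the RMS amplitude
residual rms(|U| − √H) before each sensor update is logged purely as a
diagnostic.

**Autofocus.** The study's operator selected h visually; here sharpness
is scored by the Tamura coefficient of the gradient magnitude,
√(std(g)/mean(g)) with g = |∇amplitude| by central differences — a
standard holographic autofocus metric that is offset-invariant, zero for
constant images, and decreases under blur.  The score of the
single-backpropagation amplitude is evaluated on a coarse grid (default
2300–2800 μm in 10 μm steps, bracketing the study's ≈2546 μm), ties
break toward smaller h, and an optional golden-section pass refines
within ±step.  For phantoms that carry phase as well as absorption the
sharpest-amplitude plane sits 10–15 μm beyond the geometric object
plane (the grains act as weak lenses); this physical focal shift is well
inside the ±2-step recovery tolerance used in the tests and matches the
centimetre-scale reproducibility one expects of visual refocusing.

**Twin suppression metric.** std(background of backprop amplitude) /
std(background of GS amplitude), with the background taken as the
complement of the truth mask eroded by 5 px.  On noiseless scenes the GS
background can converge to exactly 1, making the ratio infinite; the
ratio is therefore reported per scene and summarised by win fraction and
per-method background noise rather than by its own mean.

## Synthetic data

The generator stands in for the study's slides and reading sessions; its
defaults are the study conditions where stated, and field-typical values
otherwise.

*Scenes.* Six stylised silhouettes (oval + pore for timothy grass, disk
with 12 × 2 μm spikes for ragweed, rounded triangles for birch and
hazel, rounded pentagon for alder, furrowed bean for olive) with
diameters drawn per species from 20–40 μm normal laws (literature-
typical — the study prints no sizes), minimum interior transmission 0.3,
peak phase delay 1.0 rad, a ~1-pixel soft edge, and non-overlapping
uniform placement (100 retries, then an error).  Every scene satisfies
|T| ≤ 1, the passivity assumption of the GS object constraint.

*Sensor.* The scene is propagated by +h under unit plane-wave
illumination; |U|² is scaled so the brightest pixel hits the 12-bit full
scale; Poisson shot noise (default 5000 photons at unit intensity),
Gaussian read noise (2 counts) and rounding are then applied.  Zero
photons selects an exact noiseless path (no rounding), which the
closed-loop reconstruction tests use.

*What the phantoms do not model:* real pollen texture and internal
structure, partially coherent illumination, slide debris, overlapping
or damaged grains, sensor fixed-pattern noise.  Passing closed-loop
tests therefore demonstrate that the algorithmic chain is correct under
its own forward model, not that classification of real slides would
reach the same quality.

*Reading sessions.* `generate_study_records` draws assigned labels from
per-modality 6×6 row-stochastic confusion matrices, 8 test images per
class per modality, with image identities shared between evaluators and
modalities (required for κ to be well defined).
`reference_study_records` is the deterministic session encoding the
validation study's published summary: 48 test images per modality, two
experts, seven misclassifications (two birch→hazel, two birch→alder,
two alder→birch, one olive→birch) placed on distinct images and
distributed 1/3 (DIHM) and 2/1 (optical) across the experts.  That
layout is the unique one consistent with the per-expert accuracies, the
pooled per-class F1 values and the stated concentration of errors among
birch/alder/hazel, and it reproduces the inter-observer κ of 0.90
(DIHM), 0.93 (optical) and 0.91 (pooled) under half-up rounding.

## Statistics

Accuracy = 100·correct/total, rounded half-up to one decimal; pooled
accuracies are computed from pooled counts, never by averaging rounded
percentages ((97.9 + 93.8)/2 = 95.85 but 92/96 prints as 95.8).
Per-class F1 = 2TP/(2TP + FP + FN) from the pooled confusion matrix,
three decimals, with empty classes reported as 0 and flagged.  Cohen's
κ = (p_o − p_e)/(1 − p_e) is computed from the definition (the result
object carries p_o, p_e and the pair count); when p_e = 1 both raters
are necessarily constant on the same label, and κ is 1 by convention.
Inter-modality κ pairs each evaluator's labels across modalities on
matched image content.  The implementation is cross-checked in the test
suite against exact rational arithmetic on all 4096 binary label pairs
of length 6 and against scikit-learn's `cohen_kappa_score` on random
vectors.

## Problem sizes and numerical choices

The bundled tests and the acceptance script use 512×512 scenes at the
study's pitch and wavelength with `pad_factor=1` and 200 GS iterations
(about 6 s per scene on one CPU core), 20 seeded scenes per property,
and one full-sensor 3840×2160 reconstruction to demonstrate
feasibility at acquisition scale.  All randomness flows through
explicit seeds; reruns are bit-identical.  Reconstruction is done in
complex double precision; the final amplitude is bounded by the clip
level by construction.

## Known limitations

* Quasi-plane-wave illumination only; spherical-wave (fringe-
  magnification) geometries and partial coherence are out of scope.
* Single-plane reconstruction; no multi-focus volumetric stacks.
* The retrieved phase φ̃ is produced but not further analysed.
* Evaluator behaviour is reduced to a confusion matrix; no perceptual
  model of how image quality maps to misclassification.
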