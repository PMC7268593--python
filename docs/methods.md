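# Methods

This note records the models implemented in spherepipe, the numerical
choices behind them, what the synthetic data generator does and does
not emulate, and the known limitations.

## Physical model

A transparent sphere of radius *r* and refractive index *n* immersed in
a medium of index *n*<sub>med</sub> imposes an optical phase delay on a
plane wave of vacuum wavelength λ.  Two forward models predict the
in-focus phase image:

**Projection approximation.** Straight-ray optics:
φ(ρ) = (2π/λ)(n − n_med)·2√(r² − ρ²) for lateral distance ρ ≤ r, zero
outside.  Peak phase (4π/λ)(n − n_med)r; phase integral
(2π/λ)(n − n_med)(4/3)πr³.  Valid when diffraction within the object is
negligible — small spheres, low contrast, coarse resolution.

**Rytov approximation.** The first-order (Born) scattered field is
computed through the Fourier diffraction theorem: the 3-D transform of
the scattering potential f = k²_med·χ with χ = (n/n_med)² − 1 over a
ball has the closed form F(q) = k²_med·χ·4π(sin qR − qR·cos qR)/q³,
which is sampled on the Ewald sphere (kx, ky, k_z − k_med) with
k_z = √(k²_med − k²_x − k²_y), weighted by i/(2k_z), propagated to the
plane through the sphere centre and inverse transformed.  Evanescent
components (k²_x + k²_y > k²_med) are zeroed.  The result is used as
the complex Rytov exponent ψ = u_B/u_0: phase = Im ψ, amplitude =
exp(Re ψ).  Fields are computed on a 2× zero-padded grid and cropped,
suppressing periodic wrap-around.

In the weak-contrast limit the Rytov phase converges to the projection
phase over the sphere interior.  At the rim the two models differ at
*any* contrast — the Rytov field is band-limited to k_⊥ < k_med and
carries the Ewald-sphere curvature, both effects linear in contrast —
so convergence statements (and the corresponding tests) are evaluated
over ρ ≤ 0.8 r.  A second consequence of the formulation is that the
Rytov peak phase is mildly *superlinear* in Δn (χ ≈ 2Δn/n_med +
(Δn/n_med)²), about +1.1% relative to projection at Δn = 0.03.

**Validation oracle.** The Fourier route is cross-checked against a
brute-force direct-space quadrature of the Born integral: the sphere is
voxelised (rim voxels carry subsampled fractional occupancy) and the
free-space Green's function e^{ikR}/(4πR) is summed voxel by voxel.
Because the integrand is singular on any plane crossing the sphere, the
comparison plane lies outside it (z = r + 3 µm); for in-focus reference
images the exterior field is back-propagated with the exact
angular-spectrum factor.  At 64³ voxels with 3³ occupancy subsampling
the two routes agree to 0.9% of the field peak.  Full Mie (vector
spherical harmonics) simulation is intentionally out of scope; the
Born quadrature is the independent reference used in this repository.

## Fitting

`SphereModel.fit()` minimises Σ(φ_model − φ_data)² over
(n, r, cx, cy, phase_offset) with `scipy.optimize.least_squares`
(trust-region reflective), bounds n ∈ [n_med − 0.05, n_med + 0.30],
r ∈ [0.3, 3]·r_init, centre inside the ROI, free offset;
termination at relative cost improvement < 1e-9 (configurable) or 250
model evaluations per parameter.  Model images are rendered on a 2×
supersampled grid and bin-averaged: without rim anti-aliasing the
sub-pixel rim dominates the radius bias.  The phase offset is a fitted
nuisance parameter because residual offsets survive polynomial
background correction in real data.

Initial values come from an edge estimator: Canny edge detection
(σ = 2 px) on the phase, an algebraic (Kasa) circle fit to the edge
pixels, and the projection disk-average identity
⟨φ⟩ = (2π/λ)(n − n_med)(4r/3) for the index.  The gradient maximum of
a smoothed chord profile sits systematically inside the true rim; a
fixed +1.6 px radius correction (measured once on noiseless phantoms,
stable over r = 3–7 µm) removes that bias.  Edges within 6 px of the
frame border are ignored (filtering artifacts concentrate there).  On
noiseless phantoms the estimator alone recovers r to < 0.2% and n to
< 1e-4; under 0.02 rad noise it remains a reliable initialiser.

**rytov-sc.** Fitting the Rytov forward model leaves a small systematic
bias in (n, r).  The correction is affine in the fitted contrast
x = n/n_med − 1: x_sc = c_n0 + c_n1·x, r_sc = r·(c_r0 + c_r1·x).  The
packaged default coefficients are produced by the in-repo calibration
harness (`spherepipe.calib`): reference images from the direct-space
Born oracle over x ∈ {0.005…0.05}, r ∈ {2, 4.5, 7} µm are fitted with
the FFT-route Rytov model and the affine map is regressed.  Because the
reference implements the same first-order physics by an independent
numeric route, these defaults are near-identity — they compensate the
numeric bias of the fitting pipeline, not the Rytov-vs-exact-scattering
physics bias.  Coefficients calibrated against an exact scattering
reference can be supplied per run (`[sphere] rytov_sc_coeffs`).

## Hologram reconstruction

The sideband is the argmax of the spectral magnitude over the
half-plane k_y ≥ 0 (DC disk of radius max(3, N/20) bins excluded), with
3×3 centroid refinement.  Since the centroid is only bin-accurate,
auto-detected carriers are refined after demodulation by the median
wrapped phase gradient — a residual-tilt estimate robust to a localized
object.  Filters are defined relative to the carrier distance
(R = size_rel·|k|, default 1/3, the largest radius that cannot overlap
DC at three-radius separation): hard disk, disk smoothed with a
Gaussian of σ = R/10 (default: ringing-free and spectrally unbiased),
Gaussian with half weight at R, square.  The phase sign convention
makes optically denser objects positive; `[holo] invert_phase` flips it
for setups with the opposite sideband geometry.  Unwrapping uses the
reliability-sorting algorithm (scikit-image); results are
offset-normalised so the border-frame median lies in (−π, π].

## Background correction

Masks are a border frame, a below-threshold rule, or their
intersection.  Surfaces (offset / tilt / poly2o) are least-squares fits
on coordinates scaled to [−1, 1] per axis — raw pixel coordinates make
the quadratic normal equations ill-conditioned at megapixel scale.
Phase surfaces are subtracted; amplitude backgrounds are fitted as an
offset and divided out.  Whole-sensor correction (default: tilt over a
5 px border) runs before object detection; per-ROI correction (default:
poly2o over a border of 10% of the ROI size, overridable, e.g. 35 px
for the nucleus profile) runs on each crop.

## Object detection

Components are 4-connected with holes filled before area measurement —
bright internal structure (nucleoli) must not split or shrink an
object.  The equivalent diameter 2√(area/π) is compared with the
configured specimen size (`[roi] size_um`, converted via the pixel
size) within a relative `size_variation` band, boundaries inclusive.
Two pragmatic rules beyond that contract: kept boxes are grown to at
least the stated specimen size before padding (a high threshold may
segment only the top of a dim object, and a too-tight crop lets the
background fit swallow it), and components within 5 px of the frame
border are discarded (partially imaged; reconstruction artifacts).
ROI indices are assigned in (row, column) order and never renumbered
after exclusion-list filtering, so identifiers remain stable across
reruns — the exclusion workflow depends on that.

The `dm-nuclei` threshold t = mean + 0.2·(max_trimmed − mean) discards
the top 1% of pixel values *by count* before taking the maximum; this
reproduces the defining enumeration (99×0.0 + 1×10.0 → t = 0.08)
exactly, which percentile interpolation would not.  The rule assumes
the objects of interest dominate the upper tail; on nearly empty
fields it degrades towards the noise floor (a limitation shared with
its original use), which the size filter and ignore lists absorb.

## Dry mass

The Barer relation n = n_med + α·c links refractive index excess to
dry-matter concentration.  Defaults use α = 0.18 mL/g, the conventional
protein value; every exported table records the α used.  The two
routes — (4/3)πr³(n − n_med)/α from the fit and λ·px²·Σφ/(2πα) from the
integrated phase — agree to discretisation error on exact projection
phantoms (0.004% at 0.05 µm sampling).

## Synthetic data

The generator emulates: projection- or Rytov-model spheres (radii
2–7 µm, indices 1.34–1.38, aqueous medium n_med = 1.335, λ = 550 nm,
0.107 µm pixels — the cell-nucleus regime), quadratic phase
backgrounds, off-axis carrier fringes (default (2.2, 1.5) rad/px,
period ≈ 2.4 px as in typical off-axis setups; a coarser carrier
narrows the sideband filter into a lowpass that visibly biases fits),
fringe-contrast scaling, and seeded Gaussian noise — the single source
of randomness.  It does **not** emulate fixed-pattern camera noise,
vignetting, aberrations beyond polynomial backgrounds, defocus,
object asphericity or internal structure.  Passing tests therefore
demonstrate correctness of the reconstruction-detection-fitting chain
under the stated optical model, not robustness to every real-world
artifact; the exclusion-list workflow exists precisely for data the
model does not capture.

Test and acceptance problem sizes (5 frames of 700², 15 objects;
20 + 5 phantom fits; one 64³ oracle volume) were chosen as the smallest
ensembles that exercise every code path with stable statistics.

## Pipeline semantics

Each stage writes only into `<input>_dm/`.  Stage caches are keyed by a
hash of the dataset content identifier plus the relevant configuration
sections (convert ← [meta, holo]; roi ← [roi, bg.*]; sphere ←
[sphere]) chained with the upstream stage hash: editing an unrelated
section never invalidates a stage, re-running unchanged reuses outputs,
and two runs from scratch on the same input and configuration produce
byte-identical statistics tables.  Whether an input series contains
holograms or ready phase maps is decided by attempting sideband
detection on the first frame.

## Known limitations

- Single-sphere-per-ROI model: touching or overlapping objects are not
  split (no watershed), and objects are not tracked across frames.
- The Rytov forward model is first-order: at high contrast
  (|n/n_med − 1| ≳ 0.1) its accuracy, and with it the fitted values,
  degrade; the packaged rytov-sc defaults do not correct physics bias
  (see above).
- The proprietary SID4Bio TIF dialect is detected and rejected, not
  decoded.
- Reference-image background correction performs no registration.
- TIF timestamps have 1 s resolution; faster acquisition falls back to
  file times or the configured frame interval.
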