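# Methods

`mechanoscope` implements quantitative micro-elastography by compression
optical coherence elastography (OCE) at optical-coherence-microscopy (OCM)
resolution, together with a forward simulator that generates acquisitions
with known mechanical ground truth. This note records the model, its
assumptions, the parameters that matter, and the numerical choices, so that
results produced by the package can be interpreted and reproduced.

## Mechanical model

A sample slab (hydrogel, optionally containing spheroid-like inclusions) of
thickness `L_s` sits on the imaging window; a pre-characterized compliant
silicone layer of thickness `L_layer` (default 1 mm) sits between the sample
and a piezo actuator that applies a quasi-static bulk displacement δ per
load step. Depth `z` is measured from the window; the window is fixed, so
axial displacement `u_z(0) = 0` and compressive displacement (toward the
window) is positive, as are compressive strain and stress.

The model is uniaxial stress with mechanically independent A-line columns:
within each lateral position (x, y) the stress σ is constant along z and
satisfies the series-compliance balance

    ε_layer(σ) · L_layer + Σ_i (σ / E_i) · h_i = δ,

where `ε_layer = f⁻¹(σ)` inverts the layer's monotone stress–strain curve
`σ = f(ε)` and the sum runs over the sample voxels of the column (heights
`h_i`, Young's moduli `E_i`). Strain is `ε = σ / E` per sample voxel and
displacement is the cumulative axial integral of strain from the window.
The simulator solves the balance by vectorized bisection **on the layer
strain**, so only the forward interpolant `f` is evaluated and the solved
state is exactly consistent with what the estimator assumes; 90 bisection
steps put the residual at machine precision.

Assumptions and what they exclude: linear elastic materials (tangent modulus
= Young's modulus), no shear coupling between columns, no viscoelastic or
poroelastic time dependence, no friction at the window, one load step per
acquisition pair. Because the simulator realizes exactly the mechanical
model the reconstruction assumes, recovery is exact up to speckle and shot
noise; the simulator is therefore a test of the *signal chain*, not of
model mismatch (stress non-uniformity around stiff features in a fully coupled
solid is out of scope by design).

## Optical model

Unloaded volumes are fully developed speckle: independent complex circular
Gaussian voxels whose mean intensity is set per material (gel, layer at 2×
gel, inclusions at 1000× gel — cell spheroids backscatter far more strongly
than dilute GelMA, and this contrast is what the structural segmentation
uses). A Gaussian confocal envelope of FWHM 12 µm (amplitude, centered at
the focal depth) models the shallow depth of field of the high-NA objective;
rendering without a focal depth omits the envelope (an idealized acquisition
used for the homogeneous-phantom experiments). The loaded volume is the
unloaded speckle advanced by the double-pass phase

    Δφ = 4π · n · u_z / λ₀        (λ₀ = 800 nm, n = 1.35 by default)

plus independent additive complex noise at a configured noise floor; the
configured SNR is the gel speckle intensity over the noise power (20 dB in
the standard conditions). A wrap-hazard flag is recorded when |Δφ| ≥ π
anywhere. The refractive index of hydrogel is taken as 1.35 (≈ water);
it is configurable, and the phase-to-displacement constant scales linearly
with it.

## Reconstruction chain

1. **Phase difference.** Kasai-style estimator: the wrapped phase of the
   box-kernel-averaged conjugate product `loaded · conj(unloaded)`. The
   default kernel is lateral-only, 3 × 3 × 0 µm. An axial kernel extent is
   deliberately avoided: under the confocal envelope the amplitude-weighted
   phase average shifts each sample's effective depth toward the focus,
   which biases the subsequent slope estimate by tens of percent near the
   edges of the focal slab. The kernel-averaged intensity serves as the
   regression weight (linear scale; weighted least squares is invariant to
   its normalization, so no noise calibration is needed for weighting).
2. **Displacement.** `u_z = λ₀ Δφ / (4π n)` in nm. By default no phase
   unwrapping is performed and the actuation must keep |Δφ| < π; an optional
   axial unwrap pass supports larger actuations. Voxels whose averaged
   intensity sits less than 6 dB above the calibrated noise power carry no
   displacement information (out of focus) and get weight zero.
3. **Strain.** Lateral Gaussian smoothing of `u_z` (FWHM 5 µm), then the
   weighted least-squares slope of `u_z` versus physical depth over an
   axial window of 15 µm (implemented as vectorized moving window sums with
   zero padding, so edge windows simply use fewer points). The smoothing is
   an unweighted Gaussian: intensity-weighted smoothing would make the
   lateral mixing proportions fluctuate with depth and convert lateral
   displacement gradients (e.g. across the stress shadow of an inclusion)
   into spurious axial slopes. When the phase was unwrapped, the smoothing
   is applied to the strain *after* the per-column regression instead —
   the two orders are mathematically identical for linear operators, but
   unwrapping leaves arbitrary per-column 2π offsets that slopes ignore and
   lateral averages of `u_z` do not.
4. **Stress.** The layer–sample interface is located per column at the
   maximum axial intensity-gradient magnitude within a configured search
   band (the volume is 3-D-smoothed first; raw speckle fluctuates by 100%
   per voxel). A configured interface depth can override detection — the
   sample thickness is a designed experimental input, and under the confocal
   envelope the envelope's own intensity gradient can exceed the material
   step unless a focal plane sits at the interface. Layer strain is
   weight-averaged over the band `[interface + 10 µm, interface + 55 µm]`
   on the layer side; the 10 µm gap exceeds half the regression window so
   that no band voxel's window straddles the interface. The band mean is
   pushed through the calibration `σ = f(ε̄)` to give one stress value per
   A-line, mapped onto the interface.
5. **Young's modulus.** `E = σ / ε` per sample voxel (tangent modulus under
   the uniaxial-stress assumption). Voxels with strain at or below the
   strain floor (default 10⁻⁴, preventing unbounded moduli from noise-level
   strain) or within half a regression window of the interface are masked
   invalid rather than raising.

**Elasticity resolution.** The modulus-map resolution is the convolution of
Gaussian-equivalent optical and processing responses, i.e. FWHMs added in
quadrature per axis: with OCM resolution (0.5, 0.5, 1.4) µm, lateral
smoothing 5 µm and axial window 15 µm this gives ≈ 5.0 × 5.0 × 15.1 µm³.
The 5 µm / 15 µm processing defaults were chosen so this convolution lands
on the instrument-class 5 × 5 × 15 µm³ figure; both are configurable.

## Dynamic-focusing fusion

Multiple volumes acquired at focal depths stepped by 10 µm are blended with
axial Gaussian weights centered at each volume's focal plane (weight FWHM
12 µm by default, matching the depth-of-field envelope), normalized to sum
to one per voxel so constant fields — and kPa units — survive fusion.
Invalid voxels contribute zero weight. Voxels inside a focal-depth gap wider
than the weight FWHM are flagged (their value is an interpolation across a
coverage hole). Known axial offsets between volumes are removed by linear
interpolation before fusion (exact on affine profiles, monotone and
bounded).

Every focal acquisition repeats the same quasi-static load, but only
acquisitions focused near the compliant layer can see layer strain through
the envelope; the pipeline therefore estimates one stress map from the
acquisition focused closest to the layer band and applies it to every
volume's strain before fusing the moduli. The multi-focal configurations
used in the examples include one acquisition focused a few µm beyond the
interface for exactly this purpose.

## Segmentation and regional statistics

The spheroid is segmented from a structural volume (fused linear-scale
intensity, pre-smoothed with a 5 × 5 × 10 µm FWHM Gaussian to suppress
speckle and the residual between-focal-plane envelope ripple): min–max
normalization, threshold 0.5, largest 26-connected component, enclosed
holes filled. Min–max normalization makes the mask invariant to affine
intensity rescaling. Edge smoothing retains a pixel iff ≥ 95% of its
20 × 20-pixel neighborhood (40 × 40 µm² at 2 µm pitch) lies in the mask,
computed by exact integer window counting.

The core/periphery split is a deterministic formalization of a partly
manual procedure: per en-face plane, each mask pixel's radius r from the
(uniformly weighted) 3-D centroid is normalized by the boundary distance
R(θ) of the edge-smoothed mask along its ray, and the pixel is core iff
r ≤ core_fraction · R(θ) (default 0.5, i.e. the core is ~50% of the local
diameter). R(θ) is corrected for the known recession of the coverage
smoother — a straight edge recedes by (0.95 − 0.5) · 20 = 9 px — so that an
ideal disc of radius 40 px yields a core of radius 20 px; without the
correction the smoothing would shrink the core by nearly half. Pixels
inside the original mask but outside the smoothed mask (protrusions,
boundary fuzz) are always periphery. Regional statistics (mean ± sample SD,
voxel counts) are taken over valid modulus voxels at the en-face plane at
the centroid's z (optionally ± 1 plane).

Group comparisons use a pooled-variance two-sample Student t-test (Welch
available behind a flag), two-sided, with significance tiers at 0.05 / 0.01
/ 0.001; boxplot summaries use linear-interpolation quantiles and min/max
whiskers. Comparison tables average per-spheroid means (never pooled
voxels) and report mean ± sample SD across spheroids.

## Standard simulated conditions

The recovery experiments use the conditions the validation targets state:
homogeneous phantoms at 7 kPa (stiff) and 2 kPa (soft) on 64 × 64 × 256
grids at (2, 2, 1.8) µm pitch with a 400 µm sample under a 1 mm linear
20 kPa layer at 20 dB SNR, actuated by δ = 0.15 µm — small enough that
|Δφ| < π over the whole imaged depth for both moduli, so the default
no-unwrap path applies; and one spheroid phantom (radius 60 µm, core
fraction 0.5, core 9.85 kPa / periphery 24.5 kPa in 7 kPa background, a
96 × 96 × 256 grid) imaged with dynamic focusing (focal depths every 10 µm
across the spheroid plus one at 408 µm for the layer band). Because the
24.5 kPa periphery strains 3.5× less than the gel, a no-wrap actuation
would put its strain at the 10⁻⁴ floor; the spheroid run therefore uses
δ = 1.0 µm with the axial unwrap pass enabled, and the interface depth is
supplied from the designed sample thickness (400 µm).

## What the simulator does and does not emulate

Emulated: fully developed speckle with per-material backscatter contrast,
additive detection noise at a configured SNR, the confocal depth-of-field
envelope, double-pass phase encoding of axial displacement, wrap hazards,
stepped-focus acquisition, and exactly the series-compliance mechanics the
estimator assumes.

Not emulated: axial PSF correlation between voxels (each voxel is an
independent speckle draw), attenuation and shadowing with depth, lateral or
shear displacement, mechanical coupling between columns (so no stress
concentration around stiff features), viscoelastic creep, sample drift
between focal acquisitions, and phase decorrelation under load. Passing
recovery tests therefore demonstrates the correctness and noise behavior of
the signal chain under the stated model, not robustness to model mismatch
in real tissue.

## Numerical choices and degenerate inputs

- WLS slope via moving sums of (w, wz, wu, wz², wzu); the normal-equation
  denominator is guarded by a scale-aware cutoff, and all-zero-weight
  windows are invalid, not errors.
- Layer calibration is a monotone piecewise-cubic (PCHIP) interpolant
  anchored exactly at (0, 0); non-monotone samples are rejected. Its
  inverse is itself an interpolant — exact at the knots, interpolation-
  accurate between them — and is not used by the simulator (see above).
- Zero bulk displacement yields exactly zero stress/strain/displacement.
- Constant structural volumes are a segmentation error; empty masks have no
  centroid; a centroid voxel outside the mask is an error for the split.
- Even-size smoothing kernels follow scipy's anchoring (window
  [i − k/2, i + k/2 − 1]); coverage thresholds compare exact integer counts.
- Seeding: every stochastic routine takes an explicit seed; stacked
  acquisitions draw per-volume seeds from a `SeedSequence` of the phantom
  seed, and identical spec + seed reproduce volumes bit-for-bit.

## Known limitations

- The stress map inherits the lateral resolution of the strain estimator;
  across sharp lateral stiffness transitions the per-column stress is a
  smoothed version of the true column stress (a few percent locally).
- Under dynamic focusing, regions between focal planes are reconstructed at
  reduced SNR (envelope ripple of a few dB); fusion weights mitigate but do
  not remove this.
- The core/periphery ray rule assumes a star-shaped (ray-convex) mask about
  the centroid; strongly concave spheroids would need a geodesic rule.
- Regional means carry a small negative bias for thin stiff shells: labeling
  and resolution blur mix some core and background voxels into the periphery
  (≈ 5% for the standard spheroid conditions, within the stated tolerance).
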