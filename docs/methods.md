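# Methods

## Scope and model

`dfcc` measures spatially coherent motion in a densely labelled nucleus.
The observable is a dense displacement field between frame pairs; the
statistic is the spatial autocorrelation of that field's direction and
magnitude as a function of the scalar space lag ρ; the model fitted to
those curves is the isotropic Whittle–Matérn correlation

r(ρ) = 2^(1−ν)/Γ(ν) · (ρ/ρ_c)^ν · K_ν(ρ/ρ_c),

with correlation length ρ_c and smoothness ν (ν = ½ ⇔ exp(−ρ/ρ_c); as
ν → ∞ the model approaches a Gaussian with effective length √(2ν)·ρ_c).
The underlying assumptions are: motion within a frame interval is small
(sub-pixel to ~1 px), image brightness is approximately conserved between
frames, and the flow statistics are spatially stationary and isotropic
inside the analysed region.

## Preprocessing

Intensities are min–max normalized to [0, 1] per sequence (not per frame),
so the bilateral filter's σ_intensity = 0.3 and the Horn–Schunck α operate
on a fixed, unitless scale. The bilateral filter is single-pass with
weights = spatial Gaussian (σ_space = 5 px) × intensity-difference Gaussian
(σ_intensity = 0.3) over a 5 px window, reflect-padded; it smooths inside
structures while keeping edges, and a constant image is a fixed point.

Lateral drift is measured on the denoised frames by subpixel phase
correlation of every frame against frame 1 (upsampled ×100, i.e. 0.01 px
resolution); the summary statistic is the **maximum** drift magnitude over
frames, converted to nm through the pixel size. A recording is rejected
iff that maximum strictly exceeds 10 nm; exactly 10 nm is accepted.
Uniform (zero-variance) frames cannot be registered and are flagged rather
than assigned an arbitrary shift. Note that genuinely coherent motion of
the whole nucleus is indistinguishable from stage drift by a rigid
registration — the QC deliberately errs on the side of exclusion.

## Optical flow

Horn–Schunck flow minimizes a brightness-constancy data term plus
α²·‖∇u‖² + α²·‖∇v‖² smoothness. The solver is coarse-to-fine: 3 pyramid
levels (factor 0.5), 5 warping steps per level, and up to 100 Jacobi
iterations per warp on the linearized increment, with derivatives taken as
central differences averaged over the frame pair and warping by bilinear
interpolation with edge clamping. After every warping step both flow
components are median-filtered (radius 2 px by default), which removes
linearization outliers and never increases the maximum displacement.
Defaults (α = 1.0 on [0, 1] intensities) favour smooth, low-noise fields
for real recordings.

For validation studies on synthetic data the package uses a deliberately
weak prior (α = 0.25, median radius 1, `dfcc.validation`): the smoothness
term is itself a spatial low-pass filter on the flow, and with a strong
prior the measured flow correlation reflects the prior as much as the
data. The uncorrelated scenario quantifies this floor — it yields a fitted
correlation length of ~1.5 px, which is the estimator's own footprint, and
any claimed coherence must sit well above it.

## Spatial correlation

Directions are circular: γ = atan2(v, u) on (−π, π], undefined (masked)
where u = v = 0. Angles enter the correlation as unit complex numbers
e^{iγ}; the autocorrelation at lag (Δx, Δy) is computed by FFT (transform,
multiply by the conjugate, inverse transform) and its real part equals the
mean of cos(γ(x, y) − γ(x+Δx, y+Δy)) over valid pixel pairs. This makes
the angle difference between two vectors near the negative x-axis 2ε
rather than 2π − 2ε. The magnitude field uses the analogous Pearson-style
correlation: mean-subtracted, normalized by the population variance over
valid pixels. No resultant-vector subtraction is applied to the direction
correlation (the statistic is the raw mean cosine); zero-variance
magnitude fields are flagged as having no defined correlation.

Two numerical choices matter. The correlation is **linear, not circular**:
fields are zero-padded before the FFT and every lag is renormalized by the
exact number of valid pairs, so opposite edges of the nucleus are never
wrapped onto each other. And the 2D surface is symmetrized exactly
(r(Δ) = r(−Δ)) against FFT round-off. The FFT path is tested to 1e-10
against an exhaustive double loop over all pixel pairs.

The radial projection assigns each lag to the bin whose centre k·(bin
width) is nearest to ρ = √(Δx²+Δy²) (default width 1 px), with bin values
the pair-count-weighted mean; curves are reported out to half the smaller
field dimension. When several frame pairs contribute to one time lag,
their 2D surfaces are pooled with pair-count weights before projection.

## Whittle–Matérn fitting

The model is evaluated in log space, log r = (1−ν)ln2 − lnΓ(ν) + ν ln x +
ln K_ν(x), using the exponentially scaled Bessel function, so large ν
neither overflows Γ nor underflows x^ν. Fitting is weighted nonlinear
least squares (trust-region reflective) on (ρ_c, ν) with bounds
ρ_c ∈ (0, 10·ρ_max], ν ∈ (0.01, 50], multi-start over ν₀ ∈ {0.5, 1, 2},
ρ_c initialized at the curve's 1/e crossing. The ρ = 0 bin (trivially 1)
and bins with fewer than 100 pairs are excluded; weights default to pair
counts. Non-convergence is reported per curve without aborting the table.

ρ_c and ν are strongly coupled: at small ν the model decays steeply well
before ρ_c, so the same practical range corresponds to a much larger ρ_c
than at large ν. `MaternFit.effective_range()` (the 1/e decay distance of
the fitted model) is the reparametrization-invariant range measure and is
what should be compared across fits with different ν — the Hurst-sweep
test uses it for exactly this reason.

## Simulator

The generator reproduces the validation conditions: flow fields on a
100×100 grid, magnitudes Normal(0.5, 0.05) px truncated at zero (a 10σ
event at these parameters, handled by resampling), directions uniform on
[0, 2π). Spatially correlated scenarios come from random fields:

* **Fractal (Hurst) fields** — spectral synthesis with power-law density
  S(k) ∝ |k|^−(2H+2), DC removed, standardized exactly to mean 0 and
  variance 1. H ∈ (0, 1) tunes the correlation range (these fields are
  scale-free, so the range is set by the window, not by a parameter).
  Scalars map to directions rank-preservingly via γ = 2πΦ(z) (marginally
  uniform) and to magnitudes via m = mean + sd·z.
* **Matérn-targeted fields** — when a target ρ_c is requested, a Gaussian
  field with Matérn(ρ_c, ν) correlation is synthesized by circulant
  embedding on the torus (negative spectral components clipped; the field
  is normalized by its exact ensemble variance rather than per-realization
  sample moments, which would bias long-range correlation downward on
  windows comparable to ρ_c). Correlated **directions** are the phase
  γ = atan2(z₂, z₁) of two i.i.d. such fields whose correlation is
  pre-distorted by the inverse of the exact circular transfer
  g(c) = (π/4)·c·₂F₁(½, ½; 2; c²), so the direction field's measured
  circular correlation matches the requested Matérn curve. The phase
  mapping is used here (rather than 2πΦ(z)) because it is invariant to the
  field's local amplitude, which removes a finite-window bias of the CDF
  mapping of order 0.02 in r on the 100-grid.

Image sequences are a smooth Gaussian-filtered random texture (σ = 2 px)
advected frame-to-frame by backward bilinear warping, I[t+1](x) =
I[t](x − u(x)), plus Gaussian read noise (sd 0.005 on the [0.1, 1]
intensity scale — about 0.5 % of full signal, typical of a well-exposed
sCMOS acquisition). A warning is issued when displacements exceed a third
of the grid. All generators are bit-reproducible from (seed, config).

What the simulator does **not** emulate: photobleaching and blinking,
intensity inhomogeneity and nuclear boundaries (fields are full-frame),
polymer mechanics of chromatin, and temporal persistence of the flow
(successive fields are independent draws). Passing the round trip
therefore demonstrates the estimator chain is unbiased for known
correlated motion under ideal imaging, not that real nuclei satisfy the
model's assumptions.

## Validation study sizes

The end-to-end study pools 10 movies × 15 frame pairs (150 estimated
fields) on the 100-grid for the correlated scenario, reflecting the scale
of a 150-frame recording; a single 100-px window realization of a ρ_c =
10 px field carries large sampling variance (single-field fitted ρ_c
ranges roughly 3–30), and pooling independent pairs is what makes the
25 %-level recovery meaningful. The uncorrelated baseline uses 30 pairs.
Matérn recovery uses 50-bin curves, with 100 replicates at noise sd 0.02.
Optical-flow ground-truth checks run on 100×100 textures.

## Known limitations

* The drift estimate conflates rigid coherent motion with stage drift.
* Horn–Schunck underestimates flow where the image gradient vanishes; the
  smoothness prior fills such regions from their surroundings, which sets
  the short-range correlation floor quantified by the uncorrelated
  scenario.
* The Matérn fit assumes isotropy; anisotropic coherence is averaged out
  by the radial projection.
* Circulant synthesis with spectrum clipping slightly attenuates the very
  shortest-lag correlation of targeted fields (≲ 0.01 in r).
* Time lags are analysed independently; no joint space–time covariance is
  modelled.
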