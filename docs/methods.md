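# Methods

This note documents the model, the numerical choices, and what the test
fixtures do and do not establish.

## Image formation and enhancement

**Degradation model.**  Total irradiance is treated as the sum of a direct
component, a forward-scattered component, and backscatter.  The direct
component decays as `exp(-c·d)` with attenuation coefficient `c`
[1/distance] and path length `d`.  Forward scatter is modelled as a
Gaussian-blurred copy of the direct component: a fraction
`w_eff = w_f·(1 − exp(-c·d))` of direct light is diverted through a blur of
width `forward_blur` (default σ = 2 px), so that a zero path length leaves
the image untouched and a uniform scene attenuates exactly by Beer–Lambert.
This convex-blend form was chosen over naively *adding* a blurred copy,
which would brighten the image at `d = 0` and violate energy accounting.
Backscatter adds a uniform veil `b` (default 0.3) and marine snow replaces
a seeded random pixel fraction with bright speckle; defaults respect the
empirical magnitude ordering backscatter/snow > forward scatter >
attenuation.  The simulator is pixelwise monotone in its input and
bit-deterministic given the seed.

**Enhancement.**  The image is modelled as illumination × reflectance;
taking logs makes the product additive, with illumination concentrated at
low spatial frequencies.  The log image is decomposed with a nearly
symmetric orthogonal wavelet (`sym8`, periodised, default J = 3 levels) and
each detail subband at level j is multiplied by the high-emphasis gain

    H(j, ω_h, ω_l) = (r_h − r_l) / (1 + (k_c·c / (√(ω_h²+ω_l²)·2^j))^{2n}) + r_l

evaluated at the subband's centre frequency (ω̄_h, ω̄_l) ∈ {0, 2^{−j−1}}²
cycles/pixel; the level-J approximation band is multiplied by `r_l`.
Defaults: r_h = 2, r_l = 0.5, k_c = 1, n = 1.  The sharpening constant is
c = 0.5: with this subband mapping the radial argument `√(ω²)·2^j` equals
1/2 for single-axis detail bands at *every* level, so the cutoff must sit
at or below 1/2 for the filter to amplify detail relative to the
approximation band (c = 0.5 puts single-axis bands exactly at the half-gain
point, gain 1.25, and diagonal bands at 1.5).  A larger c would attenuate
every detail band and the filter would smooth rather than sharpen.

Optional denoising applies the interscale bivariate shrinkage rule
`ŵ = (√(w1²+w2²) − √3·σ_n²/σ_s)₊ / √(w1²+w2²) · w1` to each detail
coefficient with its parent at the next coarser scale (coarsest level:
zero parent).  σ_n defaults to the MAD of the finest diagonal subband
divided by 0.6745; σ_s is a local estimate `√(max(mean₇ₓ₇(w²) − σ_n², 0))`.
Shrinkage runs after the subband gains while σ_n is estimated on the raw
coefficients; the resulting mild overestimate of noise in bands with gain
> 1 errs on the side of stronger denoising and is intentional.

An offset ε = 10⁻³ is added before the log (and the final min–max rescale
to [0, 1] absorbs it, since min–max rescaling is invariant to additive
constants — which is also why the unit-gain configuration is an exact
identity up to wavelet reconstruction error).  Constant images are returned
unchanged.  Colour input is converted to YCbCr (BT.601); only luma is
processed, chroma passes through.

**Contrast metric.**  Enhancement quality is quantified by mean-normalised
RMS contrast σ(I)/μ(I).  Plain σ(I) is unsuitable here: homomorphic
filtering deliberately removes smooth illumination gradients, which
*lowers* global σ while making reflectance detail more visible.

## Patch pipeline

Images are cropped by m = 16 px per side (boundary effects), pre-whitened,
and tiled into non-overlapping p×p patches (p = 16, d = 256), vectorised
column-major.  Trailing rows/columns that do not fill a tile are dropped.
The pre-whitening filter is W(f) = f·exp(−(f/f₀)⁴) with f₀ = 0.8 × Nyquist
(0.4 cycles/pixel): natural-image spectra fall as 1/f, so multiplying by f
flattens the mid-band spectrum while the quartic-exponential rolloff
suppresses corner frequencies; each image is then normalised to zero mean,
unit variance.  Non-overlapping tiling (stride = p) is the intended
reading of the patch-count bookkeeping n = N·D/d; a stride parameter
exists for experimentation.

## Whitening and ICA

Covariance uses the 1/n convention, C = X̄X̄ᵀ/n, so that Z = VX̄ has unit
component variances in the ordinary sense.  q defaults to the smallest
dimension capturing 95 % of variance; an explicit integer is accepted.
Eigenvalues are floored at 10⁻¹⁰·λ_max and each eigenvector's
largest-magnitude entry is made positive, fixing the decomposition's sign
indeterminacy for reproducibility.

FastICA uses the tanh contrast, deflation with Gram–Schmidt, convergence
when |⟨b(t+1), b(t)⟩| > 1 − 10⁻⁶, at most T = 200 iterations per component
(components that hit the cap keep their last iterate and log a warning —
on near-Gaussian data, e.g. pink-noise patches, many directions have no
preferred fixed point and this is expected, not an error).  Initial
directions are seeded standard-normal draws; a degenerate update or a
vector caught in the span of earlier components triggers a re-draw.  Input
whiteness is validated (max covariance deviation ≤ 0.1).  The basis
A = UΛ^{1/2}B applies the Moore–Penrose pseudo-inverse of V, exact when
q = d; A·S = UUᵀX̄ holds algebraically for any orthogonal B, which the
tests exploit as an exact identity.

## Gaussianisation

The generalized Gaussian is parameterised with density
θ/(2σΓ(1/θ))·exp{−(|s|/σ)^θ}; θ = 1 is Laplace, θ = 2 Gaussian with
σ = √2·std.  Moment matching solves m₁²/m₂ = Γ(2/θ)²/(Γ(1/θ)Γ(3/θ)) for θ
by root bracketing on [0.1, 10] (the ratio is strictly increasing), with
clamping and a warning outside the attainable range, then
σ = m₁·Γ(1/θ)/Γ(2/θ).  The folded cdf is the regularised *lower*
incomplete gamma P(1/θ, (v/σ)^θ) — the only orientation that yields an
increasing cdf.  The activation is Φ⁻¹ of the folded cdf of |s|, clipped
to [ε, 1−ε] with ε = max(10⁻⁶, 1/(2n)) to keep tail samples finite.  An
empirical (histogram) variant uses bins from 0 to the 99.9th percentile of
|s| (1,000 bins by default), linear interpolation of the cumulative
histogram, and the same probit; a histogram with all mass in one bin falls
back to the parametric path.  The parametric path is the default
throughout, and the activation applied at transfer time always uses the
stored parametric fits.

## Hierarchy

Each layer runs center → whiten → ICA → responses → dimension rise
(Vᵀ S, the same V, no refit) → per-dimension GGD fit and activation; the
d×n output feeds the next layer.  Patch geometry is constant across
layers — layers beyond the first operate purely on the d×n matrices, with
no re-tiling or spatial pooling.  Per-layer seeds derive deterministically
from the run seed via `SeedSequence(seed, spawn_key=(layer,))`, making a
full train + apply bit-reproducible.  At apply time, centering uses the
*training* mean, so transfer is a pure linear map; test images are
pre-whitened by default to mirror training (a flag disables it).

**Activation maps.**  The per-patch q-vector of responses is placed on the
⌊(H−2m)/p⌋ × ⌊(W−2m)/p⌋ tile grid; the default aggregate view is the
per-tile L2 norm (single components on request), rendered with a
red-max/blue-min colormap in the CLI.

**Gabor-likeness metric.**  A basis column (reshaped to p×p, mean removed)
counts as an oriented bandpass feature when more than half of its non-DC
spectral power lies inside a wedge of ±30° around the peak orientation and
within one octave ([f_pk/2, 2·f_pk]) of the peak radial frequency.  The
metric is validated on positive controls (true Gabor atoms) and negative
controls (white-noise columns).

## Synthetic data

The generators define the study conditions: ten 512² training images with
p = 16, m = 16 (9,000 patches of dimension 256) mirror the reference
training geometry.  Sparse-Gabor scenes superpose k = 800 atoms from a
64-atom dictionary (4 scales with wavelengths 4–13 px × 8 orientations × 2
phases, unit-L2, fitting inside a 16×16 patch) at seeded random positions
with Laplace amplitudes and a σ = 0.02 Gaussian noise floor — k chosen so
mean atom coverage is about one per pixel, sparse but not empty.  ICA test
mixtures use unit-scale GGD sources (Laplace by default; Gaussian sources
are flagged as non-identifiable) and seeded random orthogonal mixing.
Underwater scenes composite Gabor structure, pink noise and a smooth
illumination field into [0.05, 0.95] before degradation, so the degraded
image never starts at the log-offset floor.

What passing these tests shows — and does not.  The fixtures exercise the
*assumed* statistics (1/f spectra, sparse oriented structure, GGD
marginals, the additive degradation model).  Real underwater footage adds
wavelength-dependent attenuation, spatially varying backscatter, sensor
noise and motion blur that the generators do not emulate; recovery scores
and contrast gains measured here bound behaviour under the model's
assumptions only.

## Problem sizes and tolerances

Acceptance-level checks run at: 256×9,000 patches for the whitening
(cov(Z) = I within 10⁻⁸) and reconstruction (relative error within 10⁻⁸)
identities — the ICA iteration cap is reduced to 30 on this near-Gaussian
fixture because the reconstruction identity is independent of convergence;
q = 8, n = 20,000, five seeds for BSS recovery (median Amari < 0.05);
n = 10⁵ for GGD recovery (θ within 10 %, σ within 5 %); n = 5×10⁴ for the
Gaussianisation KS bound (D < 0.02); twenty 256² scenes for the contrast
check; ten 512² images, q = 64 for Gabor-likeness (≥ 60 % of columns);
four 128² images, three layers for the determinism check.  Unit tests use
smaller replicas of the same constructions.

## Known limitations

* No noisy-ICA: the additive noise of the generative model is absorbed by
  PCA truncation, not estimated.
* Deflation only; symmetric (parallel) FastICA is out of scope.
* Enhancement processes luminance only — no colour restoration or
  wavelength-dependent attenuation correction.
* The empirical-activation histogram is not serialised; models saved to
  HDF5 replay the parametric activation.
* The degradation simulator is not a full radiative-transfer renderer (no
  camera geometry or volume scattering function).
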