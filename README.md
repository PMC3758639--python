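# uwica — hierarchical ICA model of early underwater vision

`uwica` implements an efficient-coding model of the first stages of visual
processing, aimed at underwater imagery from AUV/ROV cameras.  It is built
for researchers in computational visual neuroscience and underwater
imaging who want a self-contained, testable pipeline that

* **enhances** degraded underwater images by homomorphic wavelet filtering
  (log-domain high-emphasis gains per subband, optional interscale
  bivariate shrinkage denoising),
* **simulates** underwater degradation with the classical three-component
  irradiance model (direct + forward-scattered + backscatter light, with
  exponential attenuation over the optical path and marine-snow speckle),
* **learns** a hierarchy of independent-component layers from an image
  corpus: 1/f pre-whitening → non-overlapping patch extraction → PCA
  whitening → fixed-point ICA → generalized-Gaussian Gaussianisation,
  recursed layer over layer, and
* **transfers** the learned bases to new images, producing per-layer
  activation maps on the patch grid.

## The model

Each p×p image patch **x** ∈ R^d (d = p²) is modelled as a linear
superposition of basis functions, **x** = **A s**, with statistically
independent, sparse coefficients **s**.  After centering and PCA whitening
**Z** = **V X̄** (with **V** = Λ^(−1/2)Uᵀ), an orthogonal demixing matrix
**B** is estimated by the deflation fixed-point iteration

    b ← E{ z·tanh(bᵀz) } − E{ 1 − tanh²(bᵀz) }·b ,

with Gram–Schmidt orthogonalisation against previously found components —
a negentropy-maximising FastICA.  Responses are **S** = **B**ᵀ**Z** and the
basis is **A** = **U**Λ^(1/2)**B**, so **A S** equals the rank-q PCA
reconstruction of the centered data exactly.

Responses of layer ℓ are lifted back to d dimensions (**S** ← **V**ᵀ**S**),
their signs discarded, and each dimension is Gaussianised through its own
fitted generalized Gaussian marginal

    f(s; σ, θ) ∝ exp{ −(|s|/σ)^θ } ,
    g(|s|) = Φ⁻¹( P(1/θ, (|s|/σ)^θ) ) ,

(P the regularised lower incomplete gamma) to become the input of layer
ℓ+1.  Layer 1 learns Gabor-like oriented bandpass bases (V1-style
receptive fields); deeper layers capture residual texture structure.

Because no public corpus ships with the package, `uwica.synthetic`
generates every statistical structure the pipeline assumes (1/f noise,
sparse Gabor scenes, known-mixing ICA test sets, degraded underwater
scenes), all bit-deterministic given a seed.

## Worked example

```python
import warnings; warnings.simplefilter("ignore", RuntimeWarning)
from uwica import (HierarchicalICA, gen_sparse_gabor, gen_underwater_scene,
                   homomorphic_wavelet_enhance, rms_contrast)

corpus = [gen_sparse_gabor(256, sparsity_k=200, seed=i)[0] for i in range(6)]
model = HierarchicalICA(corpus, n_layers=2, patch_size=16, border_crop=16, q=64)
res = model.fit(seed=7)
print(res.summary())
print(f"layer-1 Gabor-like fraction: {res.bandpass_fraction(1):.2f}")

clean, degraded = gen_underwater_scene(256, seed=3)
enhanced = homomorphic_wavelet_enhance(degraded)
print(f"RMS contrast: degraded {rms_contrast(degraded):.3f} "
      f"-> enhanced {rms_contrast(enhanced):.3f}")
```

prints

```
Hierarchical ICA results
================================================================
layers: 2   patch p=16   crop m=16   prewhiten=True   seed=7
----------------------------------------------------------------
layer     d     q   conv med iters med theta med sigma
    1   256    64  64/64        33     0.654     0.082
    2   256    64  61/64        50     1.753     0.613
================================================================
layer-1 Gabor-like fraction: 0.84
RMS contrast: degraded 0.082 -> enhanced 0.208
```

Reading the output: both layers retain q = 64 of d = 256 dimensions and
(nearly) all fixed-point components converge.  The median fitted shape
parameter θ ≈ 0.65 in layer 1 says the first-layer responses are strongly
sparse (much peakier than a Laplace distribution, θ = 1), while layer 2's
θ ≈ 1.75 shows the Gaussianised hierarchy progressively whitens the
higher-order structure.  84 % of the layer-1 basis columns pass the
oriented-bandpass (Gabor-likeness) test, and enhancement raises the
mean-normalised RMS contrast of the degraded scene about 2.5-fold.

A command-line interface mirrors the library:

```bash
uwica corpus --kind sparse_gabor --n 10 --size 512 --seed 7 --out corpus/
uwica train --corpus corpus/ --layers 3 --p 16 --m 16 --q 64 --seed 7 --out model.h5
uwica apply --model model.h5 --in corpus/sparse_gabor_000.png --out-prefix maps_
uwica basis --model model.h5 --layer 1 --out basis.png
uwica simulate --in clean.png --out degraded.png --c 0.5 --d 2 --b 0.3
uwica enhance --in degraded.png --out enhanced.png
```

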