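"""Seeded generators for every statistical structure the pipeline assumes.

Real training corpora (natural images, AUV footage) are emulated by:

* :func:`gen_pink_noise` — Fourier-synthesised 1/f-amplitude noise, the
  second-order statistics of natural scenes;
* :func:`gen_sparse_gabor` — sparse superpositions of oriented Gabor atoms
  with Laplace amplitudes, the higher-order (sparse, oriented) structure
  under which learned bases should become Gabor-like;
* :func:`gen_ica_mixture` — known-mixing blind-source-separation test sets
  with generalized-Gaussian sources;
* :func:`gen_underwater_scene` — a clean textured scene plus its degraded
  counterpart under the attenuation/backscatter forward model.

:func:`amari_index` scores demixing recovery (0 = perfect up to sign and
permutation).  Every generator is bit-deterministic given its seed.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .gaussianize import sample_ggd
from .imaging import DegradationParams, rescale01, simulate_underwater

__all__ = [
    "gen_pink_noise",
    "gabor_dictionary",
    "gen_sparse_gabor",
    "gen_ica_mixture",
    "amari_index",
    "gen_underwater_scene",
]


def gen_pink_noise(size: int = 512, seed: int = 0) -> np.ndarray:
    """1/f-amplitude Gaussian noise image, zero mean and unit variance.

    Fourier synthesis: white Gaussian spectrum shaped by 1/f (power ∝ 1/f²),
    random phases from the seeded generator, DC removed.
    """
    if size < 64:
        raise ValueError("size must be >= 64")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((size, size))
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.fftfreq(size)[None, :]
    f = np.hypot(fy, fx)
    with np.errstate(divide="ignore"):
        shaping = np.where(f > 0, 1.0 / f, 0.0)
    img = np.real(np.fft.ifft2(np.fft.fft2(white) * shaping))
    img -= img.mean()
    return img / img.std()


def gabor_dictionary(
    n_scales: int = 4, n_orientations: int = 8, n_phases: int = 2
) -> list[np.ndarray]:
    """Gabor atom dictionary: default 4 scales × 8 orientations × 2 phases.

    Each atom is an odd-sized patch, zero-mean and unit-L2; wavelengths span
    4–13 px so atoms fit inside 16×16 analysis patches.
    """
    wavelengths = np.geomspace(4.0, 13.0, n_scales)
    atoms = []
    for lam in wavelengths:
        sigma = 0.5 * lam
        half = int(np.ceil(2 * sigma))
        yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
        for k in range(n_orientations):
            phi = np.pi * k / n_orientations
            xr = xx * np.cos(phi) + yy * np.sin(phi)
            envelope = np.exp(-(xx**2 + yy**2) / (2 * sigma**2))
            for phase in (0.0, np.pi / 2)[:n_phases]:
                atom = envelope * np.cos(2 * np.pi * xr / lam + phase)
                atom -= atom.mean()
                atoms.append(atom / np.linalg.norm(atom))
    return atoms


def gen_sparse_gabor(
    size: int = 512,
    dict_size: int = 64,
    sparsity_k: int = 800,
    seed: int = 0,
    noise_std: float = 0.02,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Sparse superposition of randomly placed Gabor atoms, plus the dictionary.

    ``sparsity_k`` atoms are drawn (with replacement) from the dictionary,
    placed at seeded random positions with Laplace-distributed amplitudes;
    a small Gaussian noise floor is added and the image is min–max rescaled
    to [0, 1].  The ground-truth dictionary is returned for recovery scoring.
    """
    if sparsity_k < 0 or sparsity_k >= size * size // 4:
        raise ValueError("sparsity_k must be in [0, size^2/4)")
    if dict_size not in (64,):
        # dictionary geometry fixed at 4 scales x 8 orientations x 2 phases
        raise ValueError("dict_size must be 64 (4 scales x 8 orientations x 2 phases)")
    rng = np.random.default_rng(seed)
    atoms = gabor_dictionary()
    canvas = np.zeros((size, size))
    for _ in range(sparsity_k):
        atom = atoms[rng.integers(len(atoms))]
        amp = rng.laplace(0.0, 1.0)
        h, w = atom.shape
        r = rng.integers(0, size - h)
        c = rng.integers(0, size - w)
        canvas[r : r + h, c : c + w] += amp * atom
    canvas += noise_std * rng.standard_normal((size, size))
    return rescale01(canvas), atoms


def gen_ica_mixture(
    q: int, n: int, theta_src: float = 1.0, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Known-mixing ICA test set: X = A·S with GGD(1, θ_src) sources.

    Sources are i.i.d. generalized Gaussian rows; the mixing matrix is a
    seeded random orthogonal matrix (QR of a Gaussian matrix).  θ_src = 2
    (Gaussian sources) is flagged with a warning — such mixtures are not
    identifiable by ICA.
    """
    if q < 2:
        raise ValueError("q must be >= 2")
    if n < 100 * q:
        raise ValueError("need n >= 100 q samples")
    if theta_src == 2.0:
        warnings.warn(
            "Gaussian sources (theta_src=2) are not identifiable by ICA",
            RuntimeWarning,
        )
    rng = np.random.default_rng(seed)
    S = np.stack([sample_ggd(n, 1.0, theta_src, rng) for _ in range(q)])
    Q, R = np.linalg.qr(rng.standard_normal((q, q)))
    A = Q * np.sign(np.diag(R))  # unique-sign convention
    return A @ S, A, S


def amari_index(W: np.ndarray, A_true: np.ndarray) -> float:
    """Permutation/sign-invariant demixing error in [0, 1]; 0 = perfect.

    With P = W·A_true:

        1/(2q(q−1)) [ Σ_i (Σ_j |P_ij| / max_k |P_ik| − 1)
                    + Σ_j (Σ_i |P_ij| / max_k |P_kj| − 1) ]
    """
    W = np.asarray(W, dtype=float)
    A_true = np.asarray(A_true, dtype=float)
    if W.shape != A_true.shape or W.shape[0] != W.shape[1]:
        raise ValueError("W and A_true must be square with matching shapes")
    P = np.abs(W @ A_true)
    q = P.shape[0]
    row_max = P.max(axis=1)
    col_max = P.max(axis=0)
    if np.any(row_max == 0) or np.any(col_max == 0):
        raise ValueError("singular product matrix")
    term_rows = (P / row_max[:, None]).sum(axis=1) - 1.0
    term_cols = (P / col_max[None, :]).sum(axis=0) - 1.0
    return float((term_rows.sum() + term_cols.sum()) / (2.0 * q * (q - 1)))


def gen_underwater_scene(
    size: int = 256,
    params: DegradationParams | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """A clean textured scene and its degraded underwater counterpart.

    The clean scene composites sparse Gabor structure, pink noise and a
    smooth illumination field (all seeded), rescaled to [0.05, 0.95]; the
    degraded image applies the forward attenuation/backscatter model.
    """
    if params is None:
        params = DegradationParams()
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=3)
    k = max(1, int(800 * (size / 512) ** 2))
    gabor, _ = gen_sparse_gabor(max(size, 64), sparsity_k=k, seed=int(sub[0]))
    gabor = gabor[:size, :size]
    pink = gen_pink_noise(max(size, 64), seed=int(sub[1]))[:size, :size]
    illum = ndimage.gaussian_filter(
        np.random.default_rng(int(sub[2])).standard_normal((size, size)), size / 4
    )
    clean = rescale01(2.0 * gabor + 0.5 * pink / max(pink.std(), 1e-12)
                      + 1.5 * rescale01(illum))
    clean = 0.05 + 0.9 * clean
    degraded = simulate_underwater(clean, params, seed=seed)
    return clean, degraded
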