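"""Patch extraction and 1/f pre-whitening of training images.

Natural images carry a roughly 1/f amplitude spectrum, so raw pixels are
dominated by second-order (pairwise) correlations.  Before any component
analysis the corpus is pre-whitened with the radially symmetric filter

    W(f) = f * exp(-(f / f0)^4)

which flattens the spectrum up to a smooth low-pass rolloff at ``f0``
(a fraction of the Nyquist frequency), then each image is normalised to
zero mean and unit variance.  Images are cropped by ``m`` pixels per side
to avoid boundary artefacts and tiled into non-overlapping p×p patches,
vectorised column-major into a d×n matrix (d = p²).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PatchMatrix",
    "crop_boundary",
    "prewhiten_image",
    "extract_patches",
    "reassemble_image",
]


@dataclass
class PatchMatrix:
    """d×n matrix of vectorised image patches with tiling geometry.

    ``X[:, k]`` is patch ``k`` flattened in column-major (Fortran) order;
    ``origins[k] = (image_index, row, col)`` is its top-left corner within
    the cropped image.
    """

    X: np.ndarray
    p: int
    origins: list[tuple[int, int, int]] = field(default_factory=list)

    @property
    def d(self) -> int:
        return self.X.shape[0]

    @property
    def n(self) -> int:
        return self.X.shape[1]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (d x n)")
        if self.d != self.p * self.p:
            raise ValueError(f"d={self.d} does not equal p^2={self.p**2}")
        if self.origins and len(self.origins) != self.n:
            raise ValueError("origins length must equal patch count n")


def crop_boundary(image: np.ndarray, m: int) -> np.ndarray:
    """Cut ``m`` pixels off every boundary of the image."""
    image = np.asarray(image, dtype=float)
    if m < 0:
        raise ValueError("m must be >= 0")
    if m == 0:
        return image.copy()
    H, W = image.shape
    if 2 * m >= min(H, W):
        raise ValueError(f"crop m={m} too large for image of size {H}x{W}")
    return image[m : H - m, m : W - m].copy()


def prewhiten_image(image: np.ndarray, f0_fraction: float = 0.8) -> np.ndarray:
    """Flatten the 1/f spectrum of an image and normalise it.

    Multiplies the spectrum by ``W(f) = f exp(-(f/f0)^4)`` with radial
    frequency ``f`` in cycles/pixel and ``f0 = f0_fraction × Nyquist``,
    then shifts/scales the result to zero mean and unit variance.
    """
    image = np.asarray(image, dtype=float)
    if not (0 < f0_fraction <= 1):
        raise ValueError("f0_fraction must lie in (0, 1]")
    if min(image.shape) < 16:
        raise ValueError("image side must be >= 16")
    if image.max() - image.min() < 1e-12:
        raise ValueError("constant image cannot be pre-whitened (zero variance)")
    H, W = image.shape
    fy = np.fft.fftfreq(H)[:, None]
    fx = np.fft.fftfreq(W)[None, :]
    f = np.hypot(fy, fx)
    f0 = f0_fraction * 0.5
    filt = f * np.exp(-((f / f0) ** 4))
    out = np.real(np.fft.ifft2(np.fft.fft2(image) * filt))
    out -= out.mean()
    sd = out.std()
    if sd < 1e-15:
        raise ValueError("degenerate image: zero variance after filtering")
    return out / sd


def extract_patches(
    images: list[np.ndarray] | np.ndarray,
    p: int,
    m: int = 0,
    stride: int | None = None,
) -> PatchMatrix:
    """Tile cropped images into p×p patches and stack them as columns.

    The default stride equals ``p`` (non-overlapping tiling, so that
    n = Σ ⌊(H−2m)/p⌋·⌊(W−2m)/p⌋); trailing rows/columns that do not fill a
    whole tile are dropped.
    """
    if isinstance(images, np.ndarray) and images.ndim == 2:
        images = [images]
    if p < 1:
        raise ValueError("p must be >= 1")
    if stride is None:
        stride = p
    if stride < 1:
        raise ValueError("stride must be >= 1")
    cols: list[np.ndarray] = []
    origins: list[tuple[int, int, int]] = []
    for idx, img in enumerate(images):
        cropped = crop_boundary(np.asarray(img, dtype=float), m)
        H, W = cropped.shape
        if p > min(H, W):
            raise ValueError(f"patch side p={p} exceeds cropped image side")
        for r in range(0, H - p + 1, stride):
            for c in range(0, W - p + 1, stride):
                cols.append(cropped[r : r + p, c : c + p].flatten(order="F"))
                origins.append((idx, r, c))
    if not cols:
        raise ValueError("no patches extracted")
    return PatchMatrix(X=np.stack(cols, axis=1), p=p, origins=origins)


def reassemble_image(
    pm: PatchMatrix, image_index: int = 0, shape: tuple[int, int] | None = None
) -> np.ndarray:
    """Place the tiles of one image back on their grid (inverse of tiling)."""
    sel = [k for k, (i, _, _) in enumerate(pm.origins) if i == image_index]
    if not sel:
        raise ValueError(f"no patches for image index {image_index}")
    p = pm.p
    if shape is None:
        H = max(pm.origins[k][1] for k in sel) + p
        W = max(pm.origins[k][2] for k in sel) + p
        shape = (H, W)
    out = np.zeros(shape)
    for k in sel:
        _, r, c = pm.origins[k]
        out[r : r + p, c : c + p] = pm.X[:, k].reshape(p, p, order="F")
    return out
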