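"""PCA whitening: centering, eigendecomposition, projection, dimension rise.

Patches are centered, the covariance C = X̄X̄ᵀ/n is eigendecomposed
C = UΛUᵀ, and the whitening matrix V = Λ^{-1/2}Uᵀ (q×d) maps centered data
to Z = VX̄ with identity covariance.  After ICA, responses are lifted back
to the ambient dimension with Vᵀ so the next layer sees d×n input again.

The retained dimension ``q`` may be given as an integer or as a variance
fraction in (0, 1) — the smallest q whose eigenvalues capture that share.
Eigenvalues are floored at ``eps_reg × λ_max`` so Λ^{-1/2} stays finite on
near-degenerate patch sets, and each eigenvector's largest-magnitude entry
is made positive for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["WhiteningModel", "center", "fit_whitening", "whiten",
           "rise_dimensionality", "unwhiten"]


@dataclass
class WhiteningModel:
    mean: np.ndarray          # d-vector of training means
    eigvals: np.ndarray       # q descending positive eigenvalues (floored)
    eigvecs: np.ndarray       # d×q orthonormal columns
    q: int
    eps_reg: float = 1e-10

    @property
    def d(self) -> int:
        return self.eigvecs.shape[0]

    @property
    def V(self) -> np.ndarray:
        """q×d whitening matrix Λ^{-1/2} Uᵀ."""
        return (self.eigvecs / np.sqrt(self.eigvals)).T

    def __post_init__(self) -> None:
        if self.eigvecs.shape[1] != self.q or self.eigvals.shape != (self.q,):
            raise ValueError("inconsistent eigenpair shapes")
        if np.any(self.eigvals <= 0):
            raise ValueError("eigenvalues must be strictly positive after flooring")


def center(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Subtract the per-row (per-pixel) mean: X̄ = X − m·1ᵀ."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("X must be d x n with n >= 2")
    mean = X.mean(axis=1)
    return X - mean[:, None], mean


def fit_whitening(
    Xbar: np.ndarray, q: int | float = 0.95, eps_reg: float = 1e-10
) -> WhiteningModel:
    """Eigendecompose the sample covariance of centered data and retain q dims.

    ``q`` may be an explicit integer dimension or a variance fraction in
    (0, 1).  Raises on an identically zero covariance.
    """
    Xbar = np.asarray(Xbar, dtype=float)
    d, n = Xbar.shape
    C = (Xbar @ Xbar.T) / n
    eigvals, eigvecs = np.linalg.eigh(C)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    if eigvals[0] <= 0:
        raise ValueError("covariance is identically zero; cannot whiten")

    if isinstance(q, float) and 0 < q < 1:
        share = np.cumsum(eigvals) / eigvals.sum()
        q_int = int(np.searchsorted(share, q) + 1)
    else:
        q_int = int(q)
        if not (1 <= q_int <= d):
            raise ValueError(f"q={q} out of range [1, {d}]")

    eigvals = np.maximum(eigvals[:q_int], eps_reg * eigvals[0])
    eigvecs = eigvecs[:, :q_int].copy()
    # deterministic sign: largest-magnitude entry of each eigenvector positive
    flip = np.sign(eigvecs[np.argmax(np.abs(eigvecs), axis=0), np.arange(q_int)])
    eigvecs *= np.where(flip == 0, 1.0, flip)
    # note: the mean is not fitted here; callers store it from center()
    return WhiteningModel(mean=np.zeros(d), eigvals=eigvals, eigvecs=eigvecs,
                          q=q_int, eps_reg=eps_reg)


def whiten(Xbar: np.ndarray, model: WhiteningModel) -> np.ndarray:
    """Project centered data to the q-dimensional white space: Z = VX̄."""
    Xbar = np.asarray(Xbar, dtype=float)
    if Xbar.shape[0] != model.d:
        raise ValueError(f"expected {model.d} rows, got {Xbar.shape[0]}")
    return model.V @ Xbar


def rise_dimensionality(S: np.ndarray, model: WhiteningModel) -> np.ndarray:
    """Lift a q×n response matrix back to d×n with the transposed whitener."""
    S = np.asarray(S, dtype=float)
    if S.shape[0] != model.q:
        raise ValueError(f"expected {model.q} rows, got {S.shape[0]}")
    return model.V.T @ S


def unwhiten(Z: np.ndarray, model: WhiteningModel) -> np.ndarray:
    """Map whitened data back to the centered data space: UΛ^{1/2}Z."""
    Z = np.asarray(Z, dtype=float)
    if Z.shape[0] != model.q:
        raise ValueError(f"expected {model.q} rows, got {Z.shape[0]}")
    return (model.eigvecs * np.sqrt(model.eigvals)) @ Z
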