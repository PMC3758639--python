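"""Fixed-point ICA by deflation with Gram–Schmidt orthogonalisation.

Works on whitened data Z (q×n, identity covariance).  Each unmixing
direction b maximises non-Gaussianity of bᵀz — a negentropy proxy — via the
fixed-point iteration

    b  <-  E{ z f(bᵀz) } − E{ f'(bᵀz) } b ,    f = tanh,  f' = 1 − f²

followed by Gram–Schmidt against previously found directions and
renormalisation, until successive iterates align to within tolerance.
The stacked directions form an orthogonal demixing matrix B; responses are
S = BᵀZ and the generative basis is A = UΛ^{1/2}B (the pseudo-inverse of
the whitening matrix applied to B), so that AS reproduces the rank-q PCA
reconstruction of the centered data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .whitening import WhiteningModel

__all__ = [
    "ICALayer",
    "fixed_point_update",
    "gram_schmidt",
    "fastica",
    "compute_basis",
    "responses",
    "reconstruct",
]


@dataclass
class ICALayer:
    """One trained ICA layer: demixing matrix, basis, and marginal models."""

    B: np.ndarray                      # q×q orthogonal demixing matrix
    A: np.ndarray | None = None        # d×q basis (filled from the whitener)
    iters_T: int = 200
    tol: float = 1e-6
    seed: int | None = None
    gauss_params: list = field(default_factory=list)  # per-dimension GGDParams
    n_iter: np.ndarray | None = None   # iterations used per component
    converged: np.ndarray | None = None

    @property
    def q(self) -> int:
        return self.B.shape[0]


def fixed_point_update(b: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """One un-normalised fixed-point step for a unit direction ``b``.

    Returns E{z·tanh(bᵀz)} − E{1 − tanh²(bᵀz)}·b with expectations taken as
    sample means over the columns of Z.
    """
    b = np.asarray(b, dtype=float)
    Z = np.asarray(Z, dtype=float)
    u = b @ Z
    t = np.tanh(u)
    n = Z.shape[1]
    return (Z @ t) / n - np.mean(1.0 - t**2) * b


def gram_schmidt(b: np.ndarray, previous: list[np.ndarray]) -> np.ndarray:
    """Orthogonalise ``b`` against previously found unit vectors and normalise.

    Raises ``ValueError`` when ``b`` lies (numerically) in the span of
    ``previous`` — the caller should restart from a fresh random direction.
    """
    b = np.asarray(b, dtype=float).copy()
    for prev in previous:
        b -= (b @ prev) * prev
    norm = np.linalg.norm(b)
    if norm < 1e-12:
        raise ValueError("vector lies in the span of previous components")
    return b / norm


def fastica(
    Z: np.ndarray,
    iters_T: int = 200,
    tol: float = 1e-6,
    seed: int | None = None,
    check_white: bool = True,
) -> ICALayer:
    """Estimate a full q×q orthogonal demixing matrix by deflation.

    Components are extracted one at a time: random unit start, fixed-point
    updates with Gram–Schmidt re-orthogonalisation, convergence when
    ``|<b(t+1), b(t)>| > 1 − tol``.  Non-convergence after ``iters_T``
    iterations keeps the last iterate and logs a warning.  Deterministic
    given ``seed``.
    """
    Z = np.asarray(Z, dtype=float)
    q, n = Z.shape
    if check_white:
        cov = (Z @ Z.T) / n
        dev = np.max(np.abs(cov - np.eye(q)))
        if dev > 0.1:
            raise ValueError(
                f"input is not white (max covariance deviation {dev:.3f} > 0.1)"
            )
    rng = np.random.default_rng(seed)
    basis: list[np.ndarray] = []
    n_iter = np.zeros(q, dtype=int)
    converged = np.zeros(q, dtype=bool)

    for i in range(q):
        b = _random_unit(rng, q, basis)
        for t in range(1, iters_T + 1):
            b_new = fixed_point_update(b, Z)
            if np.linalg.norm(b_new) < 1e-12:
                b = _random_unit(rng, q, basis)
                continue
            try:
                b_new = gram_schmidt(b_new, basis)
            except ValueError:
                b = _random_unit(rng, q, basis)
                continue
            if abs(b_new @ b) > 1.0 - tol:
                b = b_new
                n_iter[i] = t
                converged[i] = True
                break
            b = b_new
        else:
            n_iter[i] = iters_T
            warnings.warn(
                f"component {i} did not converge within {iters_T} iterations",
                RuntimeWarning,
                stacklevel=2,
            )
        basis.append(b)

    B = np.stack(basis, axis=1)
    return ICALayer(B=B, iters_T=iters_T, tol=tol, seed=seed,
                    n_iter=n_iter, converged=converged)


def _random_unit(rng: np.random.Generator, q: int, previous: list[np.ndarray]) -> np.ndarray:
    for _ in range(100):
        b = rng.standard_normal(q)
        try:
            return gram_schmidt(b, previous)
        except ValueError:
            continue
    raise RuntimeError("could not draw a direction outside the current span")


def compute_basis(model: WhiteningModel, B: np.ndarray) -> np.ndarray:
    """Basis A = UΛ^{1/2}B — pseudo-inverse of the whitening matrix times B."""
    B = np.asarray(B, dtype=float)
    if B.shape[0] != model.q:
        raise ValueError(f"B must have {model.q} rows, got {B.shape[0]}")
    return (model.eigvecs * np.sqrt(model.eigvals)) @ B


def responses(B: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """ICA feature coefficients S = BᵀZ."""
    B = np.asarray(B, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if B.shape[0] != Z.shape[0]:
        raise ValueError("row mismatch between B and Z")
    return B.T @ Z


def reconstruct(A: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Approximate the centered data from basis and coefficients: X̃ = AS."""
    A = np.asarray(A, dtype=float)
    S = np.asarray(S, dtype=float)
    if A.shape[1] != S.shape[0]:
        raise ValueError("column/row mismatch between A and S")
    return A @ S
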