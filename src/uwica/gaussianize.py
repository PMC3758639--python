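"""Generalized-Gaussian marginal models and the Gaussianising activation.

ICA responses on natural imagery are sparse and symmetric, well described
by the generalized Gaussian density

    f(s; σ, θ) = θ / (2 σ Γ(1/θ)) · exp{ −(|s|/σ)^θ } ,   σ, θ > 0

(Laplace at θ=1; Gaussian at θ=2, where σ is √2 times the standard
deviation).
Because the signs of ICA outputs carry no cross-dimension structure, the
layer-to-layer nonlinearity discards them and Gaussianises the folded
magnitude: v = |s| is mapped through its own fitted cdf (the regularised
lower incomplete gamma P(1/θ, (v/σ)^θ)) to a uniform variate, then through
the standard-normal inverse cdf.  The result has a standard-normal
marginal and feeds the next ICA layer.

Fitting is by moment matching: with m1 = E|s| and m2 = E s², the shape θ
solves m1²/m2 = Γ(2/θ)² / (Γ(1/θ)Γ(3/θ)) (bisected on [0.1, 10]) and
σ = m1·Γ(1/θ)/Γ(2/θ).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

__all__ = [
    "GGDParams",
    "ggd_pdf",
    "fit_ggd",
    "folded_cdf",
    "activation",
    "empirical_activation",
    "sample_ggd",
]

_THETA_LO, _THETA_HI = 0.1, 10.0


@dataclass
class GGDParams:
    """Scale/shape of a generalized Gaussian marginal (plus optional EDF)."""

    sigma: float
    theta: float
    fit_mode: str = "parametric"  # "parametric" | "empirical"
    edf: tuple[np.ndarray, np.ndarray] | None = None  # (bin edges, cum mass)

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.theta <= 0:
            raise ValueError("sigma and theta must be positive")
        if self.fit_mode not in ("parametric", "empirical"):
            raise ValueError("fit_mode must be 'parametric' or 'empirical'")


def ggd_pdf(s, params: GGDParams):
    """Generalized Gaussian density θ/(2σΓ(1/θ))·exp{−(|s|/σ)^θ}."""
    s = np.asarray(s, dtype=float)
    norm = params.theta / (2.0 * params.sigma * special.gamma(1.0 / params.theta))
    out = norm * np.exp(-((np.abs(s) / params.sigma) ** params.theta))
    return float(out) if out.ndim == 0 else out


def _moment_ratio(theta: float) -> float:
    """(E|s|)² / E s² for a GGD of shape theta (scale cancels)."""
    g1 = special.gammaln(1.0 / theta)
    g2 = special.gammaln(2.0 / theta)
    g3 = special.gammaln(3.0 / theta)
    return float(np.exp(2.0 * g2 - g1 - g3))


def fit_ggd(samples: np.ndarray) -> GGDParams:
    """Moment-matching fit of a generalized Gaussian to response samples."""
    s = np.asarray(samples, dtype=float).ravel()
    if s.size < 100:
        raise ValueError("need at least 100 samples to fit a GGD")
    m1 = np.mean(np.abs(s))
    m2 = np.mean(s**2)
    if m2 <= 0:
        raise ValueError("all-zero samples: GGD undefined")
    ratio = m1**2 / m2
    lo, hi = _moment_ratio(_THETA_LO), _moment_ratio(_THETA_HI)
    if ratio <= lo:
        warnings.warn("moment ratio below attainable range; clamping theta", RuntimeWarning)
        theta = _THETA_LO
    elif ratio >= hi:
        warnings.warn("moment ratio above attainable range; clamping theta", RuntimeWarning)
        theta = _THETA_HI
    else:
        theta = optimize.brentq(
            lambda t: _moment_ratio(t) - ratio, _THETA_LO, _THETA_HI, xtol=1e-12
        )
    sigma = m1 * special.gamma(1.0 / theta) / special.gamma(2.0 / theta)
    return GGDParams(sigma=float(sigma), theta=float(theta))


def folded_cdf(v, params: GGDParams):
    """cdf of the folded magnitude |s|: P(1/θ, (v/σ)^θ), increasing on [0, ∞)."""
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ValueError("folded_cdf is defined for v >= 0")
    out = special.gammainc(1.0 / params.theta, (v / params.sigma) ** params.theta)
    return float(out) if out.ndim == 0 else out


def activation(s, params: GGDParams, eps_u: float | None = None):
    """Sign-discarding Gaussianising activation g(|s|) = Φ⁻¹(cdf(|s|)).

    Even in s, strictly increasing in |s|; the uniform variate is clipped to
    [ε, 1−ε] with ε = max(1e−6, 1/(2n)) before the probit so tail samples
    stay finite.
    """
    s = np.asarray(s, dtype=float)
    if eps_u is None:
        n = max(int(s.size), 1)
        eps_u = max(1e-6, 0.5 / n) if n > 1 else 1e-6
    u = folded_cdf(np.abs(s), params)
    u = np.clip(u, eps_u, 1.0 - eps_u)
    out = special.ndtri(u)
    return float(out) if np.ndim(out) == 0 else out


def empirical_activation(
    s_j: np.ndarray,
    b_min: float = 0.0,
    b_max: float | None = None,
    bin_width: float | None = None,
):
    """Histogram-based Gaussianisation of one response dimension.

    The empirical cdf of |s_j| is estimated on bins [b_min, b_max) of width
    ``bin_width`` (defaults: 99.9th percentile of |s_j| and 1000 bins),
    linearly interpolated, clipped to [1/(2n), 1−1/(2n)] and pushed through
    the standard-normal inverse cdf.  Rank-preserving in |s_j|.  Falls back
    to the parametric path when the histogram is degenerate.
    """
    s_j = np.asarray(s_j, dtype=float).ravel()
    n = s_j.size
    a = np.abs(s_j)
    if b_max is None:
        b_max = float(np.percentile(a, 99.9))
    if b_max <= b_min:
        b_max = b_min + max(a.max(), 1e-12)
    if bin_width is None:
        bin_width = (b_max - b_min) / 1000.0
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    edges = np.arange(b_min, b_max + bin_width, bin_width)
    hist, edges = np.histogram(np.clip(a, b_min, b_max - 1e-12 * bin_width), bins=edges)
    if np.count_nonzero(hist) <= 1:
        warnings.warn(
            "degenerate histogram (all mass in one bin); falling back to "
            "parametric activation",
            RuntimeWarning,
        )
        return activation(s_j, fit_ggd(s_j))
    cum = np.concatenate([[0.0], np.cumsum(hist)]) / n
    u = np.interp(a, edges, cum)
    u = np.clip(u, 0.5 / n, 1.0 - 0.5 / n)
    return special.ndtri(u)


def sample_ggd(
    n: int, sigma: float, theta: float, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Draw n samples from a GGD(σ, θ) via the gamma transform.

    If G ~ Gamma(1/θ, 1) then σ·G^{1/θ} has the folded-GGD magnitude law;
    a random sign completes the symmetric draw.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    g = rng.gamma(1.0 / theta, 1.0, size=n)
    mag = sigma * g ** (1.0 / theta)
    signs = rng.choice([-1.0, 1.0], size=n)
    return mag * signs
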