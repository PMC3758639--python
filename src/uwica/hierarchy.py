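"""Hierarchical ICA: training orchestration, transfer, and visualisation.

A multi-layer efficient-coding model of early vision.  Layer 1 is trained
on pre-whitened image patches; its responses are sign-discarded,
Gaussianised and lifted back to the ambient dimension to become the input
of layer 2, and so on.  Layer 1 learns Gabor-like bases (V1-style
receptive fields); deeper layers capture residual, higher-order structure
(texture boundaries, contours).

The module follows the Model/Results convention of statistical modelling
packages: build a :class:`HierarchicalICA` from a corpus, call
:meth:`~HierarchicalICA.fit` and obtain a :class:`HierarchicalICAResults`
carrying the trained layers, convergence diagnostics and a ``summary()``
table.  The underlying operations (:func:`train_layer`,
:func:`train_hierarchy`, :func:`apply_hierarchy`) are plain functions and
remain usable on their own.

Learned bases transfer: a model trained on one corpus can be applied to
images from another (the shared-feature workflow), producing per-layer
activation maps on the patch grid without any refitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from . import gaussianize as gz
from . import ica as ica_mod
from . import patches as patches_mod
from . import whitening as wh

__all__ = [
    "LayerConfig",
    "HierarchicalModel",
    "ActivationMap",
    "train_layer",
    "train_hierarchy",
    "apply_hierarchy",
    "render_basis_mosaic",
    "bandpass_orientation_scores",
    "save_model",
    "load_model",
    "HierarchicalICA",
    "HierarchicalICAResults",
]


@dataclass
class LayerConfig:
    """Per-layer training configuration."""

    q: int | float = 0.95          # retained dimension, or variance fraction
    iters_T: int = 200
    tol: float = 1e-6
    seed: int | None = None
    activation_mode: str = "parametric"  # "parametric" | "empirical"

    def __post_init__(self) -> None:
        if self.activation_mode not in ("parametric", "empirical"):
            raise ValueError("activation_mode must be 'parametric' or 'empirical'")


@dataclass
class HierarchicalModel:
    """Ordered ICA layers with their whiteners and the patch geometry."""

    layers: list[tuple[wh.WhiteningModel, ica_mod.ICALayer]]
    p: int
    m: int
    prewhiten: bool = True
    f0_fraction: float = 0.8
    seed: int | None = None
    activation_mode: str = "parametric"

    @property
    def n_layers(self) -> int:
        return len(self.layers)


@dataclass
class ActivationMap:
    """Per-layer responses arranged on the patch grid (grid_h × grid_w × q)."""

    values: np.ndarray
    layer: int

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.values.shape[:2]

    def norm_map(self) -> np.ndarray:
        """Aggregate view: per-tile L2 norm of the response vector."""
        return np.linalg.norm(self.values, axis=2)

    def component_map(self, k: int) -> np.ndarray:
        return self.values[:, :, k]


def train_layer(
    X: np.ndarray, cfg: LayerConfig | None = None
) -> tuple[wh.WhiteningModel, ica_mod.ICALayer, np.ndarray]:
    """Run one full layer of the recursive pipeline on a d×n input matrix.

    center → fit whitening → whiten → fixed-point ICA → responses →
    rise dimensionality → fit a generalized Gaussian per dimension →
    sign-discarding Gaussianising activation.  Returns the whitener, the
    trained ICA layer (with per-dimension marginal parameters) and the
    next layer's d×n input X′ = g(|VᵀS|).
    """
    if cfg is None:
        cfg = LayerConfig()
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("input matrix contains non-finite values")
    Xbar, mean = wh.center(X)
    model = wh.fit_whitening(Xbar, q=cfg.q)
    model.mean = mean
    Z = wh.whiten(Xbar, model)
    layer = ica_mod.fastica(Z, iters_T=cfg.iters_T, tol=cfg.tol, seed=cfg.seed)
    layer.A = ica_mod.compute_basis(model, layer.B)
    S = ica_mod.responses(layer.B, Z)
    S_risen = wh.rise_dimensionality(S, model)
    X_next = np.empty_like(S_risen)
    layer.gauss_params = []
    for i in range(S_risen.shape[0]):
        params = gz.fit_ggd(S_risen[i])
        layer.gauss_params.append(params)
        if cfg.activation_mode == "empirical":
            X_next[i] = gz.empirical_activation(S_risen[i])
        else:
            X_next[i] = gz.activation(S_risen[i], params)
    return model, layer, X_next


def _prepare_patches(
    images: list[np.ndarray],
    p: int,
    m: int,
    prewhiten: bool,
    f0_fraction: float,
) -> patches_mod.PatchMatrix:
    processed = []
    for img in images:
        cropped = patches_mod.crop_boundary(np.asarray(img, dtype=float), m)
        if prewhiten:
            cropped = patches_mod.prewhiten_image(cropped, f0_fraction)
        processed.append(cropped)
    return patches_mod.extract_patches(processed, p=p, m=0)


def train_hierarchy(
    images: list[np.ndarray],
    n_layers: int = 3,
    configs: list[LayerConfig] | LayerConfig | None = None,
    p: int = 16,
    m: int = 16,
    prewhiten: bool = True,
    f0_fraction: float = 0.8,
    seed: int | None = None,
) -> HierarchicalModel:
    """Train an L-layer hierarchical ICA model on an image corpus.

    Layer 1 sees non-overlapping p×p patches of the cropped (and by default
    pre-whitened) images; each subsequent layer sees the Gaussianised,
    dimension-risen responses of the previous one.  Per-layer seeds are
    derived deterministically from ``seed`` unless explicit per-layer
    configs carry their own.
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    if isinstance(configs, LayerConfig):
        configs = [configs] * n_layers
    if configs is None:
        configs = [LayerConfig() for _ in range(n_layers)]
    if len(configs) != n_layers:
        raise ValueError("need one LayerConfig per layer")

    pm = _prepare_patches(images, p, m, prewhiten, f0_fraction)
    X = pm.X
    if X.shape[1] <= X.shape[0]:
        import warnings

        warnings.warn(
            f"corpus yields only n={X.shape[1]} patches for d={X.shape[0]}; "
            "estimates may be unstable",
            RuntimeWarning,
        )

    layers = []
    mode = configs[0].activation_mode
    for ell, cfg in enumerate(configs):
        if cfg.seed is None and seed is not None:
            layer_seed = int(
                np.random.SeedSequence(seed, spawn_key=(ell,)).generate_state(1)[0]
                % (2**31)
            )
            cfg = LayerConfig(q=cfg.q, iters_T=cfg.iters_T, tol=cfg.tol,
                              seed=layer_seed, activation_mode=cfg.activation_mode)
        model, layer, X = train_layer(X, cfg)
        layers.append((model, layer))
    return HierarchicalModel(
        layers=layers, p=p, m=m, prewhiten=prewhiten,
        f0_fraction=f0_fraction, seed=seed, activation_mode=mode,
    )


def apply_hierarchy(
    model: HierarchicalModel,
    image: np.ndarray,
    prewhiten: bool | None = None,
) -> list[ActivationMap]:
    """Apply a trained model to one image; returns per-layer activation maps.

    Patches are extracted with the model's stored geometry; each layer
    centers with its *training* mean (transfer is a pure linear map), whitens
    with the stored V, computes S = BᵀZ, and feeds the stored rising +
    activation forward.  No parameter is refitted.
    """
    image = np.asarray(image, dtype=float)
    if prewhiten is None:
        prewhiten = model.prewhiten
    if min(image.shape) <= model.p + 2 * model.m:
        raise ValueError("image too small for the model's patch geometry")
    cropped = patches_mod.crop_boundary(image, model.m)
    if prewhiten:
        cropped = patches_mod.prewhiten_image(cropped, model.f0_fraction)
    pm = patches_mod.extract_patches([cropped], p=model.p, m=0)
    grid_h = (cropped.shape[0]) // model.p
    grid_w = (cropped.shape[1]) // model.p

    X = pm.X
    maps: list[ActivationMap] = []
    for ell, (wmodel, layer) in enumerate(model.layers):
        if X.shape[0] != wmodel.d:
            raise ValueError("patch geometry does not match the trained model")
        Xbar = X - wmodel.mean[:, None]
        Z = wh.whiten(Xbar, wmodel)
        S = ica_mod.responses(layer.B, Z)
        values = S.T.reshape(grid_h, grid_w, wmodel.q)
        maps.append(ActivationMap(values=values, layer=ell + 1))
        S_risen = wh.rise_dimensionality(S, wmodel)
        X = np.empty_like(S_risen)
        for i in range(S_risen.shape[0]):
            X[i] = gz.activation(S_risen[i], layer.gauss_params[i])
    return maps


def render_basis_mosaic(A: np.ndarray, p: int) -> np.ndarray:
    """Tile the columns of a d×q basis as p×p images with 1-px separators.

    Each column is reshaped column-major, independently min–max normalised,
    and placed on a ⌈√q⌉ × ⌈√q⌉ grid; the mosaic side is ⌈√q⌉(p+1)+1.
    """
    A = np.asarray(A, dtype=float)
    d, q = A.shape
    if d != p * p:
        raise ValueError(f"basis rows d={d} must equal p^2={p**2}")
    g = int(np.ceil(np.sqrt(q)))
    side = g * (p + 1) + 1
    mosaic = np.zeros((side, side))
    for k in range(q):
        tile = A[:, k].reshape(p, p, order="F")
        lo, hi = tile.min(), tile.max()
        tile = (tile - lo) / (hi - lo) if hi - lo > 1e-15 else np.full_like(tile, 0.5)
        r, c = divmod(k, g)
        top = 1 + r * (p + 1)
        left = 1 + c * (p + 1)
        mosaic[top : top + p, left : left + p] = tile
    return mosaic


def bandpass_orientation_scores(A: np.ndarray, p: int) -> np.ndarray:
    """Spectral concentration score of each basis column in [0, 1].

    For each column (reshaped to p×p, mean removed) the 2-D power spectrum
    is computed; the score is the fraction of non-DC power inside a wedge of
    ±30° around the peak orientation and within one octave of the peak
    radial frequency.  A score > 0.5 marks the column as a localized
    oriented bandpass (Gabor-like) feature.
    """
    A = np.asarray(A, dtype=float)
    d, q = A.shape
    if d != p * p:
        raise ValueError("basis rows must equal p^2")
    fy = np.fft.fftfreq(p)[:, None]
    fx = np.fft.fftfreq(p)[None, :]
    f = np.hypot(fy, fx)
    ang = np.arctan2(fy, fx) % np.pi  # orientation mod pi
    scores = np.empty(q)
    for k in range(q):
        w = A[:, k].reshape(p, p, order="F")
        w = w - w.mean()
        P = np.abs(np.fft.fft2(w)) ** 2
        P[0, 0] = 0.0
        total = P.sum()
        if total <= 0:
            scores[k] = 0.0
            continue
        pk = np.unravel_index(np.argmax(P), P.shape)
        f_pk = f[pk]
        a_pk = ang[pk]
        dang = np.abs(ang - a_pk)
        dang = np.minimum(dang, np.pi - dang)
        wedge = (dang <= np.deg2rad(30.0)) & (f >= f_pk / 2.0) & (f <= 2.0 * f_pk)
        scores[k] = P[wedge].sum() / total
    return scores


# ---------------------------------------------------------------------------
# serialization

def save_model(model: HierarchicalModel, path: str) -> None:
    """Write a trained model to an HDF5 container (bit-exact round trip)."""
    with h5py.File(path, "w") as h5:
        h5.attrs["format"] = "uwica-hica-v1"
        h5.attrs["p"] = model.p
        h5.attrs["m"] = model.m
        h5.attrs["prewhiten"] = model.prewhiten
        h5.attrs["f0_fraction"] = model.f0_fraction
        h5.attrs["seed"] = -1 if model.seed is None else model.seed
        h5.attrs["activation_mode"] = model.activation_mode
        h5.attrs["n_layers"] = model.n_layers
        for ell, (wmodel, layer) in enumerate(model.layers, start=1):
            grp = h5.create_group(f"layer_{ell}")
            grp.create_dataset("mean", data=wmodel.mean)
            grp.create_dataset("U", data=wmodel.eigvecs)
            grp.create_dataset("Lambda", data=wmodel.eigvals)
            grp.create_dataset("B", data=layer.B)
            grp.create_dataset(
                "ggd_sigma", data=np.array([g.sigma for g in layer.gauss_params])
            )
            grp.create_dataset(
                "ggd_theta", data=np.array([g.theta for g in layer.gauss_params])
            )
            if layer.n_iter is not None:
                grp.create_dataset("n_iter", data=layer.n_iter)
            if layer.converged is not None:
                grp.create_dataset("converged", data=layer.converged.astype(np.int8))
            grp.attrs["q"] = wmodel.q
            grp.attrs["eps_reg"] = wmodel.eps_reg
            grp.attrs["iters_T"] = layer.iters_T
            grp.attrs["tol"] = layer.tol
            grp.attrs["seed"] = -1 if layer.seed is None else layer.seed


def load_model(path: str) -> HierarchicalModel:
    """Read a model written by :func:`save_model`."""
    with h5py.File(path, "r") as h5:
        if h5.attrs.get("format") != "uwica-hica-v1":
            raise ValueError("not a uwica hierarchical-ICA model file")
        layers = []
        for ell in range(1, int(h5.attrs["n_layers"]) + 1):
            grp = h5[f"layer_{ell}"]
            wmodel = wh.WhiteningModel(
                mean=grp["mean"][...],
                eigvals=grp["Lambda"][...],
                eigvecs=grp["U"][...],
                q=int(grp.attrs["q"]),
                eps_reg=float(grp.attrs["eps_reg"]),
            )
            seed = int(grp.attrs["seed"])
            layer = ica_mod.ICALayer(
                B=grp["B"][...],
                iters_T=int(grp.attrs["iters_T"]),
                tol=float(grp.attrs["tol"]),
                seed=None if seed < 0 else seed,
                n_iter=grp["n_iter"][...] if "n_iter" in grp else None,
                converged=grp["converged"][...].astype(bool) if "converged" in grp else None,
            )
            layer.A = ica_mod.compute_basis(wmodel, layer.B)
            sigmas = grp["ggd_sigma"][...]
            thetas = grp["ggd_theta"][...]
            layer.gauss_params = [
                gz.GGDParams(sigma=float(s), theta=float(t))
                for s, t in zip(sigmas, thetas)
            ]
            layers.append((wmodel, layer))
        seed = int(h5.attrs["seed"])
        return HierarchicalModel(
            layers=layers,
            p=int(h5.attrs["p"]),
            m=int(h5.attrs["m"]),
            prewhiten=bool(h5.attrs["prewhiten"]),
            f0_fraction=float(h5.attrs["f0_fraction"]),
            seed=None if seed < 0 else seed,
            activation_mode=str(h5.attrs["activation_mode"]),
        )


# ---------------------------------------------------------------------------
# Model / Results front end

class HierarchicalICA:
    """Hierarchical ICA model of an image corpus.

    Parameters
    ----------
    images : sequence of 2-D arrays
        Training corpus, luminance in [0, 1] (or any real-valued images if
        ``prewhiten`` is on, since pre-whitening renormalises them).
    n_layers : int
        Depth of the hierarchy.
    patch_size, border_crop : int
        Patch side p and boundary crop m.
    q : int or float
        Retained dimension per layer (integer) or variance fraction.
    prewhiten : bool
        Apply the 1/f pre-whitening filter before patch extraction.

    Examples
    --------
    >>> model = HierarchicalICA(images, n_layers=3, patch_size=16)
    >>> res = model.fit(seed=7)
    >>> print(res.summary())
    >>> maps = res.activation_maps(test_image)
    """

    def __init__(
        self,
        images,
        n_layers: int = 3,
        patch_size: int = 16,
        border_crop: int = 16,
        q: int | float = 0.95,
        prewhiten: bool = True,
        f0_fraction: float = 0.8,
        activation_mode: str = "parametric",
    ) -> None:
        self.images = [np.asarray(img, dtype=float) for img in images]
        self.n_layers = n_layers
        self.patch_size = patch_size
        self.border_crop = border_crop
        self.q = q
        self.prewhiten = prewhiten
        self.f0_fraction = f0_fraction
        self.activation_mode = activation_mode

    def fit(
        self, seed: int | None = 0, iters_T: int = 200, tol: float = 1e-6
    ) -> "HierarchicalICAResults":
        cfg = LayerConfig(q=self.q, iters_T=iters_T, tol=tol,
                          activation_mode=self.activation_mode)
        model = train_hierarchy(
            self.images,
            n_layers=self.n_layers,
            configs=[cfg] * self.n_layers if self.n_layers > 1 else [cfg],
            p=self.patch_size,
            m=self.border_crop,
            prewhiten=self.prewhiten,
            f0_fraction=self.f0_fraction,
            seed=seed,
        )
        return HierarchicalICAResults(self, model)


class HierarchicalICAResults:
    """Fitted hierarchical ICA model with diagnostics.

    Attributes
    ----------
    model : HierarchicalICA
        The model specification this was fitted from (may be ``None`` when
        loaded from disk).
    layers : list of (WhiteningModel, ICALayer)
        Trained parameters, outermost first.
    """

    def __init__(self, model: HierarchicalICA | None, fitted: HierarchicalModel):
        self.model = model
        self._fitted = fitted

    @property
    def fitted_model(self) -> HierarchicalModel:
        return self._fitted

    @property
    def layers(self):
        return self._fitted.layers

    def basis(self, layer: int = 1) -> np.ndarray:
        """d×q basis matrix A of one layer (1-based index)."""
        return self._fitted.layers[layer - 1][1].A

    def basis_mosaic(self, layer: int = 1) -> np.ndarray:
        return render_basis_mosaic(self.basis(layer), self._fitted.p)

    def activation_maps(self, image, prewhiten: bool | None = None):
        return apply_hierarchy(self._fitted, image, prewhiten=prewhiten)

    def bandpass_fraction(self, layer: int = 1, threshold: float = 0.5) -> float:
        """Fraction of a layer's basis columns that are oriented bandpass."""
        scores = bandpass_orientation_scores(self.basis(layer), self._fitted.p)
        return float(np.mean(scores > threshold))

    def save(self, path: str) -> None:
        save_model(self._fitted, path)

    @classmethod
    def load(cls, path: str) -> "HierarchicalICAResults":
        return cls(None, load_model(path))

    def summary(self) -> str:
        """Plain-text per-layer summary table."""
        m = self._fitted
        lines = [
            "Hierarchical ICA results",
            "=" * 64,
            f"layers: {m.n_layers}   patch p={m.p}   crop m={m.m}   "
            f"prewhiten={m.prewhiten}   seed={m.seed}",
            "-" * 64,
            f"{'layer':>5} {'d':>5} {'q':>5} {'conv':>6} {'med iters':>9} "
            f"{'med theta':>9} {'med sigma':>9}",
        ]
        for ell, (wmodel, layer) in enumerate(m.layers, start=1):
            thetas = [g.theta for g in layer.gauss_params]
            sigmas = [g.sigma for g in layer.gauss_params]
            conv = (
                f"{int(layer.converged.sum())}/{layer.q}"
                if layer.converged is not None
                else "n/a"
            )
            iters = (
                f"{np.median(layer.n_iter):.0f}" if layer.n_iter is not None else "n/a"
            )
            lines.append(
                f"{ell:>5} {wmodel.d:>5} {wmodel.q:>5} {conv:>6} {iters:>9} "
                f"{np.median(thetas):>9.3f} {np.median(sigmas):>9.3f}"
            )
        lines.append("=" * 64)
        return "\n".join(lines)
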