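"""Layer orchestration, transfer, serialization, and visualisation."""

import warnings

import numpy as np
import pytest
from scipy import stats

import uwica.hierarchy as hi
from uwica.gaussianize import sample_ggd
from uwica.hierarchy import (
    HierarchicalICA,
    HierarchicalICAResults,
    LayerConfig,
    apply_hierarchy,
    bandpass_orientation_scores,
    load_model,
    render_basis_mosaic,
    save_model,
    train_hierarchy,
    train_layer,
)
from uwica.synthetic import gabor_dictionary, gen_sparse_gabor


def _ggd_mixture(d, n, seed):
    rng = np.random.default_rng(seed)
    S = np.stack([sample_ggd(n, 1.0, 0.8, rng) for _ in range(d)])
    Q = np.linalg.qr(rng.standard_normal((d, d)))[0]
    return Q @ S


@pytest.fixture(scope="module")
def small_corpus():
    return [gen_sparse_gabor(128, sparsity_k=80, seed=30 + i)[0] for i in range(4)]


@pytest.fixture(scope="module")
def trained(small_corpus):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return train_hierarchy(
            small_corpus, n_layers=2, configs=LayerConfig(q=32),
            p=8, m=8, seed=11,
        )


class TestTrainLayer:
    def test_next_input_shape_restores_d(self):
        X = _ggd_mixture(16, 4000, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            model, layer, X_next = train_layer(X, LayerConfig(q=8, seed=0))
        assert X_next.shape == X.shape
        assert layer.A.shape == (16, 8)

    def test_output_rows_approximately_standard_normal(self):
        X = _ggd_mixture(8, 20000, seed=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            _, _, X_next = train_layer(X, LayerConfig(q=8, seed=1))
        for row in X_next:
            assert stats.kstest(row, "norm").statistic < 0.05

    def test_deterministic_given_seed(self):
        X = _ggd_mixture(6, 3000, seed=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m1, l1, x1 = train_layer(X, LayerConfig(q=6, seed=3))
            m2, l2, x2 = train_layer(X, LayerConfig(q=6, seed=3))
        assert np.array_equal(l1.B, l2.B)
        assert np.array_equal(x1, x2)


class TestTrainHierarchy:
    def test_layer_shapes_chain(self, trained):
        assert trained.n_layers == 2
        for wmodel, layer in trained.layers:
            assert wmodel.d == 64  # p=8 geometry
            assert layer.B.shape == (32, 32)

    def test_gabor_corpus_learns_bandpass_oriented_bases(self):
        imgs = [gen_sparse_gabor(256, sparsity_k=200, seed=50 + i)[0] for i in range(6)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            model = train_hierarchy(
                imgs, n_layers=1, configs=LayerConfig(q=32, seed=2), p=16, m=16
            )
        scores = bandpass_orientation_scores(model.layers[0][1].A, 16)
        assert np.mean(scores > 0.5) >= 0.6

    def test_serialization_round_trips_bit_exactly(self, trained, tmp_path):
        path = str(tmp_path / "model.h5")
        save_model(trained, path)
        loaded = load_model(path)
        for (w1, l1), (w2, l2) in zip(trained.layers, loaded.layers):
            assert np.array_equal(w1.mean, w2.mean)
            assert np.array_equal(w1.eigvals, w2.eigvals)
            assert np.array_equal(w1.eigvecs, w2.eigvecs)
            assert np.array_equal(l1.B, l2.B)
            for g1, g2 in zip(l1.gauss_params, l2.gauss_params):
                assert g1.sigma == g2.sigma and g1.theta == g2.theta
        assert loaded.p == trained.p and loaded.m == trained.m


class TestApplyHierarchy:
    def test_map_grid_dimensions(self, trained, small_corpus):
        maps = apply_hierarchy(trained, small_corpus[0])
        assert len(maps) == 2
        grid = ((128 - 16) // 8, (128 - 16) // 8)
        for amap in maps:
            assert amap.grid_shape == grid
            assert amap.norm_map().shape == grid

    def test_training_image_reproduces_training_responses(self, trained, small_corpus):
        # the same preprocessing and stored parameters give identical patches
        maps = apply_hierarchy(trained, small_corpus[0])
        pm = hi._prepare_patches([small_corpus[0]], 8, 8, True, 0.8)
        wmodel, layer = trained.layers[0]
        S = layer.B.T @ (wmodel.V @ (pm.X - wmodel.mean[:, None]))
        grid = maps[0].grid_shape
        assert np.allclose(
            maps[0].values, S.T.reshape(grid[0], grid[1], wmodel.q), atol=1e-12
        )

    def test_constant_image_responses_are_small(self, small_corpus):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            model = train_hierarchy(
                small_corpus, n_layers=1, configs=LayerConfig(q=16, seed=4),
                p=8, m=8, prewhiten=False,
            )
        wmodel, _ = model.layers[0]
        const = np.full((128, 128), float(wmodel.mean.mean()))
        ref = apply_hierarchy(model, small_corpus[1], prewhiten=False)[0]
        got = apply_hierarchy(model, const, prewhiten=False)[0]
        assert got.norm_map().mean() < 0.1 * ref.norm_map().mean()

    def test_geometry_mismatch_raises(self, trained):
        with pytest.raises(ValueError):
            apply_hierarchy(trained, np.random.default_rng(0).random((20, 20)))

    def test_transfer_keeps_responses_sparse(self, trained):
        # bases trained on one corpus, applied to a fresh sparse corpus:
        # per-dimension excess kurtosis stays positive
        other = gen_sparse_gabor(128, sparsity_k=80, seed=99)[0]
        amap = apply_hierarchy(trained, other)[0]
        S = amap.values.reshape(-1, amap.values.shape[2]).T
        kurt = stats.kurtosis(S, axis=1)
        assert np.median(kurt) > 0


class TestVisualisation:
    def test_single_tile_mosaic(self):
        A = np.random.default_rng(0).random((16, 1))
        assert render_basis_mosaic(A, 4).shape == (6, 6)

    def test_mosaic_layout_arithmetic(self):
        A = np.random.default_rng(0).random((64, 10))
        g = int(np.ceil(np.sqrt(10)))
        side = g * (8 + 1) + 1
        assert render_basis_mosaic(A, 8).shape == (side, side)

    def test_identity_basis_renders_one_hot_tiles(self):
        A = np.eye(16)
        mosaic = render_basis_mosaic(A, 4)
        tile0 = mosaic[1:5, 1:5]
        assert tile0.max() == 1.0 and np.sum(tile0 == 1.0) == 1

    def test_non_square_dimension_raises(self):
        with pytest.raises(ValueError):
            render_basis_mosaic(np.ones((15, 2)), 4)

    def test_gabor_atoms_score_high_noise_scores_low(self, rng):
        atoms = [a for a in gabor_dictionary() if a.shape[0] <= 16]
        cols = []
        for a in atoms[:16]:
            pad = np.zeros((16, 16))
            pad[: a.shape[0], : a.shape[1]] = a
            cols.append(pad.flatten(order="F"))
        A_gabor = np.stack(cols, axis=1)
        gabor_scores = bandpass_orientation_scores(A_gabor, 16)
        noise_scores = bandpass_orientation_scores(rng.standard_normal((256, 16)), 16)
        assert np.median(gabor_scores) > np.median(noise_scores)
        assert np.mean(gabor_scores > 0.5) > 0.8


class TestModelResultsFrontEnd:
    def test_fit_returns_results_with_summary(self, small_corpus):
        model = HierarchicalICA(
            small_corpus, n_layers=1, patch_size=8, border_crop=8, q=16
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = model.fit(seed=5)
        text = res.summary()
        assert "layer" in text and "theta" in text
        assert res.basis(1).shape == (64, 16)
        assert 0.0 <= res.bandpass_fraction(1) <= 1.0

    def test_results_save_load(self, small_corpus, tmp_path):
        model = HierarchicalICA(
            small_corpus, n_layers=1, patch_size=8, border_crop=8, q=8
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = model.fit(seed=6)
        path = str(tmp_path / "m.h5")
        res.save(path)
        loaded = HierarchicalICAResults.load(path)
        assert np.array_equal(loaded.basis(1), res.basis(1))
        maps_a = res.activation_maps(small_corpus[0])
        maps_b = loaded.activation_maps(small_corpus[0])
        assert np.array_equal(maps_a[0].values, maps_b[0].values)
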