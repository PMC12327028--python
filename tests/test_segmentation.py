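import numpy as np
import pytest

from oracles import histogram_equalize
from octa3d import (
    LayeredPhantomSpec,
    SegModelSpec,
    boundary_error,
    clahe_enhance,
    extract_boundaries,
    make_layered_volume,
    predict_labels,
    thickness_stats,
    train_unet,
)
from octa3d.segmentation import BoundarySurfaces, SegModel


class TestClahe:
    def test_unclipped_single_tile_matches_global_equalization(self):
        rng = np.random.default_rng(0)
        img = rng.random((8, 8))
        out = clahe_enhance(img, clip_limit=1e9, tiles=(1, 1))
        oracle = histogram_equalize(img)
        assert np.abs(out - oracle).max() < 0.05

    def test_uniform_histogram_image_is_near_fixed_point(self):
        img = np.linspace(0, 1, 64 * 64).reshape(64, 64)
        out = clahe_enhance(img, clip_limit=1e9, tiles=(1, 1))
        assert np.abs(out - img).max() < 0.05

    def test_output_range_contract(self):
        rng = np.random.default_rng(1)
        for scale in (0.01, 1.0, 1000.0):
            img = rng.normal(0, scale, (32, 32))
            out = clahe_enhance(img)
            assert out.min() >= 0.0 and out.max() <= 1.0

    def test_constant_image_warns_and_passes_through(self):
        img = np.full((16, 16), 0.5)
        with pytest.warns(UserWarning, match="constant"):
            out = clahe_enhance(img)
        assert np.array_equal(out, img)


def _phantom_bscans(shape=(32, 32, 24), seed=0, **kw):
    spec = LayeredPhantomSpec(shape=shape, depths=(6.0, 12.0, 26.0),
                              boundary_amplitude=1.5, additive_sigma=0.01,
                              seed=seed, **kw)
    vol, labels = make_layered_volume(spec)
    return np.moveaxis(vol, 2, 0), np.moveaxis(labels, 2, 0), vol, labels


class TestTraining:
    def test_smoke_run_trains_and_serializes(self, tmp_path):
        x, y, _, _ = _phantom_bscans()
        spec = SegModelSpec(depth=2, base_channels=4, epochs=1, folds=2, seed=0)
        model = train_unet(x[:8], y[:8], spec)
        assert len(model.history["folds"]) == 2
        assert len(model.history["final"]["loss"]) == 1
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = SegModel.load(path)
        pred1 = model.predict_bscan(x[8])
        pred2 = loaded.predict_bscan(x[8])
        assert np.array_equal(pred1, pred2)

    def test_cross_validation_partitions_disjoint_and_complete(self):
        x, y, _, _ = _phantom_bscans()
        spec = SegModelSpec(depth=2, base_channels=4, epochs=1, folds=3, seed=1)
        model = train_unet(x[:12], y[:12], spec)
        held = [set(f["val_indices"]) for f in model.history["folds"]]
        all_idx = set().union(*held)
        assert all_idx == set(range(12))
        assert sum(len(h) for h in held) == 12

    def test_constant_class_labels_learned_perfectly(self):
        rng = np.random.default_rng(2)
        x = rng.random((8, 16, 16))
        y = np.ones((8, 16, 16), np.uint8)
        spec = SegModelSpec(depth=2, base_channels=4, epochs=30, folds=2, seed=0)
        model = train_unet(x, y, spec, cross_validate=False, clahe=False)
        preds = np.stack([model.predict_bscan(b) for b in x])
        assert np.all(preds == 1)  # post-training accuracy 1.0

    def test_invalid_label_values_rejected(self):
        x = np.zeros((4, 16, 16))
        y = np.full((4, 16, 16), 3, np.uint8)
        with pytest.raises(ValueError, match="labels"):
            train_unet(x, y, SegModelSpec(depth=2, folds=2, epochs=1))

    def test_training_is_seed_deterministic(self):
        x, y, _, _ = _phantom_bscans()
        spec = SegModelSpec(depth=2, base_channels=4, epochs=2, folds=2, seed=3)
        m1 = train_unet(x[:8], y[:8], spec, cross_validate=False)
        m2 = train_unet(x[:8], y[:8], spec, cross_validate=False)
        for k in m1.net.params:
            assert np.array_equal(m1.net.params[k], m2.net.params[k])


class TestPrediction:
    def test_phantom_recovery_within_boundary_band(self, seg_model_tiny):
        # noise-free flat phantom: mislabels only in a 2-voxel boundary band
        spec = LayeredPhantomSpec(shape=(32, 32, 16), depths=(6.0, 12.0, 26.0),
                                  boundary_amplitude=0.0, speckle_shape=None,
                                  additive_sigma=0.0, seed=99)
        vol, truth = make_layered_volume(spec)
        pred = predict_labels(seg_model_tiny, vol)
        assert pred.shape == truth.shape
        # disagreements allowed only within a 2-voxel band of a boundary
        wrong = pred != truth
        band = np.zeros_like(wrong)
        for dz in range(-2, 3):
            band |= np.roll(truth, dz, axis=0) != truth
        assert not (wrong & ~band).any()

    def test_prediction_deterministic(self, seg_model_tiny):
        spec = LayeredPhantomSpec(shape=(32, 32, 8), depths=(6.0, 12.0, 26.0),
                                  seed=5)
        vol, _ = make_layered_volume(spec)
        p1 = predict_labels(seg_model_tiny, vol)
        p2 = predict_labels(seg_model_tiny, vol)
        assert np.array_equal(p1, p2)

    def test_shape_mismatch_rejected(self, seg_model_tiny):
        with pytest.raises(ValueError, match="geometry"):
            predict_labels(seg_model_tiny, np.zeros((16, 16, 8)))


class TestBoundaries:
    def test_flat_phantom_boundaries_exact(self):
        b = tuple(np.full((12, 12), d) for d in (20.0, 50.0, 80.0))
        spec = LayeredPhantomSpec(shape=(100, 12, 12), boundaries=b,
                                  speckle_shape=None, additive_sigma=0.0)
        _, labels = make_layered_volume(spec)
        surf = extract_boundaries(labels)
        assert np.all(surf.ab1 == 20) and np.all(surf.ab2 == 50)
        assert np.all(surf.ab3 == 80)

    def test_sinusoidal_boundary_roundtrip(self):
        nx = ny = 24
        x = np.arange(nx)[:, None]
        ab2 = 16 + 4 * np.sin(2 * np.pi * x / nx) * np.ones((1, ny))
        b = (np.full((nx, ny), 8.0), ab2, np.full((nx, ny), 28.0))
        spec = LayeredPhantomSpec(shape=(32, nx, ny), boundaries=b,
                                  speckle_shape=None, additive_sigma=0.0)
        _, labels = make_layered_volume(spec)
        surf = extract_boundaries(labels)
        assert np.array_equal(surf.ab2, np.ceil(ab2))

    def test_empty_dermis_column_flagged_not_interpolated(self):
        labels = np.zeros((20, 4, 4), np.uint8)
        labels[5:10] = 1
        labels[10:15] = 2
        labels[10:15, 2, 3] = 0  # this A-line has no dermis
        surf = extract_boundaries(labels)
        assert np.isnan(surf.ab2[2, 3]) and np.isnan(surf.ab3[2, 3])
        assert surf.qc_flags["undefined_columns"] == 1

    def test_multiple_runs_keep_longest_and_flag(self):
        labels = np.zeros((30, 1, 1), np.uint8)
        labels[4:6, 0, 0] = 1    # short epidermis run (speckle)
        labels[8:16, 0, 0] = 1   # the real epidermis
        labels[16:24, 0, 0] = 2
        surf = extract_boundaries(labels)
        assert surf.ab1[0, 0] == 8
        assert surf.qc_flags["multi_run_columns"] == 1

    def test_monotone_ordering_enforced(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 3, (24, 6, 6)).astype(np.uint8)
        surf = extract_boundaries(labels)
        ok = surf.defined()
        assert np.all(surf.ab1[ok] <= surf.ab2[ok])
        assert np.all(surf.ab2[ok] <= surf.ab3[ok])


class TestBoundaryError:
    def _surf(self, ab1, ab2, ab3):
        return BoundarySurfaces(np.asarray(ab1, float), np.asarray(ab2, float),
                                np.asarray(ab3, float))

    def test_identity_gives_zero(self):
        s = self._surf(np.full((4, 4), 5.0), np.full((4, 4), 10.0),
                       np.full((4, 4), 15.0))
        err = boundary_error(s, s)
        assert err == {"ab1": 0.0, "ab2": 0.0, "ab3": 0.0}

    def test_constant_offset(self):
        t = self._surf(np.full((4, 4), 5.0), np.full((4, 4), 10.0),
                       np.full((4, 4), 15.0))
        p = self._surf(t.ab1 + 3, t.ab2 + 3, t.ab3 + 3)
        assert boundary_error(p, t) == {"ab1": 3.0, "ab2": 3.0, "ab3": 3.0}

    def test_undefined_columns_excluded_hand_worked_case(self):
        # 4 columns; column 2 undefined in pred: mean over cols {0,1,3}
        # of |pred-truth| = (1 + 2 + 5) / 3
        truth = self._surf([[10.0, 10.0, 10.0, 10.0]] ,
                           [[20.0, 20.0, 20.0, 20.0]],
                           [[30.0, 30.0, 30.0, 30.0]])
        pred_ab1 = np.array([[11.0, 12.0, np.nan, 15.0]])
        pred = self._surf(pred_ab1, pred_ab1 + 10, pred_ab1 + 20)
        err = boundary_error(pred, truth)
        assert err["ab1"] == pytest.approx(8.0 / 3.0)

    def test_no_common_columns_errors(self):
        t = self._surf(np.full((2, 2), 5.0), np.full((2, 2), 6.0),
                       np.full((2, 2), 7.0))
        p = self._surf(np.full((2, 2), np.nan), np.full((2, 2), np.nan),
                       np.full((2, 2), np.nan))
        with pytest.raises(ValueError):
            boundary_error(p, t)


class TestThickness:
    def test_flat_layers_give_uniform_thickness(self):
        b = tuple(np.full((8, 8), d) for d in (20.0, 50.0, 80.0))
        spec = LayeredPhantomSpec(shape=(100, 8, 8), boundaries=b,
                                  speckle_shape=None, additive_sigma=0.0)
        _, labels = make_layered_volume(spec)
        maps = thickness_stats(labels, voxel_size_um=5.0)
        assert maps["epidermis"].mean == pytest.approx(150.0)
        assert maps["epidermis"].variance == pytest.approx(0.0)
        assert maps["dermis"].mean == pytest.approx(150.0)

    def test_sinusoidal_boundary_variance_closed_form(self):
        # thickness(x) = T0 + a sin(2 pi x / nx): variance -> a^2/2 (in vox)
        nx, ny = 64, 8
        x = np.arange(nx)[:, None]
        a = 6.0
        ab3 = 40 + a * np.sin(2 * np.pi * x / nx) * np.ones((1, ny))
        b = (np.full((nx, ny), 8.0), np.full((nx, ny), 20.0), ab3)
        spec = LayeredPhantomSpec(shape=(64, nx, ny), boundaries=b,
                                  speckle_shape=None, additive_sigma=0.0)
        _, labels = make_layered_volume(spec)
        maps = thickness_stats(labels, voxel_size_um=5.0)
        expected = a ** 2 / 2 * 5.0 ** 2
        assert maps["dermis"].variance == pytest.approx(expected, rel=0.10)

    def test_empty_layer_gives_null_summary(self):
        labels = np.zeros((20, 4, 4), np.uint8)  # no tissue at all
        maps = thickness_stats(labels, voxel_size_um=5.0)
        assert maps["epidermis"].empty and maps["dermis"].empty
        assert np.all(np.isnan(maps["epidermis"].values_um))

    def test_summary_invariant_to_lateral_permutation(self):
        _, _, _, labels = _phantom_bscans(seed=7)
        maps1 = thickness_stats(labels, voxel_size_um=5.0)
        rng = np.random.default_rng(0)
        perm = rng.permutation(labels.shape[1])
        maps2 = thickness_stats(labels[:, perm, :], voxel_size_um=5.0)
        for layer in ("epidermis", "dermis"):
            assert maps1[layer].mean == pytest.approx(maps2[layer].mean)
            assert maps1[layer].variance == pytest.approx(maps2[layer].variance)
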