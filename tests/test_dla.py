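"""Autoencoder features: patch extraction, training, codes, traversal."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from lungsig import dla
from lungsig.volumes import LesionVolume

from conftest import make_sphere_volume


def blob_patches(n: int, shape=(32, 32), seed: int = 0, radii=(4.0, 10.0)):
    """Soft circular blobs with varying radius on a noisy background."""
    rng = np.random.default_rng(seed)
    ax = np.arange(shape[0])
    gx, gy = np.meshgrid(ax, ax, indexing="ij")
    patches, radii_out = [], []
    for _ in range(n):
        r = rng.uniform(*radii)
        cx, cy = shape[0] / 2 + rng.uniform(-2, 2, 2)
        d = np.sqrt((gx - cx) ** 2 + (gy - cy) ** 2)
        img = 1.0 / (1.0 + np.exp((d - r) / 1.5))
        img = np.clip(img + rng.normal(0, 0.02, shape), 0, 1)
        patches.append(img)
        radii_out.append(r)
    return patches, np.array(radii_out)


@pytest.fixture(scope="module")
def trained():
    patches, radii = blob_patches(120, seed=1)
    model = dla.train_autoencoder(patches, latent_dim=16, epochs=25, seed=0)
    return model, patches, radii


class TestPatchExtraction:
    def test_patch_centre_inside_mask(self):
        vol = make_sphere_volume(radius_mm=8.0)
        patch = dla.extract_patch(vol, patch_mm=24.0, patch_shape=(32, 32))
        idx = vol.largest_roi_slice()
        assert patch.slice_index == idx
        centre = patch.intensities[16, 16]
        assert centre > patch.intensities[0, 0]  # lesion centre bright vs corner

    def test_constant_volume_maps_to_zero(self):
        img = np.full((20, 20, 8), -300.0)
        mask = np.zeros_like(img, dtype=bool)
        mask[8:12, 8:12, 4] = True
        vol = LesionVolume(img, (1, 1, 1), mask)
        patch = dla.extract_patch(vol, patch_mm=10.0, patch_shape=(16, 16))
        assert np.all(patch.intensities == 0.0)

    def test_values_outside_window_are_clipped(self):
        base = make_sphere_volume(radius_mm=6.0, inside_hu=200.0, outside_hu=-980.0)
        hot = LesionVolume(
            np.where(base.image > 0, 3000.0, -1500.0), base.spacing, base.mask
        )
        ref = LesionVolume(
            np.where(base.image > 0, 500.0, -1200.0), base.spacing, base.mask
        )
        a = dla.extract_patch(hot, patch_mm=20.0, patch_shape=(16, 16))
        b = dla.extract_patch(ref, patch_mm=20.0, patch_shape=(16, 16))
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_out_of_volume_patch_warns(self):
        vol = make_sphere_volume(radius_mm=6.0, shape=(20, 20, 8))
        with pytest.warns(UserWarning, match="outside"):
            dla.extract_patch(vol, patch_mm=60.0, patch_shape=(16, 16))


class TestTraining:
    def test_training_reduces_reconstruction_mse(self, trained):
        model, patches, _ = trained
        assert model.loss_history[-1] < model.loss_history[0]
        held_out, _ = blob_patches(40, seed=99)
        x = np.stack([p.ravel() for p in held_out])
        untrained = dla.train_autoencoder(held_out[:20], latent_dim=16, epochs=0, seed=0)
        assert model.mse(x) < untrained.mse(x)

    def test_deterministic_given_seed(self):
        patches, _ = blob_patches(24, seed=2)
        a = dla.train_autoencoder(patches, latent_dim=8, epochs=3, seed=5)
        b = dla.train_autoencoder(patches, latent_dim=8, epochs=3, seed=5)
        assert a.loss_history == b.loss_history
        assert all(np.array_equal(w1, w2) for w1, w2 in zip(a.weights, b.weights))

    def test_default_latent_dim_is_32(self):
        patches, _ = blob_patches(20, seed=3)
        model = dla.train_autoencoder(patches, epochs=1, seed=0)
        code = dla.encode(model, patches[0])
        assert len(code) == 32
        assert list(code.index[:2]) == ["dla_00", "dla_01"]

    def test_too_few_patches_rejected(self):
        patches, _ = blob_patches(10, seed=4)
        with pytest.raises(ValueError, match=">= 16"):
            dla.train_autoencoder(patches)

    def test_latent_dim_exceeding_patch_rejected(self):
        patches, _ = blob_patches(20, shape=(8, 8), seed=4)
        with pytest.raises(ValueError, match="latent_dim"):
            dla.train_autoencoder(patches, latent_dim=64)


class TestCodesAndDecoding:
    def test_round_trip_mse_below_90th_percentile(self, trained):
        model, patches, _ = trained
        x = np.stack([p.ravel() for p in patches])
        errs = np.mean((model.reconstruct(x) - x) ** 2, axis=1)
        p0 = patches[0]
        rt = float(np.mean((dla.decode(model, dla.encode(model, p0)) - p0) ** 2))
        assert rt <= np.quantile(errs, 0.9)

    def test_decode_zero_vector_valid_patch(self, trained):
        model, _, _ = trained
        img = dla.decode(model, np.zeros(model.latent_dim))
        assert img.shape == model.patch_shape
        assert img.min() >= 0.0 and img.max() <= 1.0

    def test_batch_encode_order_preserving(self, trained):
        model, patches, _ = trained
        batch = dla.encode_batch(model, patches[:10])
        assert batch.shape == (10, model.latent_dim)
        single = dla.encode(model, patches[3])
        np.testing.assert_allclose(batch.iloc[3].to_numpy(), single.to_numpy())

    def test_shape_mismatch_rejected(self, trained):
        model, _, _ = trained
        with pytest.raises(ValueError, match="shape"):
            dla.encode(model, np.zeros((8, 8)))
        with pytest.raises(ValueError, match="latent"):
            dla.decode(model, np.zeros(3))

    def test_save_load_round_trip(self, trained, tmp_path):
        model, patches, _ = trained
        dla.save_model(model, tmp_path / "model.npz")
        back = dla.load_model(tmp_path / "model.npz")
        np.testing.assert_allclose(
            dla.encode(model, patches[0]), dla.encode(back, patches[0])
        )


class TestTraversal:
    def test_traversal_counts_and_identity(self, trained):
        model, patches, _ = trained
        z = dla.encode(model, patches[0])
        imgs = dla.latent_traversal(model, patches[0], 2, np.linspace(-1, 1, 5))
        assert len(imgs) == 5
        ident = dla.latent_traversal(model, patches[0], 2, [z.iloc[2]])[0]
        recon = dla.decode(model, z.to_numpy())
        np.testing.assert_allclose(ident, recon)

    def test_out_of_range_dimension_rejected(self, trained):
        model, patches, _ = trained
        with pytest.raises(ValueError, match="dim_index"):
            dla.latent_traversal(model, patches[0], 99, [0.0])

    def test_some_dimension_controls_lesion_area(self, trained):
        """On size-varying blobs, one latent axis sweeps decoded area monotonically."""
        model, patches, _ = trained
        codes = dla.encode_batch(model, patches)
        best = 0.0
        for d in range(model.latent_dim):
            lo, hi = codes.iloc[:, d].min(), codes.iloc[:, d].max()
            vals = np.linspace(lo, hi, 7)
            areas = [
                float((im > 0.5).sum())
                for im in dla.latent_traversal(model, patches[0], d, vals)
            ]
            if np.std(areas) == 0:
                continue
            rho = spearmanr(vals, areas).statistic
            if abs(rho) > abs(best):
                best = rho
        assert abs(best) >= 0.9

    def test_latent_codes_carry_class_signal(self):
        """Latent AUC > 0.6 for some dimension when size differs by class."""
        from lungsig.evaluation import delong_auc_variance

        small, _ = blob_patches(60, seed=7, radii=(4.0, 7.0))
        large, _ = blob_patches(60, seed=8, radii=(8.0, 12.0))
        model = dla.train_autoencoder(small + large, latent_dim=16, epochs=20, seed=1)
        codes = dla.encode_batch(model, small + large)
        y = np.array([0] * 60 + [1] * 60)
        aucs = [
            max(a, 1 - a)
            for a in (
                delong_auc_variance(codes.iloc[:, j].to_numpy(), y)[0]
                for j in range(codes.shape[1])
            )
        ]
        assert max(aucs) > 0.6
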