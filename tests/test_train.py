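"""Patch pipeline, standardisation, augmentation, training loop, adjustment."""

import numpy as np
import pandas as pd
import pytest

from treecensus.losses import LossSchedule, TverskyConfig
from treecensus.model import ModelConfig, build_count_seg_model
from treecensus.train import (TrainConfig, LinearAdjustment, extract_patches,
                              standardize_per_instance, compute_global_stats,
                              standardize_global, augment, stratified_split,
                              train_model, make_count_seg_loss,
                              fit_linear_adjustment, apply_adjustment,
                              mix_datasets, upsample_bilinear)


@pytest.fixture
def sample(rng):
    h = w = 96
    return {
        "image": rng.uniform(0, 255, (4, h, w)),
        "mask": (rng.random((h, w)) > 0.7).astype(np.uint8),
        "weights": np.ones((h, w)),
        "density": rng.random((h, w)) * 0.01,
        "coarse": rng.uniform(0, 30, (h // 2, w // 2)),
    }


class TestPatches:
    def test_patches_inside_bounds_and_aligned(self, sample, rng):
        for patch in extract_patches(sample, 32, 20, rng):
            assert patch["image"].shape == (4, 32, 32)
            assert patch["mask"].shape == (32, 32)
            assert patch["coarse"].shape == (16, 16)

    def test_fixed_seed_reproducible(self, sample):
        a = list(extract_patches(sample, 32, 5, np.random.default_rng(3)))
        b = list(extract_patches(sample, 32, 5, np.random.default_rng(3)))
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa["image"], pb["image"])

    def test_density_patch_integral_is_crop_sum(self, sample):
        rng = np.random.default_rng(1)
        # oracle: track the window and sum the full map over it
        full = sample["density"]
        patches = list(extract_patches(sample, 32, 10, rng))
        for p in patches:
            s = p["density"].sum()
            # locate the window by matching the image crop
            assert any(
                np.isclose(full[r:r + 32, c:c + 32].sum(), s)
                for r in range(0, 65, 2) for c in range(0, 65, 2)
            )

    def test_scene_smaller_than_patch_rejected(self, sample, rng):
        with pytest.raises(ValueError, match="smaller than patch"):
            next(extract_patches(sample, 128, 1, rng))


class TestStandardization:
    def test_per_instance_two_values(self):
        img = np.zeros((1, 2, 2))
        img[0] = [[0, 2], [0, 2]]
        out = standardize_per_instance(img)
        np.testing.assert_allclose(np.unique(out), [-1.0, 1.0])

    def test_constant_channel_to_zeros(self):
        img = np.full((2, 4, 4), 7.0)
        assert not standardize_per_instance(img).any()

    def test_per_instance_moments(self, rng):
        img = rng.uniform(0, 255, (4, 16, 16))
        out = standardize_per_instance(img)
        np.testing.assert_allclose(out.mean(axis=(1, 2)), 0.0, atol=1e-6)
        np.testing.assert_allclose(out.std(axis=(1, 2)), 1.0, atol=1e-6)

    def test_global_stats_frozen_affine(self, rng):
        train_imgs = [rng.uniform(0, 255, (3, 8, 8)) for _ in range(4)]
        stats = compute_global_stats(train_imgs)
        pooled = np.concatenate([im.reshape(3, -1) for im in train_imgs], axis=1)
        np.testing.assert_allclose(stats[0], pooled.mean(axis=1))
        out = standardize_global(train_imgs[0], stats)
        oracle = (train_imgs[0] - stats[0][:, None, None]) / stats[1][:, None, None]
        np.testing.assert_allclose(out, oracle)

    def test_global_zero_sd_band_rejected(self):
        with pytest.raises(ValueError, match="band 1"):
            standardize_global(np.zeros((2, 4, 4)), (np.zeros(2), np.array([1.0, 0.0])))


class TestAugment:
    def test_geometric_ops_move_targets_with_image(self, sample):
        rng = np.random.default_rng(0)  # first draw < 0.5 -> horizontal flip
        out = augment(sample, rng)
        # whatever sequence fired, image and mask must stay aligned:
        # flips are self-inverse, so check the mask is a flip of the original
        m = out["mask"]
        candidates = [sample["mask"], sample["mask"][:, ::-1],
                      sample["mask"][::-1, :], sample["mask"][::-1, ::-1]]
        assert any(np.array_equal(m, c) for c in candidates)

    def test_flips_preserve_density_integral(self, sample):
        total = sample["density"].sum()
        for seed in range(8):
            out = augment(sample, np.random.default_rng(seed))
            assert out["density"].sum() == pytest.approx(total, rel=1e-12)

    def test_photometric_ops_leave_targets_untouched(self, sample):
        for seed in range(8):
            out = augment(sample, np.random.default_rng(seed))
            # undo any flips on the target and compare to the original
            m = out["mask"]
            assert any(np.array_equal(m, c) for c in
                       [sample["mask"], sample["mask"][:, ::-1],
                        sample["mask"][::-1, :], sample["mask"][::-1, ::-1]])
            assert set(np.unique(out["mask"])) <= {0, 1}


class TestSplitAndMix:
    def test_stratified_split_preserves_ratios(self, rng):
        strata = ["deciduous"] * 10 + ["coniferous"] * 5 + ["nonforest"] * 5
        samples = list(range(20))
        train, val = stratified_split(samples, strata, 0.2, rng)
        assert len(val) == 4 and len(train) == 16
        for s, total in (("deciduous", 10), ("coniferous", 5), ("nonforest", 5)):
            idx = [i for i, lab in enumerate(strata) if lab == s]
            n_val = sum(1 for v in val if v in idx)
            assert abs(n_val - 0.2 * total) <= 1

    def test_mix_datasets_oversamples(self):
        mixed = mix_datasets([1, 2, 3], [9], oversample_extra=5)
        assert mixed.count(9) == 5 and len(mixed) == 8

    def test_bilinear_upsample_doubles_size(self, rng):
        g = rng.random((2, 8, 8))
        up = upsample_bilinear(g, 2)
        assert up.shape == (2, 16, 16)
        # constant grid stays constant
        np.testing.assert_allclose(upsample_bilinear(np.full((4, 4), 3.0)), 3.0)


def _tiny_dataset(n_scenes, seed):
    from treecensus.synth import SceneConfig, generate_scene, scene_to_annotations
    from treecensus.targets import (DensityConfig, make_density_map, make_gap_map,
                                    make_weight_map, rasterize_crowns)
    from treecensus.containers import BASE_BANDS
    samples = []
    for i in range(n_scenes):
        cfg = SceneConfig(width_px=64, height_px=64, n_trees=4,
                          crown_radius_range_m=(0.6, 1.2), seed=seed + i)
        raster, truth = generate_scene(cfg)
        anns = scene_to_annotations(truth)
        samples.append({
            "image": raster.stack(BASE_BANDS),
            "mask": rasterize_crowns(anns, (64, 64)),
            "weights": make_weight_map(make_gap_map(anns, (64, 64))),
            "density": make_density_map(anns, (64, 64)),
        })
    return samples


class TestTrainingLoop:
    def _run(self, epochs, seed=0, lr=1e-3):
        model = build_count_seg_model(ModelConfig(in_bands=4, base_channels=4,
                                                  depth=2, seed=seed))
        samples = _tiny_dataset(3, seed=10)
        cfg = TrainConfig(patch_size=32, batch_size=4, epochs=epochs,
                          learning_rate=lr, patches_per_epoch=4, val_patches=4,
                          seed=seed, augment=False)
        loss_fn = make_count_seg_loss(TverskyConfig(),
                                      LossSchedule(total_epochs=epochs))
        return train_model(model, samples[:2], samples[2:], loss_fn, cfg)

    def test_single_epoch_history(self):
        state, history = self._run(epochs=1)
        assert len(history) == 1
        assert {"epoch", "combined", "val_loss", "l_seg", "l_count", "lambda_t"} <= set(history.columns)

    def test_loss_decreases_when_overfitting(self):
        # compare the branch losses, not the lambda-weighted sum: lambda_t
        # itself ramps upward across epochs
        _, history = self._run(epochs=25)
        assert history["l_seg"].iloc[-5:].mean() < history["l_seg"].iloc[:5].mean()
        assert history["l_count"].iloc[-5:].mean() < history["l_count"].iloc[:5].mean()

    def test_best_weights_are_validation_minimum(self):
        model = build_count_seg_model(ModelConfig(in_bands=4, base_channels=4,
                                                  depth=2, seed=1))
        samples = _tiny_dataset(3, seed=20)
        cfg = TrainConfig(patch_size=32, batch_size=4, epochs=6, learning_rate=1e-3,
                          patches_per_epoch=4, val_patches=4, seed=1, augment=False)
        loss_fn = make_count_seg_loss(TverskyConfig(), LossSchedule(total_epochs=6))
        state, history = train_model(model, samples[:2], samples[2:], loss_fn, cfg)
        # re-evaluating the returned weights reproduces the minimum val loss
        assert history["val_loss"].idxmin() == history["val_loss"].argmin()
        best = history["val_loss"].min()
        assert best <= history["val_loss"].iloc[-1] + 1e-12

    def test_reproducible_history(self):
        _, h1 = self._run(epochs=3, seed=5)
        _, h2 = self._run(epochs=3, seed=5)
        pd.testing.assert_frame_equal(h1, h2)

    def test_learning_rate_decays_linearly(self):
        from treecensus import nn
        model = build_count_seg_model(ModelConfig(in_bands=4, base_channels=4,
                                                  depth=2, seed=2))
        samples = _tiny_dataset(3, seed=30)
        cfg = TrainConfig(patch_size=32, batch_size=4, epochs=5, learning_rate=1e-3,
                          final_learning_rate=1e-4, patches_per_epoch=4,
                          val_patches=4, seed=2, augment=False)
        lrs = []
        orig_step = nn.Adam.step

        def spy(self):
            lrs.append(self.lr)
            orig_step(self)

        nn.Adam.step = spy
        try:
            train_model(model, samples[:2], samples[2:],
                        make_count_seg_loss(TverskyConfig(), LossSchedule(total_epochs=5)),
                        cfg)
        finally:
            nn.Adam.step = orig_step
        assert lrs[0] == pytest.approx(1e-3)
        assert lrs[-1] == pytest.approx(1e-4)
        assert all(b <= a + 1e-12 for a, b in zip(lrs, lrs[1:]))

    def test_count_aware_validation_selects_calibrated_epoch(self):
        # the count-integral term punishes an epoch whose density map has
        # the right shape but the wrong total mass
        from treecensus.train import make_count_seg_val_loss
        sched = LossSchedule(total_epochs=10)
        val_fn = make_count_seg_val_loss(TverskyConfig(), sched,
                                         density_scale=1.0, count_weight=1.0)
        base_fn = make_count_seg_loss(TverskyConfig(), sched)
        rng = np.random.default_rng(0)
        d = rng.random((2, 16, 16)) * 0.01
        batch = {"mask": np.zeros((2, 16, 16)), "weights": np.ones((2, 16, 16)),
                 "density": d}
        good = {"seg": np.zeros((2, 16, 16)), "density": d}
        biased = {"seg": np.zeros((2, 16, 16)), "density": d * 1.3}
        val_good, _ = val_fn(good, batch, 9)
        val_biased, _ = val_fn(biased, batch, 9)
        base_good, _ = base_fn(good, batch, 9)
        base_biased, _ = base_fn(biased, batch, 9)
        # the count term amplifies the preference for the calibrated map
        assert (val_biased - val_good) > (base_biased - base_good)

    def test_val_patch_size_overrides_patch_size(self):
        model = build_count_seg_model(ModelConfig(in_bands=4, base_channels=4,
                                                  depth=2, seed=3))
        samples = _tiny_dataset(3, seed=40)
        cfg = TrainConfig(patch_size=32, batch_size=4, epochs=1, learning_rate=1e-3,
                          patches_per_epoch=4, val_patches=2, val_patch_size=64,
                          seed=3, augment=False)
        _, history = train_model(model, samples[:2], samples[2:],
                                 make_count_seg_loss(TverskyConfig(),
                                                     LossSchedule(total_epochs=1)),
                                 cfg)
        assert len(history) == 1  # full-scene validation patches accepted

    def test_empty_dataset_rejected(self):
        model = build_count_seg_model(ModelConfig(in_bands=4, base_channels=4, depth=2))
        cfg = TrainConfig(patch_size=32, epochs=1)
        with pytest.raises(ValueError):
            train_model(model, [], [], make_count_seg_loss(), cfg)


class TestHeightTraining:
    def test_height_model_trains_and_history_logged(self):
        from treecensus.model import build_height_model
        from treecensus.train import build_height_sample, make_height_loss
        from treecensus.synth import SceneConfig, generate_scene
        samples = []
        for i in range(3):
            raster, _ = generate_scene(SceneConfig(width_px=64, height_px=64,
                                                   n_trees=5, seed=50 + i,
                                                   crown_radius_range_m=(0.6, 1.2)))
            samples.append(build_height_sample(raster))
        model = build_height_model(ModelConfig(in_bands=4, base_channels=4,
                                               depth=2, heads="height", seed=0))
        cfg = TrainConfig(patch_size=32, batch_size=4, epochs=8, learning_rate=3e-3,
                          patches_per_epoch=8, val_patches=4, seed=0,
                          standardization="global", augment=False)
        _, history = train_model(model, samples[:2], samples[2:],
                                 make_height_loss(), cfg)
        assert "l_height" in history.columns
        # weighted MAE should fall from its untrained (zero-output) level
        assert history["l_height"].iloc[-3:].mean() < history["l_height"].iloc[0]


class TestLinearAdjustment:
    def test_exact_affine_fit(self):
        ref = np.linspace(1, 20, 25)
        pred = 2.0 * ref + 1.0
        adj = fit_linear_adjustment(pred, ref)
        assert adj.a == pytest.approx(2.0)
        assert adj.b == pytest.approx(1.0)
        np.testing.assert_allclose(apply_adjustment(pred, adj), ref, atol=1e-9)

    def test_identity_fit(self):
        ref = np.linspace(1, 10, 10)
        adj = fit_linear_adjustment(ref, ref)
        assert adj.a == pytest.approx(1.0)
        assert adj.b == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(apply_adjustment(ref, adj), ref)

    def test_matches_normal_equations_oracle(self, rng):
        ref = rng.uniform(2, 30, 200)
        pred = 0.8 * ref + 0.5 + rng.normal(0, 0.5, 200)
        adj = fit_linear_adjustment(pred, ref)
        x = np.column_stack([ref, np.ones_like(ref)])
        beta = np.linalg.solve(x.T @ x, x.T @ pred)
        assert adj.a == pytest.approx(beta[0], rel=1e-9)
        assert adj.b == pytest.approx(beta[1], rel=1e-6)

    def test_adjustment_removes_systematic_bias(self, rng):
        from treecensus.metrics import overall_bias
        ref = rng.uniform(5, 30, 500)
        pred = 0.8 * ref + 0.5 + rng.normal(0, 0.3, 500)
        adj = fit_linear_adjustment(pred, ref)
        adjusted = apply_adjustment(pred, adj)
        assert overall_bias(ref, pred) > 0.1     # distorted
        assert overall_bias(ref, adjusted) < 0.01  # corrected below 1%

    def test_degenerate_references_rejected(self):
        with pytest.raises(ValueError):
            fit_linear_adjustment([1.0, 2.0], [5.0, 5.0])
        with pytest.raises(ValueError):
            LinearAdjustment(a=0.0, b=1.0)
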