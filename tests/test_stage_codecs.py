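import numpy as np
import pytest

from cardioshape import stage_models as sm


class TestPhaseCodec:
    def test_peak_normalized_gaussian(self):
        c = sm.encode_phase_curve(12, 30)
        assert c.values[12] == 1.0
        assert c.values[16] == pytest.approx(np.exp(-0.5), abs=1e-12)
        for k in range(1, 12):
            assert c.values[12 - k] == pytest.approx(c.values[12 + k])

    def test_decode_inverts_encode(self):
        for t in range(30):
            assert sm.decode_es_phase(sm.encode_phase_curve(t, 30)) == t

    def test_decode_averages_slices(self):
        a = sm.encode_phase_curve(10, 30)
        b = sm.encode_phase_curve(12, 30)
        assert sm.decode_es_phase([a, b]) == 11

    def test_flat_curve_warns_and_breaks_ties_early(self):
        with pytest.warns(UserWarning, match="flat"):
            assert sm.decode_es_phase([np.full(30, 0.5)]) == 0

    def test_validity_masks_restrict_average(self):
        a = sm.encode_phase_curve(25, 30)
        mask = np.zeros(30, dtype=bool)
        mask[:20] = True  # the true peak is masked out
        assert sm.decode_es_phase([a], [mask]) == 19
        with pytest.raises(ValueError):
            sm.decode_es_phase([a], [np.zeros(30, dtype=bool)])

    def test_sigma_validation(self):
        with pytest.raises(ValueError):
            sm.encode_phase_curve(5, 30, sigma=0)


class TestHeatmapCodec:
    def test_peak_at_landmark_and_sigma_falloff(self):
        hm = sm.encode_landmark_heatmap({"A": (100, 60)}, (128, 128))
        m = hm.maps[0]
        assert m[100, 60] == 1.0
        assert m[100, 72] == pytest.approx(np.exp(-0.5), abs=1e-12)  # 12 px away
        pt, conf = sm.decode_heatmap(m)
        np.testing.assert_allclose(pt, [100, 60], atol=0.1)
        assert conf == 1.0

    def test_single_pixel_decodes_exactly(self):
        m = np.zeros((32, 32))
        m[7, 21] = 0.4
        pt, conf = sm.decode_heatmap(m)
        np.testing.assert_allclose(pt, [7, 21])
        assert conf == pytest.approx(0.4)

    def test_subpixel_center_recovered(self):
        hm = sm.encode_landmark_heatmap({"A": (50.5, 50.5)}, (128, 128))
        pt, _ = sm.decode_heatmap(hm.maps[0])
        assert np.abs(pt - [50.5, 50.5]).max() <= 0.25

    def test_all_zero_map_is_absent(self):
        pt, conf = sm.decode_heatmap(np.zeros((16, 16)))
        assert pt is None and conf == 0.0

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            sm.encode_landmark_heatmap({"A": (200, 10)}, (128, 128))

    def test_two_landmarks_two_unimodal_maps(self):
        hm = sm.encode_landmark_heatmap({"A": (20, 20), "B": (90, 100)}, (128, 128))
        assert len(hm.maps) == 2
        for m, rc in zip(hm.maps, [(20, 20), (90, 100)]):
            assert np.unravel_index(np.argmax(m), m.shape) == rc


class TestViewTables:
    def test_segmentation_class_maps(self):
        assert len(sm.encode_segmentation_classes("2Ch LT")) == 3
        assert len(sm.encode_segmentation_classes("2Ch RT")) == 3
        assert len(sm.encode_segmentation_classes("4Ch")) == 5
        assert len(sm.encode_segmentation_classes("SAx")) == 5
        with pytest.raises(ValueError):
            sm.encode_segmentation_classes("LVOT")
        with pytest.raises(ValueError):
            sm.encode_segmentation_classes(sm.ViewLabel.OTHER)

    def test_landmark_sets(self):
        assert sm.landmark_set_for_view("3Ch") == ["MV1", "MV2", "AV1", "AV2"]
        assert len(sm.landmark_set_for_view("4Ch")) == 5
        assert sm.landmark_set_for_view("RVOT") == ["PV1", "PV2"]
        assert sm.landmark_set_for_view("SAx") == ["RV1", "RV2"]
        with pytest.raises(ValueError):
            sm.landmark_set_for_view("2Ch LT")

    def test_eight_view_categories(self):
        assert len(sm.ViewLabel) == 8


class TestAugment:
    def test_zero_magnitude_is_identity(self, rng):
        img = rng.normal(size=(32, 32))
        out, _ = sm.augment(img, None, {"rotation": 0.0, "zoom": 0.0,
                                        "translation": 0.0}, seed=1)
        np.testing.assert_allclose(out, img)

    def test_unknown_augmentation_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown"):
            sm.augment(rng.normal(size=(8, 8)), None, {"warp": 1}, seed=0)

    def test_time_roll_shifts_phase_label_jointly(self, rng):
        frames = rng.normal(size=(30, 8, 8))
        curve = sm.encode_phase_curve(10, 30)
        for seed in range(5):
            out, lab = sm.augment(frames, curve, {"time-roll": 1}, seed=seed)
            k = int(np.argmax(lab.values)) - 10
            np.testing.assert_allclose(out[(10 + k) % 30], frames[10])

    def test_rotation_moves_heatmap_peak_consistently(self):
        pts = {"A": np.array([40.0, 80.0])}
        hm = sm.encode_landmark_heatmap(pts, (128, 128))
        spec = {"rotation": 20.0}
        img, hm2 = sm.augment(hm.maps[0].copy(), hm, spec, seed=3)
        _img2, pts2 = sm.augment(hm.maps[0].copy(), dict(pts), spec, seed=3)
        peak, _ = sm.decode_heatmap(np.clip(hm2.maps[0], 0, None))
        np.testing.assert_allclose(peak, pts2["A"], atol=0.5)

    def test_mask_labels_stay_integer(self, rng):
        mask = (rng.uniform(size=(32, 32)) > 0.5).astype(np.int64) * 3
        _img, out = sm.augment(rng.normal(size=(32, 32)), mask,
                               {"rotation": 15.0}, seed=2)
        assert out.dtype == mask.dtype
        assert set(np.unique(out)) <= {0, 3}


class TestTrainingMechanics:
    def test_training_reproducible_and_loss_decreases(self, rng):
        data = []
        for k in range(24):
            img = rng.normal(0, 0.1, (64, 64))
            if k % 2:
                img[16:48, 16:48] += 1.0
            data.append((img, k % 2))
        cfg = dict(stage="slice", epochs=4, seed=5, input_size=64,
                   augmentation={})
        m1 = sm.train_stage("slice", data, sm.TrainConfig(**cfg))
        m2 = sm.train_stage("slice", data, sm.TrainConfig(**cfg))
        assert m1.log == m2.log
        assert m1.log[-1] < m1.log[0]

    def test_contract_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sm.train_stage("view", [(np.zeros((8, 8)), 0)],
                           sm.TrainConfig(stage="phase"))
        with pytest.raises(ValueError):
            sm.train_stage("view", [], sm.TrainConfig(stage="view"))

    def test_checkpoint_round_trip(self, tmp_path, rng):
        data = [(rng.normal(size=(32, 32)), k % 2) for k in range(8)]
        m = sm.train_stage("slice", data, sm.TrainConfig(
            stage="slice", epochs=1, seed=0, input_size=32, augmentation={}))
        sm.save_model(m, tmp_path / "ckpt")
        m2 = sm.load_model(tmp_path / "ckpt")
        img = rng.normal(size=(32, 32))
        np.testing.assert_allclose(m.predict_slice(img)[1],
                                   m2.predict_slice(img)[1], atol=1e-6)

    def test_prediction_invariant_to_intensity_scaling(self, rng):
        data = [(rng.normal(size=(32, 32)), k % 2) for k in range(8)]
        m = sm.train_stage("slice", data, sm.TrainConfig(
            stage="slice", epochs=1, seed=0, input_size=32, augmentation={}))
        img = rng.normal(size=(32, 32))
        p1 = m.predict_slice(img)[1]
        p2 = m.predict_slice(img * 7.3)[1]
        np.testing.assert_allclose(p1, p2, atol=1e-5)
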