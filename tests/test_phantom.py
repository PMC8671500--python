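"""Phantom cohort generation, lesion model, preprocessing operators."""

import dataclasses

import numpy as np
import pytest
import yaml
from sklearn.metrics import roc_auc_score

from advcad import phantom as ph
from .conftest import tiny_config


def flat_image(value=20000, size=(64, 64)):
    return ph.PhantomImage(
        pixels=np.full(size, value, dtype=np.uint16), label="negative",
        realness="real", patient_id="PX", view="CC", laterality="L")


class TestCohortGeneration:
    def test_deterministic_under_fixed_seed(self, tiny_cohort):
        again = ph.generate_cohort(tiny_config())
        assert again.assignment == tiny_cohort.assignment
        for a, b in zip(tiny_cohort.train, again.train):
            assert a.patient_id == b.patient_id
            assert np.array_equal(a.pixels, b.pixels)

    def test_patient_level_split_is_leak_free(self, desk_cohort):
        parts = {p: {im.patient_id for im in desk_cohort.partition(p)}
                 for p in ("train", "val", "test")}
        assert parts["train"] & parts["val"] == set()
        assert parts["train"] & parts["test"] == set()
        assert parts["val"] & parts["test"] == set()
        counts = {p: len(v) for p, v in parts.items()}
        assert counts == {"train": 82, "val": 9, "test": 9}  # 80/10/10 per class

    def test_positive_patients_contribute_only_lesion_views(self, desk_cohort):
        for part in ("train", "val", "test"):
            for im in desk_cohort.partition(part):
                pos_patient = im.label == "positive"
                assert bool(im.lesion_specs) == pos_patient
                if pos_patient:
                    # single affected breast
                    assert im.laterality in ("L", "R")

    def test_negative_patients_contribute_both_breasts(self, desk_cohort):
        allimg = desk_cohort.train + desk_cohort.val + desk_cohort.test
        by_patient = {}
        for im in allimg:
            by_patient.setdefault(im.patient_id, []).append(im)
        for pid, imgs in by_patient.items():
            if imgs[0].label == "negative":
                assert {i.laterality for i in imgs} == {"L", "R"}
                assert len(imgs) == 4
            else:
                assert len(imgs) == 2

    def test_realized_class_balance_within_binomial_bounds(self, desk_cohort):
        labels = {}
        for part in ("train", "val", "test"):
            for im in desk_cohort.partition(part):
                labels[im.patient_id] = im.label
        frac = np.mean([v == "positive" for v in labels.values()])
        n = len(labels)
        p = 0.285
        half_width = 2.576 * np.sqrt(p * (1 - p) / n)
        assert abs(frac - p) <= half_width

    def test_lesion_contrast_exceeds_background_everywhere(self, tiny_cohort):
        for im in tiny_cohort.train:
            if im.label == "positive":
                assert ph.contrast_statistic(im) > 0

    def test_contrast_statistic_separates_classes(self, desk_cohort):
        allimg = desk_cohort.train + desk_cohort.val + desk_cohort.test
        cfg = ph.PhantomConfig(n_patients=100, seed=11)
        rng = np.random.default_rng(1)
        scores, labels = [], []
        for im in allimg:
            if im.label == "positive":
                scores.append(ph.contrast_statistic(im))
                labels.append(1)
            else:
                probe = ph._sample_lesion_spec(cfg, rng)
                scores.append(ph.contrast_statistic(im, probe_spec=probe))
                labels.append(0)
        assert roc_auc_score(labels, scores) > 0.95

    def test_too_small_cohort_raises(self):
        with pytest.raises(ValueError):
            ph.generate_cohort(dataclasses.replace(tiny_config(), n_patients=5))


class TestInsertLesion:
    def test_zero_contrast_is_identity(self):
        img = flat_image()
        spec = ph.LesionSpec((32, 32), 8, 0.0, 0, 4)
        out = ph.insert_lesion(img, spec)
        assert np.array_equal(out.pixels, img.pixels)

    def test_additive_and_input_untouched(self, rng):
        img = flat_image()
        before = img.pixels.copy()
        spec = ph.LesionSpec((30, 28), 6, 0.2, 4, 5)
        out = ph.insert_lesion(img, spec, rng)
        assert np.array_equal(img.pixels, before)
        assert (out.pixels.astype(int) >= img.pixels.astype(int)).all()
        assert out.label == "positive" and out.lesion_specs == [spec]

    def test_center_pixel_matches_profile_formula(self):
        out = ph.insert_lesion(flat_image(20000),
                               ph.LesionSpec((32, 32), 10, 0.2, 0, 5))
        assert out.pixels[32, 32] == 20000 + round(0.2 * 65535)

    def test_out_of_bounds_spec_raises(self):
        with pytest.raises(ValueError):
            ph.insert_lesion(flat_image(), ph.LesionSpec((2, 2), 10, 0.2, 0, 5))


class TestResize:
    def test_identity_when_target_equals_source(self, tiny_cohort):
        px = tiny_cohort.train[0].pixels
        out = ph.resize_ratio_preserved(px, *px.shape)
        assert np.array_equal(out, px)

    def test_downscale_uses_min_ratio_and_zero_pads(self):
        rng = np.random.default_rng(0)
        src = (rng.random((4096, 3328)) * 65535).astype(np.uint16)
        out = ph.resize_ratio_preserved(src, 1728, 1408)
        assert out.shape == (1728, 1408) and out.dtype == np.uint16
        scale = min(1728 / 4096, 1408 / 3328)   # height ratio wins
        new_w = round(3328 * scale)
        assert new_w < 1408
        assert (out[:, new_w:] == 0).all()      # padded columns are zero
        # content aspect ratio preserved within one pixel
        assert abs(1728 / new_w - 4096 / 3328) < 4096 / 3328 / new_w + 1e-9

    def test_bad_targets_raise(self, tiny_cohort):
        with pytest.raises(ValueError):
            ph.resize_ratio_preserved(tiny_cohort.train[0].pixels, 0, 10)


class TestAugment:
    def test_deterministic_given_seed(self, tiny_cohort):
        px = tiny_cohort.train[0].pixels
        assert np.array_equal(ph.augment(px, 5), ph.augment(px, 5))

    def test_identity_parameters_return_input(self, tiny_cohort):
        px = tiny_cohort.train[0].pixels
        out = ph.apply_affine(px, rotation_deg=0, scale=1, shear_deg=0,
                              vertical_flip=False)
        assert np.array_equal(out, px)

    def test_range_and_dtype_preserved(self, tiny_cohort):
        px = tiny_cohort.train[0].pixels
        for seed in range(5):
            out = ph.augment(px, seed)
            assert out.dtype == np.uint16
            assert out.min() >= 0 and out.max() <= 65535

    def test_vertical_flip_only(self, tiny_cohort):
        px = tiny_cohort.train[0].pixels
        out = ph.apply_affine(px, vertical_flip=True)
        assert np.array_equal(out, px[::-1, :])


class TestNormalization:
    def test_constant_at_channel_mean_standardizes_to_zero(self):
        px = np.full((8, 8), round(ph.VGG_MEAN[0] * 65535)).astype(np.uint16)
        out = ph.normalize_for_model(px, 1)
        assert np.allclose(out, 0.0, atol=1e-4)

    def test_three_channels_are_affine_copies_of_one_plane(self, tiny_cohort):
        px = tiny_cohort.train[0].pixels
        out = ph.normalize_for_model(px, 3)
        x01 = px / 65535.0
        for c in range(3):
            assert np.allclose(out[c], (x01 - ph.VGG_MEAN[c]) / ph.VGG_SD[c])

    def test_round_trip_recovers_unit_plane(self, rng):
        px = (rng.random((16, 12)) * 65535).astype(np.uint16)
        back = ph.denormalize_from_model(ph.normalize_for_model(px, 3))
        assert np.allclose(back, px / 65535.0, atol=1e-6)

    def test_invalid_channel_count(self, rng):
        with pytest.raises(ValueError):
            ph.normalize_for_model(np.zeros((4, 4), dtype=np.uint16), 2)


class TestIO:
    def test_cohort_round_trip(self, tmp_path, tiny_cohort):
        ph.save_cohort(tiny_cohort, tmp_path)
        loaded = ph.load_cohort(tmp_path)
        assert loaded.assignment == tiny_cohort.assignment
        for a, b in zip(tiny_cohort.test, loaded.test):
            assert np.array_equal(a.pixels, b.pixels)
            assert a.label == b.label and a.view == b.view
            assert len(a.lesion_specs) == len(b.lesion_specs)

    def test_yaml_config_round_trip(self, tmp_path):
        cfg = tiny_config()
        raw = {
            "n_patients": cfg.n_patients,
            "positive_fraction": cfg.positive_fraction,
            "image_height": cfg.image_height,
            "image_width": cfg.image_width,
            "lesion": {"radius_range": [3, 6]},
            "split_fractions": [0.6, 0.2, 0.2],
            "seed": 3,
        }
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(raw))
        parsed = ph.config_from_yaml(path)
        assert parsed.n_patients == cfg.n_patients
        assert parsed.lesion.radius_range == (3, 6)
        assert parsed.split_fractions == (0.6, 0.2, 0.2)

    def test_invalid_split_fractions_rejected(self):
        with pytest.raises(ValueError):
            ph.PhantomConfig(split_fractions=(0.8, 0.1, 0.2)).validate()
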