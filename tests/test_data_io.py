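"""Manifests, preprocessing, augmentation balancing and splitting."""

import numpy as np
import pytest

from retwave import data_io
from retwave.data_io import (
    AugmentationConfig, Manifest, ManifestError, ManifestRecord, PreprocessConfig,
    SplitConfig, apply_transform, balance_classes, enhance_contrast,
    parse_provenance, preprocess_image, read_manifest, sample_transform, split,
    write_manifest,
)


def _manifest(counts, prefix="img"):
    records = []
    for grade, n in counts.items():
        for i in range(n):
            records.append(ManifestRecord(f"{prefix}_g{grade}_{i}", f"{prefix}_g{grade}_{i}.png", grade))
    return Manifest(records)


class TestManifestIO:
    def test_read_toy_csv(self, tmp_path):
        p = tmp_path / "labels.csv"
        p.write_text("image,level\na,0\nb,2\nc,4\n")
        m = read_manifest(p)
        assert len(m) == 3
        assert m.grades().tolist() == [0, 2, 4]

    def test_out_of_range_grade_reports_row(self, tmp_path):
        p = tmp_path / "labels.csv"
        p.write_text("image,level\na,0\nb,7\n")
        with pytest.raises(ManifestError, match="row 3.*grade 7"):
            read_manifest(p)

    def test_duplicate_id_reports_row(self, tmp_path):
        p = tmp_path / "labels.csv"
        p.write_text("image,level\na,0\na,1\n")
        with pytest.raises(ManifestError, match="row 3.*duplicate"):
            read_manifest(p)

    def test_missing_file_reported_when_checked(self, tmp_path):
        p = tmp_path / "labels.csv"
        p.write_text("image,level\nnope,0\nalso_nope,1\n")
        with pytest.raises(ManifestError) as err:
            read_manifest(p, check_files=True)
        assert len(err.value.problems) == 2

    def test_roundtrip(self, tmp_path):
        m = _manifest({0: 2, 3: 1})
        out = tmp_path / "out.csv"
        write_manifest(m, out)
        assert read_manifest(out) == m


class TestContrast:
    def test_constant_image_unchanged(self):
        img = np.full((16, 16, 3), 0.4)
        for method in ("clahe", "stretch"):
            out = enhance_contrast(img, PreprocessConfig(contrast_method=method))
            assert np.allclose(out, img)

    @pytest.mark.parametrize("method", ["clahe", "stretch"])
    def test_low_contrast_ramp_gains_spread(self, method):
        ramp = np.linspace(0.45, 0.55, 32)[None, :, None] * np.ones((32, 1, 3))
        out = enhance_contrast(ramp, PreprocessConfig(contrast_method=method))
        assert out.std() > ramp.std()

    def test_bounded_on_random_images(self, rng):
        cfg = PreprocessConfig()
        for _ in range(100):
            out = enhance_contrast(rng.random((12, 12, 3)), cfg)
            assert out.min() >= 0.0 and out.max() <= 1.0

    def test_deterministic(self, rng):
        img = rng.random((20, 20, 3))
        a = enhance_contrast(img)
        b = enhance_contrast(img)
        assert np.array_equal(a, b)


class TestPreprocess:
    CFG = PreprocessConfig(resize_side=40, crop_side=32, contrast_method="none")

    def test_output_shape(self, rng):
        out = preprocess_image(rng.random((50, 70, 3)), self.CFG, training=False)
        assert out.shape == (32, 32, 3)

    def test_fixed_seed_reproduces_crop(self, rng):
        img = rng.random((64, 64, 3))
        a = preprocess_image(img, self.CFG, training=True, rng=np.random.default_rng(4))
        b = preprocess_image(img, self.CFG, training=True, rng=np.random.default_rng(4))
        assert np.array_equal(a, b)

    def test_training_crop_is_subwindow_of_resized(self, rng):
        from skimage.transform import resize

        cfg = PreprocessConfig(resize_side=40, crop_side=32, hflip_prob=0.0,
                               contrast_method="none")
        img = rng.random((64, 64, 3))
        out = preprocess_image(img, cfg, training=True, rng=np.random.default_rng(9))
        resized = resize(img, (40, 40), order=1, mode="edge", anti_aliasing=True,
                         preserve_range=True)
        matches = [
            (oy, ox)
            for oy in range(9)
            for ox in range(9)
            if np.allclose(out, np.clip(resized[oy:oy + 32, ox:ox + 32], 0, 1))
        ]
        assert len(matches) == 1

    def test_eval_mode_is_center_crop_no_flip(self, rng):
        img = rng.random((64, 64, 3))
        a = preprocess_image(img, self.CFG, training=False)
        b = preprocess_image(img, self.CFG, training=False,
                             rng=np.random.default_rng(999))
        assert np.array_equal(a, b)


class TestAugmentation:
    def test_descriptor_replay_is_bit_exact(self, rng):
        img = rng.random((32, 32, 3))
        desc = sample_transform(rng, AugmentationConfig())
        a = apply_transform(img, desc)
        b = apply_transform(img, desc)
        assert np.array_equal(a, b)

    def test_provenance_string_roundtrip(self, rng):
        desc = sample_transform(rng, AugmentationConfig())
        s = data_io.describe_transform("img7", desc)
        src, parsed = parse_provenance(s)
        assert src == "img7"
        assert parsed == desc

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="width_shift"):
            AugmentationConfig(width_shift=0.9)
        with pytest.raises(ValueError, match="zoom_range"):
            AugmentationConfig(zoom_range=(1.1, 1.3))


class TestBalancing:
    def test_counts_balanced_to_majority(self):
        m = _manifest({0: 10, 1: 2, 2: 5})
        out = balance_classes(m)
        assert out.counts() == {0: 10, 1: 10, 2: 10}
        augmented = [r for r in out if r.is_augmented]
        assert len(augmented) == 13

    def test_originals_untouched_and_majority_never_augmented(self):
        m = _manifest({0: 10, 1: 2, 2: 5})
        out = balance_classes(m)
        assert out.records[: len(m)] == m.records
        assert not any(r.is_augmented for r in out if r.grade == 0)

    def test_already_balanced_returned_unchanged(self):
        m = _manifest({0: 4, 1: 4})
        assert balance_classes(m) is m

    def test_eyepacs_grade1_deficit(self):
        # full-scale grade counts: majority 25,810 vs grade-1 2,443
        m = _manifest({0: 25810, 1: 2443})
        out = balance_classes(m)
        aug = [r for r in out if r.is_augmented]
        assert len(aug) == 23367
        assert out.counts() == {0: 25810, 1: 25810}

    def test_augmented_records_carry_replayable_descriptor(self):
        m = _manifest({0: 3, 1: 1})
        out = balance_classes(m, AugmentationConfig(seed=2))
        aug = [r for r in out if r.is_augmented]
        for r in aug:
            parsed = parse_provenance(r.provenance)
            assert parsed is not None
            src, desc = parsed
            assert src.startswith("img_g1")
            assert abs(desc["shift_x"]) <= 0.1 and 0.9 <= desc["zoom"] <= 1.1


class TestSplit:
    def test_eighty_twenty(self):
        m = _manifest({0: 50, 1: 30, 2: 20})
        train, test = split(m, SplitConfig(seed=0))
        assert len(train) == 80 and len(test) == 20
        assert train.counts() == {0: 40, 1: 24, 2: 16}

    def test_disjoint_and_exhaustive(self):
        m = _manifest({0: 13, 1: 9})
        train, test = split(m, SplitConfig(seed=1))
        ids_train = {r.image_id for r in train}
        ids_test = {r.image_id for r in test}
        assert not ids_train & ids_test
        assert ids_train | ids_test == {r.image_id for r in m}

    def test_order_invariance(self):
        m = _manifest({0: 10, 1: 10})
        shuffled = Manifest(list(reversed(m.records)))
        t1, _ = split(m, SplitConfig(seed=3))
        t2, _ = split(shuffled, SplitConfig(seed=3))
        assert {r.image_id for r in t1} == {r.image_id for r in t2}

    def test_unstratified_overall_rounding(self):
        m = _manifest({0: 7, 1: 3})
        train, test = split(m, SplitConfig(stratified=False, seed=0))
        assert len(train) == 8 and len(test) == 2

    def test_too_few_records(self):
        with pytest.raises(ValueError, match="at least 5"):
            split(_manifest({0: 4}))

    def test_singleton_class_warns_and_goes_to_train(self):
        m = _manifest({0: 8, 1: 1})
        with pytest.warns(UserWarning, match="grade 1"):
            train, test = split(m, SplitConfig(seed=0))
        assert sum(r.grade == 1 for r in train) == 1
        assert all(r.grade == 0 for r in test)
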