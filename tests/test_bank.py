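"""Object bank: intrinsic luminance, rotations, glyph generation."""

import gzip
import struct

import numpy as np
import pytest

import bindmaps as bm
from bindmaps.bank import read_idx, read_bank, write_bank


class TestLuminanceValue:
    @pytest.mark.parametrize("image, expected", [
        (np.zeros((28, 28)), 0.0),
        (np.full((28, 28), 255), 255.0),
        (np.array([[0, 255], [0, 255]]), 127.5),
    ])
    def test_mean_over_all_pixels(self, image, expected):
        assert bm.luminance_value(image) == pytest.approx(expected)

    def test_background_pixels_count(self):
        # one bright pixel in a 2x2 patch: mean includes the 3 black pixels
        img = np.array([[200, 0], [0, 0]])
        assert bm.luminance_value(img) == pytest.approx(50.0)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            bm.luminance_value(np.zeros((0, 0)))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bm.luminance_value(np.full((2, 2), 300))


class TestLuminanceLevel:
    @pytest.mark.parametrize("value, expected", [
        (0.0, "low"),
        (31.874, "low"),
        (31.875, "medium_low"),       # 255/8: closed below
        (63.75, "medium_high"),       # 2*255/8
        (95.624, "medium_high"),
        (95.625, "high"),             # 3*255/8
        (255.0, "high"),
    ])
    def test_printed_thresholds(self, value, expected):
        assert bm.luminance_level(value) == expected

    def test_outside_range_rejected(self):
        for v in (-1.0, 255.1):
            with pytest.raises(ValueError):
                bm.luminance_level(v)

    def test_partition_has_no_gaps_or_overlaps(self):
        # every value on a fine grid maps to exactly one level, and the
        # level sequence is monotone in the value
        grid = np.linspace(0, 255, 4001)
        order = {name: i for i, name in enumerate(bm.LUMINANCE_LEVELS)}
        indices = [order[bm.luminance_level(v)] for v in grid]
        assert indices == sorted(indices)
        assert set(indices) == {0, 1, 2, 3}


class TestRotation:
    def _exemplar(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, size=(12, 12)).astype(np.uint8)
        lv = bm.luminance_value(img)
        return bm.ObjectExemplar(img, "t-shirt", lv, bm.luminance_level(lv),
                                 0)

    def test_up_is_identity(self):
        ex = self._exemplar()
        assert np.array_equal(bm.rotate_object(ex, "up").image, ex.image)

    def test_down_twice_is_identity(self):
        ex = self._exemplar()
        once = bm.rotate_object(ex, "down")
        img = np.rot90(once.image, k=bm.ORIENTATIONS.index("down"))
        assert np.array_equal(img, ex.image)

    @pytest.mark.parametrize("orientation", bm.ORIENTATIONS)
    def test_luminance_invariant_under_rotation(self, orientation):
        ex = self._exemplar()
        rot = bm.rotate_object(ex, orientation)
        assert bm.luminance_value(rot.image) == pytest.approx(
            ex.luminance_value)

    def test_four_quarter_turns_recover_original(self):
        ex = self._exemplar()
        img = ex.image
        for _ in range(4):
            img = np.rot90(img)
        assert np.array_equal(img, ex.image)

    def test_non_square_rejected(self):
        img = np.zeros((10, 12), dtype=np.uint8)
        with pytest.raises(ValueError):
            bm.bank.rotate_image(img, "left")


class TestGlyphBank:
    def test_counts_and_determinism(self):
        cfg = bm.BankConfig(class_names=("t-shirt", "pant", "shoe", "bag"),
                            n_per_class=10, seed=7)
        bank1 = bm.build_bank(cfg)
        bank2 = bm.build_bank(cfg)
        assert len(bank1) == 40
        for e1, e2 in zip(bank1.exemplars, bank2.exemplars):
            assert np.array_equal(e1.image, e2.image)
            assert e1.class_label == e2.class_label

    def test_labels_consistent_with_pixels(self, small_mixed_bank):
        for e in small_mixed_bank.exemplars:
            assert e.luminance_value == pytest.approx(
                bm.luminance_value(e.image))
            assert e.luminance_level == bm.luminance_level(e.luminance_value)

    def test_rotation_asymmetry_of_every_class(self, small_mixed_bank,
                                               small_tops_bank):
        # no glyph may coincide with any of its own quarter-turns,
        # otherwise orientation would be undecodable
        for bank in (small_mixed_bank, small_tops_bank):
            for cls in bank.class_names:
                img = bank.by_class(cls)[0].image
                for k in (1, 2, 3):
                    assert not np.array_equal(np.rot90(img, k), img)

    def test_classes_discriminable_by_nearest_centroid(self):
        train = bm.build_bank(bm.mixed_bank_config(n_per_class=30, seed=1))
        test = bm.build_bank(bm.mixed_bank_config(n_per_class=15, seed=2))
        classes = train.class_names
        centroids = {c: np.mean([e.image for e in train.by_class(c)], axis=0)
                     for c in classes}
        correct = sum(
            min(classes, key=lambda c: np.sum(
                (e.image.astype(float) - centroids[c]) ** 2)) == e.class_label
            for e in test.exemplars)
        # far above the 25% chance level
        assert correct / len(test.exemplars) > 0.6

    def test_equal_means_remove_identity_luminance_dependency(self):
        cfg = bm.BankConfig(class_names=("t-shirt", "pant", "shoe", "bag"),
                            n_per_class=150, seed=5,
                            glyph_luminance_means=(90, 90, 90, 90),
                            glyph_luminance_sds=(40, 40, 40, 40))
        bank = bm.build_bank(cfg)
        means, ses = [], []
        for c in cfg.class_names:
            vals = np.array([e.luminance_value for e in bank.by_class(c)])
            means.append(vals.mean())
            ses.append(vals.std(ddof=1) / np.sqrt(len(vals)))
        spread = max(means) - min(means)
        assert spread < 2 * max(ses) + 1e-9

    def test_class_dependent_means_by_default(self, small_mixed_bank):
        # mixed bank: shoes darker than bags, mirroring intrinsic
        # class-luminance dependency
        shoe = np.mean([e.luminance_value
                        for e in small_mixed_bank.by_class("shoe")])
        bag = np.mean([e.luminance_value
                       for e in small_mixed_bank.by_class("bag")])
        assert shoe < bag

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            bm.BankConfig(class_names=("t-shirt", "sofa"))

    def test_luminance_means_length_checked(self):
        with pytest.raises(ValueError):
            bm.BankConfig(class_names=("t-shirt", "pant"),
                          glyph_luminance_means=(90,))

    def test_roundtrip_io(self, tmp_path, small_mixed_bank):
        write_bank(small_mixed_bank, tmp_path)
        back = read_bank(tmp_path, small_mixed_bank.config)
        assert len(back) == len(small_mixed_bank)
        for a, b in zip(small_mixed_bank.exemplars, back.exemplars):
            assert np.array_equal(a.image, b.image)
            assert a.class_label == b.class_label
            assert a.luminance_level == b.luminance_level


def _write_idx(path, array):
    with gzip.open(path, "wb") as fh:
        fh.write(bytes([0, 0, 0x08, array.ndim]))
        fh.write(struct.pack(f">{array.ndim}I", *array.shape))
        fh.write(array.astype(np.uint8).tobytes())


class TestFashionAdapter:
    def test_idx_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        arr = rng.integers(0, 256, size=(5, 28, 28)).astype(np.uint8)
        _write_idx(tmp_path / "x.gz", arr)
        assert np.array_equal(read_idx(tmp_path / "x.gz"), arr)

    def test_synthetic_idx_bank(self, tmp_path):
        # synthetic stand-in for the real Fashion-MNIST files: random
        # blobs with the right labels, exercising the full adapter path
        rng = np.random.default_rng(0)
        images, labels = [], []
        for label in (0, 1, 7, 8):
            for _ in range(6):
                img = np.zeros((28, 28), dtype=np.uint8)
                img[6:22, 6:22] = rng.integers(40, 200)
                if label == 8:
                    img[0:4, 10:18] = 120  # handle reaching the top rows
                images.append(img)
                labels.append(label)
        _write_idx(tmp_path / "train-images-idx3-ubyte.gz",
                   np.stack(images))
        _write_idx(tmp_path / "train-labels-idx1-ubyte.gz",
                   np.array(labels))
        cfg = bm.BankConfig(source="fashion_mnist", n_per_class=5,
                            data_dir=str(tmp_path), seed=0)
        bank = bm.build_bank(cfg)
        assert len(bank) == 20
        assert {e.class_label for e in bank.exemplars} == set(
            cfg.class_names)

    def test_missing_files_rejected(self, tmp_path):
        cfg = bm.BankConfig(source="fashion_mnist", n_per_class=5,
                            data_dir=str(tmp_path))
        with pytest.raises(FileNotFoundError):
            bm.build_bank(cfg)
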