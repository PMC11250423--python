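"""Constraint-map ordering, target encoding and scoring."""

from itertools import combinations, permutations

import numpy as np
import pytest

import bindmaps as bm
from bindmaps.mapping import map_key
from tests.conftest import make_record

CODEC = bm.AttributeCodec(class_names=("t-shirt", "pant", "shoe", "bag"))


def brute_force_order(records, map_name, codec):
    """Independent oracle: minimum over all permutations under the
    lexicographic (map key, location key) sort key."""
    def perm_key(perm):
        return tuple((map_key(records[i], map_name, codec),
                      map_key(records[i], "location", codec))
                     for i in perm)
    return min(permutations(range(len(records))), key=perm_key)


class TestMapKey:
    def test_location_key_is_row_major(self):
        recs = [make_record(location=5), make_record(location=1),
                make_record(location=6)]
        ordering = bm.order_objects(recs, "location", CODEC)
        assert ordering.permutation == (1, 0, 2)  # locations 1, 5, 6
        assert ordering.tie_groups == ()

    def test_identity_key_follows_class_order(self):
        recs = [make_record(identity="shoe", location=1),
                make_record(identity="t-shirt", location=2),
                make_record(identity="pant", location=3)]
        ordering = bm.order_objects(recs, "identity", CODEC)
        assert [recs[i].identity for i in ordering.permutation] == \
            ["t-shirt", "pant", "shoe"]

    def test_luminance_low_first_with_tie(self):
        recs = [make_record(level="high", location=1),
                make_record(level="low", location=5),
                make_record(level="low", location=3)]
        ordering = bm.order_objects(recs, "luminance", CODEC)
        assert [recs[i].luminance_level for i in ordering.permutation] == \
            ["low", "low", "high"]
        assert ordering.tie_groups == ((0, 1),)

    def test_unknown_map_rejected(self):
        with pytest.raises(ValueError):
            map_key(make_record(), "colour", CODEC)


class TestOrderObjects:
    def test_single_object_identity_permutation(self):
        ordering = bm.order_objects([make_record()], "identity", CODEC)
        assert ordering.permutation == (0,)

    def test_two_pants_one_bag_tie_group(self):
        recs = [make_record(identity="bag", location=2),
                make_record(identity="pant", location=7),
                make_record(identity="pant", location=4)]
        ordering = bm.order_objects(recs, "identity", CODEC)
        assert [recs[i].identity for i in ordering.permutation] == \
            ["pant", "pant", "bag"]
        assert ordering.tie_groups == ((0, 1),)

    @pytest.mark.parametrize("map_name", bm.MAP_NAMES)
    def test_agrees_with_brute_force_on_samples(self, map_name):
        rng = np.random.default_rng(0)
        classes = CODEC.class_names
        for _ in range(300):
            locs = rng.choice(range(1, 10), size=3, replace=False)
            recs = [make_record(identity=classes[rng.integers(4)],
                                level=bm.LUMINANCE_LEVELS[rng.integers(4)],
                                orientation=bm.ORIENTATIONS[rng.integers(4)],
                                location=int(l)) for l in locs]
            ordering = bm.order_objects(recs, map_name, CODEC)
            assert ordering.permutation == brute_force_order(recs, map_name,
                                                             CODEC)


class TestEncodeTargets:
    def test_self_map_location_targets_sorted(self):
        recs = [make_record(location=8), make_record(location=2),
                make_record(location=5)]
        enc = bm.encode_targets(recs, ("location",), "location", CODEC)
        assert list(enc.class_index["location"]) == [1, 4, 7]  # 2, 5, 8

    def test_identity_under_location_map(self):
        recs = [make_record(identity="pant", location=7),
                make_record(identity="shoe", location=2),
                make_record(identity="bag", location=5)]
        enc = bm.encode_targets(recs, ("identity",), "location", CODEC)
        assert [CODEC.class_names[i] for i in enc.class_index["identity"]] \
            == ["shoe", "bag", "pant"]

    def test_pair_task_shares_one_ordering(self):
        recs = [make_record(identity="bag", location=1),
                make_record(identity="t-shirt", location=9),
                make_record(identity="pant", location=5)]
        enc = bm.encode_targets(recs, ("identity", "location"), "identity",
                                CODEC)
        # identity map: t-shirt first, then pant, then bag
        assert [CODEC.class_names[i] for i in enc.class_index["identity"]] \
            == ["t-shirt", "pant", "bag"]
        # the location block reports locations in that same slot order
        assert [CODEC.locations[i] for i in enc.class_index["location"]] \
            == [9, 5, 1]

    def test_onehot_rows_sum_to_one(self):
        recs = [make_record(location=l) for l in (1, 5, 9)]
        enc = bm.encode_targets(recs, ("identity", "location"), "location",
                                CODEC)
        for attr in enc.task_attributes:
            np.testing.assert_allclose(enc.onehot[attr].sum(axis=1), 1.0)

    def test_permutation_invariance_of_inputs(self):
        rng = np.random.default_rng(1)
        classes = CODEC.class_names
        for _ in range(50):
            locs = rng.choice(range(1, 10), size=3, replace=False)
            recs = [make_record(identity=classes[rng.integers(4)],
                                level=bm.LUMINANCE_LEVELS[rng.integers(4)],
                                orientation=bm.ORIENTATIONS[rng.integers(4)],
                                location=int(l)) for l in locs]
            for map_name in bm.MAP_NAMES:
                base = bm.encode_targets(recs, ("identity", "luminance"),
                                         map_name, CODEC)
                for perm in permutations(range(3)):
                    enc = bm.encode_targets([recs[i] for i in perm],
                                            ("identity", "luminance"),
                                            map_name, CODEC)
                    for attr in base.task_attributes:
                        assert np.array_equal(enc.class_index[attr],
                                              base.class_index[attr])

    def test_location_map_is_translation_invariant(self):
        # shifting all objects one grid column right keeps the ordering
        recs = [make_record(identity=c, location=l) for c, l in
                [("bag", 1), ("pant", 4), ("shoe", 8)]]
        shifted = [make_record(identity=c, location=l) for c, l in
                   [("bag", 2), ("pant", 5), ("shoe", 9)]]
        o1 = bm.order_objects(recs, "location", CODEC)
        o2 = bm.order_objects(shifted, "location", CODEC)
        assert o1.permutation == o2.permutation


def _pred_from_indices(indices, n_classes):
    """Build a (1, slots, classes) score array with argmax at indices."""
    arr = np.zeros((1, len(indices), n_classes))
    arr[0, np.arange(len(indices)), indices] = 1.0
    return arr


class TestScorePredictions:
    def _truth(self, map_name="identity"):
        recs = [make_record(identity="bag", location=2),
                make_record(identity="pant", location=7),
                make_record(identity="pant", location=4)]
        return bm.encode_targets(recs, ("location",), map_name, CODEC)

    def test_perfect_predictions_score_one(self):
        t = self._truth()
        pred = {"location": _pred_from_indices(t.class_index["location"], 9)}
        assert bm.score_predictions(pred, [t]) == 1.0

    def test_one_wrong_head_per_slot(self):
        t = self._truth()
        idx = t.class_index["location"].copy()
        idx[0] = (idx[0] + 1) % 9
        pred = {"location": _pred_from_indices(idx, 9)}
        assert bm.score_predictions(pred, [t]) == pytest.approx(2 / 3)
        assert bm.score_predictions(pred, [t], mode="per_image") == 0.0

    def test_tied_pair_swapped_free_vs_canonical(self):
        # two pants tie under the identity map (slots 0 and 1); predicting
        # their locations in swapped order is correct under free scoring
        t = self._truth("identity")
        idx = t.class_index["location"].copy()
        idx[[0, 1]] = idx[[1, 0]]
        pred = {"location": _pred_from_indices(idx, 9)}
        assert bm.score_predictions(pred, [t], tie_policy="free") == 1.0
        assert bm.score_predictions(pred, [t]) == pytest.approx(1 / 3)

    def test_free_policy_permutes_attribute_blocks_jointly(self):
        # swapping tied slots must swap identity and location together
        recs = [make_record(identity="pant", location=7),
                make_record(identity="pant", location=4)]
        t = bm.encode_targets(recs, ("identity", "location"), "identity",
                              CODEC)
        loc_idx = t.class_index["location"][::-1].copy()
        id_idx = t.class_index["identity"].copy()  # both "pant"
        pred = {"identity": _pred_from_indices(id_idx, 4),
                "location": _pred_from_indices(loc_idx, 9)}
        assert bm.score_predictions(pred, [t], tie_policy="free") == 1.0

    def test_shape_mismatch_rejected(self):
        t = self._truth()
        pred = {"location": np.zeros((2, 3, 9))}
        with pytest.raises(ValueError):
            bm.score_predictions(pred, [t])


class TestExportEncodings:
    def test_npz_shapes(self, tmp_path):
        recs1 = [make_record(identity="bag", location=1),
                 make_record(identity="pant", location=5),
                 make_record(identity="shoe", location=9)]
        recs2 = [make_record(identity="t-shirt", location=2),
                 make_record(identity="pant", location=4),
                 make_record(identity="bag", location=7)]

        class S:
            def __init__(self, objects):
                self.objects = objects

        path = tmp_path / "enc.npz"
        bm.export_encodings([S(recs1), S(recs2)], ("identity", "location"),
                            "location", CODEC, path)
        with np.load(path) as z:
            assert z["identity_onehot"].shape == (2, 3, 4)
            assert z["location_onehot"].shape == (2, 3, 9)
            assert z["permutation"].shape == (2, 3)
            assert str(z["map_name"]) == "location"
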