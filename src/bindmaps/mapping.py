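"""Constraint maps: slot ordering and one-hot target encoding.

A *constraint map* fixes the order in which a network's output slots
report the objects of a scene.  Ordering by relative location (top row
first, then left to right) gives both pathways of a two-pathway network a
shared spatial index; ordering by identity, luminance level or
orientation does the same with a non-spatial key.  Because locations are
unique within a scene the location map never has ties; the other maps can
tie, in which case the mutual order of the tied objects is free.  For
training, ties are broken canonically (by location) so that targets are
well defined; for scoring, tied slots may optionally be credited under
their best permutation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations, product

import numpy as np

from .bank import LUMINANCE_LEVELS, ORIENTATIONS
from .scenes import ObjectRecord, location_to_rowcol

__all__ = [
    "MAP_NAMES",
    "ATTRIBUTES",
    "MapOrdering",
    "TargetEncoding",
    "AttributeCodec",
    "map_key",
    "order_objects",
    "encode_targets",
    "score_predictions",
]

MAP_NAMES = ("location", "identity", "luminance", "orientation")
ATTRIBUTES = ("identity", "luminance", "orientation", "location")


@dataclass(frozen=True)
class AttributeCodec:
    """Class vocabularies for the four attributes under one dataset
    variant.  Default key orders follow the conventional report order
    (any consistent order would do): identities in configured class
    order, luminance low->high, orientation up/left/down/right,
    location row-major."""

    class_names: tuple[str, ...]
    locations: tuple[int, ...] = tuple(range(1, 10))
    luminance_order: tuple[str, ...] = LUMINANCE_LEVELS
    orientation_order: tuple[str, ...] = ORIENTATIONS
    grid_cols: int = 3

    def n_classes(self, attribute: str) -> int:
        return {"identity": len(self.class_names),
                "luminance": len(self.luminance_order),
                "orientation": len(self.orientation_order),
                "location": len(self.locations)}[attribute]

    def class_index(self, attribute: str, record: ObjectRecord) -> int:
        if attribute == "identity":
            return self.class_names.index(record.identity)
        if attribute == "luminance":
            return self.luminance_order.index(record.luminance_level)
        if attribute == "orientation":
            return self.orientation_order.index(record.orientation)
        if attribute == "location":
            return self.locations.index(record.location)
        raise ValueError(f"unknown attribute {attribute!r}")


def map_key(record: ObjectRecord, map_name: str,
            codec: AttributeCodec) -> tuple:
    """Sortable key of one object under a constraint map.

    location -> (grid row, grid col): top row first, then left to right;
    identity / luminance / orientation -> index in the configured order.
    """
    if map_name == "location":
        return location_to_rowcol(record.location, codec.grid_cols)
    if map_name in ("identity", "luminance", "orientation"):
        return (codec.class_index(map_name, record),)
    raise ValueError(f"unknown map name {map_name!r}")


def _location_key(record: ObjectRecord, codec: AttributeCodec) -> tuple:
    return location_to_rowcol(record.location, codec.grid_cols)


@dataclass(frozen=True)
class MapOrdering:
    """A permutation of a scene's objects under one constraint map.

    ``permutation[slot]`` is the index of the object reported in that
    slot.  Slots whose objects share the map key form ``tie_groups``;
    their mutual order is canonical (by location) but semantically free.
    """

    map_name: str
    permutation: tuple[int, ...]
    tie_groups: tuple[tuple[int, ...], ...]


def order_objects(records: list[ObjectRecord], map_name: str,
                  codec: AttributeCodec,
                  tie_policy: str = "canonical") -> MapOrdering:
    """Sort a scene's objects by their map key.

    Ties are broken by the location key so training labels are
    deterministic; the tie groups are recorded so scoring can treat the
    tied slots as permutation-equivalent (``tie_policy="free"``).
    """
    if not records:
        raise ValueError("need at least one object")
    if tie_policy not in ("canonical", "free"):
        raise ValueError(f"unknown tie policy {tie_policy!r}")
    keys = [map_key(r, map_name, codec) for r in records]
    perm = sorted(range(len(records)),
                  key=lambda i: (keys[i], _location_key(records[i], codec)))
    tie_groups = []
    slot = 0
    while slot < len(perm):
        end = slot
        while end + 1 < len(perm) and keys[perm[end + 1]] == keys[perm[slot]]:
            end += 1
        if end > slot:
            tie_groups.append(tuple(range(slot, end + 1)))
        slot = end + 1
    return MapOrdering(map_name, tuple(perm), tuple(tie_groups))


@dataclass(frozen=True)
class TargetEncoding:
    """Per-slot one-hot targets for one scene and task.

    ``onehot[attr]`` has shape (n_slots, n_classes(attr)); slot order is
    fixed by a single MapOrdering shared by all task attributes.
    """

    task_attributes: tuple[str, ...]
    ordering: MapOrdering
    class_index: dict  # attr -> (n_slots,) int array
    onehot: dict       # attr -> (n_slots, n_classes) float array


def encode_targets(records: list[ObjectRecord],
                   task_attributes: tuple[str, ...] | list[str],
                   map_name: str, codec: AttributeCodec) -> TargetEncoding:
    """One-hot per-slot targets, slots ordered by the constraint map."""
    task_attributes = tuple(task_attributes)
    if not task_attributes:
        raise ValueError("task_attributes must be non-empty")
    ordering = order_objects(records, map_name, codec)
    class_index, onehot = {}, {}
    for attr in task_attributes:
        nc = codec.n_classes(attr)
        idx = np.array([codec.class_index(attr, records[i])
                        for i in ordering.permutation])
        class_index[attr] = idx
        oh = np.zeros((len(records), nc))
        oh[np.arange(len(records)), idx] = 1.0
        onehot[attr] = oh
    return TargetEncoding(task_attributes, ordering, class_index, onehot)


def _sample_correct(pred_idx: dict, true_idx: dict, tie_groups, tie_policy,
                    n_slots: int) -> int:
    """Number of correct heads for one sample, maximised over tie-group
    permutations when tie_policy='free' (one joint slot permutation is
    applied to every attribute)."""
    attrs = list(true_idx)
    if tie_policy == "canonical" or not tie_groups:
        return sum(int(np.sum(pred_idx[a] == true_idx[a])) for a in attrs)
    group_perms = [list(permutations(g)) for g in tie_groups]
    best = -1
    for combo in product(*group_perms):
        slot_map = list(range(n_slots))  # slot -> slot whose truth to use
        for group, perm in zip(tie_groups, combo):
            for s, p in zip(group, perm):
                slot_map[s] = p
        total = sum(int(np.sum(pred_idx[a] == true_idx[a][slot_map]))
                    for a in attrs)
        best = max(best, total)
    return best


def score_predictions(predicted: dict, truths: list[TargetEncoding],
                      mode: str = "per_slot",
                      tie_policy: str = "canonical") -> float:
    """Accuracy of slot-wise class scores against encoded targets.

    Parameters
    ----------
    predicted
        attr -> array of shape (n_samples, n_slots, n_classes) holding
        scores (argmax is taken per slot).
    truths
        one TargetEncoding per sample.
    mode
        "per_slot": fraction of output heads with correct argmax;
        "per_image": fraction of samples with every head correct.
    tie_policy
        "canonical" scores against the canonical slot order; "free"
        credits tied slots under their best joint permutation.
    """
    if mode not in ("per_slot", "per_image"):
        raise ValueError(f"unknown mode {mode!r}")
    attrs = truths[0].task_attributes
    n_samples = len(truths)
    for a in attrs:
        if predicted[a].shape[0] != n_samples:
            raise ValueError("prediction/truth sample count mismatch")
    n_slots = truths[0].onehot[attrs[0]].shape[0]
    heads_per_sample = n_slots * len(attrs)
    total_correct = 0
    images_correct = 0
    for i, t in enumerate(truths):
        pred_idx = {a: np.argmax(predicted[a][i], axis=-1) for a in attrs}
        true_idx = {a: t.class_index[a] for a in attrs}
        c = _sample_correct(pred_idx, true_idx, t.ordering.tie_groups,
                            tie_policy, n_slots)
        total_correct += c
        images_correct += int(c == heads_per_sample)
    if mode == "per_slot":
        return total_correct / (heads_per_sample * n_samples)
    return images_correct / n_samples


def export_encodings(scenes, task_attributes, map_name: str,
                     codec: AttributeCodec, path) -> None:
    """Write stacked one-hot target tensors for a scene collection as an
    NPZ (one ``<attr>_onehot`` array of shape (n, slots, classes) per
    task attribute) plus the slot permutations, alongside a dataset CSV."""
    from pathlib import Path

    task_attributes = tuple(task_attributes)
    encs = [encode_targets(s.objects, task_attributes, map_name, codec)
            for s in scenes]
    arrays = {"permutation": np.stack([e.ordering.permutation
                                       for e in encs])}
    for attr in task_attributes:
        arrays[f"{attr}_onehot"] = np.stack([e.onehot[attr] for e in encs])
        arrays[f"{attr}_class_index"] = np.stack([e.class_index[attr]
                                                  for e in encs])
    np.savez_compressed(Path(path), map_name=map_name, **arrays)
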