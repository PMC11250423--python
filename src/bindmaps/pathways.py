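"""Pathway networks and the frozen-trunk two-pathway network.

A *pathway network* is a convolutional classifier trained to report one
attribute of every object in a scene, its output slots ordered by a
constraint map — the model of one specialised cortical visual stream.
A *two-pathway network* takes two pathway networks pre-trained under the
same constraint map, freezes their trunks (everything except the output
heads), concatenates their final trunk layers, and trains shared dense
layers that report both attributes of every object.

Because the trunks are frozen, their features for a fixed dataset are
fixed; they are computed once and the shared layers are trained on the
cached features, which is mathematically identical to backpropagating
through frozen weights and much faster.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .mapping import AttributeCodec, TargetEncoding, encode_targets, \
    score_predictions
from .scenes import Dataset, Scene

__all__ = [
    "NetworkConfig",
    "TrainedPathway",
    "TwoPathwayNet",
    "build_pathway",
    "train_pathway",
    "build_two_pathways",
    "train_two_pathways",
    "prepare_inputs",
    "prepare_targets",
    "predictions_by_attribute",
    "desk_network_config",
    "save_pathway",
    "load_pathway",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Shared architecture/training configuration for every pathway.

    All pathway networks share one structure; only the output heads
    differ with the task.  Defaults: two conv/pool blocks, two dense
    layers, 30% dropout on dense layers only, batch 256, Adam at 1e-3.
    """

    conv_blocks: tuple[tuple[int, int], ...] = ((32, 3), (64, 3))
    dense_widths: tuple[int, ...] = (512, 256)
    common_dense_widths: tuple[int, ...] = (256,)
    dropout_rate: float = 0.30
    batch_size: int = 256
    learning_rate: float = 1e-3
    max_epochs: int = 60
    patience: int = 10
    seed: int = 0


def desk_network_config(seed: int = 0, **overrides) -> NetworkConfig:
    """Small preset for CPU desk-scale runs (smaller canvas and bank)."""
    kw = dict(conv_blocks=((8, 3), (16, 3)), dense_widths=(128, 64),
              common_dense_widths=(64,), batch_size=64, learning_rate=2e-3,
              max_epochs=45, patience=6, seed=seed)
    kw.update(overrides)
    return NetworkConfig(**kw)


def build_pathway(config: NetworkConfig, input_size: int, n_objects: int,
                  n_classes: int) -> nn.MultiHeadNet:
    """Untrained pathway net: conv/pool trunk, dense stack with dropout,
    ``n_objects`` softmax heads of width ``n_classes``."""
    if n_classes < 2:
        raise ValueError("need at least 2 classes per head")
    rng = np.random.default_rng(config.seed)
    layers: list[nn.Layer] = []
    h = w = input_size
    ch = 1
    for filters, k in config.conv_blocks:
        h, w = h - k + 1, w - k + 1
        if h <= 0 or w <= 0:
            raise ValueError("input smaller than the receptive field")
        layers.append(nn.Conv2D(ch, filters, k, rng))
        layers.append(nn.MaxPool2())
        h, w, ch = h // 2, w // 2, filters
        if h < 1 or w < 1:
            raise ValueError("input smaller than the receptive field")
    layers.append(nn.Flatten())
    n_in = h * w * ch
    for width in config.dense_widths:
        layers.append(nn.Dense(n_in, width, rng))
        layers.append(nn.Dropout(config.dropout_rate, rng))
        n_in = width
    return nn.MultiHeadNet(layers, n_in, [n_classes] * n_objects, rng)


# ---------------------------------------------------------------------------
# data preparation

def prepare_inputs(scenes: list[Scene]) -> np.ndarray:
    """Stack scene canvases into a float32 (n, H, W, 1) tensor in [0,1]."""
    x = np.stack([s.canvas for s in scenes]).astype(np.float32) / 255.0
    return x[..., None]


def prepare_targets(scenes: list[Scene], task_attributes, map_name: str,
                    codec: AttributeCodec
                    ) -> tuple[np.ndarray, list[TargetEncoding]]:
    """Integer head labels (n, n_heads) plus the per-scene encodings.

    Head order: all slots of the first task attribute, then all slots of
    the second (for pair tasks); both blocks share one slot ordering.
    """
    task_attributes = tuple(task_attributes)
    truths = [encode_targets(s.objects, task_attributes, map_name, codec)
              for s in scenes]
    y = np.stack([np.concatenate([t.class_index[a] for a in task_attributes])
                  for t in truths]).astype(np.int64)
    return y, truths


def predictions_by_attribute(outputs: list[np.ndarray], task_attributes,
                             n_slots: int) -> dict:
    """Regroup per-head softmax outputs into attr -> (n, slots, classes)."""
    task_attributes = tuple(task_attributes)
    pred = {}
    for j, attr in enumerate(task_attributes):
        heads = outputs[j * n_slots:(j + 1) * n_slots]
        pred[attr] = np.stack(heads, axis=1)
    return pred


def trunk_hash(net: nn.MultiHeadNet) -> str:
    h = hashlib.sha256()
    for p in net.trunk_params():
        h.update(np.ascontiguousarray(p).tobytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# single-pathway training

@dataclass
class TrainedPathway:
    task_attribute: str
    map_name: str
    net: nn.MultiHeadNet
    codec: AttributeCodec
    config: NetworkConfig
    history: nn.FitHistory
    test_accuracy: float
    trunk_hash: str = ""
    input_size: int = 0

    def __post_init__(self) -> None:
        if not self.trunk_hash:
            self.trunk_hash = trunk_hash(self.net)


def _evaluate(net: nn.MultiHeadNet, scenes: list[Scene], task_attributes,
              map_name: str, codec: AttributeCodec,
              mode: str = "per_slot", tie_policy: str = "canonical") -> float:
    x = prepare_inputs(scenes)
    _, truths = prepare_targets(scenes, task_attributes, map_name, codec)
    outputs = net.predict(x)
    n_slots = len(scenes[0].objects)
    pred = predictions_by_attribute(outputs, task_attributes, n_slots)
    return score_predictions(pred, truths, mode=mode, tie_policy=tie_policy)


def train_pathway(dataset: Dataset, task_attribute: str, map_name: str,
                  config: NetworkConfig, codec: AttributeCodec,
                  verbose: bool = False) -> TrainedPathway:
    """Train one pathway net to report ``task_attribute`` for every
    object, slots ordered by ``map_name``; early-stops on validation
    per-slot accuracy and restores the best weights."""
    n_objects = dataset.config.n_objects
    net = build_pathway(config, dataset.config.canvas_size, n_objects,
                        codec.n_classes(task_attribute))
    x_train = prepare_inputs(dataset.train)
    y_train, _ = prepare_targets(dataset.train, (task_attribute,), map_name,
                                 codec)
    x_val = prepare_inputs(dataset.val)
    y_val, _ = prepare_targets(dataset.val, (task_attribute,), map_name,
                               codec)
    hist = nn.fit(net, x_train, y_train, x_val, y_val,
                  batch_size=config.batch_size, lr=config.learning_rate,
                  max_epochs=config.max_epochs, patience=config.patience,
                  rng=np.random.default_rng(config.seed + 1),
                  verbose=verbose)
    test_acc = _evaluate(net, dataset.test, (task_attribute,), map_name,
                         codec)
    return TrainedPathway(task_attribute, map_name, net, codec, config,
                          hist, test_acc,
                          input_size=dataset.config.canvas_size)


# ---------------------------------------------------------------------------
# two-pathway network

@dataclass
class TwoPathwayNet:
    """Two frozen pre-trained trunks + trainable shared dense layers."""

    pathway_a: TrainedPathway
    pathway_b: TrainedPathway
    common: nn.MultiHeadNet
    map_name: str
    task_pair: tuple[str, str]
    history: nn.FitHistory | None = None
    test_accuracy: float | None = None

    def trunk_hashes(self) -> tuple[str, str]:
        return trunk_hash(self.pathway_a.net), trunk_hash(self.pathway_b.net)

    def features(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        feats = []
        for i in range(0, x.shape[0], batch_size):
            xa = self.pathway_a.net.features(x[i:i + batch_size], train=False)
            xb = self.pathway_b.net.features(x[i:i + batch_size], train=False)
            feats.append(np.concatenate([xa, xb], axis=1))
        return np.concatenate(feats)

    def predict(self, x: np.ndarray) -> list[np.ndarray]:
        return self.common.predict(self.features(x))


def build_two_pathways(pathway_a: TrainedPathway, pathway_b: TrainedPathway,
                       config: NetworkConfig) -> TwoPathwayNet:
    """Assemble the two-pathway network.

    Both pathways must have been pre-trained under the *same* constraint
    map — the shared slot ordering is what lets the read-out recombine
    the two attribute streams object by object.
    """
    if pathway_a.map_name != pathway_b.map_name:
        raise ValueError(
            f"constraint map mismatch: {pathway_a.map_name!r} vs "
            f"{pathway_b.map_name!r}; both pathways must share one map")
    rng = np.random.default_rng(config.seed + 2)
    feat_a = pathway_a.net.heads[0].W.shape[0]
    feat_b = pathway_b.net.heads[0].W.shape[0]
    n_in = feat_a + feat_b
    layers: list[nn.Layer] = []
    for width in config.common_dense_widths:
        layers.append(nn.Dense(n_in, width, rng))
        layers.append(nn.Dropout(config.dropout_rate, rng))
        n_in = width
    n_objects = len(pathway_a.net.heads)
    codec_a, codec_b = pathway_a.codec, pathway_b.codec
    head_classes = ([codec_a.n_classes(pathway_a.task_attribute)] * n_objects
                    + [codec_b.n_classes(pathway_b.task_attribute)]
                    * n_objects)
    common = nn.MultiHeadNet(layers, n_in, head_classes, rng)
    return TwoPathwayNet(pathway_a, pathway_b, common, pathway_a.map_name,
                         (pathway_a.task_attribute, pathway_b.task_attribute))


def train_two_pathways(net: TwoPathwayNet, dataset: Dataset,
                       config: NetworkConfig,
                       verbose: bool = False) -> TwoPathwayNet:
    """Train the shared dense layers on cached frozen-trunk features and
    record the test accuracy over all 2 x n_objects heads."""
    task_pair = net.task_pair
    codec = net.pathway_a.codec
    f_train = net.features(prepare_inputs(dataset.train))
    f_val = net.features(prepare_inputs(dataset.val))
    y_train, _ = prepare_targets(dataset.train, task_pair, net.map_name,
                                 codec)
    y_val, _ = prepare_targets(dataset.val, task_pair, net.map_name, codec)
    net.history = nn.fit(net.common, f_train, y_train, f_val, y_val,
                         batch_size=config.batch_size,
                         lr=config.learning_rate,
                         max_epochs=config.max_epochs,
                         patience=config.patience,
                         rng=np.random.default_rng(config.seed + 3),
                         verbose=verbose)
    x_test = prepare_inputs(dataset.test)
    _, truths = prepare_targets(dataset.test, task_pair, net.map_name, codec)
    outputs = net.common.predict(net.features(x_test))
    n_slots = dataset.config.n_objects
    pred = predictions_by_attribute(outputs, task_pair, n_slots)
    net.test_accuracy = score_predictions(pred, truths)
    return net


def save_pathway(pathway: TrainedPathway, path) -> None:
    """Checkpoint a trained pathway: weights as NPZ plus a JSON metadata
    sidecar (task, map, architecture, test accuracy, trunk hash)."""
    import json
    from pathlib import Path

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    weights = pathway.net.get_weights()
    np.savez_compressed(path / "weights.npz",
                        **{f"p{i}": w for i, w in enumerate(weights)})
    meta = {
        "task_attribute": pathway.task_attribute,
        "map_name": pathway.map_name,
        "config": {k: v for k, v in vars(pathway.config).items()},
        "input_size": int(pathway.input_size),
        "n_objects": len(pathway.net.heads),
        "n_classes": int(pathway.net.heads[0].W.shape[1]),
        "test_accuracy": pathway.test_accuracy,
        "trunk_hash": pathway.trunk_hash,
        "best_val_accuracy": pathway.history.best_val_accuracy,
    }
    (path / "metadata.json").write_text(json.dumps(meta, indent=2,
                                                   default=list))


def load_pathway(path, codec: AttributeCodec) -> TrainedPathway:
    """Rebuild a checkpointed pathway; verifies the stored trunk hash."""
    import json
    from pathlib import Path

    path = Path(path)
    meta = json.loads((path / "metadata.json").read_text())
    cfg_dict = meta["config"]
    for key in ("conv_blocks", "dense_widths", "common_dense_widths"):
        cfg_dict[key] = tuple(tuple(b) if isinstance(b, list) else b
                              for b in cfg_dict[key])
    config = NetworkConfig(**cfg_dict)
    net = build_pathway(config, meta["input_size"], meta["n_objects"],
                        meta["n_classes"])
    with np.load(path / "weights.npz") as z:
        net.set_weights([z[f"p{i}"] for i in range(len(z.files))])
    hist = nn.FitHistory(best_val_accuracy=meta["best_val_accuracy"])
    pathway = TrainedPathway(meta["task_attribute"], meta["map_name"], net,
                             codec, config, hist, meta["test_accuracy"],
                             input_size=meta["input_size"])
    if pathway.trunk_hash != meta["trunk_hash"]:
        raise ValueError("trunk hash mismatch: checkpoint corrupt")
    return pathway
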