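# bindmaps

Simulations of how a *constraint map* — a shared ordering of a scene's
objects — lets two-stream visual networks solve the binding problem.

## The problem

Two-pathway models of the visual system process different attributes of
a display in segregated streams (one network reports *what*, another
*where*).  With several objects in view, the separate attribute lists do
not say which identity belongs with which location: the **binding
problem**.  One way to constrain it is to fix the order in which every
pathway's output slots report the objects, using the relative ordering
of a single attribute — a constraint map.  If the identity pathway
reports identities top-left object first and the location pathway
reports locations in the same order, slot *k* of both networks describes
the same object.

`bindmaps` implements the full simulation study around that idea:

* **stimuli** — 140×140 black canvases with three non-overlapping
  objects on a 3×3 grid, each object carrying four attributes: identity
  (4 classes), luminance level (mean pixel value binned at multiples of
  255/8), orientation (up/left/down/right) and location (1–9).
  Objects come from a built-in procedural glyph bank (a "mixed" family
  with class-dependent luminance, and a "tops" family of four similar
  garments with independent attributes), or optionally from
  Fashion-MNIST IDX/NPZ files;
* **maps** — slot orderings by relative location, identity, luminance
  or orientation, with canonical tie-breaking for training targets and
  optional best-permutation scoring for ties;
* **networks** — convolutional pathway classifiers (one softmax head
  per object) and two-pathway networks whose pre-trained trunks are
  frozen and read out by shared dense layers reporting two attributes,
  on a small deterministic numpy engine;
* **experiments** — a factorial grid (variants × maps × tasks × 3
  repetitions) with a resumable CSV ledger;
* **statistics** — mean ± SD tables, Welch's two-sample t-tests between
  map conditions, and the percentage gain
  `(LocationMapAcc − OtherMapAcc) / OtherMapAcc × 100`.

The headline phenomenon: when the four attributes are independent, the
**location map** yields the highest two-pathway accuracy for every pair
of attributes — both pathways can read the objects' relative positions
straight off the image, so a spatial slot ordering costs neither stream
anything, while ordering by any other attribute forces each pathway to
also judge that attribute.

## A worked example

```python
import bindmaps as bm

bank = bm.build_bank(bm.tops_bank_config(n_per_class=60, obj_size=14, seed=1))
cfg = bm.desk_dataset_config(variant="equal_classes_tops",
                             n_images=1500, canvas_size=48, seed=1)
dataset = bm.generate_dataset(bank, cfg)
codec = bm.AttributeCodec(class_names=bank.class_names,
                          locations=cfg.allowed_locations)
net = bm.desk_network_config(seed=1)

for map_name in ("location", "luminance"):
    pa = bm.train_pathway(dataset, "luminance", map_name, net, codec)
    pb = bm.train_pathway(dataset, "orientation", map_name, net, codec)
    two = bm.build_two_pathways(pa, pb, net)
    bm.train_two_pathways(two, dataset, net)
    print(map_name, round(two.test_accuracy, 3))
```

prints (a few minutes on one CPU):

```
location 0.869
luminance 0.713
```

Both runs bind luminance and orientation for all three objects; the
per-slot test accuracy is the fraction of the six output heads naming
the right class.  Under the location map the two frozen streams share a
spatial slot order that each can infer perfectly, so recombination is
easy; under the luminance map the orientation stream must also judge
luminance to know which slot is which, and accuracy drops.

The `examples/` scripts walk through each capability (bank, scenes and
maps, pathway training, two-pathway binding, statistics); `bindmaps
generate|run-grid|report` drive the long-running steps from a shell.

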