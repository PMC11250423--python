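# Methods

## The model

`bindmaps` studies the *binding problem* in two-stream models of the
visual system.  When separate pathways report separate attributes of a
multi-object display — one network naming the identities present, another
naming the locations — the attribute lists alone do not say which
identity goes with which location.  The simulations here constrain the
problem with a *constraint map*: every pathway reports its attribute for
all objects in a slot order fixed by the relative ordering of one chosen
attribute.  Four maps are compared:

* **location** — slots ordered top row first, then left to right
  (a relative spatial ordering: jointly translating all objects leaves
  it unchanged);
* **identity** — slots ordered by a fixed class order (t-shirt, pant,
  shoe, bag by default);
* **luminance** — slots ordered low, medium-low, medium-high, high;
* **orientation** — slots ordered up, left, down, right.

Any consistent order within a map would serve equally; the defaults are
conventions, and all of them are configurable permutations.

Each *pathway network* is a small convolutional classifier (shared trunk,
one softmax head per object slot) trained to report one attribute of all
objects.  A *two-pathway network* takes two pathway networks pre-trained
under the same map, freezes everything except their output heads,
concatenates their final trunk layers and trains shared dense layers to
report both attributes of every object.  The question answered by an
experiment grid is: under which constraint map does the two-pathway
network bind two attributes most accurately?

## Stimuli

Scenes are 140×140 black canvases with three non-overlapping object
patches centred on cells of a 3×3 grid (locations numbered 1–9
row-major).  Objects carry four attributes: identity (4 classes),
luminance level (4 bins of the mean pixel value at multiples of 255/8 —
the mean includes the black background pixels inside the patch, and is
never rescaled), orientation (4 quarter-turns: up, left, down, right,
counter-clockwise) and location.  Three structural variants are
generated:

* `original` — all 9 locations, attributes free to repeat within a scene;
  6 000 images (train/val/test = 2/3, 1/6, 1/6 → 4000/1000/1000);
* `equal_classes` — locations restricted to the corners {1,3,7,9} so all
  four attributes have exactly four classes;
* `unique_attributes` — the three objects of each scene always differ in
  all four attributes.

Each variant has a `*_tops` twin meant to be driven by the tops bank
(below); the original tops variant defaults to 12 000 images, which makes
the pair accuracies easier to compare.

## The glyph bank

The built-in object source is a procedural glyph bank: parametric
silhouettes (t-shirt, pant, shoe, bag; or the four tops t-shirt,
pullover, coat, shirt) with jittered edges and a mild multiplicative
texture, foreground intensity set so the patch mean lands near a
per-class target luminance.  It emulates the statistical structure the
simulations need:

* four identity classes with discriminable silhouettes (verified by a
  nearest-centroid probe in the test suite);
* rotation-asymmetric shapes, so all four orientations are decodable;
* controllable identity–luminance dependency.  The mixed bank draws each
  class's luminance from a class-specific normal distribution
  (t-shirt 81.0 ± 28.6, pant 57.2 ± 13.7, shoe 33.6 ± 14.9,
  bag 85.8 ± 26.2 — the class statistics measured on the corresponding
  clothing photographs), reproducing the dependency that causes the
  documented exceptions to the location-map advantage.  The tops bank
  draws every class from one shared distribution (90 ± 45, clipped to
  [8, 180]), making identity, luminance and orientation mutually
  independent — the dependency-removed condition.  The shared tops
  distribution is deliberately broad so that all four luminance levels
  occur at usable rates; its exact width is a generator choice, not a
  measured quantity.

What the glyphs do **not** emulate: the intra-class shape diversity of
photographed clothing (200 distinct real garments per class), fine
texture, or anti-aliased edges.  Identity is therefore easier on glyphs
than on photographs, and absolute accuracies are not comparable to the
full-scale numbers; the comparisons *between maps* on the same stimuli
are the quantity of interest.  An adapter for the Fashion-MNIST IDX/NPZ
files is provided for full-scale reproduction; its "bags with handles"
filter keeps bags whose pixels reach the top rows of the patch (a
documented heuristic — no item list exists), and "shoe" maps to the
sneaker class.

## Training

All pathway networks share one architecture; only the output heads
differ by task.  Full-scale defaults: two conv/pool blocks (32 and 64
3×3 filters), dense 512 and 256, 30% dropout on dense layers only,
batch 256, Adam at 10⁻³, summed per-head cross-entropy with equal
weights.  "Trained until the highest validation accuracy" is
operationalised as early stopping on validation per-slot accuracy with
best-weight restoration (default patience 10 epochs).  The engine is
plain numpy (im2col convolution + GEMM), so training is bit-for-bit
deterministic given the seed — repetitions differ only through their
seeds.

Because the two-pathway trunks are frozen, their features over a fixed
dataset are constants; they are computed once and the shared dense
layers are trained on the cached features.  This is mathematically
identical to backpropagating through frozen weights and an order of
magnitude faster.

### Accuracy metric

Test accuracy is per output head ("per-slot"): the fraction of heads
whose argmax names the target class, averaged over heads and test
scenes.  A stricter per-image mode (all heads correct) is available;
comparisons always use one mode consistently.  Slots tied under a map
(e.g. two pants under the identity map) are given canonical training
targets (tie broken by location) — a concrete order is necessary for
supervised targets — while the scorer can optionally credit tied slots
under their best joint permutation (`tie_policy="free"`), reflecting
that the tied order is semantically arbitrary.

## Desk scale

The full-scale conditions (140 px canvas, 800-exemplar bank, 6 000–12 000
images, 60+ epochs) are impractical for routine CPU runs, so a "desk"
preset scales everything down while preserving the structure: 48 px
canvas (14 px objects), 60 exemplars per class, 1 500 images
(1000/250/250), conv 8/16, dense 128/64, common dense 64, batch 64,
learning rate 2·10⁻³, up to 45 epochs with patience 6.  The higher
learning rate and smaller batch compensate for the small trunk and short
epochs; the dropout rate, loss, optimiser and early-stopping rule are
unchanged.  Undertraining is the main risk when scaling down: with too
few epochs every pathway does best under its own attribute's map
(reporting a sorted attribute list requires no binding) and the
location-map advantage disappears, so the desk preset keeps training to
convergence and shrinks the stimuli instead.

Binding an attribute to nine possible positions is the
hardest desk-scale task — at 1 500 images it stays data-limited, and the
9-location unique-attributes comparison only becomes clean at roughly
3 000 images and a doubled epoch budget (an overnight-suite setting).
The quick desk comparison therefore uses the equal-class-count tops
condition (locations restricted to the four corners): there the same
location-map ordering emerges well within a coffee-break budget, with
the location pathway at ~100%, and it is the condition under which the
class-count confound is controlled anyway.

## Statistics

Cells are summarised as mean ± sample SD over repetitions (three by
default), printed as percentages to one decimal.  Map conditions are
compared with Welch's unequal-variance two-sample t-test (two-sided,
significance at p < 0.05, no multiple-testing correction — matching the
reporting convention of the tables this reproduces).  If the
Welch–Satterthwaite denominator underflows for near-zero variances the
df falls back to n₁+n₂−2; two zero-variance samples with equal means
give p = 1 by convention, with unequal means the comparison is flagged
degenerate.  The location map's advantage is also expressed as the
percentage gain (location-map accuracy − other-map accuracy) /
other-map accuracy × 100, computed on the mean accuracies.

## Numerical and design choices

* Location numbering and the location key are row-major; only relative
  order matters to the encodings.
* Exemplars are drawn without replacement within a scene (two identical
  identities are two different exemplars of the class).
* Per-cell seeds are CRC32 hashes of (base seed, variant, task, map,
  repetition) — distinct across all cells, reproducible, below 2³¹.
* The unique-attributes sampler draws three distinct classes, then
  rejection-samples exemplars until the luminance levels are distinct
  (error after 500 tries naming the failing attribute).
* Grid cell centres are `int((i+0.5)·cell)`; any two distinct cells of a
  140/3 grid hold 28 px patches with disjoint bounding boxes.
* Empty summary cells are blank and logged, never silently zero.

## Known limitations

* Glyph identity is easier, and glyph luminance noisier near bin edges,
  than for photographed clothing; absolute accuracies differ from
  full-scale values even at equal training budgets.
* The engine is CPU-bound numpy; full-scale grids (6 variants × 120
  cells at 140 px) are overnight jobs, not interactive ones.
* Only 90° orientations and a 3×3 location grid are modelled; no
  occlusion, scaling, colour, or noise.
* The free-permutation scorer enumerates tie-group permutations, which
  is exact but exponential in tie-group size — fine for three objects.
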