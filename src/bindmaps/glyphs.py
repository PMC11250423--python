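"""Procedural glyph silhouettes used as object exemplars.

Each glyph class is a parametric silhouette drawn on a square patch.  The
shapes are deliberately rotation-asymmetric (none of them maps onto itself
under any 90-degree rotation) so that orientation is decodable, and the
classes have distinct topology/outline so that identity is decodable from
raw pixels.  Two families are provided:

* a "mixed" family (t-shirt, pant, shoe, bag) whose silhouettes differ
  strongly, mirroring a clothing/accessory object set, and
* a "tops" family (t-shirt, pullover, coat, shirt) of four upper-body
  garments whose silhouettes are more alike, mirroring an object set in
  which shape cues to identity are weaker and orientation is judged the
  same way for every class.

Jitter on every edge makes each exemplar unique.
"""

from __future__ import annotations

import numpy as np

__all__ = ["GLYPH_DRAWERS", "TOPS_DRAWERS", "draw_glyph"]


def _rect(mask: np.ndarray, r0: float, r1: float, c0: float, c1: float,
          value: bool = True) -> None:
    """Paint an axis-aligned rectangle given in fractional coordinates."""
    n = mask.shape[0]
    ri0, ri1 = int(round(r0 * n)), int(round(r1 * n))
    ci0, ci1 = int(round(c0 * n)), int(round(c1 * n))
    mask[max(ri0, 0):min(ri1, n), max(ci0, 0):min(ci1, n)] = value


def _j(rng: np.random.Generator, scale: float = 0.03) -> float:
    return float(rng.uniform(-scale, scale))


def _tshirt(size: int, rng: np.random.Generator) -> np.ndarray:
    m = np.zeros((size, size), dtype=bool)
    bw = 0.20 + _j(rng, 0.04)            # body half-width
    _rect(m, 0.10 + _j(rng), 0.32 + _j(rng), 0.05 + _j(rng), 0.95 + _j(rng))
    _rect(m, 0.10 + _j(rng), 0.92 + _j(rng), 0.5 - bw, 0.5 + bw)
    return m


def _pant(size: int, rng: np.random.Generator) -> np.ndarray:
    m = np.zeros((size, size), dtype=bool)
    gap = 0.08 + _j(rng, 0.03)
    _rect(m, 0.06 + _j(rng), 0.30 + _j(rng), 0.16 + _j(rng), 0.84 + _j(rng))
    _rect(m, 0.28, 0.94 + _j(rng), 0.16 + _j(rng), 0.5 - gap)
    _rect(m, 0.28, 0.94 + _j(rng), 0.5 + gap, 0.84 + _j(rng))
    return m


def _shoe(size: int, rng: np.random.Generator) -> np.ndarray:
    # boot-like L: tall shaft on the left, long sole at the bottom
    m = np.zeros((size, size), dtype=bool)
    _rect(m, 0.60 + _j(rng), 0.92 + _j(rng), 0.06 + _j(rng), 0.94 + _j(rng))
    _rect(m, 0.12 + _j(rng), 0.62, 0.06 + _j(rng), 0.40 + _j(rng))
    return m


def _bag(size: int, rng: np.random.Generator) -> np.ndarray:
    # body with a handle loop on top; the hole makes the handle explicit
    m = np.zeros((size, size), dtype=bool)
    _rect(m, 0.38 + _j(rng), 0.92 + _j(rng), 0.12 + _j(rng), 0.88 + _j(rng))
    _rect(m, 0.06 + _j(rng), 0.42, 0.28 + _j(rng), 0.72 + _j(rng))
    _rect(m, 0.16 + _j(rng, 0.02), 0.40, 0.38 + _j(rng, 0.02),
          0.62 + _j(rng, 0.02), value=False)
    return m


def _top_base(size: int, rng: np.random.Generator, *, sleeve_len: float,
              slit: bool = False, notch: bool = False) -> np.ndarray:
    """Shared upper-body-garment silhouette.

    All four tops classes are this same shape — shoulder bar, body,
    hanging sleeves — and differ only in small features (sleeve length,
    an open front, a collar notch), so identity is a deliberately weak
    cue, as for four kinds of real tops.
    """
    m = np.zeros((size, size), dtype=bool)
    _rect(m, 0.08 + _j(rng), 0.26 + _j(rng), 0.08 + _j(rng), 0.92 + _j(rng))
    _rect(m, 0.08, 0.92 + _j(rng), 0.27 + _j(rng), 0.73 + _j(rng))
    end = 0.26 + sleeve_len + _j(rng)
    _rect(m, 0.08, end, 0.08 + _j(rng), 0.24 + _j(rng))
    _rect(m, 0.08, end, 0.76 + _j(rng), 0.92 + _j(rng))
    if slit:
        _rect(m, 0.40 + _j(rng), 0.92, 0.46, 0.54, value=False)
    if notch:
        _rect(m, 0.08, 0.22 + _j(rng, 0.02), 0.42, 0.58, value=False)
    return m


def _pullover(size: int, rng: np.random.Generator) -> np.ndarray:
    return _top_base(size, rng, sleeve_len=0.55)


def _coat(size: int, rng: np.random.Generator) -> np.ndarray:
    return _top_base(size, rng, sleeve_len=0.55, slit=True)


def _shirt(size: int, rng: np.random.Generator) -> np.ndarray:
    return _top_base(size, rng, sleeve_len=0.15, notch=True)


def _tshirt_top(size: int, rng: np.random.Generator) -> np.ndarray:
    return _top_base(size, rng, sleeve_len=0.15)


GLYPH_DRAWERS = {
    "t-shirt": _tshirt,
    "pant": _pant,
    "shoe": _shoe,
    "bag": _bag,
    "pullover": _pullover,
    "coat": _coat,
    "shirt": _shirt,
}

#: tops-family drawers override "t-shirt" with the shared-base variant so
#: the four tops share one silhouette
TOPS_DRAWERS = {
    "t-shirt": _tshirt_top,
    "pullover": _pullover,
    "coat": _coat,
    "shirt": _shirt,
}


def draw_glyph(class_name: str, size: int, target_luminance: float,
               rng: np.random.Generator, family: str = "mixed") -> np.ndarray:
    """Draw one exemplar of `class_name` as a uint8 patch.

    The foreground intensity is chosen so that the mean over the whole
    patch (background included) lands near `target_luminance`; a mild
    multiplicative texture keeps exemplars of one class from being
    identical up to a constant.  ``family="tops"`` draws "t-shirt" with
    the shared tops silhouette instead of the distinctive mixed one.
    """
    drawers = TOPS_DRAWERS if family == "tops" else GLYPH_DRAWERS
    if class_name not in drawers:
        raise ValueError(f"unknown glyph class {class_name!r}")
    mask = drawers[class_name](size, rng)
    fill = mask.mean()
    if fill <= 0:
        raise RuntimeError("degenerate glyph: empty silhouette")
    fg = np.clip(target_luminance / fill, 4.0, 255.0)
    texture = rng.uniform(0.85, 1.15, size=mask.shape)
    img = np.where(mask, np.clip(fg * texture, 1.0, 255.0), 0.0)
    return np.round(img).astype(np.uint8)
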