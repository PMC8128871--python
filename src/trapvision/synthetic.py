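"""Synthetic yellow-sticky-trap scenes and labelled sub-image datasets.

No public image archive of annotated sticky-trap photographs exists for the
five-class taxonomy this package targets, so this module generates scenes
and patch datasets that reproduce the *statistical structure* the analysis
assumes rather than photorealistic insects:

* four insect classes with distinct body shapes, colours and speckle
  textures, plus a textured yellow background class (BKGRND);
* one deliberately hard pair: BEMITA and TRIAVA share identical geometry
  (body, wings, speckle layout) and differ only in wing colour and opacity,
  mirroring the two whitefly species that are near-identical on a trap;
* a scalar ``decay`` in [0, 1] emulating catches ageing on the trap: insect
  pixels are blended toward the trap background, wings fading faster than
  the dark body centre, so a 7-day-old catch keeps a dark blurred core while
  its wings approach transparency;
* optional CLUTTER objects (other insect species) that are rendered into
  scenes but never annotated — in the trap taxonomy all non-target species
  belong to the background.

All randomness flows through a single integer seed; identical configuration
and seed give bit-identical images and marker tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import disk, ellipse, line

from .annotations import (
    DEFAULT_TAXONOMY,
    MARKER_COLUMNS,
    PATCH_SIZE,
    SubImageRecord,
    empty_marker_table,
)

CLUTTER_LABEL = "CLUTTER"

#: Saturated yellow of an unused sticky trap, as an 8-bit HSV triplet.
DEFAULT_BACKGROUND_HSV = (32, 200, 235)

# Fraction of the way toward the background that a fully decayed (decay=1)
# pixel is blended.  Wings bleach almost completely; the dark body centre is
# retained, only blurred and paled.
_WING_FADE = 0.92
_BODY_FADE = 0.55


class PlacementError(RuntimeError):
    """Requested objects could not be placed at the required separation."""


class UnknownClassError(KeyError):
    """A label has no rendering specification."""


@dataclass(frozen=True)
class ClassSpec:
    """Rendering specification for one object class.

    shape_params
        ``body_axes`` — ellipse semi-axes in px; ``wing_count`` — 0 or 2;
        ``wing_axes`` — wing ellipse semi-axes; ``antennae`` — draw a pair of
        antennae from the head.
    colour_params
        8-bit HSV triplets for body and wings plus ``wing_alpha``, the wing
        opacity over whatever lies beneath.
    texture_params
        ``speckle_density`` — darker blobs per 100 px^2 of body area;
        ``blob_scale`` — speckle radius in px.
    """

    label: str
    shape_params: dict = field(default_factory=dict)
    colour_params: dict = field(default_factory=dict)
    texture_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key in ("body_hsv", "wing_hsv"):
            triple = self.colour_params.get(key)
            if triple is not None and not all(0 <= v <= 255 for v in triple):
                raise ValueError(f"{self.label}: {key} values must be in [0, 255]")


def default_class_specs() -> dict[str, ClassSpec]:
    """Specifications for the five taxonomy classes plus CLUTTER.

    BEMITA and TRIAVA share ``shape_params`` and ``texture_params`` by
    construction (the generator's hard pair); they differ only in wing
    colour/opacity — TRIAVA's wings stay bright white and opaque while
    BEMITA's are slightly duller and translucent.  Sizes are chosen for
    descriptor richness inside a 201x201 window, not biological scale.
    """
    whitefly_shape = {
        "body_axes": (22, 11),
        "wing_count": 2,
        "wing_axes": (30, 14),
        "antennae": False,
    }
    whitefly_texture = {"speckle_density": 1.8, "blob_scale": 2.0, "stripes": 0}
    return {
        "BEMITA": ClassSpec(
            "BEMITA",
            shape_params=dict(whitefly_shape),
            colour_params={
                "body_hsv": (22, 160, 90),
                # Dusky translucent wings: darker than the trap, where the
                # other whitefly's are bright white -- the pair's only
                # difference.
                "wing_hsv": (25, 60, 140),
                "wing_alpha": 0.62,
            },
            texture_params=dict(whitefly_texture),
        ),
        "TRIAVA": ClassSpec(
            "TRIAVA",
            shape_params=dict(whitefly_shape),
            colour_params={
                "body_hsv": (22, 160, 90),
                "wing_hsv": (35, 6, 255),
                "wing_alpha": 0.97,
            },
            texture_params=dict(whitefly_texture),
        ),
        "ENCAFO": ClassSpec(
            "ENCAFO",
            shape_params={
                "body_axes": (20, 13),
                "wing_count": 0,
                "wing_axes": (0, 0),
                "antennae": False,
            },
            colour_params={
                # Two-tone body (dark thorax, pale abdomen): the class's
                # signature structure at descriptor scale.
                "body_hsv": (16, 200, 35),
                "body2_hsv": (28, 140, 205),
                "wing_hsv": (30, 40, 210),
                "wing_alpha": 0.75,
            },
            texture_params={"speckle_density": 2.0, "blob_scale": 2.0, "stripes": 0},
        ),
        "MACRPY": ClassSpec(
            "MACRPY",
            shape_params={
                "body_axes": (34, 10),
                "wing_count": 0,
                "wing_axes": (0, 0),
                "antennae": True,
            },
            colour_params={
                "body_hsv": (72, 190, 160),
                "wing_hsv": (72, 190, 160),
                "wing_alpha": 1.0,
            },
            texture_params={"speckle_density": 2.5, "blob_scale": 2.0, "stripes": 0},
        ),
        "BKGRND": ClassSpec("BKGRND"),
        CLUTTER_LABEL: ClassSpec(
            CLUTTER_LABEL,
            shape_params={
                "body_axes": (42, 34),
                "wing_count": 0,
                "wing_axes": (0, 0),
                "antennae": False,
            },
            colour_params={
                "body_hsv": (140, 90, 85),
                "wing_hsv": (140, 90, 85),
                "wing_alpha": 1.0,
            },
            texture_params={"speckle_density": 0.4, "blob_scale": 6.0, "stripes": 0},
        ),
    }


@dataclass(frozen=True)
class SceneConfig:
    """Configuration of one synthetic trap scene.

    ``decay`` = 0 emulates a freshly photographed trap (Lab0d-like); 1
    emulates seven days of retention (Lab7d-like).  ``min_separation`` is the
    minimum pairwise distance in px between object centres (markers).
    """

    width: int = 700
    height: int = 700
    counts_per_class: Mapping[str, int] = field(default_factory=dict)
    decay: float = 0.0
    background_hsv: tuple[int, int, int] = DEFAULT_BACKGROUND_HSV
    min_separation: float = 120.0
    #: Optional stricter spacing between objects of the same class; sliding-
    #: window detection cannot split same-class individuals whose positive
    #: regions merge, so detection studies place conspecifics further apart.
    same_class_min_separation: float | None = None
    rng_seed: int = 0
    image_id: str = "scene"
    dataset_tag: str = "synthetic"
    margin: int = PATCH_SIZE // 2

    def __post_init__(self) -> None:
        if self.min_separation < 0:
            raise ValueError("min_separation must be >= 0")
        if not 0.0 <= self.decay <= 1.0:
            raise ValueError("decay must be in [0, 1]")
        for label, n in self.counts_per_class.items():
            if n < 0:
                raise ValueError(f"negative count for {label}")


# ---------------------------------------------------------------------------
# Low-level painting
# ---------------------------------------------------------------------------

def _hsv_to_rgb(hsv: Sequence[float]) -> np.ndarray:
    """8-bit HSV triplet -> float RGB triplet in [0, 255]."""
    h, s, v = (np.asarray(hsv, dtype=float) / 255.0).tolist()
    i = int(h * 6.0) % 6
    f = h * 6.0 - int(h * 6.0)
    p, q, t = v * (1 - s), v * (1 - f * s), v * (1 - (1 - f) * s)
    rgb = [(v, t, p), (q, v, p), (p, v, t), (p, q, v), (t, p, v), (v, p, q)][i]
    return np.asarray(rgb) * 255.0


def _render_background(
    shape: tuple[int, int],
    rng: np.random.Generator,
    background_hsv: Sequence[int] = DEFAULT_BACKGROUND_HSV,
) -> np.ndarray:
    """Yellow trap surface: base colour, smooth mottling and faint speckles.

    The mottling gives SIFT something to respond to on pure-background
    patches, which the BKGRND class needs to be learnable.
    """
    h, w = shape
    base = _hsv_to_rgb(background_hsv)
    img = np.empty((h, w, 3), dtype=float)
    img[:] = base
    mottle = ndimage.gaussian_filter(rng.standard_normal((h, w)), 6.0)
    mottle = mottle / (np.std(mottle) + 1e-12) * 6.0
    img += mottle[..., None]
    n_speckles = max(1, int(h * w / 2500))
    ys = rng.integers(0, h, n_speckles)
    xs = rng.integers(0, w, n_speckles)
    radii = rng.uniform(1.0, 2.5, n_speckles)
    shades = rng.uniform(0.75, 0.92, n_speckles)
    for y, x, r, sh in zip(ys, xs, radii, shades):
        rr, cc = disk((y, x), r, shape=(h, w))
        img[rr, cc] *= sh
    return img


def _thick_line(mask: np.ndarray, r0: int, c0: int, r1: int, c1: int) -> None:
    h, w = mask.shape
    rr, cc = line(r0, c0, r1, c1)
    keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
    sub = np.zeros_like(mask)
    sub[rr[keep], cc[keep]] = True
    mask |= ndimage.binary_dilation(sub, iterations=1)


def _paint_insect(
    img: np.ndarray,
    cy: int,
    cx: int,
    spec: ClassSpec,
    decay: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Paint one insect onto ``img`` (float RGB, modified in place).

    Returns the boolean foreground mask.  All random draws concern geometry
    only, so two specs differing only in colour parameters consume the rng
    identically and produce identical masks for the same seed.
    """
    h, w = img.shape[:2]
    sp, cp, tp = spec.shape_params, spec.colour_params, spec.texture_params
    a, b = sp["body_axes"]
    theta = rng.uniform(0.0, np.pi)

    background = img.copy()
    body_colour = _hsv_to_rgb(cp["body_hsv"])
    wing_colour = _hsv_to_rgb(cp["wing_hsv"])
    wing_alpha = float(cp.get("wing_alpha", 1.0))

    body_mask = np.zeros((h, w), dtype=bool)
    rr, cc = ellipse(cy, cx, a, b, shape=(h, w), rotation=theta)
    body_mask[rr, cc] = True

    wing_mask = np.zeros((h, w), dtype=bool)
    n_wings = int(sp.get("wing_count", 0))
    wa, wb = sp.get("wing_axes", (0, 0))
    wing_angles = []
    for k in range(n_wings):
        side = 1 if k % 2 == 0 else -1
        # Wings spread laterally and symmetrically about the body axis, so
        # the foreground (and keypoint) centroid stays near the body centre.
        spread = rng.uniform(1.25, 1.75)
        wing_angles.append(theta + side * spread)
    vein_mask = np.zeros((h, w), dtype=bool)
    for ang in wing_angles:
        wcy = cy + int(round(0.75 * wa * np.sin(ang)))
        wcx = cx + int(round(0.75 * wa * np.cos(ang)))
        rr, cc = ellipse(wcy, wcx, wa, wb, shape=(h, w), rotation=ang)
        wing_mask[rr, cc] = True
        # Wing veins: fixed geometry, visible in proportion to wing opacity.
        for v in range(3):
            voff = rng.uniform(-0.35, 0.35)
            tip_y = wcy + int(round(0.95 * wa * np.sin(ang + voff)))
            tip_x = wcx + int(round(0.95 * wa * np.cos(ang + voff)))
            base_y = cy + int(round(0.2 * a * np.sin(ang)))
            base_x = cx + int(round(0.2 * a * np.cos(ang)))
            _thick_line(vein_mask, base_y, base_x, tip_y, tip_x)
    vein_mask &= wing_mask

    antenna_mask = np.zeros((h, w), dtype=bool)
    if sp.get("antennae", False):
        head_y = cy + int(round(a * np.sin(theta)))
        head_x = cx + int(round(a * np.cos(theta)))
        for side in (1, -1):
            ang = theta + side * rng.uniform(0.35, 0.65)
            length = rng.uniform(0.6, 0.9) * a
            tip_y = head_y + int(round(length * np.sin(ang)))
            tip_x = head_x + int(round(length * np.cos(ang)))
            _thick_line(antenna_mask, head_y, head_x, tip_y, tip_x)

    # Wings first (translucent over the trap), body and antennae on top.
    only_wing = wing_mask & ~body_mask
    img[only_wing] = (1 - wing_alpha) * img[only_wing] + wing_alpha * wing_colour
    only_vein = vein_mask & ~body_mask
    img[only_vein] = (1 - wing_alpha) * img[only_vein] + wing_alpha * (
        wing_colour * 0.55
    )
    img[body_mask] = body_colour
    body2 = cp.get("body2_hsv")
    if body2 is not None:
        # Two-tone body: the posterior half (along the major axis) takes the
        # second colour, giving a strong internal boundary.
        yy, xx = np.nonzero(body_mask)
        along = (yy - cy) * np.sin(theta) + (xx - cx) * np.cos(theta)
        rear = along < 0
        img[yy[rear], xx[rear]] = _hsv_to_rgb(body2)
    img[antenna_mask] = body_colour * 0.5

    # Speckle texture inside the body: darker chitin blobs.
    density = tp.get("speckle_density", 0.0)
    n_speckles = int(round(density * body_mask.sum() / 100.0))
    blob = tp.get("blob_scale", 2.0)
    bys, bxs = np.nonzero(body_mask)
    for _ in range(n_speckles):
        j = rng.integers(0, len(bys))
        r = rng.uniform(0.6, 1.0) * blob
        shade = rng.uniform(0.45, 0.7)
        rr, cc = disk((bys[j], bxs[j]), r, shape=(h, w))
        keep = body_mask[rr, cc]
        img[rr[keep], cc[keep]] *= shade

    # Transverse body stripes (banded abdomen), evenly spaced along the
    # major axis, perpendicular to it.
    n_stripes = int(tp.get("stripes", 0))
    if n_stripes:
        stripe_mask = np.zeros((h, w), dtype=bool)
        for k in range(n_stripes):
            t = (k + 0.5) / n_stripes * 2.0 - 1.0  # in (-1, 1)
            sy = cy + t * a * np.sin(theta)
            sx = cx + t * a * np.cos(theta)
            dy, dx = np.cos(theta), -np.sin(theta)  # perpendicular direction
            _thick_line(
                stripe_mask,
                int(round(sy - b * dy)),
                int(round(sx - b * dx)),
                int(round(sy + b * dy)),
                int(round(sx + b * dx)),
            )
        stripe_mask &= body_mask
        img[stripe_mask] = body_colour * 0.45

    mask = body_mask | wing_mask | antenna_mask

    if decay > 0:
        fade = np.zeros((h, w), dtype=float)
        fade[mask] = _BODY_FADE
        fade[only_wing] = _WING_FADE
        wvals = (decay * fade)[..., None]
        img[:] = (1.0 - wvals) * img + wvals * background
        # Ageing also blurs the insect's outline into the adhesive.
        blur_sigma = 1.5 * decay
        if blur_sigma > 0:
            sub = ndimage.gaussian_filter(img, (blur_sigma, blur_sigma, 0))
            soft = ndimage.gaussian_filter(mask.astype(float), 3.0)[..., None]
            img[:] = soft * sub + (1 - soft) * img
    return mask


def _finalize(img: np.ndarray) -> np.ndarray:
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Public generators
# ---------------------------------------------------------------------------

def render_insect_patch(
    spec: ClassSpec | str,
    decay: float,
    rng_seed: int,
    background_hsv: Sequence[int] = DEFAULT_BACKGROUND_HSV,
    specs: Mapping[str, ClassSpec] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one 201x201 RGB patch with a centred object.

    Returns ``(patch, mask)`` where ``mask`` is the boolean foreground.  For
    the BKGRND class the mask is empty and the patch is pure trap texture.
    The blend of foreground pixels toward the background is monotone
    non-decreasing in ``decay``; identical ``(spec, decay, seed)`` gives a
    bit-identical patch.
    """
    if not 0.0 <= decay <= 1.0:
        raise ValueError(f"decay must be in [0, 1], got {decay}")
    if isinstance(spec, str):
        table = default_class_specs() if specs is None else specs
        if spec not in table:
            raise UnknownClassError(spec)
        spec = table[spec]
    rng = np.random.default_rng(rng_seed)
    img = _render_background((PATCH_SIZE, PATCH_SIZE), rng, background_hsv)
    if spec.label == "BKGRND":
        return _finalize(img), np.zeros((PATCH_SIZE, PATCH_SIZE), dtype=bool)
    half = PATCH_SIZE // 2
    mask = _paint_insect(img, half, half, spec, decay, rng)
    return _finalize(img), mask


def generate_trap_scene(
    config: SceneConfig,
    specs: Mapping[str, ClassSpec] | None = None,
    max_tries: int = 300,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a full trap scene and its marker table.

    Objects are placed uniformly at random inside the margins, rejecting
    positions closer than ``min_separation`` to any already-placed object.
    CLUTTER objects are painted but never listed in the marker table (all
    non-target species belong to the background); BKGRND counts reserve
    empty, annotated background positions.
    """
    table = default_class_specs() if specs is None else specs
    for label in config.counts_per_class:
        if label not in table:
            raise UnknownClassError(label)
    rng = np.random.default_rng(config.rng_seed)
    h, w = config.height, config.width
    m = config.margin
    if w - 2 * m <= 0 or h - 2 * m <= 0:
        raise PlacementError(
            f"scene {w}x{h} too small for margin {m}"
        )
    img = _render_background((h, w), rng, config.background_hsv)

    same_sep = config.same_class_min_separation or config.min_separation
    placements: list[tuple[str, int, int]] = []
    # Sequential rejection sampling can wedge itself (early objects blocking
    # every remaining slot), so a failed layout is restarted from scratch a
    # bounded number of times before giving up.
    for _restart in range(20):
        placed: list[tuple[str, float, float]] = []
        failed_label = None
        for label in sorted(config.counts_per_class):
            for _ in range(int(config.counts_per_class[label])):
                for _try in range(max_tries):
                    x = int(rng.integers(m, w - m))
                    y = int(rng.integers(m, h - m))
                    if all(
                        (x - px) ** 2 + (y - py) ** 2
                        >= (same_sep if pl == label else config.min_separation) ** 2
                        for pl, px, py in placed
                    ):
                        placed.append((label, x, y))
                        break
                else:
                    failed_label = label
                    break
            if failed_label:
                break
        if failed_label is None:
            placements = [(lab, x, y) for lab, x, y in placed]
            break
    else:
        raise PlacementError(
            f"could not place a {failed_label} object at separation "
            f"{config.min_separation} after {max_tries} tries x 20 restarts"
        )

    rows = []
    for label, x, y in placements:
        if label not in ("BKGRND", CLUTTER_LABEL):
            mask = _paint_insect(img, y, x, table[label], config.decay, rng)
            # The marker sits in the middle of the visible individual (the
            # foreground centroid), as a human annotator would place it --
            # wings and antennae shift it off the body-placement point.
            mys, mxs = np.nonzero(mask)
            if len(mys):
                x, y = int(round(mxs.mean())), int(round(mys.mean()))
        if label != CLUTTER_LABEL:
            rows.append((config.image_id, x, y, label, config.dataset_tag))
    markers = (
        pd.DataFrame(rows, columns=list(MARKER_COLUMNS))
        if rows
        else empty_marker_table()
    )
    return _finalize(img), markers


def generate_dataset(
    counts_per_class: Mapping[str, int],
    decay: float | Mapping[float, float] = 0.0,
    rng_seed: int = 0,
    dataset_tag: str = "synthetic",
    background_hsv: Sequence[int] = DEFAULT_BACKGROUND_HSV,
    specs: Mapping[str, ClassSpec] | None = None,
    clutter_in_background: float = 0.25,
) -> list[SubImageRecord]:
    """Generate a labelled collection of rendered sub-image records.

    ``decay`` is either one fraction applied to every patch or a mapping
    ``{decay_value: probability}`` sampled independently per record.  Record
    counts match the request exactly and the sequence is reproducible from
    the seed.

    The background class covers the trap surface *and* every non-target
    species, so with probability ``clutter_in_background`` a BKGRND patch
    shows a CLUTTER object instead of bare trap texture (the label stays
    BKGRND).  Set it to 0 for pure-texture background patches.
    """
    if isinstance(decay, Mapping):
        levels = np.array(sorted(decay), dtype=float)
        probs = np.array([decay[v] for v in levels], dtype=float)
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError("decay distribution probabilities must sum to 1")
    else:
        levels = np.array([float(decay)])
        probs = np.array([1.0])
    rng = np.random.default_rng(rng_seed)
    records: list[SubImageRecord] = []
    for label in sorted(counts_per_class):
        n = int(counts_per_class[label])
        if n < 0:
            raise ValueError(f"negative count for {label}")
        for i in range(n):
            d = float(levels[rng.choice(len(levels), p=probs)])
            seed = int(rng.integers(0, 2**31 - 1))
            render_label = label
            if label == "BKGRND" and rng.random() < clutter_in_background:
                render_label = CLUTTER_LABEL
            patch, _ = render_insect_patch(
                render_label, d, seed, background_hsv=background_hsv, specs=specs
            )
            records.append(
                SubImageRecord(
                    patch=patch,
                    label=label,
                    source=(f"{dataset_tag}-{label}-{i}", PATCH_SIZE // 2, PATCH_SIZE // 2),
                    dataset_tag=dataset_tag,
                    decay=d,
                )
            )
    return records
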