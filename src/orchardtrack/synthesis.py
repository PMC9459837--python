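"""Cut-and-paste canopy scene synthesis with amodal per-fruit masks.

Scenes are composited layer by layer: background plate, background
leaves, fruits, then (shadow, foreground leaf) pairs. Each fruit's full
footprint is recorded *before* any foreground occluder is painted (the
amodal mask); the visible mask keeps only pixels never covered by a
later opaque layer. Shadows darken multiplicatively and do not occlude.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from scipy import ndimage

from .annotation import PolygonAnnotation, mask_to_polygon, write_via

__all__ = [
    "Sprite",
    "GenerationParams",
    "Placement",
    "FruitInstance",
    "CompositeSample",
    "generate_fixture_assets",
    "sample_placements",
    "transform_sprite",
    "make_shadow",
    "compose_scene",
    "generate_dataset",
    "sample_seed",
]

SPRITE_KINDS = ("fruit_red", "fruit_green", "leaf", "background", "shadow")


class ConfigurationError(ValueError):
    """Raised for invalid generation parameters."""


class DegenerateTransformError(RuntimeError):
    """Raised when a sprite transform leaves an empty footprint."""


@dataclass
class Sprite:
    """An asset raster plus its opacity footprint."""

    pixels: np.ndarray     # (H, W, 3) uint8
    footprint: np.ndarray  # (H, W) bool
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in SPRITE_KINDS:
            raise ValueError(f"unknown sprite kind {self.kind!r}")
        if self.pixels.shape[:2] != self.footprint.shape:
            raise ValueError("footprint shape must match pixels")
        if self.kind in ("fruit_red", "fruit_green", "leaf") and not self.footprint.any():
            raise ValueError(f"{self.kind} sprite has empty footprint")
        if self.kind == "background" and not self.footprint.all():
            raise ValueError("background sprite must have a full footprint")

    @property
    def size(self) -> tuple[int, int]:
        """(height, width)."""
        return self.footprint.shape


@dataclass
class GenerationParams:
    """Scene-randomization ranges; defaults follow the standard recipe."""

    canvas_size: tuple[int, int] = (1088, 1088)        # (width, height)
    fruit_size_range: tuple[int, int] = (140, 190)
    leaf_size_range: tuple[int, int] = (60, 90)
    brightness_range: tuple[float, float] = (60.0, 120.0)   # percent
    angle_range: tuple[float, float] = (-90.0, 90.0)        # degrees
    n_fruits_range: tuple[int, int] = (3, 8)
    n_foreground_leaves: int = 80
    n_background_leaves: int | None = None  # None: uniform over background_leaf_choices
    background_leaf_choices: tuple[int, ...] = (0, 100, 200, 400)
    p_red_apple: float = 0.553
    shadow_luminance_factor: float = 0.55
    shadow_enabled: bool = True
    min_visible_area_fraction: float = 0.25  # discard fruits clipped below this
    seed: int = 0

    def validate(self) -> None:
        for name in ("fruit_size_range", "leaf_size_range", "brightness_range",
                     "angle_range", "n_fruits_range"):
            lo, hi = getattr(self, name)
            if lo > hi:  # degenerate (lo == hi) pins the value; allowed
                raise ConfigurationError(f"{name} must be an ordered interval, got {lo}..{hi}")
        if not 0.0 <= self.p_red_apple <= 1.0:
            raise ConfigurationError("p_red_apple must be in [0, 1]")
        if not 0.0 < self.shadow_luminance_factor <= 1.0:
            raise ConfigurationError("shadow_luminance_factor must be in (0, 1]")
        w, h = self.canvas_size
        if w <= 0 or h <= 0:
            raise ConfigurationError("canvas dimensions must be positive")
        if self.n_foreground_leaves < 0:
            raise ConfigurationError("n_foreground_leaves must be >= 0")
        if self.n_background_leaves is not None and self.n_background_leaves < 0:
            raise ConfigurationError("n_background_leaves must be >= 0")


@dataclass
class Placement:
    """One sprite's sampled pose on the canvas.

    ``position`` is the top-left of the (pre-rotation) target box; the
    compositor centers the transformed footprint on
    ``position + target/2``, so the sampled center stays on-canvas.
    """

    sprite_kind: str
    target_height: int
    target_width: int
    brightness: float
    angle: float
    position: tuple[int, int]  # (x, y)
    layer: str                 # background_leaf | fruit | foreground_leaf | shadow

    @property
    def center(self) -> tuple[float, float]:
        return (
            self.position[0] + self.target_width / 2.0,
            self.position[1] + self.target_height / 2.0,
        )


@dataclass
class FruitInstance:
    instance_id: int
    amodal_mask: np.ndarray   # (H, W) bool
    visible_mask: np.ndarray  # (H, W) bool
    bbox: tuple[int, int, int, int]  # half-open (x_min, y_min, x_max, y_max)
    center: tuple[float, float]
    is_red: bool


@dataclass
class CompositeSample:
    image: np.ndarray  # (H, W, 3) uint8
    instances: list[FruitInstance]
    params_used: GenerationParams
    seed_used: int


# ---------------------------------------------------------------------------
# procedural fixture assets
# ---------------------------------------------------------------------------

_RED_BASE = np.array([185, 40, 35], dtype=float)
_GREEN_FRUIT_BASE = np.array([150, 190, 70], dtype=float)
_LEAF_BASE = np.array([45, 110, 40], dtype=float)


def _draw_fruit(rng: np.random.Generator, red: bool, size: int = 200) -> Sprite:
    """Shaded near-elliptical blob with a specular highlight."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cy = cx = (size - 1) / 2.0
    ry = size * rng.uniform(0.38, 0.46)
    rx = size * rng.uniform(0.38, 0.46)
    r2 = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
    footprint = r2 <= 1.0
    base = _RED_BASE if red else _GREEN_FRUIT_BASE
    shade = 1.0 - 0.45 * np.clip(r2, 0, 1)  # darker toward the rim
    hy, hx = cy - 0.35 * ry, cx - 0.35 * rx
    highlight = 60.0 * np.exp(-(((yy - hy) / (0.25 * ry)) ** 2 + ((xx - hx) / (0.25 * rx)) ** 2))
    pixels = base[None, None, :] * shade[..., None] + highlight[..., None]
    pixels += rng.normal(0.0, 4.0, pixels.shape)
    pixels = np.clip(pixels, 0, 255).astype(np.uint8)
    pixels[~footprint] = 0
    kind = "fruit_red" if red else "fruit_green"
    return Sprite(pixels=pixels, footprint=footprint, kind=kind)


def _draw_leaf(rng: np.random.Generator, size: int = 100) -> Sprite:
    """Irregular green polygon: a radius-jittered star-convex blob."""
    n_vertices = int(rng.integers(7, 12))
    angles = np.sort(rng.uniform(0.0, 2 * np.pi, n_vertices))
    radii = size * 0.45 * rng.uniform(0.55, 1.0, n_vertices)
    c = (size - 1) / 2.0
    vx = c + radii * np.cos(angles)
    vy = c + 0.7 * radii * np.sin(angles)  # leaves are elongated
    from .annotation import polygon_to_mask

    footprint = polygon_to_mask(list(zip(vx, vy)), (size, size))
    if not footprint.any():  # extreme jitter; fall back to an ellipse
        yy, xx = np.mgrid[0:size, 0:size].astype(float)
        footprint = ((yy - c) / (0.3 * size)) ** 2 + ((xx - c) / (0.45 * size)) ** 2 <= 1.0
    vein = rng.normal(0.0, 10.0, (size, size, 1))
    pixels = np.clip(_LEAF_BASE[None, None, :] * rng.uniform(0.8, 1.2) + vein, 0, 255)
    pixels = pixels.astype(np.uint8)
    pixels[~footprint] = 0
    return Sprite(pixels=pixels, footprint=footprint, kind="leaf")


def _draw_background(rng: np.random.Generator, size: tuple[int, int]) -> Sprite:
    """Textured ground/canopy plate (smoothed color noise)."""
    w, h = size
    noise = rng.normal(0.0, 1.0, (h, w, 3))
    noise = ndimage.gaussian_filter(noise, sigma=(12, 12, 0))
    noise /= max(np.abs(noise).max(), 1e-9)
    base = np.array([85, 95, 60], dtype=float)
    pixels = np.clip(base[None, None, :] + 55.0 * noise, 0, 255).astype(np.uint8)
    return Sprite(pixels=pixels, footprint=np.ones((h, w), dtype=bool), kind="background")


def generate_fixture_assets(
    seed: int,
    n_fruit: int = 6,
    n_leaf: int = 8,
    background_size: tuple[int, int] = (1088, 1088),
) -> list[Sprite]:
    """Procedurally drawn sprites standing in for manually cropped photos.

    Returns ``n_fruit`` fruit sprites (alternating red/green so both colors
    are always present), ``n_leaf`` leaf sprites, and one background plate.
    Deterministic for a fixed seed.
    """
    if n_fruit < 1 or n_leaf < 1:
        raise ValueError("need at least one fruit and one leaf sprite")
    rng = np.random.default_rng(seed)
    sprites = [_draw_fruit(rng, red=(i % 2 == 0)) for i in range(n_fruit)]
    sprites += [_draw_leaf(rng) for _ in range(n_leaf)]
    sprites.append(_draw_background(rng, background_size))
    return sprites


# ---------------------------------------------------------------------------
# placement sampling
# ---------------------------------------------------------------------------

def _sample_one(
    rng: np.random.Generator,
    kind: str,
    layer: str,
    size_range: tuple[int, int],
    params: GenerationParams,
) -> Placement:
    th = int(rng.integers(size_range[0], size_range[1] + 1))
    tw = int(rng.integers(size_range[0], size_range[1] + 1))
    brightness = float(rng.uniform(*params.brightness_range))
    angle = float(rng.uniform(*params.angle_range))
    cw, ch = params.canvas_size
    cx = rng.uniform(0, cw)
    cy = rng.uniform(0, ch)
    position = (int(round(cx - tw / 2.0)), int(round(cy - th / 2.0)))
    return Placement(
        sprite_kind=kind,
        target_height=th,
        target_width=tw,
        brightness=brightness,
        angle=angle,
        position=position,
        layer=layer,
    )


def sample_placements(
    params: GenerationParams, rng: np.random.Generator
) -> list[Placement]:
    """Draw one scene's worth of placements.

    Order: background leaves, fruits, then for each foreground leaf its
    shadow placement immediately followed by the leaf itself.
    """
    params.validate()
    placements: list[Placement] = []

    n_bg = params.n_background_leaves
    if n_bg is None:
        n_bg = int(rng.choice(params.background_leaf_choices))
    for _ in range(n_bg):
        placements.append(
            _sample_one(rng, "leaf", "background_leaf", params.leaf_size_range, params)
        )

    n_fruits = int(rng.integers(params.n_fruits_range[0], params.n_fruits_range[1] + 1))
    for _ in range(n_fruits):
        is_red = rng.random() < params.p_red_apple
        kind = "fruit_red" if is_red else "fruit_green"
        placements.append(
            _sample_one(rng, kind, "fruit", params.fruit_size_range, params)
        )

    for _ in range(params.n_foreground_leaves):
        leaf = _sample_one(rng, "leaf", "foreground_leaf", params.leaf_size_range, params)
        if params.shadow_enabled:
            # shadow falls near its leaf, displaced by a small random offset
            dx, dy = rng.integers(-25, 26, size=2)
            shadow = Placement(
                sprite_kind="shadow",
                target_height=leaf.target_height,
                target_width=leaf.target_width,
                brightness=100.0,
                angle=leaf.angle,
                position=(leaf.position[0] + int(dx), leaf.position[1] + int(dy)),
                layer="shadow",
            )
            placements.append(shadow)
        placements.append(leaf)
    return placements


# ---------------------------------------------------------------------------
# sprite transforms
# ---------------------------------------------------------------------------

def transform_sprite(sprite: Sprite, placement: Placement) -> Sprite:
    """Resample to the target box, rotate about the center, scale brightness."""
    pixels = sprite.pixels
    footprint = sprite.footprint
    th, tw = placement.target_height, placement.target_width
    h, w = footprint.shape

    if (th, tw) != (h, w):
        img = Image.fromarray(pixels).resize((tw, th), Image.BILINEAR)
        fp = Image.fromarray(footprint.astype(np.uint8) * 255).resize((tw, th), Image.NEAREST)
        pixels = np.asarray(img)
        footprint = np.asarray(fp) > 127

    angle = placement.angle % 360.0
    if angle != 0.0:
        if angle in (90.0, 180.0, 270.0):
            k = int(angle // 90)
            pixels = np.rot90(pixels, k)
            footprint = np.rot90(footprint, k)
        else:
            img = Image.fromarray(pixels).rotate(
                angle, resample=Image.BILINEAR, expand=True, fillcolor=(0, 0, 0)
            )
            fp = Image.fromarray(footprint.astype(np.uint8) * 255).rotate(
                angle, resample=Image.NEAREST, expand=True, fillcolor=0
            )
            pixels = np.asarray(img)
            footprint = np.asarray(fp) > 127

    if placement.brightness != 100.0:
        pixels = np.clip(
            np.round(pixels.astype(float) * placement.brightness / 100.0), 0, 255
        ).astype(np.uint8)
    else:
        pixels = np.ascontiguousarray(pixels)

    footprint = np.ascontiguousarray(footprint)
    if not footprint.any():
        raise DegenerateTransformError("transform left an empty footprint")
    return Sprite(pixels=pixels, footprint=footprint, kind=sprite.kind)


def make_shadow(
    leaf_sprite: Sprite, params: GenerationParams, rng: np.random.Generator
) -> Sprite:
    """Shadow sprite: the leaf footprint under an independent pose draw.

    Compositing semantics are multiplicative darkening of underlying
    pixels by ``params.shadow_luminance_factor`` over the footprint.
    """
    lo, hi = params.leaf_size_range
    pose = Placement(
        sprite_kind="leaf",
        target_height=int(rng.integers(lo, hi + 1)),
        target_width=int(rng.integers(lo, hi + 1)),
        brightness=100.0,
        angle=float(rng.uniform(*params.angle_range)),
        position=(0, 0),
        layer="shadow",
    )
    transformed = transform_sprite(leaf_sprite, pose)
    return Sprite(
        pixels=np.zeros((*transformed.footprint.shape, 3), dtype=np.uint8),
        footprint=transformed.footprint,
        kind="shadow",
    )


# ---------------------------------------------------------------------------
# compositing
# ---------------------------------------------------------------------------

def _canvas_window(
    canvas_shape: tuple[int, int], footprint_shape: tuple[int, int], center: tuple[float, float]
) -> tuple[slice, slice, slice, slice] | None:
    """Clip a sprite centered at ``center`` to the canvas.

    Returns (canvas_rows, canvas_cols, sprite_rows, sprite_cols) or None if
    fully off-canvas.
    """
    ch, cw = canvas_shape
    sh, sw = footprint_shape
    x0 = int(round(center[0] - sw / 2.0))
    y0 = int(round(center[1] - sh / 2.0))
    cy0, cy1 = max(y0, 0), min(y0 + sh, ch)
    cx0, cx1 = max(x0, 0), min(x0 + sw, cw)
    if cy0 >= cy1 or cx0 >= cx1:
        return None
    return (
        slice(cy0, cy1),
        slice(cx0, cx1),
        slice(cy0 - y0, cy1 - y0),
        slice(cx0 - x0, cx1 - x0),
    )


def _clipped_footprint(
    canvas_shape: tuple[int, int], sprite: Sprite, center: tuple[float, float]
) -> np.ndarray | None:
    """Canvas-sized footprint the sprite would cover at ``center``, or None."""
    window = _canvas_window(canvas_shape, sprite.footprint.shape, center)
    if window is None:
        return None
    cr, cc, sr, sc = window
    painted = np.zeros(canvas_shape, dtype=bool)
    painted[cr, cc] = sprite.footprint[sr, sc]
    return painted if painted.any() else None


def _paste_opaque(
    canvas: np.ndarray, sprite: Sprite, center: tuple[float, float]
) -> np.ndarray | None:
    """Paint a sprite; returns the canvas-sized footprint painted, or None."""
    window = _canvas_window(canvas.shape[:2], sprite.footprint.shape, center)
    if window is None:
        return None
    cr, cc, sr, sc = window
    local = sprite.footprint[sr, sc]
    region = canvas[cr, cc]
    region[local] = sprite.pixels[sr, sc][local]
    canvas[cr, cc] = region
    painted = np.zeros(canvas.shape[:2], dtype=bool)
    painted[cr, cc] = local
    return painted if painted.any() else None


def _paste_shadow(
    canvas: np.ndarray, shadow: Sprite, center: tuple[float, float], factor: float
) -> None:
    window = _canvas_window(canvas.shape[:2], shadow.footprint.shape, center)
    if window is None:
        return
    cr, cc, sr, sc = window
    local = shadow.footprint[sr, sc]
    region = canvas[cr, cc].astype(float)
    region[local] *= factor
    canvas[cr, cc] = np.clip(np.round(region), 0, 255).astype(np.uint8)


def _pick(rng: np.random.Generator, sprites: list[Sprite]) -> Sprite:
    return sprites[int(rng.integers(len(sprites)))]


def compose_scene(
    assets: Sequence[Sprite], params: GenerationParams, seed: int
) -> CompositeSample:
    """Render one canopy scene with per-fruit amodal and visible masks."""
    params.validate()
    red = [s for s in assets if s.kind == "fruit_red"]
    green = [s for s in assets if s.kind == "fruit_green"]
    leaves = [s for s in assets if s.kind == "leaf"]
    backgrounds = [s for s in assets if s.kind == "background"]
    if not red or not green or not leaves or len(backgrounds) != 1:
        raise ValueError(
            "assets must contain >=1 red fruit, >=1 green fruit, >=1 leaf, "
            "and exactly 1 background"
        )
    cw, ch = params.canvas_size
    bg = backgrounds[0]
    if bg.size[0] < ch or bg.size[1] < cw:
        raise ValueError(f"background {bg.size} smaller than canvas {(ch, cw)}")

    rng = np.random.default_rng(seed)
    placements = sample_placements(params, rng)
    canvas = bg.pixels[:ch, :cw].copy()

    instances: list[FruitInstance] = []
    visible: list[np.ndarray] = []
    shadow_queue: Sprite | None = None

    for placement in placements:
        if placement.layer == "background_leaf":
            sprite = transform_sprite(_pick(rng, leaves), placement)
            _paste_opaque(canvas, sprite, placement.center)
        elif placement.layer == "fruit":
            is_red = placement.sprite_kind == "fruit_red"
            source = _pick(rng, red if is_red else green)
            sprite = transform_sprite(source, placement)
            unclipped_area = int(sprite.footprint.sum())
            min_area = params.min_visible_area_fraction * unclipped_area
            center = placement.center
            painted = _clipped_footprint(canvas.shape[:2], sprite, center)
            for _ in range(20):  # redraw position while clipped too small
                if painted is not None and painted.sum() >= min_area:
                    break
                center = (rng.uniform(0, cw), rng.uniform(0, ch))
                painted = _clipped_footprint(canvas.shape[:2], sprite, center)
            if painted is None:
                continue
            _paste_opaque(canvas, sprite, center)
            for v in visible:  # a later fruit occludes earlier ones
                v &= ~painted
            visible.append(painted.copy())
            instances.append(
                FruitInstance(
                    instance_id=len(instances),
                    amodal_mask=painted,
                    visible_mask=painted,  # finalized below
                    bbox=(0, 0, 0, 0),
                    center=(0.0, 0.0),
                    is_red=is_red,
                )
            )
        elif placement.layer == "shadow":
            shadow_queue = make_shadow(_pick(rng, leaves), params, rng)
            _paste_shadow(
                canvas, shadow_queue, placement.center, params.shadow_luminance_factor
            )
        elif placement.layer == "foreground_leaf":
            sprite = transform_sprite(_pick(rng, leaves), placement)
            painted = _paste_opaque(canvas, sprite, placement.center)
            if painted is not None:
                for v in visible:
                    v &= ~painted
        else:  # pragma: no cover
            raise ValueError(f"unknown layer {placement.layer!r}")

    for inst, vis in zip(instances, visible):
        rows = np.any(inst.amodal_mask, axis=1)
        cols = np.any(inst.amodal_mask, axis=0)
        y_idx = np.nonzero(rows)[0]
        x_idx = np.nonzero(cols)[0]
        inst.bbox = (int(x_idx[0]), int(y_idx[0]), int(x_idx[-1]) + 1, int(y_idx[-1]) + 1)
        ys, xs = np.nonzero(inst.amodal_mask)
        inst.center = (float(xs.mean() + 0.5), float(ys.mean() + 0.5))
        inst.visible_mask = vis

    return CompositeSample(
        image=canvas, instances=instances, params_used=params, seed_used=seed
    )


# ---------------------------------------------------------------------------
# dataset export
# ---------------------------------------------------------------------------

def sample_seed(master_seed: int, index: int) -> int:
    """Derive the per-sample seed: deterministic, order-independent."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0])


def _coco_annotation(
    ann_id: int, image_id: int, inst: FruitInstance
) -> dict:
    polygon = mask_to_polygon(inst.amodal_mask)
    seg = [float(c) for xy in polygon for c in xy]
    x0, y0, x1, y1 = inst.bbox
    return {
        "id": ann_id,
        "image_id": image_id,
        "category_id": 1,
        "segmentation": [seg],
        "bbox": [x0, y0, x1 - x0, y1 - y0],
        "area": int(inst.amodal_mask.sum()),
        "iscrowd": 0,
    }


def generate_dataset(
    params: GenerationParams,
    n_samples: int,
    out_dir: str | Path,
    assets: Sequence[Sprite] | None = None,
    execute: bool = True,
) -> dict:
    """Write composite images, per-instance amodal masks, and annotations.

    Produces ``sample_{i:05d}.png`` images, ``sample_{i:05d}_mask_{j}.png``
    0/255 masks, VIA and COCO annotation JSON, and a manifest. With
    ``execute=False`` only validates the configuration and returns the
    manifest skeleton (useful to vet paper-scale configs cheaply).
    """
    params.validate()
    if n_samples < 1:
        raise ConfigurationError("n_samples must be >= 1")
    out_dir = Path(out_dir)
    manifest: dict = {
        "n_samples": n_samples,
        "master_seed": params.seed,
        "canvas_size": list(params.canvas_size),
        "images": [],
    }
    if not execute:
        return manifest

    out_dir.mkdir(parents=True, exist_ok=True)
    if assets is None:
        cw, ch = params.canvas_size
        assets = generate_fixture_assets(params.seed, background_size=(cw, ch))

    via_annotations: list[PolygonAnnotation] = []
    coco_images: list[dict] = []
    coco_anns: list[dict] = []
    ann_id = 1
    for i in range(n_samples):
        seed_i = sample_seed(params.seed, i)
        sample = compose_scene(assets, params, seed_i)
        image_name = f"sample_{i:05d}.png"
        Image.fromarray(sample.image).save(out_dir / image_name)
        mask_names = []
        for inst in sample.instances:
            mask_name = f"sample_{i:05d}_mask_{inst.instance_id}.png"
            Image.fromarray(inst.amodal_mask.astype(np.uint8) * 255).save(
                out_dir / mask_name
            )
            mask_names.append(mask_name)
            via_annotations.append(
                PolygonAnnotation(
                    image_name=image_name,
                    vertices=mask_to_polygon(inst.amodal_mask),
                    attributes={"label": "apple"},
                )
            )
            coco_anns.append(_coco_annotation(ann_id, i, inst))
            ann_id += 1
        coco_images.append(
            {
                "id": i,
                "file_name": image_name,
                "width": sample.image.shape[1],
                "height": sample.image.shape[0],
            }
        )
        manifest["images"].append(
            {"file": image_name, "seed": seed_i, "masks": mask_names}
        )

    with open(out_dir / "annotations_via.json", "w") as fh:
        json.dump(write_via(via_annotations), fh, sort_keys=True)
    with open(out_dir / "annotations_coco.json", "w") as fh:
        json.dump(
            {
                "images": coco_images,
                "annotations": coco_anns,
                "categories": [{"id": 1, "name": "apple"}],
            },
            fh,
            sort_keys=True,
        )
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
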