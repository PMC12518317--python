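"""Procedural safflower-filament scene generator.

The real grading datasets in this domain are private, so this module renders
a structurally analogous benchmark: curved filament strokes (random cubic
Bezier curves with per-vertex width) on variably lit, optionally cluttered
or occluded backgrounds, at two quality grades and two task levels.

* ``premium`` filaments: vivid orange-red hue, high saturation, consistent
  stroke width, smooth curvature, rare breaks (high fibre integrity).
* ``normal`` filaments: dull yellow-brown hue, low saturation, irregular
  width, stronger curvature, frequent alpha gaps along the stroke (breaks).
* ``monomer`` scenes contain exactly one filament; ``cluster`` scenes draw
  many overlapping ones.

The two grades are separable by construction — their hue/saturation ranges
are disjoint — so a trivial mean-hue threshold classifies a default dataset
well and any failure of a trained network is attributable to the network.
An alternative "localized" cue mode puts the grade-discriminative colour
only into small spots along each stroke (shared base colour otherwise),
which rewards spatially selective models.

Determinism: a dataset's master seed spawns one child seed per image through
``numpy.random.SeedSequence(master).spawn(n)`` (index-keyed, so generation is
order-independent); a scene's ``(spec, seed)`` fully determines its pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "ValidationError", "SceneSpec", "GradeAppearance", "DatasetConfig",
    "DatasetManifest", "default_appearance", "render_scene",
    "generate_dataset", "allocate_splits", "largest_remainder",
    "augment", "rotate", "hflip", "brightness", "affine",
    "HueThresholdBaseline",
]

GRADES = ("premium", "normal")
LEVELS = ("cluster", "monomer")
LIGHTING = ("natural", "supplementary")
BACKGROUNDS = ("clean", "cluttered", "occluded")
VIEWS = ("close", "distant")
SPLITS = ("train", "val", "test")

MANIFEST_COLUMNS = ["path", "grade", "level", "lighting", "background",
                    "view", "split"]


class ValidationError(ValueError):
    """Raised for invalid scene/dataset specifications."""


# ---------------------------------------------------------------------------
# Scene specification and appearance model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneSpec:
    grade: str
    level: str
    n_filaments: int
    lighting: str = "natural"
    background: str = "clean"
    view: str = "close"
    seed: int = 0

    def __post_init__(self):
        if self.grade not in GRADES:
            raise ValidationError(f"grade must be one of {GRADES}")
        if self.level not in LEVELS:
            raise ValidationError(f"level must be one of {LEVELS}")
        if self.lighting not in LIGHTING:
            raise ValidationError(f"lighting must be one of {LIGHTING}")
        if self.background not in BACKGROUNDS:
            raise ValidationError(f"background must be one of {BACKGROUNDS}")
        if self.view not in VIEWS:
            raise ValidationError(f"view must be one of {VIEWS}")
        if self.level == "monomer" and self.n_filaments != 1:
            raise ValidationError("monomer scenes must have exactly one "
                                  "filament")
        if self.level == "cluster" and self.n_filaments < 5:
            raise ValidationError("cluster scenes need n_filaments >= 5")


@dataclass(frozen=True)
class GradeAppearance:
    """Grade-conditional stroke statistics.

    Hue is in degrees; saturation/brightness in [0, 1]; stroke width in
    pixels at a 224-pixel canvas (scaled with image size). ``break_prob``
    is the per-filament probability of each potential integrity gap.
    ``spot_fraction > 0`` switches to the localized-cue mode: the body of
    the stroke uses ``base_hue``/``base_sat`` (shared between grades) and
    only short spots along the stroke carry the grade's own hue.
    """

    hue: tuple[float, float]
    sat: tuple[float, float]
    val: tuple[float, float]
    width_mean: float
    width_jitter: float
    curvature: float
    break_prob: float
    spot_fraction: float = 0.0
    spot_bulge: float = 2.2   # width multiplier at spots (defect nodes)
    base_hue: tuple[float, float] = (30.0, 36.0)
    base_sat: tuple[float, float] = (0.45, 0.55)


_DEFAULTS = {
    "premium": GradeAppearance(hue=(8.0, 22.0), sat=(0.72, 0.95),
                               val=(0.72, 0.95), width_mean=3.2,
                               width_jitter=0.20, curvature=0.35,
                               break_prob=0.04),
    "normal": GradeAppearance(hue=(38.0, 58.0), sat=(0.35, 0.60),
                              val=(0.42, 0.65), width_mean=2.4,
                              width_jitter=0.55, curvature=0.80,
                              break_prob=0.35),
}


def default_appearance(grade: str, cue: str = "global") -> GradeAppearance:
    app = _DEFAULTS[grade]
    if cue == "global":
        return app
    if cue == "localized":
        # grade information lives only in short colour spots along the
        # stroke: every whole-stroke statistic (width, curvature, breaks,
        # brightness, base colour) is shared between the grades, so global
        # average cues are uninformative by construction
        return replace(app, spot_fraction=0.18, width_mean=2.8,
                       width_jitter=0.35, curvature=0.55, break_prob=0.15,
                       val=(0.55, 0.80))
    raise ValidationError(f"cue must be 'global' or 'localized', got {cue!r}")


def _hsv_to_rgb(h: float, s: float, v: float) -> np.ndarray:
    """Scalar HSV (h in degrees) to an RGB triple in [0, 1]."""
    h = (h % 360.0) / 60.0
    i = int(h) % 6
    f = h - int(h)
    p, q, t = v * (1 - s), v * (1 - s * f), v * (1 - s * (1 - f))
    rgb = [(v, t, p), (q, v, p), (p, v, t), (p, q, v), (t, p, v), (v, p, q)][i]
    return np.array(rgb, dtype=np.float32)


def _bezier(p: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Cubic Bezier through 4 control points; t shape (n,) -> (n, 2)."""
    u = 1.0 - t
    return (u[:, None] ** 3 * p[0] + 3 * (u ** 2 * t)[:, None] * p[1]
            + 3 * (u * t ** 2)[:, None] * p[2] + t[:, None] ** 3 * p[3])


def _stamp_disk(img: np.ndarray, cy: float, cx: float, r: float,
                color: np.ndarray, alpha: float = 1.0) -> None:
    size = img.shape[0]
    y0, y1 = int(max(0, cy - r - 1)), int(min(size, cy + r + 2))
    x0, x1 = int(max(0, cx - r - 1)), int(min(size, cx + r + 2))
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    cover = np.clip(r + 0.5 - np.sqrt(d2), 0.0, 1.0) * alpha
    img[y0:y1, x0:x1] += cover[:, :, None] * (color[None, None, :]
                                              - img[y0:y1, x0:x1])


def _smooth_noise(rng: np.random.Generator, n: int, scale: float) -> np.ndarray:
    """Low-frequency multiplicative jitter profile along a stroke."""
    knots = rng.normal(0.0, scale, size=max(4, n // 12))
    x = np.linspace(0, 1, knots.size)
    return np.interp(np.linspace(0, 1, n), x, knots)


def _draw_filament(img: np.ndarray, rng: np.random.Generator,
                   app: GradeAppearance, view: str) -> None:
    size = img.shape[0]
    scale = size / 224.0
    length = (rng.uniform(0.38, 0.70) if view == "close"
              else rng.uniform(0.16, 0.34)) * size
    p0 = rng.uniform(0.08 * size, 0.92 * size, size=2)
    ang = rng.uniform(0, 2 * math.pi)
    direction = np.array([math.sin(ang), math.cos(ang)])
    normal = np.array([-direction[1], direction[0]])
    p3 = p0 + direction * length
    bend = app.curvature * length
    p1 = p0 + direction * length / 3 + normal * rng.uniform(-bend, bend) * 0.5
    p2 = p0 + direction * 2 * length / 3 + normal * rng.uniform(-bend, bend) * 0.5
    npts = max(24, int(length))
    pts = _bezier(np.stack([p0, p1, p2, p3]), np.linspace(0, 1, npts))

    widths = (app.width_mean * scale
              * (1.0 + np.clip(_smooth_noise(rng, npts, app.width_jitter),
                               -0.8, 2.0)))
    widths = np.clip(widths, 0.6, None)

    # integrity gaps: each of a few candidate gaps realised with break_prob
    alpha = np.ones(npts)
    for _ in range(3):
        if rng.random() < app.break_prob:
            center = rng.uniform(0.15, 0.85)
            half = rng.uniform(0.015, 0.05)
            t = np.linspace(0, 1, npts)
            alpha[(t > center - half) & (t < center + half)] = 0.0

    body = _hsv_to_rgb(rng.uniform(*app.hue), rng.uniform(*app.sat),
                       rng.uniform(*app.val))
    if app.spot_fraction > 0.0:
        spot_color = body
        body = _hsv_to_rgb(rng.uniform(*app.base_hue),
                           rng.uniform(*app.base_sat),
                           rng.uniform(*app.val))
        n_spots = rng.integers(2, 5)
        spot_mask = np.zeros(npts, dtype=bool)
        t = np.linspace(0, 1, npts)
        for _ in range(n_spots):
            c = rng.uniform(0.1, 0.9)
            half = app.spot_fraction / (2 * n_spots)
            spot_mask |= (t > c - half) & (t < c + half)
    else:
        spot_mask = None

    shade = 1.0 + 0.12 * _smooth_noise(rng, npts, 1.0)
    for i in range(npts):
        if alpha[i] <= 0.0:
            continue
        color, width = body, widths[i]
        if spot_mask is not None and spot_mask[i]:
            # defect nodes: swollen, grade-coloured knots along the stroke,
            # wide enough to survive low-resolution rendering
            color, width = spot_color, widths[i] * app.spot_bulge
        _stamp_disk(img, pts[i, 0], pts[i, 1], width / 2,
                    np.clip(color * shade[i], 0, 1), alpha=float(alpha[i]))


def _draw_clutter(img: np.ndarray, rng: np.random.Generator) -> None:
    size = img.shape[0]
    for _ in range(rng.integers(6, 13)):
        c = rng.uniform(0.10, 0.30) * np.ones(3) + rng.uniform(-0.04, 0.04, 3)
        cy, cx = rng.uniform(0, size, 2)
        ry, rx = rng.uniform(0.02, 0.10, 2) * size
        yy, xx = np.mgrid[0:size, 0:size]
        mask = (((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2) < 1.0
        img[mask] += 0.6 * (c[None, :] - img[mask])


def _draw_decoys(img: np.ndarray, rng: np.random.Generator,
                 app: GradeAppearance, n_filaments: int, size: int) -> None:
    node_budget = 3 * n_filaments
    scale = size / 224.0
    r = app.width_mean * app.spot_bulge * scale / 2
    for grade in GRADES:
        palette = _DEFAULTS[grade]
        count = int(rng.integers(node_budget // 2, 3 * node_budget + 1))
        for _ in range(count):
            cy, cx = rng.uniform(0.02 * size, 0.98 * size, 2)
            color = _hsv_to_rgb(rng.uniform(*palette.hue),
                                rng.uniform(*palette.sat),
                                rng.uniform(*app.val))
            _stamp_disk(img, cy, cx, r * rng.uniform(0.8, 1.3), color)


def _draw_occluders(img: np.ndarray, rng: np.random.Generator) -> None:
    size = img.shape[0]
    for _ in range(rng.integers(2, 5)):
        c = rng.uniform(0.25, 0.45) * np.ones(3)
        y0 = int(rng.uniform(0, 0.8) * size)
        x0 = int(rng.uniform(0, 0.8) * size)
        h = int(rng.uniform(0.08, 0.25) * size)
        w = int(rng.uniform(0.08, 0.25) * size)
        img[y0:y0 + h, x0:x0 + w] = c[None, None, :]


def render_scene(spec: SceneSpec, appearance: GradeAppearance | None = None,
                 size: int = 224) -> np.ndarray:
    """Render one scene to an ``(size, size, 3)`` uint8 RGB array.

    Identical ``(spec, appearance, size)`` always yield bit-identical pixels.
    """
    if size < 64:
        raise ValidationError(f"size must be >= 64, got {size}")
    app = appearance if appearance is not None else _DEFAULTS[spec.grade]
    rng = np.random.default_rng(spec.seed)

    img = np.empty((size, size, 3), dtype=np.float32)
    # near-neutral (low-saturation) backing surface, so filament pixels are
    # the only strongly chromatic content in the scene
    base = np.array([0.175, 0.172, 0.168]) + rng.uniform(-0.015, 0.015)
    grad = np.linspace(-0.03, 0.03, size, dtype=np.float32)
    img[:] = base[None, None, :]
    img += grad[:, None, None]
    img += rng.normal(0, 0.01, size=img.shape).astype(np.float32)

    if spec.background in ("cluttered", "occluded"):
        _draw_clutter(img, rng)

    if app.spot_fraction > 0.0:
        # localized-cue regime: scatter off-filament decoy spots of BOTH
        # grades' spot palettes, in grade-independent randomized numbers,
        # so raw colour counts are uninformative and only the binding of
        # node colour to filament context carries the grade
        _draw_decoys(img, rng, app, spec.n_filaments, size)

    for _ in range(spec.n_filaments):
        _draw_filament(img, rng, app, spec.view)

    if spec.background == "occluded":
        _draw_occluders(img, rng)

    if spec.lighting == "natural":
        tint = np.array([1.03, 1.00, 0.95], dtype=np.float32)
    else:  # supplementary: brighter and cooler
        tint = 1.15 * np.array([0.97, 1.00, 1.06], dtype=np.float32)
    img *= tint[None, None, :]
    img += rng.normal(0, 0.012, size=img.shape).astype(np.float32)
    return (np.clip(img, 0, 1) * 255).round().astype(np.uint8)


# ---------------------------------------------------------------------------
# Dataset generation: manifests, stratified exact splits
# ---------------------------------------------------------------------------

def largest_remainder(total: int, weights: tuple) -> list[int]:
    """Apportion ``total`` across ``weights`` exactly (largest remainder)."""
    if total < 0 or any(w < 0 for w in weights) or sum(weights) <= 0:
        raise ValidationError("weights must be non-negative with positive sum")
    s = float(sum(weights))
    quotas = [total * w / s for w in weights]
    base = [int(math.floor(q)) for q in quotas]
    rest = total - sum(base)
    order = sorted(range(len(weights)),
                   key=lambda i: (-(quotas[i] - base[i]), i))
    for i in order[:rest]:
        base[i] += 1
    return base


def allocate_splits(cell_sizes: dict, ratio: tuple) -> dict:
    """Per-cell split counts whose global sums follow ``ratio`` exactly.

    Each cell is apportioned by largest remainder, water-filled against the
    remaining global quota so the global split sizes are exact. Raises if
    any (cell, split) allocation ends up empty (insufficient stratification).
    """
    total = sum(cell_sizes.values())
    remaining = largest_remainder(total, ratio)
    out: dict = {}
    cells = list(cell_sizes)
    for idx, cell in enumerate(cells):
        n = cell_sizes[cell]
        if idx == len(cells) - 1:
            alloc = list(remaining)
        else:
            alloc = largest_remainder(n, ratio)
            alloc = [min(a, r) for a, r in zip(alloc, remaining)]
            deficit = n - sum(alloc)
            while deficit > 0:
                # give to the split with the most remaining capacity
                j = max(range(len(alloc)),
                        key=lambda i: remaining[i] - alloc[i])
                alloc[j] += 1
                deficit -= 1
        remaining = [r - a for r, a in zip(remaining, alloc)]
        out[cell] = alloc
    for cell, alloc in out.items():
        if any(a < 1 for a in alloc):
            raise ValidationError(
                f"cell {cell} with {cell_sizes[cell]} images cannot cover "
                f"every split; increase the dataset size")
    return out


@dataclass
class DatasetConfig:
    out_dir: str | Path = "synth_dataset"
    n_images: int = 480
    image_size: int = 224
    split_ratio: tuple = (7, 2, 1)
    seed: int = 0
    premium_fraction: float = 0.52   # mild premium-majority imbalance
    cluster_fraction: float = 0.48   # slightly more monomer scenes
    cue: str = "global"
    p_natural: float = 0.60
    p_background: tuple = (0.51, 0.26, 0.23)
    p_close: float = 0.57

    def __post_init__(self):
        if self.n_images < 10:
            raise ValidationError("n_images must be >= 10")
        if len(self.split_ratio) != 3 or any(r <= 0 for r in self.split_ratio):
            raise ValidationError("split_ratio must be three positive numbers")


@dataclass
class DatasetManifest:
    """Image catalogue: one row per image plus generation provenance."""

    frame: pd.DataFrame
    root: Path
    seed: int
    config: dict = field(default_factory=dict)

    def records(self, split: str | None = None) -> pd.DataFrame:
        if split is None:
            return self.frame
        if split not in SPLITS:
            raise ValidationError(f"split must be one of {SPLITS}")
        return self.frame[self.frame["split"] == split]

    def save(self, path: str | Path | None = None) -> Path:
        path = Path(path) if path else self.root / "manifest.csv"
        self.frame.to_csv(path, index=False, columns=MANIFEST_COLUMNS)
        return path

    @classmethod
    def load(cls, path: str | Path, seed: int = 0) -> "DatasetManifest":
        path = Path(path)
        frame = pd.read_csv(path)
        missing = set(MANIFEST_COLUMNS) - set(frame.columns)
        if missing:
            raise ValidationError(f"manifest missing columns: {sorted(missing)}")
        return cls(frame=frame, root=path.parent, seed=seed)


def generate_dataset(config: DatasetConfig) -> DatasetManifest:
    """Render a full dataset: PNG images plus a CSV manifest.

    Stratified so every (grade x level) cell appears in every split, with
    global split sizes following the ratio exactly.
    """
    root = Path(config.out_dir)
    (root / "images").mkdir(parents=True, exist_ok=True)

    pf, cf = config.premium_fraction, config.cluster_fraction
    cell_weights = {
        ("premium", "cluster"): pf * cf,
        ("premium", "monomer"): pf * (1 - cf),
        ("normal", "cluster"): (1 - pf) * cf,
        ("normal", "monomer"): (1 - pf) * (1 - cf),
    }
    counts = largest_remainder(config.n_images,
                               tuple(cell_weights.values()))
    cell_sizes = dict(zip(cell_weights, counts))
    split_alloc = allocate_splits(cell_sizes, config.split_ratio)

    seeds = [int(s.generate_state(1)[0] % (2 ** 31))
             for s in np.random.SeedSequence(config.seed).spawn(config.n_images)]
    strat_rng = np.random.default_rng(
        np.random.SeedSequence((config.seed, 0xC0FFEE)))

    rows = []
    idx = 0
    for (grade, level), n_cell in cell_sizes.items():
        split_labels = sum(([s] * k for s, k in
                            zip(SPLITS, split_alloc[(grade, level)])), [])
        strat_rng.shuffle(split_labels)
        for j in range(n_cell):
            lighting = ("natural" if strat_rng.random() < config.p_natural
                        else "supplementary")
            background = BACKGROUNDS[
                strat_rng.choice(3, p=np.asarray(config.p_background)
                                 / sum(config.p_background))]
            view = "close" if strat_rng.random() < config.p_close else "distant"
            n_fil = (1 if level == "monomer"
                     else int(strat_rng.integers(10, 41)))
            spec = SceneSpec(grade=grade, level=level, n_filaments=n_fil,
                             lighting=lighting, background=background,
                             view=view, seed=seeds[idx])
            img = render_scene(spec, default_appearance(grade, config.cue),
                               size=config.image_size)
            rel = f"images/{grade}_{level}_{idx:05d}.png"
            Image.fromarray(img).save(root / rel)
            rows.append({"path": rel, "grade": grade, "level": level,
                         "lighting": lighting, "background": background,
                         "view": view, "split": split_labels[j]})
            idx += 1

    frame = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest = DatasetManifest(frame=frame, root=root, seed=config.seed,
                               config={k: (list(v) if isinstance(v, tuple)
                                           else str(v) if isinstance(v, Path)
                                           else v)
                                       for k, v in vars(config).items()})
    manifest.save()
    return manifest


# ---------------------------------------------------------------------------
# Augmentations
# ---------------------------------------------------------------------------

def _border_color(img: np.ndarray) -> tuple:
    border = np.concatenate([img[0], img[-1], img[:, 0], img[:, -1]])
    return tuple(int(v) for v in np.median(border, axis=0))


def rotate(img: np.ndarray, angle: float) -> np.ndarray:
    """Rotate about the centre, same output size, background-filled corners.

    Multiples of 90 degrees are exact pixel permutations.
    """
    pil = Image.fromarray(img)
    out = pil.rotate(angle, resample=Image.BILINEAR,
                     fillcolor=_border_color(img))
    return np.asarray(out)


def hflip(img: np.ndarray) -> np.ndarray:
    return img[:, ::-1].copy()


def brightness(img: np.ndarray, factor: float) -> np.ndarray:
    if factor < 0:
        raise ValidationError("brightness factor must be non-negative")
    return np.clip(img.astype(np.float32) * factor, 0, 255).round() \
             .astype(np.uint8)


def affine(img: np.ndarray, scale: float = 1.0, shear_deg: float = 0.0,
           tx: float = 0.0, ty: float = 0.0) -> np.ndarray:
    """Centre-anchored affine warp; output dims equal input dims."""
    h, w = img.shape[:2]
    cx, cy = w / 2.0, h / 2.0
    sh = math.tan(math.radians(shear_deg))
    # inverse map (output -> input) for PIL's AFFINE transform
    a, b = 1.0 / scale, sh / scale
    d, e = 0.0, 1.0 / scale
    c = cx - a * cx - b * cy - tx
    f = cy - d * cx - e * cy - ty
    pil = Image.fromarray(img)
    out = pil.transform((w, h), Image.AFFINE, (a, b, c, d, e, f),
                        resample=Image.BILINEAR,
                        fillcolor=_border_color(img))
    return np.asarray(out)


_AUG_OPS = ("rotate", "hflip", "brightness", "affine")


def augment(img: np.ndarray, ops, seed: int = 0) -> np.ndarray:
    """Apply the named augmentations with parameters drawn from ``seed``.

    Output dimensions always equal input dimensions.
    """
    rng = np.random.default_rng(seed)
    out = img
    for op in ops:
        if op == "rotate":
            out = rotate(out, float(rng.uniform(-25, 25)))
        elif op == "hflip":
            if rng.random() < 0.5:
                out = hflip(out)
        elif op == "brightness":
            out = brightness(out, float(rng.uniform(0.75, 1.25)))
        elif op == "affine":
            out = affine(out, scale=float(rng.uniform(0.9, 1.1)),
                         shear_deg=float(rng.uniform(-8, 8)),
                         tx=float(rng.uniform(-0.05, 0.05) * out.shape[1]),
                         ty=float(rng.uniform(-0.05, 0.05) * out.shape[0]))
        else:
            raise ValidationError(f"unknown augmentation {op!r}; "
                                  f"valid: {_AUG_OPS}")
    return out


# ---------------------------------------------------------------------------
# Trivial mean-hue baseline (separability guarantee)
# ---------------------------------------------------------------------------

class HueThresholdBaseline:
    """Classify by thresholding mean hue over the (saturation-masked)
    filament pixels. Exists to certify that the synthetic classes are
    separable before any network sees them.
    """

    def __init__(self, sat_min: float = 0.28, val_min: float = 0.32):
        self.sat_min = sat_min
        self.val_min = val_min
        self.threshold: float | None = None
        self.premium_below = True

    def feature(self, img: np.ndarray) -> float:
        from skimage.color import rgb2hsv
        hsv = rgb2hsv(img)
        mask = (hsv[..., 1] > self.sat_min) & (hsv[..., 2] > self.val_min)
        if mask.sum() < 10:
            mask = hsv[..., 1] > np.quantile(hsv[..., 1], 0.95)
        return float(hsv[..., 0][mask].mean())

    def _features(self, manifest: DatasetManifest, split: str):
        recs = manifest.records(split)
        feats, labels = [], []
        for _, r in recs.iterrows():
            img = np.asarray(Image.open(manifest.root / r["path"]))
            feats.append(self.feature(img))
            labels.append(1 if r["grade"] == "premium" else 0)
        return np.array(feats), np.array(labels)

    def fit(self, manifest: DatasetManifest, split: str = "train"):
        feats, labels = self._features(manifest, split)
        order = np.argsort(feats)
        f, y = feats[order], labels[order]
        cuts = np.concatenate([[f[0] - 1e-6], (f[1:] + f[:-1]) / 2,
                               [f[-1] + 1e-6]])
        best = (-1.0, cuts[0], True)
        for c in cuts:
            below = (feats <= c).astype(int)
            acc_b = (below == labels).mean()
            acc_a = ((1 - below) == labels).mean()
            if acc_b > best[0]:
                best = (acc_b, c, True)
            if acc_a > best[0]:
                best = (acc_a, c, False)
        _, self.threshold, self.premium_below = best
        return self

    def score(self, manifest: DatasetManifest, split: str = "test") -> float:
        if self.threshold is None:
            raise RuntimeError("fit the baseline before scoring")
        feats, labels = self._features(manifest, split)
        below = (feats <= self.threshold).astype(int)
        pred = below if self.premium_below else 1 - below
        return float((pred == labels).mean())
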