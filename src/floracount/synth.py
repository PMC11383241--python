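"""Seeded synthetic top-view scenes with ground-truth annotations.

Generates schematic 1 m^2-style relevée images: a noisy vegetation-green
background, optional unannotated clutter blobs, and floral count units drawn
as flat-colour shapes whose silhouette follows the species' morphology
(solitary disc, capitulum, spike, umbel, corymb).  Every drawn FCU gets a
tight bounding box — the exact pixel extent of its silhouette — so the
generator doubles as an oracle for the whole pipeline: tiling, balancing and
evaluation can be tested end-to-end without any real imagery.

Each species carries a unique flat key colour.  The default oracle detector
reads the generator's ground truth directly and corrupts it with
configurable error modes (misses, box jitter, label confusion between
look-alikes, spurious background detections); a colour-threshold detector
that actually scans the raster is provided for integration tests.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .fcu import FCURecord
from .voc import AnnotatedImage, Annotation, Box, write_voc
from .evaluation import Detection

__all__ = [
    "MORPHOLOGIES",
    "SpeciesSpec",
    "FixedAbundance",
    "PoissonAbundance",
    "ZipfAbundance",
    "SceneConfig",
    "CorruptionSpec",
    "default_species",
    "generate_scene",
    "generate_dataset",
    "oracle_detect",
    "color_threshold_detect",
]

MORPHOLOGIES = ("solitary", "capitulum", "spike", "umbel", "corymb")

#: Background base colour and noise amplitude (vegetation green).
_BG_BASE = np.array([62, 98, 46], dtype=np.int16)
_BG_NOISE = 18
#: Clutter palette: soil, litter, stones — never a species key colour.
_CLUTTER_COLORS = ((121, 96, 62), (150, 150, 150), (90, 70, 50))


@dataclass(frozen=True)
class SpeciesSpec:
    """A synthetic species: key colour, FCU morphology and size range."""

    name: str
    key_color: tuple[int, int, int]
    morphology: str = "solitary"
    size_px: tuple[int, int] = (10, 24)
    fcu_record: Optional[FCURecord] = None

    def __post_init__(self) -> None:
        if self.morphology not in MORPHOLOGIES:
            raise ValueError(f"{self.name}: unknown morphology {self.morphology!r}")
        lo, hi = self.size_px
        if lo < 3 or hi < lo:
            raise ValueError(f"{self.name}: bad size range {self.size_px}")


@dataclass(frozen=True)
class FixedAbundance:
    counts: Mapping[str, int]


@dataclass(frozen=True)
class PoissonAbundance:
    means: Mapping[str, float]


@dataclass(frozen=True)
class ZipfAbundance:
    """Deterministic long-tail: species k (1-based rank in the species list)
    receives ``round(n_total * k^-exponent / H)`` instances per scene, so
    counts are monotone non-increasing in rank by construction."""

    exponent: float = 1.0
    n_total: int = 30


Abundance = Union[FixedAbundance, PoissonAbundance, ZipfAbundance]


@dataclass(frozen=True)
class SceneConfig:
    width: int = 672
    height: int = 448
    species: tuple[SpeciesSpec, ...] = ()
    abundance: Abundance = field(default_factory=lambda: ZipfAbundance())
    overlap_allowed: bool = True
    clutter_rate: float = 3.0
    landscape: str = "grassland"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 64 or self.height < 64:
            raise ValueError(f"scene must be at least 64x64, got {self.width}x{self.height}")
        if self.clutter_rate < 0:
            raise ValueError("clutter_rate must be non-negative")
        colors = [s.key_color for s in self.species]
        if len(set(colors)) != len(colors):
            raise ValueError("species key colours must be pairwise distinct")
        forbidden = set(_CLUTTER_COLORS)
        for s in self.species:
            if s.key_color in forbidden:
                raise ValueError(f"{s.name}: key colour collides with clutter palette")


@dataclass(frozen=True)
class CorruptionSpec:
    """Independent per-annotation error modes for the oracle detector.

    ``label_confusion[a][b]`` is the probability a detection of species *a*
    is reported as species *b* (row sums must stay <= 1); ``tp_score`` and
    ``fp_score`` are uniform (low, high) score ranges.  The all-default
    spec is the perfect detector: every annotation returned exactly, score 1.
    """

    miss_rate: float = 0.0
    jitter_px: int = 0
    label_confusion: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    false_positive_rate: float = 0.0
    tp_score: tuple[float, float] = (1.0, 1.0)
    fp_score: tuple[float, float] = (0.55, 0.95)

    def __post_init__(self) -> None:
        if not (0 <= self.miss_rate <= 1):
            raise ValueError("miss_rate must be in [0,1]")
        if self.jitter_px < 0 or self.false_positive_rate < 0:
            raise ValueError("jitter_px and false_positive_rate must be >= 0")
        for src, row in self.label_confusion.items():
            if sum(row.values()) > 1 + 1e-12:
                raise ValueError(f"confusion row for {src!r} sums above 1")


# A qualitative palette of saturated flower-like colours, far from the
# green/brown/gray background tones.
_PALETTE = (
    (237, 28, 36),    # poppy red
    (255, 242, 0),    # dandelion yellow
    (255, 255, 255),  # daisy white
    (63, 72, 204),    # cornflower blue
    (163, 73, 164),   # orchid purple
    (255, 127, 39),   # hawkweed orange
    (255, 174, 201),  # clover pink
    (0, 162, 232),    # speedwell azure
    (255, 201, 14),   # buttercup gold
    (200, 191, 231),  # pale violet
    (136, 0, 21),     # deep red
    (239, 228, 176),  # cream
    (181, 230, 29),   # bright chartreuse
    (112, 146, 190),  # slate blue
    (255, 255, 128),  # pale yellow
    (128, 0, 64),     # wine
)


def default_species(n: int, size_px: tuple[int, int] = (10, 24)) -> tuple[SpeciesSpec, ...]:
    """``n`` synthetic species with distinct palette colours, morphologies
    cycling through the five archetypes."""
    if n > len(_PALETTE):
        raise ValueError(f"at most {len(_PALETTE)} default species available")
    return tuple(
        SpeciesSpec(
            name=f"species_{k:02d}",
            key_color=_PALETTE[k],
            morphology=MORPHOLOGIES[k % len(MORPHOLOGIES)],
            size_px=size_px,
        )
        for k in range(n)
    )


def _disc_mask(canvas: np.ndarray, cx: float, cy: float, r: float) -> None:
    h, w = canvas.shape
    y0, y1 = max(0, int(cy - r) - 1), min(h, int(cy + r) + 2)
    x0, x1 = max(0, int(cx - r) - 1), min(w, int(cx + r) + 2)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    canvas[y0:y1, x0:x1] |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def _disc_chain(
    canvas: np.ndarray, x0: float, y0: float, x1: float, y1: float, r: float
) -> None:
    """Discs along a segment, spaced so the chain is 8-connected."""
    length = math.hypot(x1 - x0, y1 - y0)
    n = max(2, int(math.ceil(length / max(r, 1.0))) + 1)
    for k in range(n):
        t = k / (n - 1)
        _disc_mask(canvas, x0 + t * (x1 - x0), y0 + t * (y1 - y0), r)


def _fcu_mask(morphology: str, size: int, rng: np.random.Generator) -> np.ndarray:
    """Boolean silhouette of one FCU in a local canvas, cropped tight.

    All morphologies paint a single connected blob, so the colour-threshold
    detector sees one component per FCU.
    """
    s = float(size)
    pad = size + 4
    canvas = np.zeros((pad, pad), dtype=bool)
    c = pad / 2
    if morphology == "solitary":
        _disc_mask(canvas, c, c, s / 2)
    elif morphology == "capitulum":
        _disc_mask(canvas, c, c, 0.4 * s)
        for ang in np.linspace(0, 2 * math.pi, 8, endpoint=False):
            _disc_mask(canvas, c + 0.4 * s * math.sin(ang), c + 0.4 * s * math.cos(ang), s / 8)
    elif morphology == "spike":
        x = c + rng.uniform(-1, 1)
        _disc_chain(canvas, x, c - s / 2 + s / 7, x, c + s / 2 - s / 7, s / 7)
        _disc_mask(canvas, x, c - s / 2 + s / 8, s / 8)
    elif morphology == "umbel":
        rays = int(rng.integers(5, 9))
        for k in range(rays):
            ang = 2 * math.pi * k / rays + rng.uniform(0, 0.4)
            tx = c + 0.4 * s * math.cos(ang)
            ty = c + 0.4 * s * math.sin(ang)
            _disc_chain(canvas, c, c, tx, ty, s / 12)
            _disc_mask(canvas, tx, ty, s / 8)
    elif morphology == "corymb":
        for _ in range(int(rng.integers(4, 8))):
            tx = c + rng.uniform(-0.35, 0.35) * s
            ty = c + rng.uniform(-0.35, 0.35) * s
            _disc_chain(canvas, c, c, tx, ty, s / 10)
            _disc_mask(canvas, tx, ty, s / 6)
    ys, xs = np.nonzero(canvas)
    return canvas[ys.min() : ys.max() + 1, xs.min() : xs.max() + 1]


def _instance_counts(cfg: SceneConfig, rng: np.random.Generator) -> dict[str, int]:
    names = [s.name for s in cfg.species]
    ab = cfg.abundance
    if isinstance(ab, FixedAbundance):
        unknown = set(ab.counts) - set(names)
        if unknown:
            raise ValueError(f"abundance names not in species list: {sorted(unknown)}")
        return {n: int(ab.counts.get(n, 0)) for n in names}
    if isinstance(ab, PoissonAbundance):
        return {n: int(rng.poisson(ab.means.get(n, 0.0))) for n in names}
    if isinstance(ab, ZipfAbundance):
        weights = np.array([(k + 1) ** -ab.exponent for k in range(len(names))])
        probs = weights / weights.sum()
        return {n: int(round(ab.n_total * p)) for n, p in zip(names, probs)}
    raise TypeError(f"unknown abundance model {type(ab).__name__}")


def _paint_background(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    noise = rng.integers(-_BG_NOISE, _BG_NOISE + 1, size=(cfg.height, cfg.width, 3))
    img = np.clip(_BG_BASE[None, None, :] + noise, 0, 255).astype(np.uint8)
    n_clutter = int(rng.poisson(cfg.clutter_rate))
    for _ in range(n_clutter):
        r = float(rng.uniform(4, 18))
        cx = float(rng.uniform(0, cfg.width))
        cy = float(rng.uniform(0, cfg.height))
        color = _CLUTTER_COLORS[int(rng.integers(len(_CLUTTER_COLORS)))]
        mask = np.zeros((cfg.height, cfg.width), dtype=bool)
        _disc_mask(mask, cx, cy, r)
        img[mask] = color
    return img


def generate_scene(cfg: SceneConfig, seed: Optional[int] = None) -> AnnotatedImage:
    """Render one annotated scene; deterministic given (config, seed).

    Every FCU instance is placed uniformly at random (rejection-sampled to
    avoid box overlap when ``overlap_allowed`` is off), painted in its
    species key colour, and annotated with the exact pixel bounding box of
    its silhouette.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    img = _paint_background(cfg, rng)
    counts = _instance_counts(cfg, rng)
    spec_by_name = {s.name: s for s in cfg.species}
    annotations: list[Annotation] = []
    k = 0
    for name in counts:
        spec = spec_by_name[name]
        for _ in range(counts[name]):
            size = int(rng.integers(spec.size_px[0], spec.size_px[1] + 1))
            mask = _fcu_mask(spec.morphology, size, rng)
            mh, mw = mask.shape
            if mw > cfg.width or mh > cfg.height:
                raise ValueError(f"{name}: FCU of size {size} exceeds the scene")
            for attempt in range(100):
                x0 = int(rng.integers(0, cfg.width - mw + 1))
                y0 = int(rng.integers(0, cfg.height - mh + 1))
                box = Box(x0, y0, x0 + mw, y0 + mh)
                if cfg.overlap_allowed or not any(
                    box.intersection_area(a.box) for a in annotations
                ):
                    break
            img[y0 : y0 + mh, x0 : x0 + mw][mask] = spec.key_color
            annotations.append(Annotation(name, box, annotation_id=f"syn#{k}"))
            k += 1
    return AnnotatedImage(
        image_id="synthetic-scene",
        width=cfg.width,
        height=cfg.height,
        annotations=annotations,
        landscape=cfg.landscape,
        pixels=img,
    )


def generate_dataset(
    cfg: SceneConfig,
    n_images: int,
    seed: int = 0,
    out_dir=None,
    start: datetime = datetime(2021, 6, 1, 8, 0),
    minutes_apart: int = 5,
) -> tuple[list[AnnotatedImage], dict]:
    """Generate ``n_images`` scenes with convention-compliant ids.

    Image ids are ``YYYYMMDD-HHMM-<landscape>`` with synthetic timestamps
    ``minutes_apart`` minutes apart.  When ``out_dir`` is given, JPEG+XML
    pairs are written there.  Returns the images and a manifest with
    per-species annotation totals.
    """
    if n_images < 1:
        raise ValueError(f"n_images must be >= 1, got {n_images}")
    rng = np.random.default_rng(seed)
    images = []
    totals: dict[str, int] = {}
    for i in range(n_images):
        scene = generate_scene(cfg, seed=int(rng.integers(2**31)))
        ts = start + timedelta(minutes=i * minutes_apart)
        scene.image_id = f"{ts.strftime('%Y%m%d-%H%M')}-{cfg.landscape}"
        scene.capture_datetime = ts
        # re-key annotation ids to the final image id
        scene.annotations = [
            Annotation(a.species_label, a.box, f"{scene.image_id}#{j}")
            for j, a in enumerate(scene.annotations)
        ]
        for a in scene.annotations:
            totals[a.species_label] = totals.get(a.species_label, 0) + 1
        if out_dir is not None:
            write_voc(scene, Path(out_dir))
        images.append(scene)
    manifest = {
        "n_images": n_images,
        "seed": seed,
        "per_species_totals": dict(sorted(totals.items())),
        "n_annotations": sum(totals.values()),
    }
    return images, manifest


def _jitter_box(box: Box, jitter: int, width: int, height: int, rng) -> Box:
    xmin = box.xmin + int(rng.integers(-jitter, jitter + 1))
    ymin = box.ymin + int(rng.integers(-jitter, jitter + 1))
    xmax = box.xmax + int(rng.integers(-jitter, jitter + 1))
    ymax = box.ymax + int(rng.integers(-jitter, jitter + 1))
    xmin = max(0, min(xmin, width - 1))
    ymin = max(0, min(ymin, height - 1))
    xmax = max(xmin + 1, min(xmax, width))
    ymax = max(ymin + 1, min(ymax, height))
    return Box(xmin, ymin, xmax, ymax)


def oracle_detect(
    image: AnnotatedImage,
    corruption: CorruptionSpec = CorruptionSpec(),
    seed: int = 0,
    species_specs: Sequence[SpeciesSpec] = (),
) -> list[Detection]:
    """Detections derived from the ground-truth annotations.

    With the default (zero) corruption this returns exactly the annotated
    boxes with correct labels and score 1.0.  Error modes act independently
    per annotation: drop with ``miss_rate``, jitter box corners by up to
    ``jitter_px``, relabel per the confusion rows, and add
    ``Poisson(false_positive_rate)`` spurious detections with random boxes.
    Deterministic given (image, corruption, seed).
    """
    rng = np.random.default_rng(seed)
    dets: list[Detection] = []
    for ann in image.annotations:
        if corruption.miss_rate and rng.random() < corruption.miss_rate:
            continue
        box = ann.box
        if corruption.jitter_px:
            box = _jitter_box(box, corruption.jitter_px, image.width, image.height, rng)
        label = ann.species_label
        row = corruption.label_confusion.get(label)
        if row:
            u, acc = rng.random(), 0.0
            for target, p in row.items():
                acc += p
                if u < acc:
                    label = target
                    break
        lo, hi = corruption.tp_score
        score = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
        dets.append(Detection(box, label, score, image_id=image.image_id))

    if corruption.false_positive_rate:
        labels = [s.name for s in species_specs] or sorted(
            image.species_present
        ) or ["unknown"]
        for _ in range(int(rng.poisson(corruption.false_positive_rate))):
            w = int(rng.integers(6, max(7, image.width // 8)))
            h = int(rng.integers(6, max(7, image.height // 8)))
            x0 = int(rng.integers(0, max(1, image.width - w)))
            y0 = int(rng.integers(0, max(1, image.height - h)))
            lo, hi = corruption.fp_score
            dets.append(
                Detection(
                    Box(x0, y0, x0 + w, y0 + h),
                    labels[int(rng.integers(len(labels)))],
                    float(rng.uniform(lo, hi)) if hi > lo else float(lo),
                    image_id=image.image_id,
                )
            )
    return dets


def color_threshold_detect(
    image: AnnotatedImage, species_specs: Sequence[SpeciesSpec]
) -> list[Detection]:
    """Raster-path detector: exact key-colour match + connected components.

    Each connected blob of a species' key colour becomes one detection with
    the blob's pixel bounding box and score 1.0.  On non-overlapping scenes
    this reproduces the ground truth exactly.
    """
    from skimage.measure import label as cc_label, regionprops

    if image.pixels is None:
        raise ValueError("color_threshold_detect needs an image raster")
    dets = []
    for spec in species_specs:
        mask = np.all(image.pixels == np.array(spec.key_color, dtype=np.uint8), axis=-1)
        if not mask.any():
            continue
        for region in regionprops(cc_label(mask, connectivity=2)):
            y0, x0, y1, x1 = region.bbox
            dets.append(
                Detection(Box(x0, y0, x1, y1), spec.name, 1.0, image_id=image.image_id)
            )
    return dets
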