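"""Annotation-aware image tiling ("smart tiling").

High-resolution relevée photographs (6720x4480 px) far exceed the maximum
input size of common detection backbones (1333 px per axis).  Rather than
downscaling — which destroys the fine floral detail the classifier needs —
the image is cut into a mosaic of near-input-size tiles.  A naive uniform
grid would slice through annotated floral count units; here each cut line
may move within a margin band around its uniform position and is placed
where it crosses the fewest annotation boxes.

After cutting, an annotation intersecting several tiles is kept exactly
once: in the tile containing the largest fragment of its box, clipped to
that tile.  This prevents double counting while conserving the total number
of annotations.

A cut at position ``p`` on the x axis crosses a half-open box iff
``xmin < p < xmax``; a cut exactly on a box edge does not cut it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .voc import AnnotatedImage, Annotation, Box

__all__ = [
    "TilingConfig",
    "TilingPlan",
    "Tile",
    "grid_dimensions",
    "uniform_cuts",
    "cut_cost",
    "optimize_cuts",
    "apply_tiling",
    "inference_tiling",
    "tile_image_id",
]


@dataclass(frozen=True)
class TilingConfig:
    """Geometry knobs.

    ``max_input`` is the detector's maximum input side (default 1333 px);
    ``margin`` the allowed relative slack, so a tile side may reach
    ``max_input * (1 + margin)`` and each interior cut may move by up to
    ``margin`` times the uniform tile size.
    """

    max_input: int = 1333
    margin: float = 0.20

    def __post_init__(self) -> None:
        if self.max_input < 1:
            raise ValueError(f"max_input must be >= 1, got {self.max_input}")
        if not (0 <= self.margin < 0.5):
            raise ValueError(f"margin must be in [0, 0.5), got {self.margin}")

    @property
    def max_tile_side(self) -> int:
        """Hard upper bound on any tile side, in pixels."""
        return math.floor(self.max_input * (1 + self.margin))


@dataclass(frozen=True)
class TilingPlan:
    width: int
    height: int
    x_cuts: tuple[int, ...]
    y_cuts: tuple[int, ...]

    def __post_init__(self) -> None:
        for cuts, dim, axis in ((self.x_cuts, self.width, "x"), (self.y_cuts, self.height, "y")):
            prev = 0
            for c in cuts:
                if not (prev < c < dim):
                    raise ValueError(f"{axis}-cuts {cuts} not strictly increasing inside (0,{dim})")
                prev = c

    @property
    def n_x(self) -> int:
        return len(self.x_cuts) + 1

    @property
    def n_y(self) -> int:
        return len(self.y_cuts) + 1

    @property
    def n_tiles(self) -> int:
        return self.n_x * self.n_y

    def tile_rects(self) -> list[tuple[int, int, Box]]:
        """``(row, col, rect)`` for every tile; rects partition the extent."""
        xs = (0, *self.x_cuts, self.width)
        ys = (0, *self.y_cuts, self.height)
        return [
            (r, c, Box(xs[c], ys[r], xs[c + 1], ys[r + 1]))
            for r in range(self.n_y)
            for c in range(self.n_x)
        ]


@dataclass(frozen=True)
class Tile:
    """A sub-image with annotations reassigned to tile-local coordinates.

    ``provenance`` maps each tile-local annotation id to the parent
    annotation id it was derived from.
    """

    parent_image_id: str
    row: int
    col: int
    rect: Box
    annotations: tuple[Annotation, ...]
    provenance: dict[str, str] = field(default_factory=dict)

    @property
    def tile_id(self) -> str:
        return tile_image_id(self.parent_image_id, self.row, self.col)

    @property
    def width(self) -> int:
        return self.rect.width

    @property
    def height(self) -> int:
        return self.rect.height

    def to_annotated_image(self, parent_pixels=None) -> AnnotatedImage:
        pixels = None
        if parent_pixels is not None:
            r = self.rect
            pixels = parent_pixels[r.ymin : r.ymax, r.xmin : r.xmax]
        return AnnotatedImage(
            image_id=self.tile_id,
            width=self.width,
            height=self.height,
            annotations=list(self.annotations),
            pixels=pixels,
        )


def tile_image_id(parent_id: str, row: int, col: int) -> str:
    return f"{parent_id}_r{row}c{col}"


def grid_dimensions(width: int, height: int, cfg: TilingConfig) -> tuple[int, int]:
    """Fewest tiles per axis whose uniform size respects the enlarged bound.

    ``n_axis = ceil(dim / (max_input * (1 + margin)))``; the 30.4 Mpx survey
    geometry (6720x4480 at max_input 1333, margin 0.2) yields a 5x3 mosaic.
    """
    if width < 1 or height < 1:
        raise ValueError(f"invalid image size {width}x{height}")
    bound = cfg.max_input * (1 + cfg.margin)
    return math.ceil(width / bound), math.ceil(height / bound)


def uniform_cuts(dim: int, n: int) -> tuple[int, ...]:
    """Interior cut positions of an equal-size split: round(j*dim/n)."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if n > dim:
        raise ValueError(f"cannot cut {dim} px into {n} tiles of >= 1 px")
    return tuple(round(j * dim / n) for j in range(1, n))


def _crossed_by_vertical(x: int, boxes: Sequence[Box]) -> set[int]:
    return {i for i, b in enumerate(boxes) if b.xmin < x < b.xmax}


def _crossed_by_horizontal(y: int, boxes: Sequence[Box]) -> set[int]:
    return {i for i, b in enumerate(boxes) if b.ymin < y < b.ymax}


def cut_cost(
    cuts_x: Sequence[int], cuts_y: Sequence[int], annotations: Iterable[Annotation]
) -> int:
    """Number of distinct annotations crossed by at least one cut line."""
    boxes = [a.box for a in annotations]
    crossed: set[int] = set()
    for x in cuts_x:
        crossed |= _crossed_by_vertical(x, boxes)
    for y in cuts_y:
        crossed |= _crossed_by_horizontal(y, boxes)
    return len(crossed)


def _optimize_axis(
    dim: int, n: int, intervals: list[tuple[int, int]], cfg: TilingConfig
) -> tuple[int, ...]:
    """Place ``n-1`` cuts on one axis minimizing total line-box crossings.

    Each cut j may lie within ``margin * (dim/n)`` of its uniform position
    (integer positions, clamped inside the image); consecutive cuts — with 0
    and ``dim`` as virtual ends — must stay strictly increasing and no tile
    side may exceed ``cfg.max_tile_side``.  Solved exactly by dynamic
    programming over candidate positions; among minimum-crossing solutions
    the one closest to the uniform grid is taken (then smallest coordinates),
    so the no-annotation case returns the uniform cuts unchanged.

    ``intervals`` are the ``(lo, hi)`` extents of annotation boxes on this
    axis; a cut at p crosses a box iff ``lo < p < hi``.
    """
    if n == 1:
        return ()
    t = dim / n
    half = cfg.margin * t
    max_side = cfg.max_tile_side
    uniform = uniform_cuts(dim, n)

    candidates: list[list[int]] = []
    for j, c in enumerate(uniform, start=1):
        lo = max(1, math.ceil(c - half))
        hi = min(dim - 1, math.floor(c + half))
        if lo > hi:
            lo = hi = min(max(c, 1), dim - 1)
        candidates.append(list(range(lo, hi + 1)))

    def line_cost(p: int) -> int:
        return sum(1 for lo, hi in intervals if lo < p < hi)

    # DP state: (total crossings, total |pos-uniform|, reversed position
    # tuple) — lexicographic order implements the tie-breaks.
    INF = (math.inf, math.inf, ())
    prev: dict[int, tuple] = {0: (0, 0.0, ())}
    for j, cand in enumerate(candidates):
        cur: dict[int, tuple] = {}
        for p in cand:
            cost_p = line_cost(p)
            dist_p = abs(p - uniform[j])
            best = INF
            for q, (cq, dq, path) in prev.items():
                if q < p and p - q <= max_side:
                    state = (cq + cost_p, dq + dist_p, path + (p,))
                    if state < best:
                        best = state
            if best is not INF:
                cur[p] = best
        if not cur:
            raise ValueError(
                f"no feasible cut placement on axis of length {dim} with {n} tiles"
            )
        prev = cur
    best = min(
        (state for q, state in prev.items() if dim - q <= max_side),
        default=None,
    )
    if best is None:
        raise ValueError(
            f"no feasible cut placement on axis of length {dim} with {n} tiles"
        )
    return best[2]


def optimize_cuts(image: AnnotatedImage, cfg: TilingConfig) -> TilingPlan:
    """Find the least destructive cut lines within the margin bands.

    Axes are optimized independently (a vertical line position never changes
    which boxes a horizontal line crosses).  With ``margin < 0.5`` the bands
    of neighbouring cuts on one axis cannot overlap, so the per-axis search
    is exact for the line-crossing objective.
    """
    n_x, n_y = grid_dimensions(image.width, image.height, cfg)
    x_int = [(a.box.xmin, a.box.xmax) for a in image.annotations]
    y_int = [(a.box.ymin, a.box.ymax) for a in image.annotations]
    return TilingPlan(
        width=image.width,
        height=image.height,
        x_cuts=_optimize_axis(image.width, n_x, x_int, cfg),
        y_cuts=_optimize_axis(image.height, n_y, y_int, cfg),
    )


def inference_tiling(width: int, height: int, cfg: TilingConfig) -> TilingPlan:
    """Equal-size mosaic for unannotated images (inference mode)."""
    n_x, n_y = grid_dimensions(width, height, cfg)
    return TilingPlan(
        width=width,
        height=height,
        x_cuts=uniform_cuts(width, n_x),
        y_cuts=uniform_cuts(height, n_y),
    )


def apply_tiling(image: AnnotatedImage, plan: TilingPlan) -> list[Tile]:
    """Cut the image along the plan and reassign annotations.

    Each parent annotation lands in exactly one tile: the tile where its
    clipped fragment has the largest area (ties to the smaller (row, col)),
    stored clipped and in tile-local coordinates.  The total annotation
    count is conserved.
    """
    if plan.width != image.width or plan.height != image.height:
        raise ValueError(
            f"plan is for {plan.width}x{plan.height}, image "
            f"{image.image_id!r} is {image.width}x{image.height}"
        )
    rects = plan.tile_rects()
    assigned: dict[tuple[int, int], list[tuple[Annotation, str]]] = {
        (r, c): [] for r, c, _ in rects
    }
    for ann in image.annotations:
        best_key: Optional[tuple[int, int]] = None
        best_area = 0
        best_frag: Optional[Box] = None
        for r, c, rect in rects:  # rects iterate in (row, col) order: first max wins ties
            frag = ann.box.clip(rect.xmin, rect.ymin, rect.xmax, rect.ymax)
            if frag is not None and frag.area > best_area:
                best_key, best_area, best_frag = (r, c), frag.area, frag
        assert best_frag is not None and best_key is not None
        r, c = best_key
        rect = next(rb for rr, cc, rb in rects if (rr, cc) == best_key)
        local = best_frag.shift(-rect.xmin, -rect.ymin)
        k = len(assigned[best_key])
        local_id = f"{tile_image_id(image.image_id, r, c)}#{k}"
        assigned[best_key].append(
            (Annotation(ann.species_label, local, local_id), ann.annotation_id)
        )

    tiles = []
    for r, c, rect in rects:
        pairs = assigned[(r, c)]
        tiles.append(
            Tile(
                parent_image_id=image.image_id,
                row=r,
                col=c,
                rect=rect,
                annotations=tuple(a for a, _ in pairs),
                provenance={a.annotation_id: pid for a, pid in pairs},
            )
        )
    return tiles
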