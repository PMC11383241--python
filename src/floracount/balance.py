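"""Exact-quota balanced subset selection over image tiles.

Field survey data is long-tailed: a few abundant species, many rare ones.
Training a detector directly on such data biases it toward the majority
classes, so instead a subset of tiles is selected that contains an exact,
preset number of annotations per species in each of the train/eval/test
splits (e.g. 250/50/50).  Selecting a tile for one species drags along any
other annotations it holds, which makes hitting the quotas exactly a
combinatorial problem; exhaustive search over tile combinations is
infeasible, so a randomized greedy heuristic with restarts is used.  A
species for which no solution is found within the attempt budget is dropped
rather than under-filled: quotas are exact for every retained species, by
construction.

Tiles from one parent image may land in different splits — no grouping
constraint is applied, which maximizes the tiles available for training.
"""

from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Union

from .tiling import Tile
from .voc import AnnotatedImage

__all__ = [
    "SPLITS",
    "Quota",
    "SplitAssignment",
    "tile_species_counts",
    "select_balanced_subset",
    "verify_quota",
]

SPLITS = ("train", "eval", "test")

TileLike = Union[Tile, AnnotatedImage]


@dataclass(frozen=True)
class Quota:
    """Required annotations per species in each split."""

    train: int = 250
    eval: int = 50
    test: int = 50

    def __post_init__(self) -> None:
        for split in SPLITS:
            if getattr(self, split) < 0:
                raise ValueError(f"negative quota for {split}")

    def __getitem__(self, split: str) -> int:
        if split not in SPLITS:
            raise KeyError(split)
        return getattr(self, split)

    @property
    def total(self) -> int:
        return self.train + self.eval + self.test


@dataclass
class SplitAssignment:
    """Result of the selection: tile -> split plus the achieved-count ledger.

    ``assignment`` maps every candidate tile id to one of train/eval/test/
    unused.  ``ledger[(species, split)]`` holds the achieved annotation
    count, which equals the quota exactly for every retained species.
    Annotations of dropped species inside selected tiles are not counted —
    downstream they are treated as background.
    """

    assignment: dict[str, str]
    retained_species: list[str]
    dropped_species: list[str]
    ledger: dict[tuple[str, str], int]
    quota: Quota
    seed: int
    attempts_used: int = 1

    def tiles_in(self, split: str) -> list[str]:
        return [t for t, s in self.assignment.items() if s == split]

    def split_of(self, tile_id: str) -> str:
        return self.assignment[tile_id]


def _tile_id(tile: TileLike) -> str:
    return tile.tile_id if isinstance(tile, Tile) else tile.image_id


def tile_species_counts(tiles: Iterable[TileLike]) -> dict[str, Counter]:
    """Per-tile annotation counts per species."""
    out: dict[str, Counter] = {}
    for tile in tiles:
        tid = _tile_id(tile)
        if tid in out:
            raise ValueError(f"duplicate tile id {tid!r}")
        out[tid] = Counter(a.species_label for a in tile.annotations)
    return out


def _greedy_pass(
    order: Sequence[str],
    counts: Mapping[str, Counter],
    species: set[str],
    quota: Quota,
) -> tuple[dict[str, str], dict[str, Counter]]:
    """One greedy assignment pass over a shuffled tile order.

    Each tile goes to the split with the greatest relative unmet need among
    the splits where it fits without overshooting any species quota; a tile
    that fits nowhere (or holds no annotations of the candidate species)
    stays unused.  Overshoot is impossible by construction.
    """
    achieved = {k: Counter() for k in SPLITS}
    need_total = {k: quota[k] * len(species) for k in SPLITS}
    assignment = {tid: "unused" for tid in order}
    for tid in order:
        cnt = {s: n for s, n in counts[tid].items() if s in species}
        if not cnt:
            continue
        best_split = None
        best_need = 0.0
        for k in SPLITS:
            if quota[k] == 0 or need_total[k] == 0:
                continue
            if any(achieved[k][s] + n > quota[k] for s, n in cnt.items()):
                continue
            unmet = need_total[k] - sum(achieved[k].values())
            rel_need = unmet / need_total[k]
            if rel_need > best_need:
                best_split, best_need = k, rel_need
        if best_split is not None:
            assignment[tid] = best_split
            achieved[best_split].update(cnt)
    return assignment, achieved


def _unmet_species(
    achieved: Mapping[str, Counter], species: set[str], quota: Quota
) -> set[str]:
    return {
        s
        for s in species
        for k in SPLITS
        if achieved[k][s] != quota[k]
    }


def select_balanced_subset(
    tiles: Iterable[TileLike],
    quota: Quota = Quota(),
    seed: int = 0,
    max_attempts: int = 50,
) -> SplitAssignment:
    """Select tiles into exact-quota train/eval/test splits.

    Runs up to ``max_attempts`` randomized greedy passes (tile order
    reshuffled each attempt with a seed derived from ``seed``).  If no pass
    satisfies every candidate species, the species left unmet in the last
    attempt are dropped and the attempt loop restarts without them, until
    all remaining species are satisfiable (possibly none).  Deterministic
    given (tiles, quota, seed, max_attempts).
    """
    if max_attempts < 1:
        raise ValueError(f"max_attempts must be >= 1, got {max_attempts}")
    counts = tile_species_counts(tiles)
    tile_ids = list(counts)
    all_species = sorted({s for c in counts.values() for s in c})
    rng = random.Random(seed)

    retained = set(all_species)
    dropped: list[str] = []
    attempts_used = 0
    assignment = {tid: "unused" for tid in tile_ids}
    achieved = {k: Counter() for k in SPLITS}

    while retained:
        success = False
        for _ in range(max_attempts):
            attempts_used += 1
            order = list(tile_ids)
            rng.shuffle(order)
            assignment, achieved = _greedy_pass(order, counts, retained, quota)
            unmet = _unmet_species(achieved, retained, quota)
            if not unmet:
                success = True
                break
        if success:
            break
        dropped.extend(sorted(unmet))
        retained -= unmet
    else:
        assignment = {tid: "unused" for tid in tile_ids}
        achieved = {k: Counter() for k in SPLITS}

    ledger = {
        (s, k): achieved[k][s] for s in sorted(retained) for k in SPLITS
    }
    return SplitAssignment(
        assignment=assignment,
        retained_species=sorted(retained),
        dropped_species=sorted(dropped),
        ledger=ledger,
        quota=quota,
        seed=seed,
        attempts_used=attempts_used,
    )


def verify_quota(
    assignment: SplitAssignment,
    quota: Quota,
    tiles: Iterable[TileLike] | None = None,
) -> dict:
    """Check achieved against required counts per (species, split).

    When ``tiles`` is given, achieved counts are recomputed from the tile
    contents instead of trusting the ledger.
    """
    if tiles is not None:
        counts = tile_species_counts(tiles)
        achieved = {k: Counter() for k in SPLITS}
        for tid, split in assignment.assignment.items():
            if split in SPLITS:
                for s, n in counts[tid].items():
                    if s in assignment.retained_species:
                        achieved[split][s] += n
        ledger = {
            (s, k): achieved[k][s]
            for s in assignment.retained_species
            for k in SPLITS
        }
    else:
        ledger = dict(assignment.ledger)

    discrepancies = [
        {"species": s, "split": k, "achieved": v, "required": quota[k]}
        for (s, k), v in sorted(ledger.items())
        if v != quota[k]
    ]
    return {
        "all_exact": not discrepancies,
        "discrepancies": discrepancies,
        "retained_species": list(assignment.retained_species),
        "dropped_species": list(assignment.dropped_species),
        "totals": {k: sum(v for (s, kk), v in ledger.items() if kk == k) for k in SPLITS},
    }
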