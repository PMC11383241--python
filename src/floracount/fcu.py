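"""Floral count unit (FCU) registry and count conversions.

A floral count unit is the species-specific countable entity used for
annotation — usually the botanical inflorescence (capitulum, spike, umbel,
...), sometimes a single flower where the inflorescence is impractical to
outline in a top-view photograph.  Each species carries two conversion
factors estimated from herbarium material: the mean number of individual
flowers per FCU and the mean number of FCUs per plant.  Detected FCU counts
thus convert linearly into flower counts (nectar/pollen indices) and plant
counts (demography).

Factors are population means, so converted counts are real-valued; rounding
is left to presentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "FCU_TYPES",
    "FCURecord",
    "FCURegistry",
    "CountTable",
    "RegistryError",
    "load_registry",
    "example_registry",
    "fcu_to_flowers",
    "fcu_to_plants",
    "richness_abundance",
]

#: Recognized FCU morphology tokens (botanical inflorescence types plus the
#: pragmatic single-flower units and an escape hatch).
FCU_TYPES = (
    "solitary_flower",
    "single_flower",
    "spike",
    "capitulum",
    "raceme",
    "verticillaster",
    "cyme",
    "umbel",
    "compound_umbel",
    "corymb",
    "corymb_of_capitula",
    "panicle",
    "thyrse",
    "dichasium",
    "other",
)

_REGISTRY_COLUMNS = ("species", "fcu_type", "flowers_per_fcu", "fcus_per_plant")


class RegistryError(ValueError):
    """Raised for malformed registries or unknown species in conversions."""


@dataclass(frozen=True)
class FCURecord:
    species: str
    fcu_type: str
    flowers_per_fcu: float
    fcus_per_plant: float

    def __post_init__(self) -> None:
        if self.fcu_type not in FCU_TYPES:
            raise RegistryError(
                f"{self.species}: unknown FCU type {self.fcu_type!r}"
            )
        if self.flowers_per_fcu < 1:
            raise RegistryError(
                f"{self.species}: flowers_per_fcu must be >= 1, "
                f"got {self.flowers_per_fcu}"
            )
        if self.fcus_per_plant <= 0:
            raise RegistryError(
                f"{self.species}: fcus_per_plant must be > 0, "
                f"got {self.fcus_per_plant}"
            )


class FCURegistry:
    """Mapping species -> :class:`FCURecord`, unique per species."""

    def __init__(self, records: Iterable[FCURecord]):
        self._records: dict[str, FCURecord] = {}
        for rec in records:
            if rec.species in self._records:
                raise RegistryError(f"duplicate species {rec.species!r} in registry")
            self._records[rec.species] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, species: str) -> bool:
        return species in self._records

    def __getitem__(self, species: str) -> FCURecord:
        try:
            return self._records[species]
        except KeyError:
            raise RegistryError(f"species {species!r} not in registry") from None

    @property
    def species(self) -> list[str]:
        return list(self._records)

    def _require(self, species: Iterable[str]) -> None:
        missing = sorted(set(species) - set(self._records))
        if missing:
            raise RegistryError(f"species not in registry: {missing}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self._records.values()])


@dataclass(frozen=True)
class CountTable:
    """Per-species non-negative counts in one of three domains.

    ``domain`` tags whether the numbers count FCUs (detector output),
    individual flowers, or plants.
    """

    counts: Mapping[str, float]
    domain: str = "fcu"

    _DOMAINS = ("fcu", "flower", "plant")

    def __post_init__(self) -> None:
        if self.domain not in self._DOMAINS:
            raise RegistryError(f"unknown count domain {self.domain!r}")
        for sp, c in self.counts.items():
            if c < 0:
                raise RegistryError(f"negative count for {sp!r}: {c}")
        object.__setattr__(self, "counts", dict(self.counts))

    def __getitem__(self, species: str) -> float:
        return self.counts[species]

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, name=self.domain, dtype=float)


def load_registry(csv_path) -> FCURegistry:
    """Load a registry CSV with columns species, fcu_type, flowers_per_fcu, fcus_per_plant."""
    df = pd.read_csv(csv_path)
    missing = [c for c in _REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise RegistryError(f"{csv_path}: missing columns {missing}")
    records = [
        FCURecord(
            species=str(row.species),
            fcu_type=str(row.fcu_type),
            flowers_per_fcu=float(row.flowers_per_fcu),
            fcus_per_plant=float(row.fcus_per_plant),
        )
        for row in df.itertuples()
    ]
    return FCURegistry(records)


def example_registry() -> FCURegistry:
    """The example registry shipped with the package (illustrative factors)."""
    with resources.as_file(
        resources.files("floracount.data") / "example_fcu_registry.csv"
    ) as p:
        return load_registry(p)


def fcu_to_flowers(counts: CountTable, registry: FCURegistry) -> CountTable:
    """flowers(s) = fcu_count(s) * flowers_per_fcu(s)."""
    if counts.domain != "fcu":
        raise RegistryError(f"expected an FCU-domain table, got {counts.domain!r}")
    registry._require(counts.counts)
    return CountTable(
        {s: c * registry[s].flowers_per_fcu for s, c in counts.counts.items()},
        domain="flower",
    )


def fcu_to_plants(counts: CountTable, registry: FCURegistry) -> CountTable:
    """plants(s) = fcu_count(s) / fcus_per_plant(s)."""
    if counts.domain != "fcu":
        raise RegistryError(f"expected an FCU-domain table, got {counts.domain!r}")
    registry._require(counts.counts)
    return CountTable(
        {s: c / registry[s].fcus_per_plant for s, c in counts.counts.items()},
        domain="plant",
    )


def richness_abundance(counts: CountTable) -> tuple[int, float]:
    """Species richness (count > 0) and total abundance (sum of counts)."""
    richness = sum(1 for c in counts.counts.values() if c > 0)
    abundance = float(sum(counts.counts.values()))
    return richness, abundance
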