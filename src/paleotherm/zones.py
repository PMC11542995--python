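"""Climatic-zone temperature tables and plate-model consistency checks.

Five latitude/temperature belts are encoded with their published shallow- and
deep-water habitat temperature ranges (°C):

======  ==================  ===============  =============
zone                        shallow          deep (250-500 m)
======  ==================  ===============  =============
1       tropical            20 – 35          ≤ 12
2       subtropical         18 – 25          —
3       warm temperate      12 – 20          5 – 7
4       cool temperate       4 – 10          1 – 4
5       polar                0 – 4           —
======  ==================  ===============  =============

The published ranges overlap (20–25 °C is both tropical and subtropical) and
leave a gap at 10–12 °C; both features are preserved verbatim rather than
"fixed" — deterministic disambiguation lives only in :func:`nearest_zone`.
The nominal latitude bands attached to each zone are a declared convention
(the published zonation is graphical only) and are used solely to translate a
plate-model latitude into an expected zone for the consistency check.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import pandas as pd

from .data_model import ThermalRange
from .estimation import BinEstimate

log = logging.getLogger(__name__)

Depth = Literal["shallow", "deep"]

#: Zones ordered warm → cold; ties in nearest_zone break toward the warmer.
ZONE_ORDER = (
    "tropical",
    "subtropical",
    "warm_temperate",
    "cool_temperate",
    "polar",
)


@dataclass(frozen=True)
class ZoneSpec:
    name: str
    shallow_range: ThermalRange
    deep_range: Optional[ThermalRange]
    lat_band: tuple[float, float]  # applies to |latitude|, [lo, hi)


@dataclass(frozen=True)
class ClimaticZoneTable:
    zones: tuple[ZoneSpec, ...]

    def __iter__(self):
        return iter(self.zones)

    def zone(self, name: str) -> ZoneSpec:
        for z in self.zones:
            if z.name == name:
                return z
        raise KeyError(f"unknown climatic zone {name!r}")

    def range_for(self, zone: ZoneSpec, depth: Depth) -> Optional[ThermalRange]:
        return zone.shallow_range if depth == "shallow" else zone.deep_range

    @classmethod
    def from_csv(cls, path: str | Path) -> "ClimaticZoneTable":
        """Build a table from an editable CSV fixture (one row per
        zone × depth with temperature bounds and latitude band)."""
        df = pd.read_csv(path)
        specs = []
        for name in ZONE_ORDER:
            rows = df[df["zone"] == name]
            if rows.empty:
                raise ValueError(f"zone table is missing zone {name!r}")
            shallow = rows[rows["depth"] == "shallow"].iloc[0]
            deep_rows = rows[rows["depth"] == "deep"]
            deep = (
                ThermalRange(
                    float(deep_rows.iloc[0]["t_min_c"]),
                    float(deep_rows.iloc[0]["t_max_c"]),
                )
                if not deep_rows.empty
                else None
            )
            specs.append(
                ZoneSpec(
                    name=name,
                    shallow_range=ThermalRange(
                        float(shallow["t_min_c"]), float(shallow["t_max_c"])
                    ),
                    deep_range=deep,
                    lat_band=(
                        float(shallow["lat_min_deg"]),
                        float(shallow["lat_max_deg"]),
                    ),
                )
            )
        return cls(zones=tuple(specs))

    @classmethod
    def default(cls) -> "ClimaticZoneTable":
        return _DEFAULT_TABLE


with resources.as_file(
    resources.files("paleotherm.data").joinpath("climatic_zones.csv")
) as _p:
    _DEFAULT_TABLE = ClimaticZoneTable.from_csv(_p)


def zones_for_temperature(
    t: float,
    depth: Depth = "shallow",
    table: ClimaticZoneTable | None = None,
) -> set[str]:
    """All zones whose range at the given depth contains ``t`` (inclusive).

    May be empty (the 10–12 °C shallow gap) or hold two zones (the 20–25 °C
    tropical/subtropical overlap).
    """
    table = table or ClimaticZoneTable.default()
    out = set()
    for z in table:
        rng = table.range_for(z, depth)
        if rng is not None and rng.contains(t):
            out.add(z.name)
    return out


def nearest_zone(
    t: float,
    depth: Depth = "shallow",
    table: ClimaticZoneTable | None = None,
) -> tuple[str, float]:
    """Zone whose range is closest to ``t`` (distance 0 if inside).

    Ties break toward the warmer zone, so 22 °C (inside both the tropical and
    subtropical ranges) resolves to tropical.
    """
    table = table or ClimaticZoneTable.default()
    best: tuple[str, float] | None = None
    for name in ZONE_ORDER:  # warm → cold, so first-at-distance wins ties
        rng = table.range_for(table.zone(name), depth)
        if rng is None:
            continue
        d = rng.distance_to(t)
        if best is None or d < best[1]:
            best = (name, d)
    assert best is not None
    return best


def zone_for_latitude(
    paleolat: float, table: ClimaticZoneTable | None = None
) -> str:
    """Zone whose nominal latitude band contains ``|paleolat|``.

    Bands are half-open [lo, hi) except the polar band, which closes at 90°.
    """
    table = table or ClimaticZoneTable.default()
    if abs(paleolat) > 90:
        raise ValueError(f"latitude {paleolat} outside [-90, 90]")
    a = abs(paleolat)
    for z in table:
        lo, hi = z.lat_band
        if lo <= a < hi or (hi >= 90 and a == 90):
            return z.name
    raise ValueError(f"no zone band covers latitude {paleolat}")


@dataclass
class ZoneConsistencyResult:
    """Outcome of comparing a bin's biotic temperature with a plate model.

    ``matching_zones`` are the zones whose shallow range contains the bin's
    temperature estimate; ``model_zone`` is implied by the supplied
    plate-model latitude. The two agree (``consistent``) when the model zone
    is among the matching zones, or — if the estimate falls in a gap of the
    table — equals the nearest zone.
    """

    estimate: BinEstimate
    model_latitude: float
    matching_zones: set[str] = field(default_factory=set)
    model_zone: str = ""
    consistent: bool = False
    discrepancy_note: str = ""


def check_consistency(
    estimate: BinEstimate,
    model_latitude: float,
    table: ClimaticZoneTable | None = None,
) -> ZoneConsistencyResult:
    """Check a bin estimate against the zone implied by a plate-model latitude.

    A warm biotic temperature at a latitude the plate model puts in a cold
    belt (or vice versa) flags the reconstruction as inconsistent — the
    situation in which the biota, not the model, may carry the better
    positional signal.
    """
    table = table or ClimaticZoneTable.default()
    matching = zones_for_temperature(estimate.hlm, "shallow", table)
    model_zone = zone_for_latitude(model_latitude, table)
    near, dist = nearest_zone(estimate.hlm, "shallow", table)
    if matching:
        consistent = model_zone in matching
    else:
        consistent = model_zone == near
    biota_desc = (
        "/".join(sorted(matching)) if matching else f"{near} (nearest, {dist:g} °C off)"
    )
    note = (
        f"biota at {estimate.hlm:g} °C suggest {biota_desc}; plate model at "
        f"{model_latitude:g}° implies {model_zone}: "
        + ("consistent" if consistent else "inconsistent")
    )
    if not consistent:
        log.info("%s / bin %g (%s): %s", estimate.stage, estimate.bin_label,
                 "zone check", note)
    return ZoneConsistencyResult(
        estimate=estimate,
        model_latitude=model_latitude,
        matching_zones=matching,
        model_zone=model_zone,
        consistent=consistent,
        discrepancy_note=note,
    )
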