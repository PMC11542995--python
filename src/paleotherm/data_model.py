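"""Domain types and I/O for biotic paleotemperature occurrence data.

The central objects are :class:`ThermalRange` — the habitat-temperature
interval ``[t_min, t_max]`` (°C) attributed to a taxon — and
:class:`OccurrenceRecord` — one occurrence of a taxon in one collection at a
known chronostratigraphic stage and paleolatitude. Occurrence tables are flat
delimited text (one row per occurrence); relational deposits in the PaleoSib
style (separate occurrence / collection / taxon tables linked by keys) are
joined into the same flat record list by :func:`load_paleosib_deposit`.

All temperatures are °C; coordinates are signed decimal degrees, north and
east positive.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Optional, Sequence

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .estimation import BinEstimate

log = logging.getLogger(__name__)

#: Habitat temperatures outside this band are physically implausible for
#: shallow marine settings and trigger a warning (not an error).
PLAUSIBLE_T_MIN = -5.0
PLAUSIBLE_T_MAX = 45.0

RANKS = frozenset({"species", "genus", "family", "order", "higher"})
DEPTH_CLASSES = frozenset({"shallow", "deep", "unknown"})

#: Column order of the flat occurrence format (delimited text, UTF-8, header).
FLAT_COLUMNS = (
    "record_id",
    "collection_id",
    "taxon_name",
    "gbif_id",
    "rank",
    "stage",
    "subbasin",
    "paleolat",
    "paleolon",
    "lat_modern",
    "lon_modern",
    "depth_class",
    "t_min_c",
    "t_max_c",
)


class ImplausibleTemperatureWarning(UserWarning):
    """A thermal-tolerance bound falls outside the plausible −5…45 °C band."""


# ---------------------------------------------------------------------------
# Core value types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThermalRange:
    """Habitat-temperature interval ``[t_min, t_max]`` in °C.

    The interval width ``t_max - t_min`` gauges how informative the taxon is
    about sea-surface temperature; its midpoint is the single temperature
    value fed to the estimator.
    """

    t_min: float
    t_max: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.t_min) and math.isfinite(self.t_max)):
            raise ValueError("thermal range bounds must be finite")
        if self.t_min > self.t_max:
            raise ValueError(
                f"inverted thermal range: t_min={self.t_min} > t_max={self.t_max}"
            )
        if self.t_min < PLAUSIBLE_T_MIN or self.t_max > PLAUSIBLE_T_MAX:
            warnings.warn(
                f"thermal range [{self.t_min}, {self.t_max}] °C outside the "
                f"plausible band [{PLAUSIBLE_T_MIN}, {PLAUSIBLE_T_MAX}] °C",
                ImplausibleTemperatureWarning,
                stacklevel=3,
            )

    @property
    def width(self) -> float:
        return self.t_max - self.t_min

    @property
    def midpoint(self) -> float:
        return (self.t_min + self.t_max) / 2.0

    def contains(self, t: float) -> bool:
        """Inclusive-bounds membership of a temperature."""
        return self.t_min <= t <= self.t_max

    def contains_range(self, other: "ThermalRange") -> bool:
        return self.t_min <= other.t_min and other.t_max <= self.t_max

    def intersects(self, other: "ThermalRange") -> bool:
        return self.t_min <= other.t_max and other.t_min <= self.t_max

    def distance_to(self, t: float) -> float:
        """Distance from ``t`` to the interval (0 if inside)."""
        if t < self.t_min:
            return self.t_min - t
        if t > self.t_max:
            return t - self.t_max
        return 0.0


@dataclass(frozen=True)
class OccurrenceRecord:
    """One taxon occurrence at one collection.

    ``depth_class`` is "deep" when the habitat depth exceeds the configured
    cutoff (default 300 m), "shallow" otherwise, "unknown" when the source
    gives no bathymetry.
    """

    record_id: str
    collection_id: str
    taxon_name: str
    stage: str
    paleolat: float
    thermal: ThermalRange
    gbif_id: Optional[int] = None
    rank: str = "species"
    subbasin: str = ""
    paleolon: Optional[float] = None
    lat_modern: Optional[float] = None
    lon_modern: Optional[float] = None
    depth_class: str = "unknown"

    def __post_init__(self) -> None:
        if not self.stage:
            raise ValueError("stage must be non-empty")
        if not self.taxon_name:
            raise ValueError("taxon_name must be non-empty")
        if not math.isfinite(self.paleolat) or abs(self.paleolat) > 90:
            raise ValueError(f"paleolatitude {self.paleolat} outside [-90, 90]")
        if self.paleolon is not None and abs(self.paleolon) > 180:
            raise ValueError(f"paleolongitude {self.paleolon} outside [-180, 180]")
        if self.rank not in RANKS:
            raise ValueError(f"unknown rank {self.rank!r}")
        if self.depth_class not in DEPTH_CLASSES:
            raise ValueError(f"unknown depth_class {self.depth_class!r}")


# ---------------------------------------------------------------------------
# Chronostratigraphic stage table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Stage:
    """One stage-level time slice with its age bounds in Ma (min = younger)."""

    name: str
    system: str
    age_min_ma: float
    age_max_ma: float

    def __post_init__(self) -> None:
        if not self.age_min_ma < self.age_max_ma:
            raise ValueError(f"stage {self.name}: age_min must be < age_max")


#: Synonyms mapping regional (mostly Russian) stage usage onto ICS names.
#: Editable: pass an extended mapping to StageTable.normalize.
DEFAULT_STAGE_ALIASES: Mapping[str, str] = {
    "kazanian": "Wordian",
    "ufimian": "Roadian",
    "dzhulfian": "Wuchiapingian",
    "dorashamian": "Changhsingian",
    "tournasian": "Tournaisian",
}


@dataclass(frozen=True)
class StageTable:
    """Ordered (oldest first) list of stages with strictly decreasing ages."""

    stages: tuple[Stage, ...]

    def __post_init__(self) -> None:
        names = [s.name.casefold() for s in self.stages]
        if len(set(names)) != len(names):
            raise ValueError("duplicate stage names in StageTable")
        for older, younger in zip(self.stages, self.stages[1:]):
            if not older.age_max_ma > younger.age_max_ma:
                raise ValueError("stages must be ordered oldest first")
            if older.age_min_ma < younger.age_max_ma:
                raise ValueError(
                    f"stages {older.name} and {younger.name} overlap in age"
                )

    def __len__(self) -> int:
        return len(self.stages)

    def __iter__(self):
        return iter(self.stages)

    def names(self) -> list[str]:
        return [s.name for s in self.stages]

    def normalize(
        self, name: str, aliases: Mapping[str, str] | None = None
    ) -> Optional[str]:
        """Canonical stage name for ``name``, or None if unrecognized.

        Matching is case-insensitive after trimming; ``aliases`` maps regional
        synonyms onto canonical names (defaults bundled).
        """
        key = name.strip().casefold()
        alias_map = DEFAULT_STAGE_ALIASES if aliases is None else aliases
        key = alias_map.get(key, key).strip().casefold()
        for s in self.stages:
            if s.name.casefold() == key:
                return s.name
        return None

    def index_of(self, name: str) -> int:
        canonical = self.normalize(name)
        if canonical is None:
            raise KeyError(f"unknown stage {name!r}")
        return [s.name for s in self.stages].index(canonical)

    def __contains__(self, name: str) -> bool:
        return self.normalize(str(name)) is not None


def _ics(name: str, system: str, old: float, young: float) -> Stage:
    return Stage(name=name, system=system, age_min_ma=young, age_max_ma=old)


#: The 29 Devonian–Triassic stage-level time slices used throughout the
#: package (ICS ages, Ma). The Rhaetian is omitted: it is the Triassic stage
#: most poorly represented in Siberian marine sections.
DEVONIAN_TRIASSIC_STAGES = StageTable(
    stages=(
        _ics("Lochkovian", "Devonian", 419.2, 410.8),
        _ics("Pragian", "Devonian", 410.8, 407.6),
        _ics("Emsian", "Devonian", 407.6, 393.3),
        _ics("Eifelian", "Devonian", 393.3, 387.7),
        _ics("Givetian", "Devonian", 387.7, 382.7),
        _ics("Frasnian", "Devonian", 382.7, 372.2),
        _ics("Famennian", "Devonian", 372.2, 358.9),
        _ics("Tournaisian", "Carboniferous", 358.9, 346.7),
        _ics("Visean", "Carboniferous", 346.7, 330.9),
        _ics("Serpukhovian", "Carboniferous", 330.9, 323.2),
        _ics("Bashkirian", "Carboniferous", 323.2, 315.2),
        _ics("Moscovian", "Carboniferous", 315.2, 307.0),
        _ics("Kasimovian", "Carboniferous", 307.0, 303.7),
        _ics("Gzhelian", "Carboniferous", 303.7, 298.9),
        _ics("Asselian", "Permian", 298.9, 293.52),
        _ics("Sakmarian", "Permian", 293.52, 290.1),
        _ics("Artinskian", "Permian", 290.1, 283.5),
        _ics("Kungurian", "Permian", 283.5, 273.01),
        _ics("Roadian", "Permian", 273.01, 266.9),
        _ics("Wordian", "Permian", 266.9, 264.28),
        _ics("Capitanian", "Permian", 264.28, 259.51),
        _ics("Wuchiapingian", "Permian", 259.51, 254.14),
        _ics("Changhsingian", "Permian", 254.14, 251.9),
        _ics("Induan", "Triassic", 251.9, 251.2),
        _ics("Olenekian", "Triassic", 251.2, 247.2),
        _ics("Anisian", "Triassic", 247.2, 242.0),
        _ics("Ladinian", "Triassic", 242.0, 237.0),
        _ics("Carnian", "Triassic", 237.0, 227.0),
        _ics("Norian", "Triassic", 227.0, 208.5),
    )
)


# ---------------------------------------------------------------------------
# Screening report
# ---------------------------------------------------------------------------

@dataclass
class ScreeningReport:
    """Census of records removed/retained by each ecological screening rule.

    Record-level counts partition the input: every input record is counted
    exactly once among retained (``n_narrow`` + ``n_moderate``),
    ``n_wide_excluded``, ``n_deepwater_excluded`` and ``n_overlap_excluded``.
    Taxon- and collection-level tallies are carried alongside because the
    deep-water and exotic-overlap exclusions are naturally quoted as fractions
    of collections and of species respectively.
    """

    n_input: int = 0
    n_narrow: int = 0
    n_moderate: int = 0
    n_wide_excluded: int = 0
    n_deepwater_excluded: int = 0
    n_overlap_excluded: int = 0
    n_unknown_depth_retained: int = 0
    n_taxa_input: int = 0
    n_taxa_deepwater_excluded: int = 0
    n_taxa_overlap_excluded: int = 0
    n_collections_input: int = 0
    n_collections_deepwater_only: int = 0

    @property
    def n_after_tolerance(self) -> int:
        return self.n_narrow + self.n_moderate

    @property
    def n_retained(self) -> int:
        return (
            self.n_input
            - self.n_wide_excluded
            - self.n_deepwater_excluded
            - self.n_overlap_excluded
        )

    def _frac(self, num: int, den: int) -> float:
        return num / den if den else 0.0

    def fractions(self) -> dict[str, float]:
        """Exclusion/retention fractions relative to the input record count."""
        n = self.n_input
        return {
            "retained": self._frac(self.n_retained, n),
            "narrow": self._frac(self.n_narrow, n),
            "moderate": self._frac(self.n_moderate, n),
            "wide_excluded": self._frac(self.n_wide_excluded, n),
            "deepwater_excluded": self._frac(self.n_deepwater_excluded, n),
            "overlap_excluded": self._frac(self.n_overlap_excluded, n),
        }

    def taxa_fractions(self) -> dict[str, float]:
        """Exclusion fractions with taxa (and collections) as denominator."""
        return {
            "deepwater_excluded_taxa": self._frac(
                self.n_taxa_deepwater_excluded, self.n_taxa_input
            ),
            "overlap_excluded_taxa": self._frac(
                self.n_taxa_overlap_excluded, self.n_taxa_input
            ),
            "deepwater_only_collections": self._frac(
                self.n_collections_deepwater_only, self.n_collections_input
            ),
        }

    def as_dict(self) -> dict:
        out = {f.name: getattr(self, f.name) for f in fields(self)}
        out["n_after_tolerance"] = self.n_after_tolerance
        out["n_retained"] = self.n_retained
        out["fractions"] = self.fractions()
        out["taxa_fractions"] = self.taxa_fractions()
        return out


# ---------------------------------------------------------------------------
# Flat occurrence I/O
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SkippedRow:
    """Machine-readable log entry for one rejected input row."""

    row: int  # 0-based data-row index in the source table
    reason: str  # short reason code, e.g. "inverted_thermal_range"
    detail: str = ""


@dataclass
class ReadResult:
    records: list[OccurrenceRecord]
    skipped: list[SkippedRow] = field(default_factory=list)

    @property
    def n_skipped(self) -> int:
        return len(self.skipped)

    def __iter__(self):
        return iter(self.records)


def _opt_float(value, what: str) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    if not s or s.lower() in {"na", "nan", "none"}:
        return None
    try:
        return float(s)
    except ValueError as exc:
        raise ValueError(f"unparseable_{what}") from exc


def _row_to_record(
    row: Mapping[str, object],
    column_map: Mapping[str, str],
    stage_table: StageTable,
    stage_aliases: Mapping[str, str] | None,
) -> OccurrenceRecord:
    def get(field_name: str, default=None):
        col = column_map.get(field_name)
        if col is None:
            return default
        val = row.get(col, default)
        if isinstance(val, float) and math.isnan(val):
            return default
        return val

    t_min = _opt_float(get("t_min_c"), "temperature")
    t_max = _opt_float(get("t_max_c"), "temperature")
    if t_min is None or t_max is None:
        raise ValueError("missing_temperature")
    thermal = ThermalRange(t_min=t_min, t_max=t_max)

    raw_stage = str(get("stage", "") or "").strip()
    if not raw_stage:
        raise ValueError("missing_stage")
    stage = stage_table.normalize(raw_stage, aliases=stage_aliases)
    if stage is None:
        raise ValueError("unknown_stage")

    paleolat = _opt_float(get("paleolat"), "coordinate")
    if paleolat is None:
        raise ValueError("missing_paleolat")

    gbif_raw = get("gbif_id")
    gbif_id: Optional[int] = None
    if gbif_raw is not None and str(gbif_raw).strip() not in {"", "na", "nan"}:
        try:
            gbif_id = int(float(gbif_raw))
        except ValueError as exc:
            raise ValueError("unparseable_gbif_id") from exc

    depth = str(get("depth_class", "unknown") or "unknown").strip().lower()

    return OccurrenceRecord(
        record_id=str(get("record_id", "") or "").strip(),
        collection_id=str(get("collection_id", "") or "").strip(),
        taxon_name=str(get("taxon_name", "") or "").strip(),
        stage=stage,
        paleolat=paleolat,
        thermal=thermal,
        gbif_id=gbif_id,
        rank=str(get("rank", "species") or "species").strip().lower(),
        subbasin=str(get("subbasin", "") or "").strip(),
        paleolon=_opt_float(get("paleolon"), "coordinate"),
        lat_modern=_opt_float(get("lat_modern"), "coordinate"),
        lon_modern=_opt_float(get("lon_modern"), "coordinate"),
        depth_class=depth,
    )


def _records_from_frame(
    df: pd.DataFrame,
    column_map: Mapping[str, str],
    stage_table: StageTable,
    stage_aliases: Mapping[str, str] | None = None,
) -> ReadResult:
    records: list[OccurrenceRecord] = []
    skipped: list[SkippedRow] = []
    for i, (_, row) in enumerate(df.iterrows()):
        try:
            records.append(
                _row_to_record(row, column_map, stage_table, stage_aliases)
            )
        except ValueError as exc:
            reason = str(exc).split(":")[0].replace(" ", "_")
            skipped.append(SkippedRow(row=i, reason=reason, detail=str(exc)))
            log.warning("skipping row %d: %s", i, exc)
    return ReadResult(records=records, skipped=skipped)


REQUIRED_FIELDS = (
    "record_id",
    "collection_id",
    "taxon_name",
    "stage",
    "paleolat",
    "t_min_c",
    "t_max_c",
)


def read_occurrences(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = ",",
    stage_table: StageTable = DEVONIAN_TRIASSIC_STAGES,
    stage_aliases: Mapping[str, str] | None = None,
) -> ReadResult:
    """Read a flat occurrence table into validated records.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    column_map
        Mapping from record field name to source column name. Defaults to the
        flat format's own column names (:data:`FLAT_COLUMNS`).
    delimiter
        Field delimiter; comma by default, tab accepted.

    Rows that fail validation are skipped, logged, and returned in
    ``ReadResult.skipped`` with a machine-readable reason code. A missing
    *mapped* column or an empty file is a hard error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=delimiter, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty occurrence file: {path}") from None
    cmap = dict(column_map) if column_map else {c: c for c in FLAT_COLUMNS}
    missing = [
        cmap[f] for f in REQUIRED_FIELDS if f in cmap and cmap[f] not in df.columns
    ]
    if missing:
        raise ValueError(
            f"mapped column(s) missing from {path.name}: {', '.join(missing)}"
        )
    return _records_from_frame(df, cmap, stage_table, stage_aliases)


def records_to_frame(records: Iterable[OccurrenceRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "record_id": r.record_id,
                "collection_id": r.collection_id,
                "taxon_name": r.taxon_name,
                "gbif_id": r.gbif_id,
                "rank": r.rank,
                "stage": r.stage,
                "subbasin": r.subbasin,
                "paleolat": r.paleolat,
                "paleolon": r.paleolon,
                "lat_modern": r.lat_modern,
                "lon_modern": r.lon_modern,
                "depth_class": r.depth_class,
                "t_min_c": r.thermal.t_min,
                "t_max_c": r.thermal.t_max,
            }
        )
    return pd.DataFrame(rows, columns=list(FLAT_COLUMNS))


def write_occurrences(
    records: Sequence[OccurrenceRecord], path: str | Path, delimiter: str = ","
) -> None:
    """Write records in the flat occurrence format (round-trips with
    :func:`read_occurrences`)."""
    records_to_frame(records).to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# PaleoSib-style relational deposits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JoinSpec:
    """Declares how a relational deposit's tables join into flat occurrences.

    The deposit is expected to contain (at least) an occurrence table, a
    collection table and a taxon table; foreign keys on the occurrence table
    point at the other two. ``column_map`` maps record fields onto columns of
    the *joined* frame and defaults to the flat format's column names.
    Temperature columns may live on the taxon table (taxon-level tolerance
    broadcast to every record) or directly on the occurrence table.
    """

    occurrences: str = "occurrences.csv"
    collections: str = "collections.csv"
    taxa: str = "taxa.csv"
    occurrence_collection_key: str = "collection_id"
    occurrence_taxon_key: str = "taxon_id"
    collection_key: str = "collection_id"
    taxon_key: str = "taxon_id"
    record_id_column: str = "record_id"
    column_map: Optional[Mapping[str, str]] = None
    delimiter: str = ","


@dataclass
class DepositCensus:
    """Load-time totals for comparison with a deposit's published census."""

    n_records: int
    n_collections: int
    n_taxa: int


@dataclass
class DepositResult:
    records: list[OccurrenceRecord]
    skipped: list[SkippedRow]
    n_dangling: int
    census: DepositCensus


def load_paleosib_deposit(
    directory: str | Path,
    join_spec: JoinSpec | None = None,
    stage_table: StageTable = DEVONIAN_TRIASSIC_STAGES,
    stage_aliases: Mapping[str, str] | None = None,
) -> DepositResult:
    """Join a relational occurrence deposit into a flat record list.

    Occurrence rows whose foreign keys do not resolve are skipped and counted
    in ``n_dangling``; a duplicated record identifier is a hard error.
    """
    spec = join_spec or JoinSpec()
    directory = Path(directory)

    def read_table(name: str) -> pd.DataFrame:
        return pd.read_csv(directory / name, sep=spec.delimiter, dtype=str)

    occ = read_table(spec.occurrences)
    coll = read_table(spec.collections)
    taxa = read_table(spec.taxa)

    if occ[spec.record_id_column].duplicated().any():
        dupes = occ[spec.record_id_column][
            occ[spec.record_id_column].duplicated()
        ].tolist()
        raise ValueError(f"duplicate record_id in deposit: {sorted(set(dupes))}")

    merged = occ.merge(
        coll.add_prefix("coll__"),
        left_on=spec.occurrence_collection_key,
        right_on=f"coll__{spec.collection_key}",
        how="left",
        indicator="_coll_merge",
    ).merge(
        taxa.add_prefix("tax__"),
        left_on=spec.occurrence_taxon_key,
        right_on=f"tax__{spec.taxon_key}",
        how="left",
        indicator="_tax_merge",
    )
    # Stable statistics regardless of input row order.
    merged = merged.sort_values(spec.record_id_column, kind="mergesort")

    resolved = (merged["_coll_merge"] == "both") & (merged["_tax_merge"] == "both")
    n_dangling = int((~resolved).sum())
    if n_dangling:
        for rid in merged.loc[~resolved, spec.record_id_column]:
            log.warning("deposit record %s has a dangling foreign key; skipped", rid)
    merged = merged.loc[resolved]

    if spec.column_map is not None:
        cmap: Mapping[str, str] = dict(spec.column_map)
    else:
        # Default: resolve each flat field against the joined frame, trying
        # the bare name, then the collection- and taxon-table prefixes.
        cmap = {}
        for f in FLAT_COLUMNS:
            for candidate in (f, f"coll__{f}", f"tax__{f}"):
                if candidate in merged.columns:
                    cmap[f] = candidate
                    break
    cmap = dict(cmap)
    cmap.setdefault("record_id", spec.record_id_column)
    cmap.setdefault("collection_id", spec.occurrence_collection_key)

    result = _records_from_frame(merged, cmap, stage_table, stage_aliases)
    census = DepositCensus(
        n_records=len(result.records),
        n_collections=len({r.collection_id for r in result.records}),
        n_taxa=len({r.taxon_name for r in result.records}),
    )
    log.info(
        "deposit %s: %d records, %d collections, %d distinct taxa, %d dangling",
        directory,
        census.n_records,
        census.n_collections,
        census.n_taxa,
        n_dangling,
    )
    return DepositResult(
        records=result.records,
        skipped=result.skipped,
        n_dangling=n_dangling,
        census=census,
    )


# ---------------------------------------------------------------------------
# Bin-estimate output
# ---------------------------------------------------------------------------

BIN_ESTIMATE_COLUMNS = (
    "Stage",
    "Paleolatitude",
    "n",
    "n_int",
    "HLM",
    "Q1",
    "Q3",
    "IQR",
)


def write_bin_estimates(
    estimates: Sequence["BinEstimate"], path: str | Path, delimiter: str = ","
) -> None:
    """Write per-(stage, paleolatitude-bin) estimates as delimited text.

    Columns mirror the summary-table layout: n, n_int (unique temperature
    intervals), HLM (Hodges-Lehmann estimate), Q1, Q3, IQR. Numeric values
    keep 4 decimals, so a read-back reproduces them exactly at that precision.
    """
    if not estimates:
        raise ValueError("no estimates to write")
    rows = []
    for e in estimates:
        rows.append(
            {
                "Stage": e.stage,
                "Paleolatitude": f"{e.bin_label:g}",
                "n": e.n,
                "n_int": e.n_int,
                "HLM": f"{e.hlm:.4f}",
                "Q1": f"{e.q1:.4f}",
                "Q3": f"{e.q3:.4f}",
                "IQR": f"{e.iqr:.4f}",
            }
        )
    pd.DataFrame(rows, columns=list(BIN_ESTIMATE_COLUMNS)).to_csv(
        path, sep=delimiter, index=False
    )


def read_bin_estimates(path: str | Path, delimiter: str = ",") -> pd.DataFrame:
    """Read back a bin-estimate table with numeric dtypes."""
    df = pd.read_csv(path, sep=delimiter)
    for col in ("Paleolatitude", "HLM", "Q1", "Q3", "IQR"):
        df[col] = df[col].astype(float)
    for col in ("n", "n_int"):
        df[col] = df[col].astype(int)
    return df
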