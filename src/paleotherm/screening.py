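"""Ecological screening of occurrence records as sea-surface-temperature evidence.

Three rules decide admissibility:

1. *Tolerance rule* — only taxa whose thermal-tolerance width is at most
   ``max_tolerance_width`` (default 5 °C) carry a usable temperature signal;
   widths ≤ ``narrow_cutoff`` (default 3 °C) are "narrow", the rest up to the
   maximum are "moderate".
2. *Depth rule* — taxa living below the deep-water cutoff (250–300 m,
   default 300 m) track cold intermediate water, not the sea surface, so
   deep-water records are excluded.
3. *Overlap rule* — taxa whose tolerance straddles both a warm ("red") and a
   cold ("blue") temperature grade are rare out-of-zone migrants whose
   conflicting signal is provisionally excluded at the taxon level.

The red/blue grade machinery mirrors interactive warm/cold sample selection:
grade bounds are user-set temperature ranges, and membership can be judged by
the interval midpoint, full containment, or any overlap.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

from .data_model import OccurrenceRecord, ScreeningReport, ThermalRange

log = logging.getLogger(__name__)

ToleranceClass = Literal["narrow", "moderate", "excluded"]
Grade = Literal["red", "blue", "both", "neither"]
MembershipRule = Literal["midpoint", "containment", "overlap"]


@dataclass(frozen=True)
class ScreeningConfig:
    """Thresholds for the admissibility rules (temperatures °C, depth m)."""

    max_tolerance_width: float = 5.0
    narrow_cutoff: float = 3.0
    deep_cutoff_m: float = 300.0
    exclude_deep: bool = True
    exclude_overlap: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.narrow_cutoff < self.max_tolerance_width:
            raise ValueError(
                "require 0 < narrow_cutoff < max_tolerance_width, got "
                f"{self.narrow_cutoff} / {self.max_tolerance_width}"
            )
        if self.deep_cutoff_m <= 0:
            raise ValueError("deep_cutoff_m must be positive")


@dataclass(frozen=True)
class GradeSpec:
    """Warm (red) and cold (blue) temperature grades for sample selection.

    The two ranges may overlap; the overlap region is exactly what drives the
    exotic-taxon exclusion rule.
    """

    red_range: ThermalRange
    blue_range: ThermalRange
    membership_rule: MembershipRule = "midpoint"


def tolerance_width(thermal: ThermalRange) -> float:
    """Width ``t_max − t_min`` of a thermal-tolerance interval, °C."""
    return thermal.width


def classify_tolerance(
    thermal: ThermalRange, cfg: ScreeningConfig
) -> ToleranceClass:
    """Tolerance class of a range: narrow / moderate / excluded.

    Boundary semantics are inclusive upward: width exactly equal to
    ``narrow_cutoff`` is narrow; exactly ``max_tolerance_width`` is moderate.
    The width is rounded at the nano-degree to keep boundary classification
    immune to binary-representation noise (e.g. 12.3 − 7.3 exceeding 5.0 by
    one ulp).
    """
    w = round(thermal.width, 9)
    if w <= cfg.narrow_cutoff:
        return "narrow"
    if w <= cfg.max_tolerance_width:
        return "moderate"
    return "excluded"


def classify_grade(
    record: OccurrenceRecord | ThermalRange, spec: GradeSpec
) -> Grade:
    """Red/blue grade membership of a record's thermal range.

    Under the default midpoint rule a range is "both" only when its midpoint
    lies in the intersection of the two grades; under containment/overlap the
    whole interval is compared.
    """
    rng = record.thermal if isinstance(record, OccurrenceRecord) else record
    if spec.membership_rule == "midpoint":
        m = rng.midpoint
        in_red = spec.red_range.contains(m)
        in_blue = spec.blue_range.contains(m)
    elif spec.membership_rule == "containment":
        in_red = spec.red_range.contains_range(rng)
        in_blue = spec.blue_range.contains_range(rng)
    elif spec.membership_rule == "overlap":
        in_red = spec.red_range.intersects(rng)
        in_blue = spec.blue_range.intersects(rng)
    else:  # pragma: no cover - guarded by the Literal type
        raise ValueError(f"unknown membership rule {spec.membership_rule!r}")
    if in_red and in_blue:
        return "both"
    if in_red:
        return "red"
    if in_blue:
        return "blue"
    return "neither"


def filter_admissible(
    records: Sequence[OccurrenceRecord], cfg: ScreeningConfig
) -> tuple[list[OccurrenceRecord], ScreeningReport]:
    """Apply the tolerance and depth rules; tally every removal.

    Order of retained records is preserved. Records with unknown depth are
    retained (only *exclusively* deep-water taxa lack a surface signal) but
    counted in ``n_unknown_depth_retained``. Each input record is counted
    under exactly one rule: tolerance first, then depth.
    """
    report = ScreeningReport(n_input=len(records))
    report.n_taxa_input = len({r.taxon_name for r in records})
    report.n_collections_input = len({r.collection_id for r in records})

    retained: list[OccurrenceRecord] = []
    for r in records:
        cls = classify_tolerance(r.thermal, cfg)
        if cls == "excluded":
            report.n_wide_excluded += 1
            continue
        if cfg.exclude_deep and r.depth_class == "deep":
            report.n_deepwater_excluded += 1
            continue
        if r.depth_class == "unknown":
            report.n_unknown_depth_retained += 1
        if cls == "narrow":
            report.n_narrow += 1
        else:
            report.n_moderate += 1
        retained.append(r)

    if cfg.exclude_deep:
        # Taxa/collections found exclusively in deep water, among records that
        # pass the tolerance rule (the natural denominator for "% excluded").
        ok_width = [
            r for r in records if classify_tolerance(r.thermal, cfg) != "excluded"
        ]
        by_taxon: dict[str, list[str]] = {}
        by_coll: dict[str, list[str]] = {}
        for r in ok_width:
            by_taxon.setdefault(r.taxon_name, []).append(r.depth_class)
            by_coll.setdefault(r.collection_id, []).append(r.depth_class)
        report.n_taxa_deepwater_excluded = sum(
            1 for v in by_taxon.values() if all(d == "deep" for d in v)
        )
        report.n_collections_deepwater_only = sum(
            1 for v in by_coll.values() if all(d == "deep" for d in v)
        )
    if report.n_unknown_depth_retained:
        log.warning(
            "%d records with unknown depth class retained",
            report.n_unknown_depth_retained,
        )
    return retained, report


@dataclass
class OverlapResult:
    retained: list[OccurrenceRecord]
    excluded_taxa: list[tuple[str, ThermalRange]]
    n_records_removed: int


def exclude_overlapping(
    records: Sequence[OccurrenceRecord],
    spec: GradeSpec,
    cfg: ScreeningConfig,
) -> OverlapResult:
    """Remove every record of taxa whose grade classification is "both".

    Operates at taxon level: a taxon with any thermal range classified "both"
    under ``spec`` loses all of its records. A no-op (returning all records)
    when ``cfg.exclude_overlap`` is false.
    """
    if not cfg.exclude_overlap:
        return OverlapResult(list(records), [], 0)
    ranges_by_taxon: dict[str, set[ThermalRange]] = {}
    for r in records:
        ranges_by_taxon.setdefault(r.taxon_name, set()).add(r.thermal)
    excluded: dict[str, ThermalRange] = {}
    for taxon, ranges in ranges_by_taxon.items():
        for rng in ranges:
            if classify_grade(rng, spec) == "both":
                excluded[taxon] = rng
                break
    retained = [r for r in records if r.taxon_name not in excluded]
    excluded_list = sorted(excluded.items())
    for taxon, rng in excluded_list:
        log.info(
            "taxon %s excluded: tolerance [%g, %g] °C straddles both grades",
            taxon,
            rng.t_min,
            rng.t_max,
        )
    return OverlapResult(
        retained=retained,
        excluded_taxa=excluded_list,
        n_records_removed=len(records) - len(retained),
    )


def screen(
    records: Sequence[OccurrenceRecord],
    cfg: ScreeningConfig | None = None,
    grade_spec: GradeSpec | None = None,
) -> tuple[list[OccurrenceRecord], ScreeningReport]:
    """Full screening pass: tolerance + depth rules, then overlap exclusion.

    The overlap rule runs only when a ``grade_spec`` is supplied and
    ``cfg.exclude_overlap`` is set; its removals are merged into the report.
    """
    cfg = cfg or ScreeningConfig()
    retained, report = filter_admissible(records, cfg)
    if grade_spec is not None and cfg.exclude_overlap:
        overlap = exclude_overlapping(retained, grade_spec, cfg)
        report.n_overlap_excluded = overlap.n_records_removed
        report.n_taxa_overlap_excluded = len(overlap.excluded_taxa)
        # Overlap removals also come out of the narrow/moderate tallies so
        # that retained = n_narrow + n_moderate stays true.
        removed = {id(r) for r in retained} - {id(r) for r in overlap.retained}
        for r in retained:
            if id(r) in removed:
                if classify_tolerance(r.thermal, cfg) == "narrow":
                    report.n_narrow -= 1
                else:
                    report.n_moderate -= 1
        retained = overlap.retained
    return retained, report
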