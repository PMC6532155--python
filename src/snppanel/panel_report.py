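"""Descriptive summaries of a designed panel.

Per-chromosome counts and mean adjacent spacing, source-group
composition, consequence-annotation breakdown, and positional overlap
between panels.  Percentages and kilobase distances are rounded half-up
to two decimals, matching the printed-table convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations

from .datamodel_io import AnnotationTable, Group, Panel, PassLabel, Priority

__all__ = [
    "ChromosomeSummary",
    "CompositionSummary",
    "AnnotationSummary",
    "OverlapSummary",
    "round_half_up",
    "per_chromosome_summary",
    "group_composition",
    "annotation_summary",
    "panel_overlap",
]


def round_half_up(value: float, decimals: int = 2) -> float:
    """Round half away from zero at the printed precision (bankers'
    rounding would understate .005 boundaries)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ChromosomeSummary:
    """Per chromosome: marker count and mean adjacent distance (K bp).

    Mean distance is the mean of successive position differences divided
    by 1000, to 2 decimals; chromosomes with fewer than two markers
    report None.
    """

    counts: dict[str, int]
    mean_distance_kbp: dict[str, float | None]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class CompositionSummary:
    """Marker counts per source group and per priority tier."""

    by_group: dict[Group, int]
    by_priority: dict[Priority, int]
    by_pass: dict[PassLabel, int]
    total: int


@dataclass
class AnnotationSummary:
    """Consequence-class counts and percents of the panel total."""

    counts: dict[str, int]
    percents: dict[str, float]
    total: int
    annotatable_count: int
    annotatable_percent: float


@dataclass
class OverlapSummary:
    """Venn-region counts for 2–3 panels keyed by (chrom, pos) identity.

    ``regions`` maps a frozenset of panel names to the count of positions
    found in exactly those panels.  ``pairwise_percent[(a, b)]`` is
    100·|A∩B|/|A| rounded to the nearest integer.
    """

    panel_names: tuple[str, ...]
    regions: dict[frozenset, int]
    pairwise_percent: dict[tuple[str, str], int]

    @property
    def union_size(self) -> int:
        return sum(self.regions.values())


# ---------------------------------------------------------------------------


def per_chromosome_summary(panel: Panel) -> ChromosomeSummary:
    """Count markers and mean adjacent spacing per chromosome."""
    by_chrom: dict[str, list[int]] = {}
    for e in panel.entries:
        by_chrom.setdefault(e.snp.locus.chrom, []).append(e.snp.locus.pos)
    counts: dict[str, int] = {}
    dist: dict[str, float | None] = {}
    for chrom, positions in by_chrom.items():
        positions.sort()
        counts[chrom] = len(positions)
        if len(positions) < 2:
            dist[chrom] = None
        else:
            gaps = [b - a for a, b in zip(positions, positions[1:])]
            dist[chrom] = round_half_up(sum(gaps) / len(gaps) / 1000.0)
    return ChromosomeSummary(counts=counts, mean_distance_kbp=dist)


def group_composition(panel: Panel) -> CompositionSummary:
    """Count panel markers per source group, priority tier and design pass."""
    by_group = {g: 0 for g in Group}
    by_priority = {p: 0 for p in Priority}
    by_pass = {p: 0 for p in PassLabel}
    for e in panel.entries:
        by_group[e.snp.group] += 1
        by_priority[e.snp.priority] += 1
        by_pass[e.pass_label] += 1
    return CompositionSummary(
        by_group=by_group,
        by_priority=by_priority,
        by_pass=by_pass,
        total=len(panel.entries),
    )


def annotation_summary(panel: Panel, annotations: AnnotationTable) -> AnnotationSummary:
    """Consequence-class breakdown of the panel with half-up percentages."""
    counts: dict[str, int] = {}
    for e in panel.entries:
        cls = annotations.lookup(e.snp.locus.chrom, e.snp.locus.pos)
        counts[cls] = counts.get(cls, 0) + 1
    total = len(panel.entries)
    percents = {
        cls: (round_half_up(100.0 * n / total) if total else 0.0)
        for cls, n in counts.items()
    }
    annotatable = total - counts.get("unannotated", 0)
    annotatable_pct = round_half_up(100.0 * annotatable / total) if total else 0.0
    return AnnotationSummary(
        counts=counts,
        percents=percents,
        total=total,
        annotatable_count=annotatable,
        annotatable_percent=annotatable_pct,
    )


def panel_overlap(
    panels: dict[str, set[tuple[str, int]] | list[tuple[str, int]]],
) -> OverlapSummary:
    """Exact positional overlap (Venn regions) between 2–3 panels.

    Duplicate keys within one panel are deduplicated with a warning.
    Pairwise percent is relative to the first panel of each ordered pair,
    rounded half-up to an integer.
    """
    if not 2 <= len(panels) <= 3:
        raise ValueError("panel_overlap supports 2 or 3 panels")
    names = tuple(panels)
    sets: dict[str, set[tuple[str, int]]] = {}
    for name, positions in panels.items():
        as_list = list(positions)
        as_set = set(as_list)
        if len(as_set) != len(as_list):
            warnings.warn(
                f"panel {name!r} contains duplicate positions; deduplicated",
                UserWarning,
                stacklevel=2,
            )
        sets[name] = as_set

    regions: dict[frozenset, int] = {}
    union = set().union(*sets.values())
    for key in union:
        members = frozenset(n for n in names if key in sets[n])
        regions[members] = regions.get(members, 0) + 1

    pairwise: dict[tuple[str, str], int] = {}
    for a, b in combinations(names, 2):
        inter = len(sets[a] & sets[b])
        pairwise[(a, b)] = int(round_half_up(100.0 * inter / len(sets[a]), 0)) if sets[a] else 0
        pairwise[(b, a)] = int(round_half_up(100.0 * inter / len(sets[b]), 0)) if sets[b] else 0
    return OverlapSummary(panel_names=names, regions=regions, pairwise_percent=pairwise)
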