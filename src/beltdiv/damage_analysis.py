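"""Trunk-damage tallies and the occupancy-damage regression.

Per site: counts and percentages of trees at each bark-damage level (1
traces only; 2 peeled bark with a gallery, no termites; 3 gallery with
active termites), the combined damaged percentage, and attribution of
level-3 damage to the genera and functional groups found on the trunks.

Across sites: an ordinary least-squares line relating a functional group's
occupied area (its section occupancy, a fraction) to the level-3
active-termite incidence attributed to that group.  Site counts in this
kind of survey are small, so fits on fewer than five points carry an
explicit small-sample flag rather than being suppressed.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .assemblage_metrics import TaxonShare
from .core_data import ConsistencyError, DamageRecord, FormatError, TaxonomyMap

logger = logging.getLogger(__name__)

SMALL_N = 5


@dataclass
class DamageSummary:
    """Per-site damage tally."""

    site_id: str
    n_trees: int
    counts: dict[int, int]                 # level -> number of trees (0-3)
    percentages: dict[int, float]          # level 1-3 -> 100 * count/n_trees
    combined_percentage: float             # levels 1-3 together
    level3_genus_counts: dict[str, int]
    level3_group_counts: dict[str, int]

    def to_json(self) -> dict:
        return {
            "site_id": self.site_id,
            "n_trees": self.n_trees,
            "counts": {str(k): v for k, v in sorted(self.counts.items())},
            "percentages": {str(k): v for k, v in sorted(self.percentages.items())},
            "combined_percentage": self.combined_percentage,
            "level3_genus_counts": dict(sorted(self.level3_genus_counts.items())),
            "level3_group_counts": dict(sorted(self.level3_group_counts.items())),
        }


@dataclass
class OccupancyDamageFit:
    """OLS of level-3 incidence on functional-group occupied area."""

    group: str
    response: str                          # "count" or "percentage"
    points: list[tuple[float, float, str]]  # (occupancy, response, site)
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    small_n: bool

    def to_json(self) -> dict:
        return {
            "group": self.group,
            "response": self.response,
            "points": [
                {"site": s, "occupancy": x, "response": y}
                for x, y, s in self.points
            ],
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
            "small_n": self.small_n,
        }


def tally_damage(
    records: Sequence[DamageRecord],
    taxonomy: TaxonomyMap,
) -> dict[str, DamageSummary]:
    """Tally damage levels per site and attribute level-3 damage to taxa.

    Record-level invariants (level in 0-3; taxa present exactly at level 3)
    are enforced by :class:`DamageRecord` itself; here the trunk genera are
    additionally resolved against the taxonomy.
    """
    by_site: dict[str, list[DamageRecord]] = {}
    for rec in records:
        by_site.setdefault(rec.site_id, []).append(rec)
    summaries = {}
    for site_id in sorted(by_site):
        site_records = by_site[site_id]
        seen = Counter(r.tree_id for r in site_records)
        dup = [t for t, c in seen.items() if c > 1]
        if dup:
            raise ConsistencyError(
                f"site {site_id!r}: duplicate tree record(s) {sorted(dup)}"
            )
        n_trees = len(site_records)
        counts = {lvl: 0 for lvl in (0, 1, 2, 3)}
        genus_counts: Counter[str] = Counter()
        group_counts: Counter[str] = Counter()
        for rec in site_records:
            counts[rec.level] += 1
            if rec.level == 3:
                for genus in sorted(rec.taxa_on_trunk):
                    genus_counts[genus] += 1
                for group in {taxonomy.group_of(g) for g in rec.taxa_on_trunk}:
                    group_counts[group] += 1
        percentages = {
            lvl: 100.0 * counts[lvl] / n_trees for lvl in (1, 2, 3)
        }
        summaries[site_id] = DamageSummary(
            site_id=site_id,
            n_trees=n_trees,
            counts=counts,
            percentages=percentages,
            combined_percentage=sum(percentages.values()),
            level3_genus_counts=dict(genus_counts),
            level3_group_counts=dict(group_counts),
        )
    return summaries


def damage_regression(
    summaries: Mapping[str, DamageSummary],
    occupancies: Mapping[str, Iterable[TaxonShare]],
    group: str = "IIf",
    response: str = "count",
) -> OccupancyDamageFit:
    """Least-squares line of level-3 incidence on group occupancy.

    ``summaries`` maps site -> :class:`DamageSummary`; ``occupancies`` maps
    site -> functional-group :class:`TaxonShare` collection (as produced by
    :func:`beltdiv.assemblage_metrics.occupancy` at functional-group rank).
    ``response`` is the level-3 incidence ``count`` attributed to the group
    (default) or its ``percentage`` of surveyed trees.
    """
    if response not in ("count", "percentage"):
        raise FormatError(f"response must be 'count' or 'percentage', "
                          f"got {response!r}")
    points: list[tuple[float, float, str]] = []
    for site_id in sorted(summaries):
        if site_id not in occupancies:
            continue
        share = next(
            (s for s in occupancies[site_id] if s.taxon == group), None
        )
        if share is None:
            continue
        summary = summaries[site_id]
        y = float(summary.level3_group_counts.get(group, 0))
        if response == "percentage":
            y = 100.0 * y / summary.n_trees
        points.append((share.occupancy, y, site_id))
    if len(points) < 2:
        raise FormatError(
            f"regression needs >= 2 sites with both damage and occupancy "
            f"data for group {group!r}, got {len(points)}"
        )
    xs = [p[0] for p in points]
    ys = [p[1] for p in points]
    if len(set(xs)) < 2:
        raise FormatError("singular design: all occupancy values identical")
    result = stats.linregress(xs, ys)
    small_n = len(points) < SMALL_N
    if small_n:
        logger.warning(
            "occupancy-damage regression on only %d sites; treat the fit "
            "as indicative", len(points)
        )
    return OccupancyDamageFit(
        group=group,
        response=response,
        points=points,
        slope=float(result.slope),
        intercept=float(result.intercept),
        r_squared=float(result.rvalue) ** 2,
        n_points=len(points),
        small_n=small_n,
    )
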