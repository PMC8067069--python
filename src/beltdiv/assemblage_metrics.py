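"""Proportion and occupancy of taxa across transect sections.

Two per-taxon summaries over a section-level incidence matrix:

* *proportion* -- a taxon's share of all section-level incidences in the
  transect (incidences of t divided by total incidences of all taxa at the
  same rank); proportions over one transect sum to 1.
* *occupancy* -- the fraction of sections the taxon occupies (incidences
  divided by the declared number of sections, by default all 20 sections of
  the belt transect, empty ones included).

Both are incidence-based: multiple encounters with the same taxon in the
same section count once (union semantics).  The alternative per-encounter
counting is available from raw records via
:func:`proportions_from_records(..., count_encounters=True)`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .core_data import (
    FormatError,
    IncidenceMatrix,
    OccurrenceRecord,
    TaxonomyMap,
)


@dataclass(frozen=True)
class TaxonShare:
    """Proportion / occupancy summary for one taxon in one transect."""

    taxon: str
    rank: str
    proportion: float
    occupancy: float
    incidences: int


def _require_section_level(incidence: IncidenceMatrix, what: str) -> None:
    if incidence.level != "section":
        raise FormatError(
            f"{what} are defined on section-level incidences; got a "
            f"{incidence.level}-level matrix"
        )


def proportions(incidence: IncidenceMatrix, rank: str,
                n_sections: int | None = None) -> list[TaxonShare]:
    """Per-taxon share of all section incidences in one transect.

    Returns one :class:`TaxonShare` per taxon (occupancy filled in too);
    an all-empty matrix yields an empty list rather than dividing by zero.
    """
    _require_section_level(incidence, "proportions")
    counts = incidence.occupancy_counts()
    total = int(counts.sum())
    if total == 0:
        return []
    denom = _sections_denominator(incidence, n_sections)
    return [
        TaxonShare(
            taxon=str(taxon),
            rank=rank,
            proportion=int(k) / total,
            occupancy=int(k) / denom,
            incidences=int(k),
        )
        for taxon, k in counts.items()
    ]


def occupancy(incidence: IncidenceMatrix, rank: str,
              n_sections: int | None = None) -> list[TaxonShare]:
    """Per-taxon fraction of occupied sections (incidences / n_sections)."""
    _require_section_level(incidence, "occupancies")
    denom = _sections_denominator(incidence, n_sections)
    counts = incidence.occupancy_counts()
    total = int(counts.sum())
    return [
        TaxonShare(
            taxon=str(taxon),
            rank=rank,
            proportion=(int(k) / total) if total else 0.0,
            occupancy=int(k) / denom,
            incidences=int(k),
        )
        for taxon, k in counts.items()
    ]


def _sections_denominator(incidence: IncidenceMatrix,
                          n_sections: int | None) -> int:
    denom = incidence.n_units if n_sections is None else int(n_sections)
    if denom <= 0:
        raise FormatError("number of sections must be positive")
    return denom


def proportions_from_records(
    records: Sequence[OccurrenceRecord],
    rank: str,
    count_encounters: bool = False,
) -> dict[str, float]:
    """Taxon proportions straight from occurrence records.

    With ``count_encounters=False`` (default) repeated encounters with a
    taxon in one section count once, matching matrix-based proportions;
    with ``True`` every record row counts.
    """
    taxonomy = TaxonomyMap.from_records(records)
    events: Iterable[tuple[str, str]]
    if count_encounters:
        events = [(r.section_id, taxonomy.relabel(r.species, rank))
                  for r in records]
    else:
        events = {(r.section_id, taxonomy.relabel(r.species, rank))
                  for r in records}
    counts: dict[str, int] = {}
    for _, taxon in events:
        counts[taxon] = counts.get(taxon, 0) + 1
    total = sum(counts.values())
    return {t: c / total for t, c in sorted(counts.items())} if total else {}
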