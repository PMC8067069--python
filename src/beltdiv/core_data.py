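"""Domain types and I/O for incidence-based belt-transect surveys.

The survey design this package targets is a 100 m x 2 m belt transect split
into 20 contiguous 5 m x 2 m sections.  Every statistic downstream is
computed from *incidence* (presence/absence), never abundance: a taxon is
"present" in a sampling unit (a section, or a whole site) as soon as it was
encountered there at least once.

This module provides

* :class:`OccurrenceRecord` / :class:`DamageRecord` -- one encounter / one
  surveyed tree;
* :class:`TaxonomyMap` -- species -> genus -> feeding (functional) group;
* :class:`IncidenceMatrix` -- the binary units x species table that is the
  substrate of every downstream statistic;
* readers/writers for the long occurrence CSV, the wide incidence CSV and
  the damage CSV, plus JSON export with a schema version;
* :func:`load_fixture_table3` -- the packaged 13-species x 3-plantation
  presence table from the teak-plantation case study that the package's
  worked examples use.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"

#: Feeding (functional) group codes: I dead wood/grass feeders with gut
#: flagellates; II generalist wood/litter feeders; IIf fungus-growing
#: termites; III humus feeders; IV true soil feeders.
FUNCTIONAL_GROUPS = ("I", "II", "IIf", "III", "IV")

LEVELS = ("section", "site")
RANKS = ("species", "genus", "functional_group")

OCCURRENCE_COLUMNS = ("site", "section", "species", "genus", "functional_group")
DAMAGE_COLUMNS = ("tree", "site", "section", "level", "taxa")


class FormatError(ValueError):
    """A file or table does not have the expected shape/columns/values."""


class ConsistencyError(ValueError):
    """Records contradict each other (e.g. one species, two genera)."""


@dataclass(frozen=True)
class OccurrenceRecord:
    """One taxon encounter in one transect section."""

    site_id: str
    section_id: str
    species: str
    genus: str
    functional_group: str

    def __post_init__(self) -> None:
        if self.functional_group not in FUNCTIONAL_GROUPS:
            raise FormatError(
                f"unknown functional group {self.functional_group!r} for "
                f"species {self.species!r}; expected one of {FUNCTIONAL_GROUPS}"
            )


@dataclass(frozen=True)
class DamageRecord:
    """One surveyed tree trunk with its graded bark-damage level.

    Levels: 0 no damage observed; 1 damage traces only; 2 bark peeled with a
    foraging gallery but no termites; 3 gallery with active termites.  By
    definition only level 3 has termites on the trunk, so ``taxa_on_trunk``
    (genus labels) must be non-empty exactly at level 3.
    """

    tree_id: str
    site_id: str
    section_id: str
    level: int
    taxa_on_trunk: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.level not in (0, 1, 2, 3):
            raise FormatError(
                f"tree {self.tree_id!r}: damage level must be 0-3, "
                f"got {self.level!r}"
            )
        if self.level == 3 and not self.taxa_on_trunk:
            raise ConsistencyError(
                f"tree {self.tree_id!r}: level 3 requires at least one "
                "genus on the trunk (active termites define the level)"
            )
        if self.level < 3 and self.taxa_on_trunk:
            raise ConsistencyError(
                f"tree {self.tree_id!r}: level {self.level} excludes "
                "termites on the trunk but taxa were recorded"
            )


@dataclass(frozen=True)
class TaxonomyMap:
    """Species -> genus and genus -> functional group lookup."""

    species_to_genus: Mapping[str, str]
    genus_to_group: Mapping[str, str]

    @classmethod
    def from_records(cls, records: Iterable[OccurrenceRecord]) -> "TaxonomyMap":
        sp2g: dict[str, str] = {}
        g2f: dict[str, str] = {}
        for rec in records:
            prev = sp2g.setdefault(rec.species, rec.genus)
            if prev != rec.genus:
                raise ConsistencyError(
                    f"species {rec.species!r} mapped to two genera: "
                    f"{prev!r} and {rec.genus!r}"
                )
            prevg = g2f.setdefault(rec.genus, rec.functional_group)
            if prevg != rec.functional_group:
                raise ConsistencyError(
                    f"genus {rec.genus!r} mapped to two functional groups: "
                    f"{prevg!r} and {rec.functional_group!r}"
                )
        return cls(sp2g, g2f)

    def genus_of(self, species: str) -> str:
        try:
            return self.species_to_genus[species]
        except KeyError:
            raise ConsistencyError(f"species {species!r} missing from taxonomy")

    def group_of(self, genus: str) -> str:
        try:
            return self.genus_to_group[genus]
        except KeyError:
            raise ConsistencyError(f"genus {genus!r} missing from taxonomy")

    def group_of_species(self, species: str) -> str:
        return self.group_of(self.genus_of(species))

    def relabel(self, species: str, rank: str) -> str:
        """Map a species label to its label at ``rank``."""
        if rank == "species":
            return species
        if rank == "genus":
            return self.genus_of(species)
        if rank == "functional_group":
            return self.group_of_species(species)
        raise FormatError(f"unknown taxon rank {rank!r}; expected one of {RANKS}")

    def check_covers(self, species_ids: Iterable[str]) -> None:
        missing = [s for s in species_ids if s not in self.species_to_genus]
        if missing:
            raise ConsistencyError(f"taxonomy does not cover species: {missing}")


@dataclass
class IncidenceMatrix:
    """Binary sampling-units x taxa table.

    Rows are sampling units (transect sections or whole sites), columns are
    taxa at some rank.  Cells are strictly 0/1.  Row and column labels are
    unique and kept in sorted order so every downstream computation is
    reproducible independent of input order.
    """

    data: pd.DataFrame
    level: str

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise FormatError(f"level must be one of {LEVELS}, got {self.level!r}")
        if self.data.index.has_duplicates:
            raise FormatError("duplicate unit labels in incidence matrix")
        if self.data.columns.has_duplicates:
            raise FormatError("duplicate taxon labels in incidence matrix")
        values = self.data.to_numpy()
        if values.size and not ((values == 0) | (values == 1)).all():
            raise FormatError("incidence matrix cells must be strictly 0/1")
        # canonical deterministic ordering
        self.data = (
            self.data.astype("int8")
            .sort_index(axis=0, key=_natural_key)
            .sort_index(axis=1, key=_natural_key)
        )

    # -- basic accessors -------------------------------------------------

    @property
    def unit_ids(self) -> tuple[str, ...]:
        return tuple(str(u) for u in self.data.index)

    @property
    def taxon_ids(self) -> tuple[str, ...]:
        return tuple(str(s) for s in self.data.columns)

    @property
    def n_units(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_taxa(self) -> int:
        return int(self.data.shape[1])

    def values(self):
        return self.data.to_numpy(dtype=bool)

    def species_set(self, unit_id: str) -> frozenset[str]:
        row = self.data.loc[unit_id]
        return frozenset(row.index[row > 0])

    def species_sets(self) -> list[frozenset[str]]:
        return [self.species_set(u) for u in self.unit_ids]

    def richness(self) -> pd.Series:
        """Per-unit species richness (alpha diversity)."""
        return self.data.sum(axis=1)

    def pooled_richness(self) -> int:
        """Richness of the union of all units (gamma diversity)."""
        return int((self.data.sum(axis=0) > 0).sum())

    def occupancy_counts(self) -> pd.Series:
        """Number of units occupied by each taxon."""
        return self.data.sum(axis=0)

    # -- I/O -------------------------------------------------------------

    def to_wide_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index_label="unit")

    @classmethod
    def from_wide_csv(cls, path: str | Path, level: str) -> "IncidenceMatrix":
        frame = pd.read_csv(path, dtype={0: str})
        if frame.shape[1] < 2:
            raise FormatError(f"{path}: wide incidence CSV needs a unit column "
                              "plus at least one taxon column")
        frame = frame.set_index(frame.columns[0])
        frame.index = frame.index.astype(str)
        return cls(frame, level=level)

    def to_json(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "kind": "incidence_matrix",
            "level": self.level,
            "unit_ids": list(self.unit_ids),
            "taxon_ids": list(self.taxon_ids),
            "cells": self.data.to_numpy(dtype=int).tolist(),
        }

    @classmethod
    def from_json(cls, payload: Mapping) -> "IncidenceMatrix":
        frame = pd.DataFrame(
            payload["cells"],
            index=[str(u) for u in payload["unit_ids"]],
            columns=[str(t) for t in payload["taxon_ids"]],
        )
        return cls(frame, level=str(payload["level"]))


def _natural_key(index: pd.Index) -> pd.Index:
    """Sort '2' before '10' for numeric labels, lexicographic otherwise."""

    def key(label: object) -> tuple:
        text = str(label)
        return (0, int(text), "") if text.isdigit() else (1, 0, text)

    return pd.Index([key(x) for x in index])


def section_ids(n_sections: int) -> tuple[str, ...]:
    """Canonical 1-based section labels '1'..'n'."""
    return tuple(str(i) for i in range(1, n_sections + 1))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_occurrences(path: str | Path) -> list[OccurrenceRecord]:
    """Read long-format occurrence records (one encounter per row).

    Required header columns: ``site,section,species,genus,functional_group``.
    Unknown extra columns are ignored with a warning.  Taxonomic consistency
    is enforced across the whole file.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, header row required")
        missing = [c for c in OCCURRENCE_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
        extra = [c for c in reader.fieldnames if c not in OCCURRENCE_COLUMNS]
        if extra:
            logger.warning("%s: ignoring unknown column(s) %s", path, extra)
        records = [
            OccurrenceRecord(
                site_id=row["site"].strip(),
                section_id=row["section"].strip(),
                species=row["species"].strip(),
                genus=row["genus"].strip(),
                functional_group=row["functional_group"].strip(),
            )
            for row in reader
        ]
    TaxonomyMap.from_records(records)  # raises ConsistencyError on conflicts
    return records


def write_occurrences(records: Iterable[OccurrenceRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(OCCURRENCE_COLUMNS)
        for rec in records:
            writer.writerow(
                [rec.site_id, rec.section_id, rec.species, rec.genus,
                 rec.functional_group]
            )


def read_damage_records(path: str | Path) -> list[DamageRecord]:
    """Read per-tree damage records.

    Columns: ``tree,site,section,level,taxa`` where ``taxa`` is a
    semicolon-separated genus list (empty below level 3).
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, header row required")
        missing = [c for c in DAMAGE_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
        records = []
        for row in reader:
            raw = row["taxa"].strip()
            taxa = frozenset(t.strip() for t in raw.split(";") if t.strip())
            try:
                level = int(row["level"])
            except ValueError:
                raise FormatError(
                    f"{path}: tree {row['tree']!r} has non-integer "
                    f"level {row['level']!r}"
                )
            records.append(
                DamageRecord(
                    tree_id=row["tree"].strip(),
                    site_id=row["site"].strip(),
                    section_id=row["section"].strip(),
                    level=level,
                    taxa_on_trunk=taxa,
                )
            )
    return records


def write_damage_records(records: Iterable[DamageRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(DAMAGE_COLUMNS)
        for rec in records:
            writer.writerow(
                [rec.tree_id, rec.site_id, rec.section_id, rec.level,
                 ";".join(sorted(rec.taxa_on_trunk))]
            )


# ---------------------------------------------------------------------------
# incidence construction
# ---------------------------------------------------------------------------

def build_incidence(
    records: Sequence[OccurrenceRecord],
    level: str,
    taxon_rank: str = "species",
    unit_ids: Sequence[str] | None = None,
) -> IncidenceMatrix:
    """Collapse occurrence records into a binary incidence matrix.

    A unit is marked present for a taxon if *any* member occurrence falls in
    it (union semantics): two genera of the same functional group in one
    section contribute a single group incidence, and duplicated records
    change nothing.

    ``unit_ids`` declares the full unit set (e.g. all 20 sections, including
    empty ones); defaults to the units observed in the records.  At section
    level the records must come from a single site.
    """
    if level not in LEVELS:
        raise FormatError(f"level must be one of {LEVELS}, got {level!r}")
    if taxon_rank not in RANKS:
        raise FormatError(
            f"unknown taxon rank {taxon_rank!r}; expected one of {RANKS}"
        )
    taxonomy = TaxonomyMap.from_records(records)
    if level == "section":
        sites = {r.site_id for r in records}
        if len(sites) > 1:
            raise ConsistencyError(
                "section-level incidence mixes sections of multiple sites "
                f"({sorted(sites)}); build one matrix per site"
            )
    present: set[tuple[str, str]] = set()
    units: set[str] = set(str(u) for u in unit_ids) if unit_ids else set()
    taxa: set[str] = set()
    for rec in records:
        unit = rec.site_id if level == "site" else rec.section_id
        if unit_ids is not None and unit not in units:
            raise ConsistencyError(
                f"record in unit {unit!r} outside declared unit set"
            )
        taxon = taxonomy.relabel(rec.species, taxon_rank)
        units.add(unit)
        taxa.add(taxon)
        present.add((unit, taxon))
    frame = pd.DataFrame(
        0, index=sorted(units), columns=sorted(taxa), dtype="int8"
    )
    for unit, taxon in present:
        frame.loc[unit, taxon] = 1
    return IncidenceMatrix(frame, level=level)


# ---------------------------------------------------------------------------
# packaged fixture
# ---------------------------------------------------------------------------

def load_fixture_table3() -> tuple[IncidenceMatrix, TaxonomyMap]:
    """Packaged species-by-plantation presence table of the teak case study.

    13 termite species (4 genera, functional groups IIf and III) scored in
    three plantations A (5 y), B (6 y) and C (9 y); per-site richness is
    6, 6 and 9 and three species occur at every site.
    """
    data_dir = resources.files("beltdiv").joinpath("data")
    with resources.as_file(data_dir.joinpath("table3_incidence.csv")) as p:
        matrix = IncidenceMatrix.from_wide_csv(p, level="site")
    sp2g: dict[str, str] = {}
    g2f: dict[str, str] = {}
    with resources.as_file(data_dir.joinpath("table3_taxonomy.csv")) as p:
        with open(p, newline="", encoding="utf-8") as handle:
            for row in csv.DictReader(handle):
                sp2g[row["species"]] = row["genus"]
                g2f[row["genus"]] = row["functional_group"]
    taxonomy = TaxonomyMap(sp2g, g2f)
    taxonomy.check_covers(matrix.taxon_ids)
    return matrix, taxonomy


def records_from_incidence(
    matrix: IncidenceMatrix, taxonomy: TaxonomyMap
) -> list[OccurrenceRecord]:
    """Expand a species-rank incidence matrix back into occurrence records.

    Site-level matrices yield one record per (site, species) with the
    section label '1' as a placeholder, which is sufficient for all
    site-level statistics.
    """
    records = []
    for unit in matrix.unit_ids:
        for species in sorted(matrix.species_set(unit)):
            genus = taxonomy.genus_of(species)
            records.append(
                OccurrenceRecord(
                    site_id=unit if matrix.level == "site" else "S1",
                    section_id="1" if matrix.level == "site" else unit,
                    species=species,
                    genus=genus,
                    functional_group=taxonomy.group_of(genus),
                )
            )
    return records


def export_json(obj: dict, path: str | Path | None = None) -> str:
    """Serialise a result payload (adds schema_version if absent)."""
    payload = dict(obj)
    payload.setdefault("schema_version", SCHEMA_VERSION)
    text = json.dumps(payload, indent=2, sort_keys=False, allow_nan=True)
    if path is not None:
        Path(path).write_text(text + "\n", encoding="utf-8")
    return text
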