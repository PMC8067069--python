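"""Beta-diversity partitioning into turnover and nestedness components.

Total pairwise dissimilarity between two species sets (Sørensen or Jaccard
family) is decomposed into

* *turnover* -- dissimilarity from species replacement, insensitive to
  richness differences (beta_sim / beta_jtu);
* *nestedness-resultant* dissimilarity -- the remainder, reflecting poorer
  units holding subsets of richer units' species (beta_sne / beta_jne).

With a = shared species, b and c = species exclusive to each unit,
m = min(b, c) and M = max(b, c):

    Sørensen:  total = (b+c)/(2a+b+c)   turnover = m/(a+m)
    Jaccard:   total = (b+c)/(a+b+c)    turnover = 2m/(a+2m)

and nestedness = total - turnover in both families.  The multisite forms
replace per-pair quantities by sums over all unordered unit pairs, with
sum(S_i) - S_T as the multisite analogue of the shared pool.  The
nestedness ratio beta_RAT (multisite) / beta_rat (pairwise) is
nestedness / total, undefined when total = 0.

Uncertainty is attached by resampling units ("randomizations"): by default
a bootstrap over units with replacement at full size, recomputing the
multisite partition per replicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .core_data import FormatError, IncidenceMatrix

logger = logging.getLogger(__name__)

FAMILIES = ("sorensen", "jaccard")
COMPONENTS = ("total", "turnover", "nestedness")


@dataclass(frozen=True)
class PairCounts:
    """Shared/exclusive species counts for one unit pair."""

    a: int
    b: int
    c: int

    @classmethod
    def from_sets(cls, unit1: frozenset[str] | set[str],
                  unit2: frozenset[str] | set[str]) -> "PairCounts":
        shared = len(unit1 & unit2)
        return cls(a=shared, b=len(unit1) - shared, c=len(unit2) - shared)


@dataclass
class BetaPartition:
    """One decomposition: total = turnover + nestedness (one family/level)."""

    family: str
    level: str
    total: float
    turnover: float
    nestedness: float
    ratio: float | None
    degenerate: bool = False

    def to_json(self) -> dict:
        return {
            "family": self.family,
            "level": self.level,
            "total": self.total,
            "turnover": self.turnover,
            "nestedness": self.nestedness,
            "ratio": self.ratio,
            "degenerate": self.degenerate,
        }


@dataclass
class ResampledBeta:
    """Unit-resampled multisite partitions with per-component mean/sd."""

    family: str
    replicates: list[BetaPartition]
    mean: dict[str, float]
    sd: dict[str, float]
    n_replicates: int
    subset_size: int
    replace: bool
    seed: int | None

    def to_json(self) -> dict:
        return {
            "family": self.family,
            "level": "multisite",
            "mean": self.mean,
            "sd": self.sd,
            "n_replicates": self.n_replicates,
            "subset_size": self.subset_size,
            "replace": self.replace,
            "seed": self.seed,
        }


def _check_family(family: str) -> None:
    if family not in FAMILIES:
        raise FormatError(f"family must be one of {FAMILIES}, got {family!r}")


def _safe_div(num: float, den: float, what: str) -> tuple[float, bool]:
    if den == 0.0:
        if num != 0.0:  # cannot happen for these formulas, but be explicit
            raise ZeroDivisionError(what)
        logger.warning("degenerate denominator in %s; component set to 0", what)
        return 0.0, True
    return num / den, False


def pairwise_partition(
    unit1: Iterable[str],
    unit2: Iterable[str],
    family: str = "sorensen",
) -> BetaPartition:
    """Partition the dissimilarity between two units' species sets."""
    _check_family(family)
    counts = PairCounts.from_sets(set(unit1), set(unit2))
    a, b, c = counts.a, counts.b, counts.c
    m = min(b, c)
    if family == "sorensen":
        total, deg1 = _safe_div(b + c, 2 * a + b + c, "Sørensen pairwise total")
        turnover, deg2 = _safe_div(m, a + m, "Sørensen pairwise turnover")
    else:
        total, deg1 = _safe_div(b + c, a + b + c, "Jaccard pairwise total")
        turnover, deg2 = _safe_div(2 * m, a + 2 * m, "Jaccard pairwise turnover")
    nestedness = total - turnover
    return BetaPartition(
        family=family,
        level="pairwise",
        total=total,
        turnover=turnover,
        nestedness=nestedness,
        ratio=(nestedness / total) if total > 0 else None,
        degenerate=deg1 or deg2,
    )


def multisite_partition(
    incidence: IncidenceMatrix | Sequence[frozenset[str]],
    family: str = "sorensen",
) -> BetaPartition:
    """Multisite partition over all units of an incidence matrix.

    Also accepts a plain sequence of species sets (used by the resampler,
    where bootstrap replicates may repeat units).
    """
    _check_family(family)
    if isinstance(incidence, IncidenceMatrix):
        sets = incidence.species_sets()
    else:
        sets = [frozenset(s) for s in incidence]
    if len(sets) < 2:
        raise FormatError("multisite partition requires at least 2 units")
    pooled = frozenset().union(*sets)
    core = sum(len(s) for s in sets) - len(pooled)  # sum S_i - S_T
    sum_min = 0
    sum_max = 0
    for s1, s2 in combinations(sets, 2):
        b = len(s1 - s2)
        c = len(s2 - s1)
        sum_min += min(b, c)
        sum_max += max(b, c)
    if family == "sorensen":
        turnover, deg1 = _safe_div(sum_min, core + sum_min,
                                   "Sørensen multisite turnover")
        total, deg2 = _safe_div(sum_min + sum_max,
                                2 * core + sum_min + sum_max,
                                "Sørensen multisite total")
    else:
        turnover, deg1 = _safe_div(2 * sum_min, core + 2 * sum_min,
                                   "Jaccard multisite turnover")
        total, deg2 = _safe_div(sum_min + sum_max,
                                core + sum_min + sum_max,
                                "Jaccard multisite total")
    nestedness = total - turnover
    return BetaPartition(
        family=family,
        level="multisite",
        total=total,
        turnover=turnover,
        nestedness=nestedness,
        ratio=(nestedness / total) if total > 0 else None,
        degenerate=deg1 or deg2,
    )


def nestedness_ratio(partition: BetaPartition) -> float | None:
    """nestedness / (nestedness + turnover); ``None`` when total is 0."""
    if partition.total <= 0:
        return None
    return partition.nestedness / partition.total


def beta_resample(
    incidence: IncidenceMatrix,
    family: str = "sorensen",
    n_replicates: int = 100,
    subset_size: int | None = None,
    replace: bool = True,
    seed: int | None = None,
) -> ResampledBeta:
    """Randomized multisite partitions by resampling units.

    Each replicate draws ``subset_size`` units (default: all units, with
    replacement -- a bootstrap over units) and recomputes the multisite
    partition.  Seeded and reproducible; the scheme is recorded in the
    output.
    """
    _check_family(family)
    if n_replicates < 1:
        raise FormatError("n_replicates must be >= 1")
    n_units = incidence.n_units
    size = n_units if subset_size is None else int(subset_size)
    if size > n_units and not replace:
        raise FormatError("subset_size exceeds number of units")
    if size < 2:
        raise FormatError("subset_size must be >= 2 for a multisite partition")
    sets = incidence.species_sets()
    rng = np.random.default_rng(seed)
    replicates = []
    for _ in range(n_replicates):
        chosen = rng.choice(n_units, size=size, replace=replace)
        replicates.append(
            multisite_partition([sets[j] for j in chosen], family=family)
        )
    mean = {}
    sd = {}
    for comp in COMPONENTS:
        vals = np.array([getattr(r, comp) for r in replicates])
        mean[comp] = float(vals.mean())
        sd[comp] = float(vals.std(ddof=1)) if n_replicates > 1 else 0.0
    return ResampledBeta(
        family=family,
        replicates=replicates,
        mean=mean,
        sd=sd,
        n_replicates=n_replicates,
        subset_size=size,
        replace=replace,
        seed=seed,
    )
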