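"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive (full enumeration) and shares no code
with the implementation paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.special import comb


def brute_zeta(values: np.ndarray, order: int) -> tuple[float, float]:
    """Mean and sample sd of intersection size over all order-subsets."""
    sizes = [
        int(values[list(chosen)].all(axis=0).sum())
        for chosen in itertools.combinations(range(values.shape[0]), order)
    ]
    mean = float(np.mean(sizes))
    sd = float(np.std(sizes, ddof=1)) if len(sizes) > 1 else 0.0
    return mean, sd


def brute_accumulation_permutation(values: np.ndarray) -> np.ndarray:
    """Exact mean cumulative richness per t over all unit orderings."""
    n = values.shape[0]
    totals = np.zeros(n)
    count = 0
    for perm in itertools.permutations(range(n)):
        cumulative = np.maximum.accumulate(values[list(perm)], axis=0)
        totals += cumulative.sum(axis=1)
        count += 1
    return totals / count


def brute_bootstrap_multisite_mean(sets, size: int, family: str) -> float:
    """Exact expectation of the multisite total over all ordered bootstrap
    draws of ``size`` units (with replacement)."""
    from beltdiv import multisite_partition

    totals = [
        multisite_partition([sets[i] for i in draw], family=family).total
        for draw in itertools.product(range(len(sets)), repeat=size)
    ]
    return float(np.mean(totals))


def brute_expected_zeta(ps, n_sections: int, order: int) -> float:
    """E[zeta_order] under independent occupancy, by enumerating every
    occupancy pattern of every species over the section universe."""
    total = 0.0
    denom = comb(n_sections, order, exact=True)
    for p in ps:
        for pattern in itertools.product((0, 1), repeat=n_sections):
            k = sum(pattern)
            prob = (p ** k) * ((1 - p) ** (n_sections - k))
            total += prob * comb(k, order, exact=True) / denom
    return total


def random_incidence(rng: np.random.Generator, n_units: int, n_species: int,
                     p: float = 0.4):
    """A random binary incidence matrix wrapped as an IncidenceMatrix."""
    import pandas as pd

    from beltdiv import IncidenceMatrix

    cells = (rng.random((n_units, n_species)) < p).astype("int8")
    frame = pd.DataFrame(
        cells,
        index=[str(i + 1) for i in range(n_units)],
        columns=[f"sp{j:02d}" for j in range(n_species)],
    )
    return IncidenceMatrix(frame, level="section")
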