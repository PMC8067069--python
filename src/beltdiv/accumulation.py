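"""Sample-based species-accumulation curves by randomization.

The curve reports the expected cumulative species richness after pooling
t = 1..N sampling units, smoothed over many randomized unit orderings.  Two
schemes are provided because survey software phrases "randomization with
replacement" ambiguously:

* ``with_replacement`` (default) -- each randomization draws N units with
  replacement (a bootstrap of the sampling process);
* ``permutation`` -- each randomization shuffles the observed units, the
  classical sample-based rarefaction; at t = N every randomization reaches
  the pooled richness exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_data import FormatError, IncidenceMatrix

SCHEMES = ("with_replacement", "permutation")


@dataclass
class AccumulationCurve:
    """Mean/sd cumulative richness per number of pooled units."""

    t: np.ndarray
    mean_richness: np.ndarray
    sd: np.ndarray
    n_randomizations: int
    scheme: str
    seed: int | None

    def to_json(self) -> dict:
        return {
            "t": self.t.tolist(),
            "mean_richness": self.mean_richness.tolist(),
            "sd": self.sd.tolist(),
            "n_randomizations": self.n_randomizations,
            "scheme": self.scheme,
            "seed": self.seed,
        }


def accumulation_curve(
    incidence: IncidenceMatrix,
    n_randomizations: int = 100,
    scheme: str = "with_replacement",
    seed: int | None = None,
) -> AccumulationCurve:
    """Randomized species-accumulation curve over the matrix's units."""
    if n_randomizations < 1:
        raise FormatError("n_randomizations must be >= 1")
    if scheme not in SCHEMES:
        raise FormatError(f"scheme must be one of {SCHEMES}, got {scheme!r}")
    n_units = incidence.n_units
    if n_units < 1:
        raise FormatError("accumulation requires at least one unit")
    values = incidence.values()
    rng = np.random.default_rng(seed)
    richness = np.empty((n_randomizations, n_units))
    for rep in range(n_randomizations):
        if scheme == "with_replacement":
            order = rng.integers(0, n_units, size=n_units)
        else:
            order = rng.permutation(n_units)
        cumulative = np.maximum.accumulate(values[order], axis=0)
        richness[rep] = cumulative.sum(axis=1)
    mean = richness.mean(axis=0)
    sd = richness.std(axis=0, ddof=1) if n_randomizations > 1 \
        else np.zeros(n_units)
    return AccumulationCurve(
        t=np.arange(1, n_units + 1),
        mean_richness=mean,
        sd=sd,
        n_randomizations=n_randomizations,
        scheme=scheme,
        seed=seed,
    )
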