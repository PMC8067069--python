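# Methods

This note documents the statistical model behind each `beltdiv` component,
the defaults and why they were chosen, the numerical conventions, and what
the synthetic-data generator does and does not emulate.

## Data model

All statistics operate on binary incidence matrices: sampling units
(transect sections, or whole sites) × taxa, cells 1 if the taxon was
encountered in the unit at least once.  Functional-group and genus tables
are derived from species records by per-unit **union**: a section holding
two fungus-growing genera contributes *one* group-IIf incidence.  This is
the only reading consistent with field summaries in which summed genus
proportions exceed the corresponding group proportions; the alternative
per-encounter counting is available behind an explicit flag
(`proportions_from_records(..., count_encounters=True)`).

Row and column labels are unique and held in natural sort order
(`"2" < "10"`), so outputs are reproducible regardless of input order.
Occupancy divides by the *declared* section count (default 20, empty
sections included), not by the number of non-empty sections, matching the
fixed transect design.

## Zeta diversity

ζᵢ is the mean number of species shared by i units over uniformly chosen
i-subsets.  Because the mean over all subsets satisfies

    ζᵢ = Σₛ C(kₛ, i) / C(N, i),        kₛ = units occupied by species s,

with the analogous pair identity (co-occupancy counts k_st) for the second
moment, "exact" mode evaluates these closed forms instead of enumerating
subsets; the test suite verifies equality with naive enumeration for
N ≤ 12.  Monte-Carlo mode draws `n_samples` subsets per order from a
seeded generator and is used automatically once C(N, i) exceeds 100,000
(full enumeration covers the 20-section design: C(20,5) = 15,504).

The reported spread is the sample standard deviation of intersection sizes
over subsets; the plotted band is mean ± 1.96 sd.  A subtle consequence of
the identity above: uniform-subset zeta depends *only* on the occupancy
counts kₛ, never on which particular sections a species occupies.  Spatial
aggregation per se is therefore invisible to this statistic; what
distinguishes assembly processes is their occupancy-frequency profile
(see "Community presets" below).

**Decline models.**  Exponential: OLS of ln ζᵢ on i.  Power law: OLS of
ln ζᵢ on ln i.  Natural logarithms throughout; rescaling the response
(equivalently, changing the log base) shifts both AICs equally, so ΔAIC is
base-invariant (property-tested).  Orders with ζ = 0 are truncated before
fitting (their log is undefined) and at least three positive orders are
required.  AIC uses the full Gaussian-likelihood convention

    AIC = n ln(2π) + n ln(RSS/n) + n + 2(k+1),  k = 2,

which matches what R's `AIC()` reports for `lm` fits, so magnitudes are
comparable to values produced with mainstream statistical software.  An
RSS below 1e-20 is treated as an exact fit (AIC −∞); when both models fit
exactly (e.g. constant ζ) ΔAIC is defined as 0.

**Verdict.**  ΔAIC = AIC(power law) − AIC(exponential);
ΔAIC ≥ 2 → "stochastic", ΔAIC ≤ −2 → "niche_driven", otherwise
"indeterminate".  The threshold 2 is the conventional
barely-distinguishable margin for AIC comparisons and is configurable; the
verdict is always reported next to the raw AICs, never instead of them.

## Beta-diversity partitioning

With a shared species, b and c exclusive species, m = min(b, c),
M = max(b, c):

| family  | total            | turnover     | nestedness        |
|---------|------------------|--------------|-------------------|
| Sørensen| (b+c)/(2a+b+c)   | m/(a+m)      | total − turnover  |
| Jaccard | (b+c)/(a+b+c)    | 2m/(a+2m)    | total − turnover  |

Multisite analogues replace a by ΣSᵢ − S_T (summed unit richness minus
pooled richness) and m, M by Σmin, Σmax over unordered unit pairs.
Turnover is the replacement component insensitive to richness differences;
nestedness-resultant dissimilarity is the remainder.  The ratio
nestedness/total (β_RAT multisite, β_rat pairwise) is reported as
*undefined* (not 0) when total = 0.  Degenerate denominators (all units
empty) yield 0 components with a logged warning and a `degenerate` flag,
keeping summaries additive.  The multisite Sørensen partition is
cross-checked in the test suite against an independent implementation
(vegan's `nestedbetasor`) on the packaged fixture.

"Randomizations" are implemented as a seeded bootstrap over units
(default: full size, with replacement, 100 replicates), since the exact
randomization scheme used by survey software is underdetermined with a
handful of sites; subset size and replacement are configurable and echoed
in the output.

## Species accumulation

Per randomization, units are drawn (bootstrap) or shuffled (permutation)
and cumulative union richness recorded at each pooling depth t; means and
sds are taken over randomizations (default 100, seeded).  The permutation
scheme's mean is checked against exact enumeration of all orderings for
N ≤ 6.  No parametric richness estimators (Chao, ICE, Mao Tau) are
provided; only the randomized empirical curve.

## Damage analysis

Bark-damage levels: 1 traces only; 2 peeled bark with gallery, no
termites; 3 gallery with active termites; 0 records an undamaged tree so
percentages have the full tree count as denominator.  Record validity is
structural: taxa on the trunk are required exactly at level 3.  Level-3
damage is attributed to genera, and to functional groups by per-tree union.

The occupancy–damage relationship is an OLS line (scipy `linregress`) of a
group's level-3 incidence count (optionally percentage) on its occupied
area across sites.  Site counts are inherently small in this design; fits
with n < 5 carry a `small_n` flag and a logged warning rather than being
suppressed — with n = 2 the fit is trivially perfect (r² = 1) and the flag
is the only honest signal.

## Synthetic data

`simulate_transect` draws a 20-section transect for a configurable species
pool (label, genus, group, occupancy probability p_s) under three
placement regimes: *independent* (each section independently with
probability p_s), *aggregated* (one uniformly placed contiguous window of
length round(p_s·n); a fixed window width can override), and *nested*
(species s occupies the prefix 1..⌈p_s·n⌉ — maximal nestedness, multisite
turnover exactly 0).  A single integer seed is split into one child stream
per species (and per section for damage), so adding a species never
perturbs the draws of the others.  For the independent regime
E[ζ_order] = Σₛ p_sᵒʳᵈᵉʳ is exposed as `expected_zeta` and serves as a
closed-form oracle.

**Community presets.**  Because uniform-subset zeta sees only occupancy
counts (above), an assembly process must be emulated by its
occupancy-frequency profile together with its arrangement:

* `neutral_community` — independent placement with near-equivalent
  moderate probabilities, evenly spaced 0.50 → 0.20 across the 13-species
  pool.  Species equivalence is the defining neutral-assembly assumption;
  the expected decline Σ p_sᵢ is then close to log-linear and the AIC
  verdict is "stochastic".
* `niche_community` — maximally nested staircase with graded
  core–satellite probabilities, evenly spaced 0.95 → 0.05.  Graded
  occupancy is what nestedness means structurally (a flat profile under
  prefix placement would be a degenerate block, not a nested pattern);
  the ubiquitous core retains shared species at high orders, the decline
  log-log-linearises, and the verdict is "niche_driven".

The pool size (13 species, four genera, groups IIf/III) and the 20-section
design mirror the shipped case study.  Preset recovery — verdict
"stochastic" for ≥80% of neutral transects and "niche_driven" for ≥80% of
nested ones over 200 seeds — is asserted in the acceptance tests, with
exact zeta and the default ΔAIC threshold.

`simulate_damage` assigns each tree a level-3 probability
logistic(baseline + effect·w) where w is the IIf occupancy of the
section's radius-1 neighborhood; defaults baseline = −3 (≈5% attack at
zero occupancy) and effect = 3.  Levels 1/2 are drawn among the remaining
trees with probabilities 0.35/0.25, and 3 trees per section emulate the
observed planting density (50–68 trees per 20-section transect).  Trunk
genera at level 3 are sampled from the IIf genera present in the section;
a level-3 draw where none is present is downgraded to level 2 (gallery
without termites) with a log message.  `plantation_series` provides three
transects with occupancy scale factors 0.2/0.5/1.0 so the group-level
occupied area (a union across member species, which saturates quickly)
genuinely varies across sites.

**What the generator does not emulate:** colony/foraging mechanics,
between-species interactions, distance decay within the transect,
observer error, or abundance structure.  Passing recovery tests therefore
show that the *pipeline* distinguishes the statistical signatures it
targets, not that field data of this size always will.

## Numerical conventions and edge cases

* Additivity total = turnover + nestedness holds to 1e-12 and is
  property-tested at both levels, both families.
* Proportions over one transect sum to 1 exactly when any incidence
  exists; an all-empty matrix yields an empty result, never 0/0.
* Sample standard deviations use ddof = 1; a single replicate/subset
  reports sd 0.
* Monte-Carlo/bootstrap agreement tests use three standard errors of the
  estimate as tolerance.
* Problem sizes in the test suite (transects of 20 sections, 13 species;
  200-replicate recovery experiments; 1000 small random matrices for
  monotonicity) keep the full run around half a minute on one CPU while
  leaving the Monte-Carlo tolerances meaningful.

## Known limitations

* The exact zeta identity assumes uniform subset sampling; ordered or
  nearest-neighbour zeta schemes (where spatial aggregation *would*
  matter) are out of scope.
* Beta randomization with very few units (3 sites) mixes few distinct
  bootstrap configurations; the replicate sd is reported but should be
  read as a resampling spread, not a sampling-theory standard error.
* The occupancy–damage regression is descriptive; with the 2–3 sites a
  realistic survey provides it cannot support inference beyond the sign
  and rough magnitude of the association.
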