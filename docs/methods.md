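# Methods

This note documents the statistical model, the conventions and numerical
choices the package commits to, the synthetic-registry generator, and the
study conditions used by the validation suite and `scripts/acceptance.py`.
It states no empirical result that the tests or the acceptance script do not
themselves compute.

## The Knox test and its null

The Knox statistic `O(s, t)` counts unordered case pairs whose birth
locations are less than `s` meters apart (Euclidean distance on projected
planar coordinates — the package performs no CRS transformations or geodesic
computation) *and* whose birth dates are less than `t` days apart.
Inequalities are **strict**; a pair exactly at a lag is excluded. Time is
handled as integer days with "2 years" = 730 days, "6/12/18 months" =
182/365/548 days; no month- or year-length convention beyond that is
assumed. The default lag grid is {0.5, 1, 2, 5, 10} km × {182, 365, 548,
730} days.

**Null construction.** Under the null of no space-time interaction, where a
child was born should be exchangeable with the residence of any child of the
same birth period. The Monte-Carlo null therefore holds all birth dates (and
all covariates) fixed and independently resamples each case's birth location
from the child-population intensity evaluated at that case's birth date: a
grid cell is chosen with probability proportional to its time-interpolated
child count and the location is uniform within the cell. Population
snapshots (census-style cell counts) are interpolated linearly in time
between snapshot dates and clamped to the nearest snapshot outside their
range. The published analysis this reconstructs describes its null only as
"accounting for uneven shifts of the residential population" with details in
an unavailable appendix; the conditional-location resampling above is this
package's documented reconstruction of that idea, and the generator's null
mode draws case locations by the *same* mechanism, which makes the null
exact by exchangeability in the validation studies.

Because the interpolated cell counts `(1−a)·W_k + a·W_{k+1}` form a
two-component mixture, replicate sampling picks one of the two bracketing
snapshots with probability proportional to `(1−a)·total_k` vs
`a·total_{k+1}` and then inverse-CDF samples a cell from that snapshot. This
is numerically identical to sampling the interpolated vector directly and
lets per-snapshot CDFs be reused across replicates.

**p-values.** All Monte-Carlo p-values use the add-one convention
`p = (1 + #{replicate ≥ observed}) / (B + 1)`, so `p ∈ [1/(B+1), 1]` and a
replicate count of at least 99 is enforced.

**Multiplicity over the lag grid.** The grid-search correction is a
max-statistic (min-p) construction computed from a single null ensemble: the
observed data and the B replicates are pooled, every member's per-cell
p-value is its rank within the pooled ensemble (`#{members ≥ itself}/(B+1)`,
which for the observed member reproduces the add-one formula exactly), and
the adjusted p-value is the pooled fraction of members whose minimum
per-cell p is at most the observed minimum. Treating the observed data
symmetrically with the replicates makes the min-p statistic exchangeable
under the null, so the familywise level is exact up to tie-induced
conservatism; an earlier asymmetric variant (replicate ranks computed on a
denominator of B) measurably inflated the familywise rate in calibration and
was replaced by the pooled construction. The adjusted p can never fall below
the smallest per-cell p.

**Critical lags.** The lag pair with the smallest per-cell p is selected;
ties are broken by larger observed/expected ratio, then smaller spatial lag,
then smaller temporal lag — deterministic and reported with results.

## Clusters and the size spectrum

A case is clustered iff it has at least one other case within the critical
lags; clusters are the connected components of the close-pair graph
(networkx), so chains merge transitively. The size spectrum counts clusters
of each exact size, with nonclustered cases entering as size-1 clusters, and
the partition identity Σ k·count(k) = n always holds. For each size k the
test statistic is the number of clusters of size ≥ k; its null distribution
comes from the same location-resampling null, and p-values use the add-one
convention — consequently a size with zero observed clusters has p exactly
1.0 (some published tables print 0.999 for such rows under an unstated
convention; this package reports 1.0 and documents the difference rather
than replicate an unexplained constant).

## Child-population-density index

For case i, let `p_i` be the probability that at least one *other* case
falls within the critical space-time cylinder around case i's observed birth
location and date, under the null. The index is `logit(p_i)`; added to the
case-comparison regressions it absorbs associations that merely reflect
population density. Two estimators:

- `method="mc"` (default): the share of B null replicates in which some
  other replicate case lies within the lags. `p_i` is clamped to
  `[1/(2B), 1 − 1/(2B)]` before the logit so the index is finite, with the
  number of clamped cases reported.
- `method="poisson"`: `p_i = 1 − exp(−λ_i)` with
  `λ_i = Σ_{j≠i, |d_j−d_i|<t} P(location_j ∈ disc_i)`, where the location
  probability integrates the interpolated cell intensities against exact
  disc/cell overlap areas (shapely polygon intersection, cell weights
  evaluated on a monthly time grid). The index conditions on the case's own
  birth date and on the other cases' observed birth dates, which matches the
  MC estimand; the two methods agree on the logit scale within Monte-Carlo
  error in the cross-method test.

## Case comparison

Odds ratios come from logistic fits (statsmodels) of clustered status on the
categorical characteristic, with Wald 95% CIs per level and a
likelihood-ratio test per characteristic; for a binary characteristic
without adjustment this is identical to the 2×2 cross-product OR. Missing
values (including "untested" marker status) are excluded listwise per
characteristic, which is why denominators differ between rows. Zero cells in
a 2×2 get a 0.5 continuity correction on all cells, flagged and warned —
an extension beyond the published tables, which contain no zero cells.
Reference levels are configurable per characteristic. Perfect separation is
caught and flagged with a pointer to the Monte-Carlo fallback.

For covariates that are deterministic functions of birth location (distance
bands to point sources), regression inference is invalid because the
clustered label induces dependence between cases; the Monte-Carlo p-value
re-runs the full chain per replicate (resample locations → re-classify
clustered → recompute the covariate from the new locations → refit) and
compares likelihood-ratio statistics with the add-one formula.

Holm's step-down correction is applied across the tested characteristics
(statsmodels `multipletests`); by default the family is the
density-adjusted characteristic-level p-values of one comparison table —
whether a published family spans additional tables is not stated in the
source material, so the family is a configuration choice.

## Synthetic-registry generator

The generator emulates the structure the analysis assumes, not any real
geography:

- **Region & population:** a 50 km × 50 km plane gridded into 1 km cells;
  three Gaussian population centers (scale 3–6 km) whose mixture weights
  drift linearly between three census snapshots (1990/2000/2010); 150,000
  children per snapshot, multinomially allocated. With one static center,
  snapshots differ only by sampling noise.
- **Cases:** 1,282 by default (the scale of the motivating registry), birth
  dates uniform over 1985–2014, locations drawn by the null mechanism;
  diagnosis dates uniform within 16 years of birth.
- **Alternative:** a Poisson number (`cluster_rate`) of mini-epidemics; each
  has a seed case drawn from the null mechanism plus `cluster_excess_cases`
  extra cases uniform in the disc of radius 500 m and within 365 days after
  the seed (a marked Poisson cluster process — Matérn-like in space, boxcar
  in time). The published study offers no generative alternative; this is
  the minimal one the Knox test should detect, and its free parameters are
  reported with every result that uses them.
- **Marker:** binary with background prevalence 0.25, raised to 0.75 inside
  induced clusters (a 3× enrichment), and set to "untested" completely at
  random for 55.6% of cases — matching the tested fraction (569/1,282) of
  the motivating study without modeling calendar time of testing.
- **Covariates:** sex; age-at-diagnosis group; an urban/rural flag defined
  as local child density above the population-weighted median (a pure
  function of location, which is what makes it density-confounded by
  construction); distance bands (≤5 km / 5–10 km / >10 km) to fixed point
  sources.
- **Siblings:** with probability 0.004 per case a sibling is added at <50 m
  and within 3 years, sharing a `sibling_group`; the preprocessing rule
  keeps the earliest-born member (ties: lowest id) and reports unexplained
  <50 m pairs for review.

What the generator does **not** emulate: real geography or migration between
birth and diagnosis, age-incidence structure by subtype, calendar trends in
marker testing, or spatially structured covariate confounding beyond
density. Passing validation on this generator therefore demonstrates the
statistical machinery is correct and calibrated under its stated
assumptions, not that any particular real-world dataset satisfies them.

## Validation study conditions

Chosen once as the package's standing validation settings:

- **Type-I calibration:** 200 simulated null studies, 500 cases each,
  B = 199 replicates; the average per-cell rejection rate at α = 0.05 and
  the familywise rate of the adjusted p must lie in the exact binomial 99%
  band around 0.05 (the uncorrected min-cell rate demonstrably inflates).
  Per-cell MC p-values are discrete, and ties at sparsely populated cells
  make individual cells mildly conservative; averaging over the 20 grid
  cells is reported.
- **Power / recovery:** 100 seeds with `cluster_rate=20`, 500 background
  cases, one excess case per mini-epidemic, 3× marker enrichment, B = 199
  (Knox) and 99 (size spectrum), against 100 matched null seeds.
- **Density attenuation:** 5 null seeds at 800 cases, poisson density
  estimator; the geometric-mean "urban" OR and its shrinkage toward 1 after
  adjustment are reported.
- **Oracle equivalence:** 200 random instances (n ≤ 200) against brute-force
  double-loop pair counting, neighborhood flags, and DFS components.

These sizes keep the full validation suite in the minutes range on a single
CPU while leaving the binomial acceptance bands meaningful.

## Known limitations

- The null-replicate mechanism is a reconstruction (see above); stratified
  or cell-resolution variants of the cited procedure may differ in detail.
- Locations are resampled at cell resolution (uniform within 1 km cells by
  default), so null spatial structure below the cell size is smoothed.
- The density index's closed form ignores within-replicate dependence
  between other cases (Poisson approximation to a sum of independent but
  non-identical Bernoullis); the MC estimator is the default.
- Whether per-cell published p-values used the add-one convention is
  unstated; this package uses add-one throughout, which changes p by at most
  1/(B+1).
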