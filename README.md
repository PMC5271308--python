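# stclust

Space-time clustering analysis of registry point events — built for
epidemiological questions of the form *"are cases of a rare childhood disease
born unusually close to each other in space and time, and do clustered cases
differ from non-clustered ones?"* The motivating application is childhood
leukemia, where localized space-time excesses around birth are a predicted
signature of an infectious contribution to etiology, but the machinery applies
to any georeferenced, dated case registry with census-style population data.

## What it computes

**1. Knox tests over a lag grid.** For spatial lag *s* and temporal lag *t*,
the Knox statistic is the number of unordered case pairs with

```
O(s, t) = #{ (i, j) : ‖x_i − x_j‖ < s  and  |d_i − d_j| < t }
```

(strict inequalities; Euclidean distance on projected planar birth
coordinates, birth-date differences in days). Significance comes from a
Monte-Carlo null that holds birth dates fixed and resamples each case's birth
location from the time-interpolated child population at that case's birth
date — so uneven regional population growth cannot masquerade as clustering.
Per cell, `p = (1 + #{O_b ≥ O}) / (B + 1)`. Searching the grid is corrected
with a max-statistic (min-p) adjustment computed from the same null ensemble,
and the lag pair with the smallest per-cell p becomes the *critical lags*
(s\*, t\*).

**2. Clustered-case comparison.** A case is *clustered* if born within
(s\*, t\*) of at least one other case. Clustered and nonclustered cases are
compared characteristic by characteristic with logistic regression
(likelihood-ratio tests, Wald CIs on odds ratios), with and without a
*child-population-density index* — the per-case log-odds of being clustered
by chance alone — as an adjustment covariate. Covariates that are themselves
functions of location (distance to a point source) get Monte-Carlo p-values
by re-running the whole chain per null replicate. Holm's step-down procedure
corrects across characteristics.

**3. Cluster sizes.** Clustered cases are linked into individual clusters as
connected components of the close-pair graph, and the number of clusters of
each size ≥ k is tested against the same Monte-Carlo null.

A synthetic-registry generator (`stclust.simulate`) produces population
snapshots and case tables under a configurable null (no clustering) or
alternative (induced "mini-epidemic" excesses with an enriched genetic
marker), and `stclust.studies` packages the calibration / power /
attenuation studies used to validate the machinery.

## Worked example

```python
import stclust as st

cfg   = st.SimConfig(n_cases=400, cluster_rate=25.0, seed=31)   # induced clustering
pop   = st.generate_population(cfg)
cases = st.generate_cases(cfg, pop)
cases, _ = st.exclude_siblings(cases)

kt = st.KnoxTest(n_replicates=999, random_state=1).fit(cases, pop)
print(kt.grid_.head(4).to_string(index=False))
print("critical lags:", kt.critical_lags_, " adjusted p:", kt.adjusted_p_max_)

lab = st.link_clusters(cases, *kt.critical_lags_)
print("clustered cases:", lab.n_clustered, "of", len(cases))
print("size spectrum:", lab.size_spectrum)
```

Output:

```
 spatial_lag_m  temporal_lag_days  observed  expected    ratio  p_mc
         500.0              182.0        15  5.469469 2.742496 0.001
         500.0              365.0        30 10.770771 2.785316 0.001
         500.0              548.0        36 15.809810 2.277067 0.001
         500.0              730.0        38 20.851852 1.822380 0.002
critical lags: (500.0, 365.0)  adjusted p: 0.007
clustered cases: 57 of 438
size spectrum: {1: 381, 2: 27, 3: 1}
```

Reading this: at the (0.5 km, 12 months) cell there are 30 observed close
pairs against 10.8 expected under the population-shift null (per-cell
Monte-Carlo p = 0.001); after correcting for searching all 20 lag
combinations the familywise p is 0.007, so the study rejects the null of no
space-time interaction, and the critical lags land on the planted cluster
geometry (radius 500 m, duration 1 y). At those lags, 57 of 438 cases are
clustered, almost all in pairs — as expected when the generator plants
mini-epidemics of one excess case each.

The same stages are available from the shell:

```bash
stclust simulate --n-cases 400 --cluster-rate 25 --seed 31 \
        --cases-out cases.csv --population-out pop.csv
stclust knox --cases cases.csv --population pop.csv --replicates 999 \
        --seed 1 --out knox.json
stclust clusters --cases cases.csv --population pop.csv \
        --s-star 1000 --t-star 730 --replicates 999 --seed 1 \
        --out-cases clusters.csv --out-spectrum spectrum.json
stclust run --config analysis.yaml      # full pipeline from a YAML config
```

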