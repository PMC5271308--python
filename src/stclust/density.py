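"""Child-population-density index.

For each case the index is the log-odds that the case would be clustered —
i.e. that at least one other case would occur within the critical spatial and
temporal lags of its birth — by chance alone, under the same
population-shift-adjusted null as the Knox test.  Adding this index to the
clustered-vs-nonclustered regressions removes associations that merely
reflect child population density (a case born in a dense area is more likely
to be near another case whatever its characteristics).

Two estimators are provided.  ``method="mc"`` (default) estimates the
probability empirically: over B null replicates, the share in which the case
— location and date held fixed — has at least one *replicate* case within the
lags.  ``method="poisson"`` is a closed form: the expected number of other
cases in the space-time cylinder, computed from the interpolated population
intensity (with exact disc/cell overlap areas) and the overall case rate,
converted through p = 1 − exp(−λ).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator

from .knox import _case_arrays
from .population import LocationResampler, PopulationModel

__all__ = ["ChildDensityIndex", "density_index"]


class ChildDensityIndex(BaseEstimator):
    """Per-case log-odds of being clustered by chance alone.

    Attributes after ``fit(cases, population)``:

    p_chance_ : ndarray
        Probability of ≥1 other case within (s*, t*) under the null, clamped
        to [1/(2B), 1 − 1/(2B)] so the logit is finite.
    index_ : ndarray
        logit(p_chance_), the adjustment covariate.
    """

    def __init__(self, spatial_lag_m=1000.0, temporal_lag_days=730.0,
                 method="mc", n_replicates=999, random_state=None):
        self.spatial_lag_m = spatial_lag_m
        self.temporal_lag_days = temporal_lag_days
        self.method = method
        self.n_replicates = n_replicates
        self.random_state = random_state

    def fit(self, cases: pd.DataFrame, population):
        if self.method not in ("mc", "poisson"):
            raise ValueError("method must be 'mc' or 'poisson'")
        model = (population if isinstance(population, PopulationModel)
                 else PopulationModel(population))
        if self.method == "mc":
            if int(self.n_replicates) < 199:
                raise ValueError("method 'mc' requires n_replicates >= 199")
            p = self._fit_mc(cases, model)
        else:
            p = self._fit_poisson(cases, model)
        b = max(int(self.n_replicates), 199)
        lo, hi = 1.0 / (2 * b), 1.0 - 1.0 / (2 * b)
        self.n_clamped_ = int(((p < lo) | (p > hi)).sum())
        p = np.clip(p, lo, hi)
        self.p_chance_ = p
        self.index_ = np.log(p / (1.0 - p))
        return self

    def fit_transform(self, cases, population):
        return self.fit(cases, population).index_

    # -- Monte-Carlo estimator ---------------------------------------------

    def _fit_mc(self, cases, model):
        B = int(self.n_replicates)
        s, t = float(self.spatial_lag_m), float(self.temporal_lag_days)
        rng = np.random.default_rng(self.random_state)
        x, y, days = _case_arrays(cases)
        n = len(cases)
        obs_pts = np.column_stack([x, y])
        sampler = LocationResampler(model, days)
        hits = np.zeros(n, dtype=np.int64)
        for _ in range(B):
            xy = sampler.sample(rng)
            tree = cKDTree(xy)
            neigh = tree.query_ball_point(obs_pts, s, return_sorted=False)
            lens = np.fromiter((len(v) for v in neigh), dtype=np.intp, count=n)
            if lens.sum() == 0:
                continue
            j = np.fromiter((k for v in neigh for k in v), dtype=np.intp, count=lens.sum())
            i = np.repeat(np.arange(n), lens)
            ok = (i != j) & (np.abs(days[i] - days[j]) < t)
            # strict spatial inequality: query_ball_point includes d == s
            d = np.hypot(obs_pts[i[ok], 0] - xy[j[ok], 0], obs_pts[i[ok], 1] - xy[j[ok], 1])
            hit_rows = np.unique(i[ok][d < s])
            hits[hit_rows] += 1
        return hits / B

    # -- closed-form Poisson approximation ----------------------------------

    def _fit_poisson(self, cases, model):
        s, t = float(self.spatial_lag_m), float(self.temporal_lag_days)
        x, y, days = _case_arrays(cases)
        n = len(cases)
        w0, w1 = days.min(), days.max()
        # evaluate on a monthly grid spanning the birth dates
        grid = np.arange(w0, w1 + 30.44, 30.44)
        k0, k1, a = model.bracket(grid)
        w_grid = ((1 - a)[:, None] * model.counts[k0] + a[:, None] * model.counts[k1])
        tot_grid = w_grid.sum(axis=1)

        # exact disc/cell overlap fractions via polygon intersection
        half = model.cell_size_m / 2.0
        tree = cKDTree(model.cell_xy)
        lam = np.empty(n)
        cell_area = model.cell_size_m**2
        for i in range(n):
            disc = shapely.buffer(shapely.Point(x[i], y[i]), s, quad_segs=32)
            cand = tree.query_ball_point([x[i], y[i]], s + half * np.sqrt(2.0))
            cand = np.asarray(cand, dtype=np.intp)
            boxes = shapely.box(model.cell_xy[cand, 0] - half, model.cell_xy[cand, 1] - half,
                                model.cell_xy[cand, 0] + half, model.cell_xy[cand, 1] + half)
            frac = shapely.area(shapely.intersection(boxes, disc)) / cell_area
            # probability a null case born at date u falls inside the disc
            p_disc = w_grid[:, cand] @ frac / tot_grid
            # expected count: sum over the *other* cases whose (fixed) birth
            # dates fall within the temporal lag of case i
            near = np.abs(days - days[i]) < t
            near[i] = False
            lam[i] = np.interp(days[near], grid, p_disc).sum()
        self.lambda_ = lam
        return 1.0 - np.exp(-lam)


def density_index(cases, population, spatial_lag_m=1000.0, temporal_lag_days=730.0,
                  n_replicates=999, seed=None, method="mc") -> ChildDensityIndex:
    """Functional wrapper: fit and return a :class:`ChildDensityIndex`."""
    return ChildDensityIndex(spatial_lag_m, temporal_lag_days, method,
                             n_replicates, random_state=seed).fit(cases, population)
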