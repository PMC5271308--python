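"""Cluster classification, graph linking, and cluster-size inference.

A case is *clustered* if it was born within the critical spatial and temporal
lags of at least one other case; clustered cases are linked into individual
local clusters as the connected components of the close-pair graph, so
transitive chains merge even when their endpoints are not themselves a close
pair.  The size spectrum (number of clusters of each exact size, singletons
counted as size 1) is compared against the same Monte-Carlo null as the Knox
test: for each size k the p-value is the null probability of at least as many
clusters of size ≥ k as observed.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator

from .knox import _candidate_pairs, _case_arrays, close_pair_count
from .population import LocationResampler, PopulationModel

__all__ = [
    "ClusterLabeling",
    "ClusterLabeler",
    "ClusterSizeTest",
    "classify_clustered",
    "link_clusters",
    "size_spectrum_test",
]


@dataclass
class ClusterLabeling:
    """Per-case clustered flags, cluster ids (−1 = nonclustered), and the
    exact-size spectrum, where nonclustered cases count as clusters of size 1."""

    clustered: np.ndarray
    cluster_id: np.ndarray
    size_spectrum: dict

    @property
    def n_clustered(self) -> int:
        return int(self.clustered.sum())


def classify_clustered(cases: pd.DataFrame, spatial_lag_m: float,
                       temporal_lag_days: float) -> np.ndarray:
    """Boolean flag per case: born within the lags of at least one other case."""
    if spatial_lag_m <= 0 or temporal_lag_days <= 0:
        raise ValueError("critical lags must be positive")
    _, pairs = close_pair_count(cases, spatial_lag_m, temporal_lag_days)
    flags = np.zeros(len(cases), dtype=bool)
    if len(pairs):
        flags[pairs.ravel()] = True
    return flags


def link_clusters(cases: pd.DataFrame, spatial_lag_m: float,
                  temporal_lag_days: float) -> ClusterLabeling:
    """Link clustered cases into individual local clusters via graph
    connectivity: close pairs are edges, clusters are connected components.

    Cluster ids are assigned in order of each component's smallest row index,
    so the labeling is deterministic. Nonclustered cases get id −1.
    """
    n = len(cases)
    _, pairs = close_pair_count(cases, spatial_lag_m, temporal_lag_days)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(map(tuple, pairs))
    cluster_id = np.full(n, -1, dtype=int)
    comps = [sorted(c) for c in nx.connected_components(g) if len(c) > 1]
    comps.sort(key=lambda c: c[0])
    spectrum: dict[int, int] = {}
    for cid, comp in enumerate(comps):
        cluster_id[comp] = cid
        spectrum[len(comp)] = spectrum.get(len(comp), 0) + 1
    n_single = int((cluster_id == -1).sum())
    if n_single:
        spectrum[1] = n_single
    clustered = cluster_id >= 0
    return ClusterLabeling(clustered=clustered, cluster_id=cluster_id,
                           size_spectrum=dict(sorted(spectrum.items())))


class ClusterLabeler(BaseEstimator):
    """Estimator wrapper around :func:`link_clusters` with a clustering-style
    API: ``fit`` sets ``labels_`` (cluster id, −1 for nonclustered),
    ``clustered_`` and ``size_spectrum_``."""

    def __init__(self, spatial_lag_m=1000.0, temporal_lag_days=730.0):
        self.spatial_lag_m = spatial_lag_m
        self.temporal_lag_days = temporal_lag_days

    def fit(self, cases: pd.DataFrame, y=None):
        lab = link_clusters(cases, self.spatial_lag_m, self.temporal_lag_days)
        self.labels_ = lab.cluster_id
        self.clustered_ = lab.clustered
        self.size_spectrum_ = lab.size_spectrum
        self.n_clusters_ = int(self.labels_.max() + 1)
        self.labeling_ = lab
        return self

    def fit_predict(self, cases: pd.DataFrame, y=None):
        return self.fit(cases).labels_


def _component_size_counts(x, y, days, s, t, n):
    """Counts of components per exact size (index = size), singletons included."""
    i, j, d, dt = _candidate_pairs(x, y, days, s, t)
    keep = (d < s) & (dt < t)
    i, j = i[keep], j[keep]
    if len(i) == 0:
        out = np.zeros(2, dtype=np.int64)
        out[1] = n
        return out
    a = coo_matrix((np.ones(len(i)), (i, j)), shape=(n, n))
    _, lab = connected_components(a, directed=False)
    sizes = np.bincount(lab)
    return np.bincount(sizes)


class ClusterSizeTest(BaseEstimator):
    """Monte-Carlo test of the cluster-size spectrum at the critical lags.

    For each cluster size k, compares the observed number of clusters of size
    ≥ k with its distribution over null replicates (locations resampled from
    the shifting population, dates fixed). p-values use the add-one
    convention, so sizes never observed get p = 1.0 exactly.

    Attributes after ``fit``: ``table_`` with one row per size — observed
    exact count, MC mean/min/max of the exact count, observed cumulative
    count (size ≥ k), and ``p_mc``; plus ``labeling_`` for the observed data.
    """

    def __init__(self, spatial_lag_m=1000.0, temporal_lag_days=730.0,
                 n_replicates=999, random_state=None):
        self.spatial_lag_m = spatial_lag_m
        self.temporal_lag_days = temporal_lag_days
        self.n_replicates = n_replicates
        self.random_state = random_state

    def fit(self, cases: pd.DataFrame, population):
        B = int(self.n_replicates)
        if B < 99:
            raise ValueError("n_replicates must be >= 99")
        s, t = float(self.spatial_lag_m), float(self.temporal_lag_days)
        model = (population if isinstance(population, PopulationModel)
                 else PopulationModel(population))
        rng = np.random.default_rng(self.random_state)
        x, y, days = _case_arrays(cases)
        n = len(cases)

        obs_counts = _component_size_counts(x, y, days, s, t, n)
        sampler = LocationResampler(model, days)
        rep_counts = []
        kmax = len(obs_counts)
        for _ in range(B):
            xy = sampler.sample(rng)
            c = _component_size_counts(xy[:, 0], xy[:, 1], days, s, t, n)
            rep_counts.append(c)
            kmax = max(kmax, len(c))

        def pad(c):
            return np.pad(c, (0, kmax - len(c)))

        obs = pad(obs_counts)
        rep = np.vstack([pad(c) for c in rep_counts])
        # cumulative "size >= k" counts
        obs_cum = obs[::-1].cumsum()[::-1]
        rep_cum = rep[:, ::-1].cumsum(axis=1)[:, ::-1]

        sizes = np.arange(1, kmax)
        p = (1.0 + (rep_cum[:, 1:] >= obs_cum[None, 1:]).sum(axis=0)) / (B + 1.0)
        self.table_ = pd.DataFrame(
            {
                "size": sizes,
                "observed": obs[1:],
                "mc_mean": rep[:, 1:].mean(axis=0),
                "mc_min": rep[:, 1:].min(axis=0),
                "mc_max": rep[:, 1:].max(axis=0),
                "observed_cum": obs_cum[1:],
                "p_mc": p,
            }
        )
        self.labeling_ = link_clusters(cases, s, t)
        self.n_replicates_ = B
        return self


def size_spectrum_test(cases, population, spatial_lag_m, temporal_lag_days,
                       n_replicates=999, seed=None) -> ClusterSizeTest:
    """Functional wrapper: fit and return a :class:`ClusterSizeTest`."""
    return ClusterSizeTest(spatial_lag_m, temporal_lag_days, n_replicates,
                           random_state=seed).fit(cases, population)
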