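"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive close-pair counts, clustered flags and
connected components with naive O(n²) loops and a hand-rolled DFS so they
share no code path with the implementations they check.
"""

import numpy as np
import pandas as pd
import pytest

from stclust import SimConfig, generate_cases, generate_population
from stclust.population import to_days


# ---------------------------------------------------------------- oracles

def brute_close_pairs(cases, s, t):
    """All close pairs by exhaustive double loop (strict inequalities)."""
    x = cases["x_birth"].to_numpy(float)
    y = cases["y_birth"].to_numpy(float)
    d = np.atleast_1d(to_days(cases["birth_date"]))
    out = []
    for i in range(len(x)):
        for j in range(i + 1, len(x)):
            dist = ((x[i] - x[j]) ** 2 + (y[i] - y[j]) ** 2) ** 0.5
            if dist < s and abs(d[i] - d[j]) < t:
                out.append((i, j))
    return out


def brute_clustered_flags(cases, s, t):
    n = len(cases)
    flags = np.zeros(n, dtype=bool)
    for i, j in brute_close_pairs(cases, s, t):
        flags[i] = flags[j] = True
    return flags


def brute_components(cases, s, t):
    """Connected components of the close-pair graph via iterative DFS.

    Returns a frozenset of frozensets (components of size >= 2)."""
    n = len(cases)
    adj = {i: set() for i in range(n)}
    for i, j in brute_close_pairs(cases, s, t):
        adj[i].add(j)
        adj[j].add(i)
    seen, comps = set(), []
    for start in range(n):
        if start in seen or not adj[start]:
            continue
        stack, comp = [start], set()
        while stack:
            v = stack.pop()
            if v in comp:
                continue
            comp.add(v)
            stack.extend(adj[v] - comp)
        seen |= comp
        comps.append(frozenset(comp))
    return frozenset(comps)


def random_case_table(rng, n, extent=10_000.0, date_span=3650):
    """A bare random case table (uniform, no population structure)."""
    days = rng.integers(5000, 5000 + date_span, n)
    return pd.DataFrame(
        {
            "case_id": np.arange(1, n + 1),
            "x_birth": rng.uniform(0, extent, n),
            "y_birth": rng.uniform(0, extent, n),
            "birth_date": pd.to_datetime(days, unit="D"),
            "diagnosis_date": pd.to_datetime(days + rng.integers(0, 5000, n), unit="D"),
        }
    )


# ---------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def small_config():
    """Small, fast synthetic-registry configuration used across tests."""
    return SimConfig(n_cases=300, seed=7)


@pytest.fixture(scope="session")
def small_registry(small_config):
    pop = generate_population(small_config)
    cases = generate_cases(small_config, pop)
    return cases, pop


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
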