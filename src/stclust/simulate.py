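"""Synthetic registry generator.

Emulates a national childhood-leukemia registry linked to census data: an
inhomogeneous child population that shifts between census snapshots, case
birth events drawn proportional to the local child population at the birth
date, optional localized space-time excesses ("mini-epidemics") with an
enriched binary genetic marker (emulating ETV6-RUNX1), spatially determined
covariates (distance bands to fixed point sources, an urban/rural flag
derived from local child density), and occasional sibling pairs at
near-identical coordinates.

Under the null configuration (``cluster_rate = 0``) case locations are drawn
by exactly the mechanism the Monte-Carlo null resamples from, so downstream
test p-values are uniform by construction — the property the calibration
studies verify.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .population import PopulationModel, PopulationSnapshot, to_days

__all__ = [
    "SimConfig",
    "generate_population",
    "generate_cases",
    "point_source_band",
    "urban_flag",
]

DAYS_16_YEARS = 16 * 365.25
SIBLING_MAX_SEP_M = 50.0
SIBLING_MAX_DT_DAYS = 3 * 365


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated registry.

    Defaults emulate a 30-year national study (births 1985–2014, diagnosis at
    age 0–15) over a 50 km × 50 km region with three population centers whose
    weights drift linearly between three census snapshots. ``cluster_rate``
    is the expected number of induced mini-epidemics per study; each consists
    of a seed case plus ``cluster_excess_cases`` extra cases within
    ``cluster_radius_m`` and ``cluster_duration_days`` of the seed.
    """

    region_extent: tuple = (0.0, 50_000.0, 0.0, 50_000.0)  # xmin, xmax, ymin, ymax (m)
    snapshot_dates: tuple = ("1990-12-01", "2000-12-01", "2010-12-01")
    cell_size_m: float = 1000.0
    n_population_centers: int = 3
    centers: tuple | None = None  # optional ((x, y, sigma_m, w_start, w_end), ...)
    total_children: int = 150_000
    n_cases: int = 1282
    study_start: str = "1985-01-01"
    study_end: str = "2014-12-31"
    cluster_rate: float = 0.0
    cluster_radius_m: float = 500.0
    cluster_duration_days: float = 365.0
    cluster_excess_cases: int = 1
    marker_prevalence_background: float = 0.25
    marker_prevalence_in_cluster: float = 0.75
    marker_untested_fraction: float = 0.556
    sibling_pair_rate: float = 0.004
    n_point_sources: int = 2
    seed: int = 0

    @property
    def n_snapshot_dates(self) -> int:
        return len(self.snapshot_dates)

    def validate(self) -> None:
        probs = {
            "marker_prevalence_background": self.marker_prevalence_background,
            "marker_prevalence_in_cluster": self.marker_prevalence_in_cluster,
            "marker_untested_fraction": self.marker_untested_fraction,
            "sibling_pair_rate": self.sibling_pair_rate,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"configuration error: {name}={p} not in [0, 1]")
        if self.n_population_centers < 1 and not self.centers:
            raise ValueError("configuration error: at least one population center required")
        if self.n_snapshot_dates < 2:
            raise ValueError("configuration error: at least two snapshot dates required")
        if self.cluster_rate > 0 and (
            self.cluster_radius_m <= 0 or self.cluster_duration_days <= 0
        ):
            raise ValueError(
                "configuration error: cluster radius and duration must be positive "
                "when cluster_rate > 0"
            )
        xmin, xmax, ymin, ymax = self.region_extent
        if xmax <= xmin or ymax <= ymin:
            raise ValueError("configuration error: degenerate region extent")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=int(seed))


def _resolved_centers(config: SimConfig) -> np.ndarray:
    """Population centers as an (K, 5) array of (x, y, sigma, w_start, w_end).

    When not given explicitly they are drawn deterministically from the seed:
    centers uniform in the inner 80% of the region, kernel scales 3–6 km, and
    Dirichlet-ish start/end weights so that relative center weights drift
    linearly over the census period.
    """
    if config.centers is not None:
        arr = np.asarray(config.centers, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 5 or len(arr) == 0:
            raise ValueError("configuration error: centers must be (x, y, sigma, w0, w1) rows")
        return arr
    rng = np.random.default_rng([int(config.seed), 7])
    k = config.n_population_centers
    xmin, xmax, ymin, ymax = config.region_extent
    mx, my = 0.1 * (xmax - xmin), 0.1 * (ymax - ymin)
    x = rng.uniform(xmin + mx, xmax - mx, k)
    y = rng.uniform(ymin + my, ymax - my, k)
    sigma = rng.uniform(3000.0, 6000.0, k)
    w0 = rng.dirichlet(np.full(k, 5.0))
    w1 = rng.dirichlet(np.full(k, 5.0))
    return np.column_stack([x, y, sigma, w0, w1])


def _point_sources(config: SimConfig) -> np.ndarray:
    rng = np.random.default_rng([int(config.seed), 8])
    xmin, xmax, ymin, ymax = config.region_extent
    return np.column_stack(
        [
            rng.uniform(xmin, xmax, config.n_point_sources),
            rng.uniform(ymin, ymax, config.n_point_sources),
        ]
    )


def generate_population(config: SimConfig) -> list[PopulationSnapshot]:
    """Draw census-style child-count snapshots on a square grid.

    Cell intensities follow a mixture of Gaussian kernels whose weights drift
    linearly between the first and last snapshot dates; counts are multinomial
    with the configured total, so each snapshot's total is exact.
    """
    config.validate()
    centers = _resolved_centers(config)
    rng = np.random.default_rng([int(config.seed), 11])
    xmin, xmax, ymin, ymax = config.region_extent
    cs = config.cell_size_m
    cx = np.arange(xmin + cs / 2, xmax, cs)
    cy = np.arange(ymin + cs / 2, ymax, cs)
    gx, gy = np.meshgrid(cx, cy, indexing="ij")
    cell_xy = np.column_stack([gx.ravel(), gy.ravel()])

    days = to_days(list(config.snapshot_dates))
    span = max(days.max() - days.min(), 1.0)
    snapshots = []
    for d in days:
        tau = (d - days.min()) / span
        w = (1.0 - tau) * centers[:, 3] + tau * centers[:, 4]
        intensity = np.zeros(len(cell_xy))
        for (px, py, sig), wk in zip(centers[:, :3], w):
            q = ((cell_xy[:, 0] - px) ** 2 + (cell_xy[:, 1] - py) ** 2) / (2 * sig**2)
            intensity += wk * np.exp(-q) / sig**2
        intensity += 1e-9 * intensity.max()  # avoid exactly-empty cells far from centers
        counts = rng.multinomial(config.total_children, intensity / intensity.sum())
        cells = pd.DataFrame({"x": cell_xy[:, 0], "y": cell_xy[:, 1], "child_count": counts})
        snapshots.append(
            PopulationSnapshot(date=pd.Timestamp(np.datetime64(int(d), "D")), cells=cells,
                               cell_size_m=cs)
        )
    return snapshots


def point_source_band(x, y, sources, edges=(5000.0, 10000.0)) -> np.ndarray:
    """Distance band to the nearest point source, as a categorical label.

    A deterministic function of location only, which is what makes it a
    "geographically determined" covariate requiring Monte-Carlo inference.
    """
    sources = np.asarray(sources, dtype=float)
    pts = np.column_stack([np.atleast_1d(x), np.atleast_1d(y)])
    d2 = ((pts[:, None, :] - sources[None, :, :]) ** 2).sum(-1)
    dmin = np.sqrt(d2.min(axis=1))
    labels = np.array([f"<={edges[0]/1000:g}km", f"{edges[0]/1000:g}-{edges[1]/1000:g}km",
                       f">{edges[1]/1000:g}km"])
    return labels[np.searchsorted(np.asarray(edges, float), dmin, side="left")]


def urban_flag(x, y, model: PopulationModel, eval_day: float, threshold: float) -> np.ndarray:
    """Urban/rural flag: local child density above a fixed threshold."""
    return np.where(model.density_at(x, y, eval_day) >= threshold, "urban", "rural")


def urban_threshold(model: PopulationModel, eval_day: float) -> float:
    """Population-weighted median cell density at ``eval_day`` (children/m²)."""
    w = model.weights_at(eval_day)
    dens = w / model.cell_size_m**2
    order = np.argsort(dens)
    cw = np.cumsum(w[order])
    idx = np.searchsorted(cw, 0.5 * cw[-1])
    return float(dens[order[min(idx, len(order) - 1)]])


def generate_cases(config: SimConfig, population: list[PopulationSnapshot]) -> pd.DataFrame:
    """Simulate a registry case table against the given population snapshots.

    Background cases have birth dates uniform over the study window and birth
    locations drawn from the time-interpolated population intensity at their
    birth date.  If ``cluster_rate > 0``, a Poisson number of mini-epidemics
    is induced: each has a seed case (location from the population intensity,
    date uniform) plus excess cases uniform in the disc of
    ``cluster_radius_m`` and within ``cluster_duration_days`` after the seed;
    all members carry ``truth_cluster_id``.  The binary marker is drawn with
    elevated prevalence inside induced clusters and is set to "untested"
    completely at random at the configured rate.  Sibling pairs share a
    ``sibling_group`` id, coordinates within 50 m, and birth dates within 3
    years.
    """
    config.validate()
    if not population:
        raise ValueError("population must be nonempty")
    model = PopulationModel(population)
    rng = np.random.default_rng([int(config.seed), 13])
    w0, w1 = to_days(config.study_start), to_days(config.study_end)
    xmin, xmax, ymin, ymax = config.region_extent

    # background cases
    n = int(config.n_cases)
    days = np.floor(rng.uniform(w0, w1 + 1, n))
    xy = model.sample_locations(days, rng)
    truth = np.full(n, -1, dtype=int)

    # induced mini-epidemics
    n_clusters = rng.poisson(config.cluster_rate) if config.cluster_rate > 0 else 0
    extra_xy, extra_days, extra_truth = [], [], []
    for cid in range(n_clusters):
        seed_day = np.floor(rng.uniform(w0, w1 + 1))
        seed_xy = model.sample_locations([seed_day], rng)[0]
        m = int(config.cluster_excess_cases)
        r = config.cluster_radius_m * np.sqrt(rng.random(m))
        theta = rng.uniform(0, 2 * np.pi, m)
        ex = np.column_stack([seed_xy[0] + r * np.cos(theta), seed_xy[1] + r * np.sin(theta)])
        ex[:, 0] = np.clip(ex[:, 0], xmin, xmax)
        ex[:, 1] = np.clip(ex[:, 1], ymin, ymax)
        dts = np.floor(rng.uniform(0, config.cluster_duration_days, m))
        extra_xy.append(np.vstack([seed_xy, ex]))
        extra_days.append(np.concatenate([[seed_day], np.clip(seed_day + dts, w0, w1)]))
        extra_truth.append(np.full(1 + m, cid))
    if n_clusters:
        xy = np.vstack([xy] + extra_xy)
        days = np.concatenate([days] + extra_days)
        truth = np.concatenate([truth] + extra_truth)
    n_total = len(days)

    # marker, with higher prevalence inside induced clusters
    in_cluster = truth >= 0
    p_pos = np.where(in_cluster, config.marker_prevalence_in_cluster,
                     config.marker_prevalence_background)
    positive = rng.random(n_total) < p_pos
    tested = rng.random(n_total) >= config.marker_untested_fraction
    marker = np.where(tested, np.where(positive, "yes", "no"), "untested")

    diag_days = days + np.floor(rng.uniform(0.0, DAYS_16_YEARS - 1.0, n_total))
    sibling = np.full(n_total, -1, dtype=int)

    # sibling pairs: duplicate a case at <50 m and <3 y
    n_sib = rng.binomial(n_total, config.sibling_pair_rate)
    if n_sib:
        idx = rng.choice(n_total, size=n_sib, replace=False)
        r = (SIBLING_MAX_SEP_M - 1) * np.sqrt(rng.random(n_sib))
        theta = rng.uniform(0, 2 * np.pi, n_sib)
        sib_xy = xy[idx] + np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        sib_days = np.clip(
            days[idx] + np.floor(rng.uniform(-SIBLING_MAX_DT_DAYS, SIBLING_MAX_DT_DAYS, n_sib)),
            w0, w1,
        )
        sib_diag = sib_days + np.floor(rng.uniform(0.0, DAYS_16_YEARS - 1.0, n_sib))
        sib_pos = rng.random(n_sib) < config.marker_prevalence_background
        sib_tested = rng.random(n_sib) >= config.marker_untested_fraction
        sib_marker = np.where(sib_tested, np.where(sib_pos, "yes", "no"), "untested")
        groups = np.arange(n_sib)
        sibling[idx] = groups
        xy = np.vstack([xy, sib_xy])
        days = np.concatenate([days, sib_days])
        diag_days = np.concatenate([diag_days, sib_diag])
        marker = np.concatenate([marker, sib_marker])
        truth = np.concatenate([truth, np.full(n_sib, -1)])
        sibling = np.concatenate([sibling, groups])
        n_total += n_sib

    # covariates
    sex = np.where(rng.random(n_total) < 0.515, "male", "female")
    age_years = (diag_days - days) / 365.25
    age_group = pd.cut(age_years, [-0.01, 1, 6, 11, 16],
                       labels=["0", "1-5", "6-10", "11-15"], right=False).astype(str)
    mid_day = 0.5 * (w0 + w1)
    thr = urban_threshold(model, mid_day)
    urban = urban_flag(xy[:, 0], xy[:, 1], model, mid_day, thr)
    sources = _point_sources(config)
    band = point_source_band(xy[:, 0], xy[:, 1], sources)

    df = pd.DataFrame(
        {
            "case_id": np.arange(1, n_total + 1),
            "x_birth": xy[:, 0],
            "y_birth": xy[:, 1],
            "birth_date": pd.to_datetime(
                days.astype(np.int64).astype("datetime64[D]")).astype("datetime64[ns]"),
            "diagnosis_date": pd.to_datetime(
                diag_days.astype(np.int64).astype("datetime64[D]")).astype("datetime64[ns]"),
            "marker_positive": marker,
            "sex": sex,
            "age_group": age_group,
            "urban": urban,
            "dist_point_source": band,
            "sibling_group": pd.array(np.where(sibling >= 0, sibling, pd.NA), dtype="Int64"),
            "truth_cluster_id": pd.array(np.where(truth >= 0, truth, pd.NA), dtype="Int64"),
        }
    )
    df.attrs["point_sources"] = sources.tolist()
    df.attrs["urban_threshold"] = thr
    df.attrs["urban_eval_day"] = mid_day
    return df
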