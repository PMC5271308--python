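"""Time-interpolated spatial intensity of the child population.

The residential child population is represented by census-style snapshots:
counts of children in square grid cells observed at a handful of census dates.
Between snapshots, per-cell counts are interpolated linearly in time; before
the first and after the last snapshot the nearest snapshot applies.  This
surface is the sampling distribution of the Monte-Carlo null: under the null
hypothesis of no space-time interaction, a case's birth location is
exchangeable with a draw from the child population alive at its birth date,
so uneven regional population growth cannot mimic clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "PopulationSnapshot",
    "PopulationModel",
    "LocationResampler",
    "to_days",
]


def to_days(dates) -> np.ndarray:
    """Convert date-likes (strings, datetimes, arrays) to float days since 1970-01-01."""
    scalar = np.isscalar(dates) or isinstance(dates, (pd.Timestamp, np.datetime64))
    idx = pd.DatetimeIndex(pd.to_datetime(np.atleast_1d(np.asarray(dates, dtype=object))))
    days = idx.values.astype("datetime64[D]").astype(np.int64).astype(float)
    return float(days[0]) if scalar else days


@dataclass(frozen=True)
class PopulationSnapshot:
    """Child counts per grid cell at one census date.

    ``cells`` has columns ``x``, ``y`` (cell-center coordinates in meters on a
    projected planar grid) and ``child_count`` (nonnegative). ``cell_size_m``
    is the side length of the square cells.
    """

    date: pd.Timestamp
    cells: pd.DataFrame = field(repr=False)
    cell_size_m: float = 1000.0

    def __post_init__(self):
        missing = {"x", "y", "child_count"} - set(self.cells.columns)
        if missing:
            raise ValueError(f"snapshot cells missing columns: {sorted(missing)}")
        if (self.cells["child_count"] < 0).any():
            raise ValueError("child counts must be nonnegative")


class PopulationModel:
    """Piecewise-linear-in-time population intensity built from snapshots.

    All snapshots must share one cell layout. The model exposes the two
    primitives the analysis needs: evaluating interpolated cell weights at a
    date, and resampling locations for cases conditional on their (fixed)
    birth dates — cell chosen proportional to the interpolated intensity,
    location uniform within the cell.
    """

    def __init__(self, snapshots: list[PopulationSnapshot]):
        if not snapshots:
            raise ValueError("at least one population snapshot is required")
        snaps = sorted(snapshots, key=lambda s: s.date)
        ref = snaps[0].cells[["x", "y"]].to_numpy(float)
        for s in snaps[1:]:
            if not np.array_equal(s.cells[["x", "y"]].to_numpy(float), ref):
                raise ValueError("all snapshots must share an identical cell layout")
            if s.cell_size_m != snaps[0].cell_size_m:
                raise ValueError("all snapshots must share one cell size")
        self.snapshots = snaps
        self.cell_xy = ref
        self.cell_size_m = float(snaps[0].cell_size_m)
        self.dates_days = np.array([to_days(s.date) for s in snaps])
        if len(np.unique(self.dates_days)) != len(snaps):
            raise ValueError("snapshot dates must be distinct")
        self.counts = np.vstack([s.cells["child_count"].to_numpy(float) for s in snaps])
        self.totals = self.counts.sum(axis=1)
        # per-snapshot CDF over cells, for inverse-transform cell sampling;
        # an all-empty snapshot only errors if a birth date actually needs it
        safe = np.where(self.totals > 0, self.totals, 1.0)
        self._cdfs = np.cumsum(self.counts, axis=1) / safe[:, None]
        self._tree = cKDTree(self.cell_xy)

    # -- time interpolation -------------------------------------------------

    def bracket(self, days):
        """Return (k0, k1, alpha): interpolate between snapshots k0 and k1 with
        weight ``alpha`` on k1. Dates outside the snapshot range clamp to the
        nearest snapshot (alpha = 0)."""
        days = np.atleast_1d(np.asarray(days, dtype=float))
        hi = np.searchsorted(self.dates_days, days, side="right")
        k0 = np.clip(hi - 1, 0, len(self.dates_days) - 1)
        k1 = np.clip(hi, 0, len(self.dates_days) - 1)
        denom = self.dates_days[k1] - self.dates_days[k0]
        with np.errstate(invalid="ignore"):
            alpha = np.where(denom > 0, (days - self.dates_days[k0]) / np.maximum(denom, 1), 0.0)
        return k0, k1, np.clip(alpha, 0.0, 1.0)

    def weights_at(self, day: float) -> np.ndarray:
        """Interpolated per-cell child counts at one date (float days)."""
        k0, k1, a = self.bracket([day])
        return (1.0 - a[0]) * self.counts[k0[0]] + a[0] * self.counts[k1[0]]

    def totals_at(self, days) -> np.ndarray:
        k0, k1, a = self.bracket(days)
        return (1.0 - a) * self.totals[k0] + a * self.totals[k1]

    def density_at(self, x, y, day: float) -> np.ndarray:
        """Children per square meter in the cell containing each point, at ``day``."""
        pts = np.column_stack([np.atleast_1d(x), np.atleast_1d(y)])
        _, cell = self._tree.query(pts, p=np.inf)
        w = self.weights_at(day)
        return w[cell] / self.cell_size_m**2

    # -- sampling -----------------------------------------------------------

    def sample_locations(self, days, rng: np.random.Generator) -> np.ndarray:
        """Draw one location per entry of ``days`` from the interpolated intensity."""
        return LocationResampler(self, days).sample(rng)

    @property
    def bounds(self):
        half = self.cell_size_m / 2.0
        (xmin, ymin), (xmax, ymax) = self.cell_xy.min(0), self.cell_xy.max(0)
        return (xmin - half, xmax + half, ymin - half, ymax + half)

    # -- (de)serialization helpers ------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for s in self.snapshots:
            f = s.cells[["x", "y", "child_count"]].copy()
            f.insert(0, "snapshot_date", pd.Timestamp(s.date))
            f["cell_size_m"] = s.cell_size_m
            frames.append(f)
        return pd.concat(frames, ignore_index=True)


class LocationResampler:
    """Fast repeated resampling of case locations at fixed birth dates.

    The linear interpolation ``(1-a)·W_k0 + a·W_k1`` of two cell-count vectors
    is a two-component mixture, so a draw is taken by first choosing one of
    the two bracketing snapshots with probability proportional to
    ``(1-a)·total_k0`` vs ``a·total_k1`` and then inverse-CDF sampling a cell
    from that snapshot; the location is uniform within the chosen cell. This
    is numerically identical to sampling from the interpolated weights and
    lets the per-snapshot CDFs be reused across Monte-Carlo replicates.
    """

    def __init__(self, model: PopulationModel, days):
        self.model = model
        days = np.asarray(days, dtype=float)
        self.n = len(days)
        k0, k1, a = model.bracket(days)
        w0 = (1.0 - a) * model.totals[k0]
        w1 = a * model.totals[k1]
        tot = w0 + w1
        if (tot <= 0).any():
            bad = days[tot <= 0][0]
            raise ValueError(
                f"total population intensity is zero at birth date {bad:.0f} (days since epoch)"
            )
        self._k0, self._k1 = k0, k1
        self._p1 = w1 / tot

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        m = self.model
        snap = np.where(rng.random(self.n) < self._p1, self._k1, self._k0)
        u = rng.random(self.n)
        cell = np.empty(self.n, dtype=np.intp)
        for k in np.unique(snap):
            mask = snap == k
            cell[mask] = np.searchsorted(m._cdfs[k], u[mask], side="left")
        jitter = rng.uniform(-0.5, 0.5, size=(self.n, 2)) * m.cell_size_m
        return m.cell_xy[cell] + jitter
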