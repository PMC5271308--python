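"""Clustered-vs-nonclustered case comparison.

Implements the case-case analysis: 2×2 odds ratios with Wald confidence
intervals, unadjusted and density-adjusted logistic regressions with
likelihood-ratio tests, Monte-Carlo p-values for geographically determined
covariates (where ordinary regression inference is invalid because the
clustered label induces dependence between cases), and Holm step-down
correction across the tested characteristics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .cluster import classify_clustered
from .population import PopulationModel, LocationResampler
from .knox import _case_arrays

__all__ = [
    "OddsRatio",
    "CharacteristicResult",
    "HolmResult",
    "ClusteredComparison",
    "or_2x2",
    "fit_clustering_model",
    "mc_covariate_pvalue",
    "holm_adjust",
]

MISSING_TOKENS = ("untested", "unknown", "")
Z95 = 1.959963984540054


@dataclass(frozen=True)
class OddsRatio:
    oddsratio: float
    ci_low: float
    ci_high: float
    corrected: bool = False  # 0.5 continuity correction applied


def or_2x2(a: int, b: int, c: int, d: int) -> OddsRatio:
    """Odds ratio (a·d)/(b·c) with a Wald 95% CI from a 2×2 table.

    a = exposed clustered, b = unexposed clustered, c = exposed nonclustered,
    d = unexposed nonclustered. A zero cell triggers the 0.5 continuity
    correction on all cells (flagged and warned).
    """
    cells = np.array([a, b, c, d], dtype=float)
    if (cells < 0).any():
        raise ValueError("cell counts must be nonnegative")
    corrected = bool((cells == 0).any())
    if corrected:
        warnings.warn("zero cell in 2x2 table; applying 0.5 continuity correction",
                      stacklevel=2)
        cells = cells + 0.5
    a_, b_, c_, d_ = cells
    log_or = np.log(a_ * d_ / (b_ * c_))
    se = np.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    return OddsRatio(
        oddsratio=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - Z95 * se)),
        ci_high=float(np.exp(log_or + Z95 * se)),
        corrected=corrected,
    )


@dataclass
class CharacteristicResult:
    """Per-characteristic regression result: one row per non-reference level
    plus a characteristic-level likelihood-ratio p-value."""

    characteristic: str
    table: pd.DataFrame  # level, n_clustered, N_clustered, n_nonclustered, ...
    p_value: float
    p_source: str = "lrt"
    df: int = 1
    separation_flagged: bool = False


def _clustered_array(labeling) -> np.ndarray:
    if hasattr(labeling, "clustered"):
        return np.asarray(labeling.clustered, dtype=bool)
    return np.asarray(labeling, dtype=bool)


def _density_array(density):
    if density is None:
        return None
    if hasattr(density, "index_"):
        return np.asarray(density.index_, dtype=float)
    return np.asarray(density, dtype=float)


def _prepare(cases, characteristic, reference):
    col = cases[characteristic]
    vals = col.astype(object).where(~col.isna(), np.nan)
    vals = vals.replace({tok: np.nan for tok in MISSING_TOKENS})
    keep = vals.notna().to_numpy()
    levels = pd.unique(vals[keep]).tolist()
    if len(levels) < 2:
        raise ValueError(
            f"characteristic {characteristic!r} needs >=2 observed levels, got {levels}"
        )
    if reference is None:
        reference = sorted(map(str, levels))[0]
    if reference not in set(map(str, levels)):
        raise ValueError(f"reference level {reference!r} not observed for {characteristic!r}")
    ordered = [reference] + sorted(str(v) for v in levels if str(v) != reference)
    cat = pd.Categorical(vals[keep].astype(str), categories=ordered)
    return keep, cat, ordered


def _logit_fit(y, x_mat):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter from near-separated fits
        warnings.simplefilter("error", PerfectSeparationWarning)
        model = sm.Logit(y, x_mat)
        return model.fit(disp=0, maxiter=200)


def fit_clustering_model(cases: pd.DataFrame, labeling, characteristic: str,
                         density=None, reference=None) -> CharacteristicResult:
    """Logistic regression of clustered status on one categorical
    characteristic, optionally adjusted for the child-density index.

    Cases with a missing value for the characteristic are excluded listwise,
    which is what makes the denominators vary between characteristics. Per
    non-reference level the table reports counts among clustered and
    nonclustered cases, the OR with Wald 95% CI; the characteristic-level
    p-value is a likelihood-ratio test against the nested model (intercept,
    plus the density term when adjusting).
    """
    y_all = _clustered_array(labeling).astype(float)
    dens_all = _density_array(density)
    keep, cat, ordered = _prepare(cases, characteristic, reference)
    y = y_all[keep]
    dummies = pd.get_dummies(cat, drop_first=True).to_numpy(float)
    x_parts = [np.ones((len(y), 1)), dummies]
    x0_parts = [np.ones((len(y), 1))]
    if dens_all is not None:
        dcol = dens_all[keep][:, None]
        x_parts.append(dcol)
        x0_parts.append(dcol)
    x_full = np.hstack(x_parts)
    x_null = np.hstack(x0_parts)

    separation = False
    try:
        fit_full = _logit_fit(y, x_full)
        fit_null = _logit_fit(y, x_null)
        lrt = 2.0 * (fit_full.llf - fit_null.llf)
        df = dummies.shape[1]
        p = float(stats.chi2.sf(max(lrt, 0.0), df))
        params = fit_full.params[1:1 + df]
        ses = fit_full.bse[1:1 + df]
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        separation = True
        df = dummies.shape[1]
        p = float("nan")
        params = np.full(df, np.nan)
        ses = np.full(df, np.nan)
        warnings.warn(
            f"perfect separation fitting {characteristic!r}; "
            "consider a Monte-Carlo p-value (mc_covariate_pvalue)",
            stacklevel=2,
        )

    n_clu, n_non = int(y.sum()), int((1 - y).sum())
    rows = []
    codes = np.asarray(cat.codes)
    for k, level in enumerate(ordered):
        in_level = codes == k
        a = int((in_level & (y == 1)).sum())
        c = int((in_level & (y == 0)).sum())
        if k == 0:
            rows.append(dict(level=level, n_clustered=a, N_clustered=n_clu,
                             n_nonclustered=c, N_nonclustered=n_non,
                             oddsratio=1.0, ci_low=np.nan, ci_high=np.nan,
                             reference=True))
        else:
            beta, se = params[k - 1], ses[k - 1]
            rows.append(dict(level=level, n_clustered=a, N_clustered=n_clu,
                             n_nonclustered=c, N_nonclustered=n_non,
                             oddsratio=float(np.exp(beta)),
                             ci_low=float(np.exp(beta - Z95 * se)),
                             ci_high=float(np.exp(beta + Z95 * se)),
                             reference=False))
    table = pd.DataFrame(rows)
    table["pct_clustered"] = 100.0 * table["n_clustered"] / max(n_clu, 1)
    table["pct_nonclustered"] = 100.0 * table["n_nonclustered"] / max(n_non, 1)
    return CharacteristicResult(characteristic=characteristic, table=table,
                                p_value=p, p_source="lrt", df=df,
                                separation_flagged=separation)


def _lrt_stat(y, cat_values) -> float:
    """LRT statistic of clustered ~ covariate vs intercept-only (the test
    statistic whose null distribution the MC chain simulates)."""
    cat = pd.Categorical(cat_values)
    dummies = pd.get_dummies(cat, drop_first=True).to_numpy(float)
    if dummies.shape[1] == 0:
        return 0.0
    x_full = np.hstack([np.ones((len(y), 1)), dummies])
    x_null = np.ones((len(y), 1))
    try:
        f1 = _logit_fit(y, x_full)
        f0 = _logit_fit(y, x_null)
        return float(max(2.0 * (f1.llf - f0.llf), 0.0))
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        return float("inf")


def mc_covariate_pvalue(cases: pd.DataFrame, population, covariate_fn,
                        spatial_lag_m: float, temporal_lag_days: float,
                        n_replicates: int = 999, random_state=None) -> float:
    """Monte-Carlo p-value for a geographically determined covariate.

    ``covariate_fn(x, y) -> array of category labels`` must derive the
    covariate from birth coordinates alone (e.g. distance band to a point
    source).  Each replicate re-runs the full chain: resample locations from
    the population-shift null, re-classify clustered status at the critical
    lags, recompute the covariate from the new locations, and refit the
    logistic model; the p-value is the add-one tail probability of the
    observed likelihood-ratio statistic.
    """
    if not callable(covariate_fn):
        raise ValueError("covariate_fn must be a callable deriving the covariate "
                         "from birth coordinates")
    B = int(n_replicates)
    if B < 99:
        raise ValueError("n_replicates must be >= 99")
    model = (population if isinstance(population, PopulationModel)
             else PopulationModel(population))
    rng = np.random.default_rng(random_state)
    x, y_coord, days = _case_arrays(cases)

    y_obs = classify_clustered(cases, spatial_lag_m, temporal_lag_days).astype(float)
    stat_obs = _lrt_stat(y_obs, covariate_fn(x, y_coord))

    sampler = LocationResampler(model, days)
    rep = cases.copy()
    count_ge = 0
    for _ in range(B):
        xy = sampler.sample(rng)
        rep["x_birth"], rep["y_birth"] = xy[:, 0], xy[:, 1]
        y_b = classify_clustered(rep, spatial_lag_m, temporal_lag_days).astype(float)
        stat_b = _lrt_stat(y_b, covariate_fn(xy[:, 0], xy[:, 1]))
        if stat_b >= stat_obs:
            count_ge += 1
    return (1.0 + count_ge) / (B + 1.0)


@dataclass
class HolmResult:
    labels: list
    raw: np.ndarray
    adjusted: np.ndarray
    reject: np.ndarray
    alpha: float


def holm_adjust(pvalues, labels=None, alpha: float = 0.05) -> HolmResult:
    """Holm step-down familywise correction.

    Sorted ascending, the i-th smallest p is multiplied by (m − i + 1), a
    running maximum enforces monotonicity, and values are capped at 1.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    if labels is None:
        labels = [f"p{i}" for i in range(len(p))]
    reject, adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    return HolmResult(labels=list(labels), raw=p, adjusted=adj, reject=reject, alpha=alpha)


class ClusteredComparison(BaseEstimator):
    """Full clustered-vs-nonclustered comparison table.

    Parameters
    ----------
    characteristics : sequence of str or dict
        Columns of the case table to compare. A dict maps each name to
        options, currently ``{"reference": level}``.
    alpha : float
        Familywise level for the Holm correction.
    holm_on : "adjusted" | "unadjusted"
        Which per-characteristic p-values enter the Holm family (the
        density-adjusted ones by default, falling back to unadjusted when no
        density index is supplied).

    After ``fit(cases, labeling, density=None)``: ``table_`` mirrors the
    published layout (counts, unadjusted OR/CI/p, density-adjusted OR/CI/p
    per level) and ``holm_`` holds the step-down-corrected family.
    """

    def __init__(self, characteristics, alpha=0.05, holm_on="adjusted"):
        self.characteristics = characteristics
        self.alpha = alpha
        self.holm_on = holm_on

    def _char_options(self):
        if isinstance(self.characteristics, dict):
            return {k: (v or {}) for k, v in self.characteristics.items()}
        return {name: {} for name in self.characteristics}

    def fit(self, cases: pd.DataFrame, labeling, density=None):
        charopts = self._char_options()
        dens = _density_array(density)
        rows = []
        family_p, family_labels = [], []
        self.results_ = {}
        for name, opts in charopts.items():
            ref = opts.get("reference")
            unadj = fit_clustering_model(cases, labeling, name, density=None, reference=ref)
            adj = (fit_clustering_model(cases, labeling, name, density=dens, reference=ref)
                   if dens is not None else None)
            self.results_[name] = (unadj, adj)
            for k in range(len(unadj.table)):
                row = {"characteristic": name, **unadj.table.iloc[k].to_dict()}
                row["p_unadj"] = unadj.p_value if k == 0 else np.nan
                if adj is not None:
                    row["or_adj"] = adj.table.iloc[k]["oddsratio"]
                    row["ci_low_adj"] = adj.table.iloc[k]["ci_low"]
                    row["ci_high_adj"] = adj.table.iloc[k]["ci_high"]
                    row["p_adj"] = adj.p_value if k == 0 else np.nan
                rows.append(row)
            use = adj if (adj is not None and self.holm_on == "adjusted") else unadj
            if np.isfinite(use.p_value):
                family_p.append(use.p_value)
                family_labels.append(name)
        self.table_ = pd.DataFrame(rows).rename(
            columns={"oddsratio": "or_unadj", "ci_low": "ci_low_unadj",
                     "ci_high": "ci_high_unadj"}
        )
        self.holm_ = holm_adjust(family_p, labels=family_labels, alpha=self.alpha)
        holm_map = dict(zip(self.holm_.labels, self.holm_.adjusted))
        # characteristic-level p-values sit on the first (reference) row
        self.table_["p_holm"] = [
            holm_map.get(ch, np.nan) if is_first else np.nan
            for ch, is_first in zip(self.table_["characteristic"],
                                    ~self.table_["characteristic"].duplicated())
        ]
        return self
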