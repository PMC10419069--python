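"""Nonparametric cohort statistics.

The comparison workflow mirrors common histology-cohort practice:

* paired Wilcoxon signed-rank tests check for left/right hemisphere
  differences (zeros dropped before ranking, exact null for small n);
* hemispheres are then averaged per mouse (bilateral measures);
* sonicated vs non-sonicated groups are compared per region with two-sided
  Mann–Whitney tests — exact by complete enumeration of all
  C(n1+n2, n1) group labelings when n1+n2 ≤ 16 (mid-rank ties handled by
  permuting the observed values), normal approximation with tie correction
  otherwise;
* for display, values are normalized so the control-group mean is exactly
  100%;
* a two-sided Grubbs test flags at most one outlier per invocation, and
  every exclusion is recorded, never silent;
* p-values map to stars as *: p<0.05, **: p<0.01, ***: p<0.005,
  ****: p<0.0005 (note the 0.005/0.0005 tiers), 'ns' otherwise.

No multiple-testing correction is applied by default (per-region p-values
are reported uncorrected); ``holm_adjust`` is available when one is wanted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "METRICS",
    "PairedTestResult",
    "ComparisonResult",
    "OutlierReport",
    "validate_measure_table",
    "hemisphere_test",
    "bilateral_average",
    "mannwhitney",
    "group_compare",
    "normalize_to_control",
    "detect_outlier",
    "stars",
    "rank_correlation",
    "holm_adjust",
]

METRICS = ("AT8_hscore", "Iba1_load", "Iba1_density", "GFAP_load")

_TABLE_COLUMNS = (
    "mouse_id",
    "genotype",
    "group",
    "delay_days",
    "region",
    "hemisphere",
    "metric",
    "value",
)


def validate_measure_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the per-mouse per-region measure table contract."""
    missing = [c for c in _TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"measure table missing columns {missing}")
    if not np.isfinite(table["value"].to_numpy(dtype=float)).all():
        raise ValueError("measure table contains non-finite values")
    bad = set(table["metric"]) - set(METRICS) - {
        m for m in set(table["metric"]) if str(m).startswith("class_fraction:")
    }
    if bad:
        raise ValueError(f"unknown metrics {sorted(bad)}")
    dup = table.duplicated(subset=["mouse_id", "region", "hemisphere", "metric"])
    if dup.any():
        raise ValueError("duplicate (mouse, region, hemisphere, metric) rows")
    return table


# ---------------------------------------------------------------------------
# Paired hemisphere test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedTestResult:
    statistic: float  # W+ = sum of ranks of positive (left-right) differences
    p: float
    n_pairs: int
    underpowered: bool
    dropped_mice: tuple[str, ...] = ()


def _signed_rank_exact(diffs: np.ndarray) -> tuple[float, float]:
    """Exact two-sided signed-rank p by 2^n sign enumeration (midranks)."""
    absd = np.abs(diffs)
    ranks = sps.rankdata(absd)
    w_obs = float(ranks[diffs > 0].sum())
    n = len(diffs)
    signs = np.array(
        np.meshgrid(*([[0, 1]] * n), indexing="ij")
    ).reshape(n, -1).T.astype(bool)
    w_all = (signs * ranks).sum(axis=1)
    p_le = float((w_all <= w_obs + 1e-12).mean())
    p_ge = float((w_all >= w_obs - 1e-12).mean())
    return w_obs, min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(
    left: Sequence[float], right: Sequence[float]
) -> tuple[float, float, int]:
    """Paired signed-rank test on (left − right); returns (W+, p, n used).

    Zero differences are dropped before ranking.  Exact null for n ≤ 25
    without ties (scipy), own 2ⁿ midrank enumeration for tied n ≤ 16,
    normal approximation otherwise.  All differences zero → p = 1 with a
    warning (degenerate case).
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape:
        raise ValueError("paired samples must have equal length")
    diffs = left - right
    diffs = diffs[diffs != 0]
    n = len(diffs)
    if n == 0:
        warnings.warn("all paired differences are zero; returning p = 1")
        return 0.0, 1.0, 0
    # report W+ (sum of positive-difference ranks) regardless of method;
    # scipy's two-sided statistic is min(W+, W-)
    w_plus = float(sps.rankdata(np.abs(diffs))[diffs > 0].sum())
    has_ties = len(np.unique(np.abs(diffs))) < n
    if not has_ties and n <= 25:
        res = sps.wilcoxon(diffs, alternative="two-sided", method="exact")
        return w_plus, float(res.pvalue), n
    if has_ties and n <= 16:
        _, p = _signed_rank_exact(diffs)
        return w_plus, p, n
    res = sps.wilcoxon(diffs, alternative="two-sided", method="approx", correction=True)
    return w_plus, float(res.pvalue), n


def hemisphere_test(
    table: pd.DataFrame, metric: str, region: str
) -> PairedTestResult:
    """Left vs right paired test for one metric in one region.

    Mice with a missing hemisphere are dropped (and reported); fewer than 3
    usable pairs flags the result as underpowered but p is still computed.
    """
    sub = table[(table.metric == metric) & (table.region == region)]
    wide = sub.pivot_table(index="mouse_id", columns="hemisphere", values="value")
    dropped = tuple(
        sorted(wide.index[wide.get("left", pd.Series(dtype=float)).isna() | wide.get("right", pd.Series(dtype=float)).isna()])
    ) if not wide.empty else ()
    if dropped:
        warnings.warn(f"dropping mice with a missing hemisphere: {list(dropped)}")
    usable = wide.dropna(subset=[c for c in ("left", "right") if c in wide.columns])
    if "left" not in wide.columns or "right" not in wide.columns or usable.empty:
        raise ValueError(f"no usable left/right pairs for {metric} in {region}")
    w, p, n = wilcoxon_signed_rank(usable["left"].to_numpy(), usable["right"].to_numpy())
    return PairedTestResult(w, p, len(usable), underpowered=len(usable) < 3, dropped_mice=dropped)


def bilateral_average(table: pd.DataFrame) -> pd.DataFrame:
    """Average hemispheres per (mouse, region, metric); idempotent.

    The returned table has hemisphere = 'both' and an ``n_sides`` provenance
    column (1 or 2 hemispheres contributed).  Single-side mice pass through.
    """
    if (table["hemisphere"] == "both").all():
        return table.copy()  # already averaged: fixpoint
    keys = ["mouse_id", "genotype", "group", "delay_days", "region", "metric"]
    grouped = table.groupby(keys, as_index=False, sort=False).agg(
        value=("value", "mean"),
        n_sides=("hemisphere", "nunique"),
    )
    grouped["hemisphere"] = "both"
    return grouped[keys[:5] + ["hemisphere", "metric", "value", "n_sides"]]


# ---------------------------------------------------------------------------
# Two-group comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparisonResult:
    n_treated: int
    n_control: int
    U: float
    p: float
    control_mean: float
    normalized_means: dict[str, float]
    percent_change: float
    stars: str
    method: str


def _u_statistic(ranks: np.ndarray, idx: np.ndarray, n1: int) -> np.ndarray:
    return ranks[idx].sum(axis=-1) - n1 * (n1 + 1) / 2.0


def mannwhitney(
    treated: Sequence[float], control: Sequence[float], exact_max_n: int = 16
) -> tuple[float, float, str]:
    """Two-sided Mann–Whitney U (treated vs control); returns (U, p, method).

    Exact p by complete enumeration of all C(n1+n2, n1) labelings of the
    pooled mid-ranks when n1+n2 ≤ exact_max_n; otherwise the normal
    approximation with tie correction and continuity correction.
    """
    x = np.asarray(treated, dtype=float)
    y = np.asarray(control, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    if n1 + n2 <= exact_max_n:
        idx = np.array(list(combinations(range(n1 + n2), n1)))
        u_all = _u_statistic(ranks, idx, n1)
        p_le = float((u_all <= u_obs + 1e-12).mean())
        p_ge = float((u_all >= u_obs - 1e-12).mean())
        return u_obs, min(1.0, 2.0 * min(p_le, p_ge)), "exact"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u_obs, float(res.pvalue), "asymptotic"


def group_compare(
    treated: Sequence[float],
    control: Sequence[float],
    group_labels: tuple[str, str] = ("treated", "control"),
    exact_max_n: int = 16,
) -> ComparisonResult:
    """Mann–Whitney comparison with control-normalized percent change.

    percent_change = 100·(mean_treated − mean_control)/mean_control;
    normalized means are percent of the control mean (control = 100 exactly).
    """
    x = np.asarray(treated, dtype=float)
    y = np.asarray(control, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    u, p, method = mannwhitney(x, y, exact_max_n)
    mc = float(y.mean())
    if mc == 0:
        raise ValueError("control mean is zero; normalization undefined")
    mt = float(x.mean())
    return ComparisonResult(
        n_treated=len(x),
        n_control=len(y),
        U=u,
        p=p,
        control_mean=mc,
        normalized_means={
            group_labels[0]: 100.0 * mt / mc,
            group_labels[1]: 100.0,
        },
        percent_change=100.0 * (mt - mc) / mc,
        stars=stars(p),
        method=method,
    )


def normalize_to_control(
    values_by_group: dict[str, Sequence[float]], control_label: str
) -> dict[str, np.ndarray]:
    """Express every value as percent of the control-group mean (control mean → 100)."""
    if control_label not in values_by_group:
        raise ValueError(f"control group {control_label!r} not present")
    control = np.asarray(values_by_group[control_label], dtype=float)
    if control.size == 0:
        raise ValueError("control group is empty")
    mc = control.mean()
    if mc == 0:
        raise ValueError("control mean is zero; normalization undefined")
    return {
        g: np.asarray(v, dtype=float) * 100.0 / mc for g, v in values_by_group.items()
    }


# ---------------------------------------------------------------------------
# Outliers, stars, utilities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OutlierReport:
    tested_group: str
    flagged: tuple[str, ...]
    statistic: float
    critical: float
    alpha: float


def detect_outlier(
    values: Sequence[float],
    alpha: float = 0.05,
    ids: Sequence[str] | None = None,
    group: str = "",
) -> OutlierReport:
    """Two-sided Grubbs test; flags at most the single most extreme value.

    G = max|x − mean| / sd against the Grubbs critical value at ``alpha``.
    Needs n ≥ 3; constant values yield no flag with a warning.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("Grubbs test needs at least 3 values")
    ids = tuple(ids) if ids is not None else tuple(str(i) for i in range(n))
    if len(ids) != n:
        raise ValueError("ids length must match values")
    sd = x.std(ddof=1)
    if sd == 0:
        warnings.warn("zero variance; no outlier flagged")
        return OutlierReport(group, (), 0.0, np.inf, alpha)
    dev = np.abs(x - x.mean())
    g = float(dev.max() / sd)
    t = sps.t.ppf(1 - alpha / (2 * n), n - 2)
    crit = float((n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t)))
    flagged = (ids[int(np.argmax(dev))],) if g > crit else ()
    return OutlierReport(group, flagged, g, crit, alpha)


def stars(p: float) -> str:
    """Significance label: * <0.05, ** <0.01, *** <0.005, **** <0.0005, else ns."""
    if not (0 < p <= 1):
        raise ValueError("p must lie in (0, 1]")
    if p < 0.0005:
        return "****"
    if p < 0.005:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def rank_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Plain Spearman rank correlation (rho, p)."""
    res = sps.spearmanr(np.asarray(x, float), np.asarray(y, float))
    return float(res.statistic), float(res.pvalue)


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; off by default upstream)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    adj = np.empty_like(p)
    running = 0.0
    m = len(p)
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj
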