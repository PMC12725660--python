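"""Group statistics for fitted clamp parameters.

The comparison workflow mirrors common practice in mouse metabolic
phenotyping: per-group interquartile-range outlier exclusion, pairwise
two-sided Welch's t tests with Benjamini-Hochberg adjustment within each
parameter's family, Williams' step-down trend test against the control for
parameters hypothesized to change monotonically with age/diet duration, and
Spearman rank correlations.

Williams' test uses the classical amalgamated (isotonic) mean statistic

    t_k = (max_{u<=k} sum_{j=u..k} n_j ybar_j / sum_{j=u..k} n_j - ybar_0)
          / sqrt(s^2 (1/n_k + 1/n_0))

with the pooled within-group variance s^2 over all groups including the
control. Critical values are obtained by seeded Monte-Carlo simulation of
the null (all groups one normal distribution) at the observed group sizes,
which is exact up to simulation error for any design, rather than by the
published unequal-n table approximations. Testing proceeds step-down from
the highest group and stops at the first non-rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "iqr_exclude",
    "welch_bh",
    "williams_trend",
    "spearman",
    "run_group_comparison",
    "GroupComparisonReport",
    "stars",
]

STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def stars(p: float) -> str:
    """Significance stars at the conventional four thresholds."""
    for thr, s in STAR_THRESHOLDS:
        if p < thr:
            return s
    return ""


def iqr_exclude(values) -> tuple[np.ndarray, np.ndarray]:
    """Split values into (kept, excluded) by the 1.5*IQR fence rule.

    Quartiles use linear interpolation of order statistics; values strictly
    outside [Q1 - 1.5*IQR, Q3 + 1.5*IQR] are excluded. With fewer than 4
    finite values the data are returned unfiltered with a warning.
    """
    import warnings

    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 4:
        warnings.warn(
            f"only {v.size} finite values; outlier rule needs >= 4, returning all",
            stacklevel=2,
        )
        return v, np.empty(0)
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    keep = (v >= lo) & (v <= hi)
    return v[keep], v[~keep]


def welch_bh(groups: dict[str, np.ndarray], pairs=None) -> pd.DataFrame:
    """Pairwise two-sided Welch's t tests with BH adjustment over the family.

    ``pairs`` defaults to all pairwise combinations in the given order. Two
    identical (or both-degenerate equal-mean) samples get p = 1 by
    convention. Returns a tidy frame with t, Satterthwaite df, raw and
    adjusted p, and star annotations.
    """
    labels = list(groups)
    for lab in labels:
        if np.asarray(groups[lab]).size < 2:
            raise ValueError(f"group {lab!r} needs >= 2 values")
    if pairs is None:
        pairs = list(combinations(labels, 2))
    rows = []
    for a, b in pairs:
        x, y = np.asarray(groups[a], float), np.asarray(groups[b], float)
        if np.var(x) == 0 and np.var(y) == 0:
            t, p = (0.0, 1.0) if np.mean(x) == np.mean(y) else (np.inf, 0.0)
            df = float(x.size + y.size - 2)
        else:
            res = sps.ttest_ind(x, y, equal_var=False)
            t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
        rows.append({"group_a": a, "group_b": b, "t": t, "df": df, "p_raw": p})
    out = pd.DataFrame(rows)
    out["p_bh"] = multipletests(out["p_raw"], method="fdr_bh")[1]
    out["stars"] = out["p_bh"].map(stars)
    return out


# ---------------------------------------------------------------------------
# Williams' trend test

_NULL_CACHE: dict[tuple, np.ndarray] = {}


def _williams_stats(
    means: np.ndarray, ns: np.ndarray, control_mean: float, n0: int, s2: float
) -> np.ndarray:
    """Amalgamated-mean statistics t_k for every group k (increasing case)."""
    K = means.size
    out = np.empty(K)
    for k in range(K):
        best = -np.inf
        wsum = 0.0
        msum = 0.0
        for u in range(k, -1, -1):  # suffix means ending at k
            wsum += ns[u]
            msum += ns[u] * means[u]
            best = max(best, msum / wsum)
        diff = best - control_mean
        denom = np.sqrt(s2 * (1.0 / ns[k] + 1.0 / n0))
        if denom == 0.0:
            out[k] = 0.0 if diff == 0.0 else np.sign(diff) * np.inf
        else:
            out[k] = diff / denom
    return out


def _null_distribution(
    sizes: tuple[int, ...], n_mc: int, seed: int
) -> np.ndarray:
    """Monte-Carlo null sample of (t_1..t_K) under one shared normal."""
    key = (sizes, n_mc, seed)
    if key in _NULL_CACHE:
        return _NULL_CACHE[key]
    rng = np.random.default_rng(seed)
    n0, *rest = sizes
    ns = np.array(rest)
    K = len(rest)
    N = sum(sizes)
    dof = N - (K + 1)
    out = np.empty((n_mc, K))
    block = 2000
    for start in range(0, n_mc, block):
        b = min(block, n_mc - start)
        draws = rng.standard_normal((b, N))
        # group slices: control first
        ofs = np.cumsum((0,) + tuple(sizes))
        gmeans = np.stack(
            [draws[:, ofs[i]:ofs[i + 1]].mean(axis=1) for i in range(K + 1)],
            axis=1,
        )
        gvars = np.stack(
            [draws[:, ofs[i]:ofs[i + 1]].var(axis=1, ddof=1) for i in range(K + 1)],
            axis=1,
        )
        s2 = (gvars * (np.array(sizes) - 1)).sum(axis=1) / dof
        for r in range(b):
            out[start + r] = _williams_stats(
                gmeans[r, 1:], ns, gmeans[r, 0], n0, s2[r]
            )
    _NULL_CACHE[key] = out
    return out


def williams_trend(
    control,
    ordered_groups: list,
    direction: str = "increasing",
    alpha: float = 0.05,
    n_mc: int = 100_000,
    seed: int = 0,
    group_labels=None,
) -> pd.DataFrame:
    """Step-down Williams' trend test of ordered groups against a control.

    ``ordered_groups`` are ordered low-to-high dose (age); testing starts at
    the highest and stops at the first non-rejection, so the rejection set is
    always a contiguous suffix. p-values are upper-tail Monte-Carlo
    probabilities of the per-step statistic under the simulated null.
    """
    if direction not in ("increasing", "decreasing"):
        raise ValueError("direction must be 'increasing' or 'decreasing'")
    ctrl = np.asarray(control, dtype=float)
    grps = [np.asarray(g, dtype=float) for g in ordered_groups]
    if ctrl.size < 2 or any(g.size < 2 for g in grps) or not grps:
        raise ValueError("control and every group need >= 2 values")
    sign = 1.0 if direction == "increasing" else -1.0
    ctrl_s = sign * ctrl
    grps_s = [sign * g for g in grps]

    sizes = (ctrl.size,) + tuple(g.size for g in grps)
    ns = np.array(sizes[1:])
    K = len(grps)
    dof = sum(sizes) - (K + 1)
    allv = [ctrl_s] + grps_s
    s2 = sum((v.size - 1) * np.var(v, ddof=1) for v in allv) / dof
    means = np.array([g.mean() for g in grps_s])
    tstats = _williams_stats(means, ns, ctrl_s.mean(), ctrl.size, s2)

    null = _null_distribution(sizes, n_mc, seed)
    labels = (
        list(group_labels) if group_labels is not None
        else [f"group{k + 1}" for k in range(K)]
    )
    pvals = np.empty(K)
    for k in range(K):
        pvals[k] = (1.0 + np.sum(null[:, k] >= tstats[k])) / (n_mc + 1.0)

    rejected = np.zeros(K, dtype=bool)
    for k in range(K - 1, -1, -1):  # step-down from the highest group
        if pvals[k] < alpha:
            rejected[k] = True
        else:
            break
    return pd.DataFrame(
        {
            "group": labels,
            "direction": direction,
            "tbar": sign * tstats,  # on the original scale's sign convention
            "p_mc": pvals,
            "rejected": rejected,
            "n_mc": n_mc,
            "seed": seed,
        }
    )


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    The p-value uses the exact permutation distribution for n <= 9 and the
    usual t approximation otherwise. Returns (nan, nan) when either vector
    has zero rank variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    if np.var(rx) == 0 or np.var(ry) == 0:
        return float("nan"), float("nan")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if n <= 9:
        from itertools import permutations

        count = 0
        total = 0
        obs = abs(rho)
        for perm in permutations(ry):
            r = np.corrcoef(rx, np.asarray(perm))[0, 1]
            total += 1
            if abs(r) >= obs - 1e-12:
                count += 1
        return rho, count / total
    t = rho * np.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
    p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return rho, min(p, 1.0)


# ---------------------------------------------------------------------------
# full comparison workflow

#: default trend directions for the parameters hypothesized to change
#: monotonically with obesity progression
DEFAULT_TREND_DIRECTIONS = {
    "k2": "decreasing",
    "k3": "increasing",
    "k5": "decreasing",
    "k7": "increasing",
}


@dataclass
class GroupComparisonReport:
    parameter: str
    summaries: pd.DataFrame  # group, n, mean, se, q1, median, q3, n_outliers
    pairwise: pd.DataFrame | None
    trend: pd.DataFrame | None
    outliers: dict[str, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


def run_group_comparison(
    param_table: pd.DataFrame,
    group_order: list[str],
    parameters=None,
    trend_directions: dict[str, str] | None = None,
    alpha: float = 0.05,
    n_mc: int = 100_000,
    seed: int = 0,
    exclude_outliers: bool = True,
) -> dict[str, GroupComparisonReport]:
    """Per-parameter group comparison over a table of fitted parameters.

    ``param_table`` needs a ``group`` column plus one column per parameter;
    ``group_order`` lists groups from control to the highest dose/age. For
    each parameter: outlier exclusion within group, box summaries, pairwise
    Welch+BH (skipped for a single group), and — for parameters listed in
    ``trend_directions`` — Williams' step-down trend versus the first group.
    """
    if trend_directions is None:
        trend_directions = DEFAULT_TREND_DIRECTIONS
    if parameters is None:
        parameters = [
            c for c in param_table.columns
            if c not in ("mouse_id", "group", "body_weight", "rss")
        ]
    missing = set(group_order) - set(param_table["group"])
    if missing:
        raise ValueError(f"groups {sorted(missing)} absent from the table")

    reports = {}
    for pname in parameters:
        groups_kept: dict[str, np.ndarray] = {}
        outliers: dict[str, np.ndarray] = {}
        rows = []
        for lab in group_order:
            vals = param_table.loc[param_table["group"] == lab, pname].to_numpy()
            if exclude_outliers:
                kept, out = iqr_exclude(vals)
            else:
                kept, out = np.asarray(vals, float), np.empty(0)
            groups_kept[lab] = kept
            outliers[lab] = out
            q1, med, q3 = np.percentile(kept, [25, 50, 75])
            rows.append(
                {
                    "group": lab,
                    "n": kept.size,
                    "mean": kept.mean(),
                    "se": kept.std(ddof=1) / np.sqrt(kept.size) if kept.size > 1 else np.nan,
                    "q1": q1,
                    "median": med,
                    "q3": q3,
                    "n_outliers": out.size,
                }
            )
        summaries = pd.DataFrame(rows)
        pairwise = trend = None
        if len(group_order) > 1:
            pairwise = welch_bh(groups_kept)
            pairwise.insert(0, "parameter", pname)
            direction = trend_directions.get(pname)
            if direction is not None:
                trend = williams_trend(
                    groups_kept[group_order[0]],
                    [groups_kept[g] for g in group_order[1:]],
                    direction=direction,
                    alpha=alpha,
                    n_mc=n_mc,
                    seed=seed,
                    group_labels=group_order[1:],
                )
                trend.insert(0, "parameter", pname)
        reports[pname] = GroupComparisonReport(
            parameter=pname,
            summaries=summaries,
            pairwise=pairwise,
            trend=trend,
            outliers=outliers,
            meta={"alpha": alpha, "n_mc": n_mc, "seed": seed,
                  "group_order": list(group_order)},
        )
    return reports
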