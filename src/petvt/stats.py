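"""Group-level inference on regional and voxelwise V_T.

Implements the statistical chain applied to cohort V_T tables: fixed-effects
two-way ANOVA (group x region, Type III sums of squares for the unbalanced
design), Holm-Sidak step-down multiplicity adjustment, pairwise post hoc
group contrasts per region using the pooled ANOVA error term, pooled-variance
two-sample voxelwise t-maps with cluster-extent thresholding, and two-tailed
Pearson correlations between behavior scores and regional V_T.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf
from skimage.measure import label as cc_label
from statsmodels.stats.anova import anova_lm

from .exceptions import ValidationError

__all__ = [
    "AnovaResult",
    "ClusterTable",
    "validate_cohort_table",
    "two_way_anova",
    "holm_sidak_adjust",
    "posthoc_group_by_region",
    "voxelwise_two_sample_map",
    "extract_clusters",
    "pearson_correlation",
    "GROUP_ORDER",
]

GROUP_ORDER = ("buffer", "10Q", "85Q")

_REQUIRED_COLS = {"animal", "group", "region", "vt"}


def validate_cohort_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = _REQUIRED_COLS - set(table.columns)
    if missing:
        raise ValidationError(f"cohort table missing columns: {sorted(missing)}")
    dup = table.duplicated(subset=["animal", "region"])
    if dup.any():
        raise ValidationError("cohort table has duplicate animal x region rows")
    return table


@dataclass(eq=False)
class AnovaResult:
    """Two-way ANOVA factor table plus the pooled error term."""

    effects: pd.DataFrame  # effect, df, F, p
    mse: float
    df_error: float
    table: pd.DataFrame


def two_way_anova(table: pd.DataFrame) -> AnovaResult:
    """Fixed-effects group x region ANOVA with Type III sums of squares.

    Sum-to-zero contrasts make the Type III decomposition well defined for
    the unbalanced group sizes.  Every group x region cell must be
    non-empty.
    """
    table = validate_cohort_table(table)
    groups = table["group"].unique()
    regions = table["region"].unique()
    if len(groups) < 2 or len(regions) < 2:
        raise ValidationError("need >= 2 groups and >= 2 regions")
    counts = table.groupby(["group", "region"], observed=True).size()
    for g in groups:
        for r in regions:
            if (g, r) not in counts.index:
                raise ValidationError(f"empty cell: group '{g}' x region '{r}'")
    n_g, n_r, n = len(groups), len(regions), len(table)
    if np.ptp(table["vt"].to_numpy()) == 0:
        # degenerate constant response: all effects are exactly null
        dfs = {"group": n_g - 1, "region": n_r - 1,
               "group x region": (n_g - 1) * (n_r - 1)}
        effects = pd.DataFrame([{"effect": k, "df": float(v), "F": 0.0, "p": 1.0}
                                for k, v in dfs.items()])
        return AnovaResult(effects=effects, mse=0.0,
                           df_error=float(n - n_g * n_r), table=table)
    fit = smf.ols("vt ~ C(group, Sum) * C(region, Sum)", data=table).fit()
    aov = anova_lm(fit, typ=3)
    name_map = {
        "C(group, Sum)": "group",
        "C(region, Sum)": "region",
        "C(group, Sum):C(region, Sum)": "group x region",
    }
    rows = []
    for key, name in name_map.items():
        rows.append({
            "effect": name,
            "df": float(aov.loc[key, "df"]),
            "F": float(aov.loc[key, "F"]),
            "p": float(aov.loc[key, "PR(>F)"]),
        })
    df_error = float(aov.loc["Residual", "df"])
    mse = float(aov.loc["Residual", "sum_sq"] / df_error)
    return AnovaResult(effects=pd.DataFrame(rows), mse=mse,
                       df_error=df_error, table=table)


def holm_sidak_adjust(pvals, m: int | None = None) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values.

    Sort ascending, apply adj_i = 1 - (1 - p_(i))^(m - i + 1), enforce
    monotonicity with a running maximum, clip at 1, and return in the
    original order.  ``m`` defaults to the number of p-values and may not
    be smaller.
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    n = p.size
    if m is None:
        m = n
    if m < n:
        raise ValidationError(f"family size m={m} smaller than {n} tests")
    order = np.argsort(p, kind="stable")
    adj = 1.0 - (1.0 - p[order]) ** (m - np.arange(n))
    adj = np.minimum(np.maximum.accumulate(adj), 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def _group_pairs(groups) -> list:
    present = [g for g in GROUP_ORDER if g in groups]
    if len(present) == len(groups):
        # canonical ordering: disease-vs-control contrasts first
        return [(a, b) for a, b in combinations(reversed(present), 2)]
    return list(combinations(sorted(groups), 2))


def posthoc_group_by_region(table: pd.DataFrame,
                            anova: AnovaResult | None = None,
                            alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise group contrasts per region using the pooled error term.

    t = (mean_a - mean_b) / sqrt(MSE (1/n_a + 1/n_b)) on the ANOVA error
    degrees of freedom; Holm-Sidak adjustment over the contrast family
    within each region.
    """
    if anova is None:
        anova = two_way_anova(table)
    table = validate_cohort_table(table)
    pairs = _group_pairs(list(table["group"].unique()))
    rows = []
    for region, sub in table.groupby("region", observed=True, sort=False):
        stats = sub.groupby("group", observed=True)["vt"].agg(["mean", "count"])
        praw, meta = [], []
        for a, b in pairs:
            na, nb = stats.loc[a, "count"], stats.loc[b, "count"]
            diff = stats.loc[a, "mean"] - stats.loc[b, "mean"]
            se = np.sqrt(anova.mse * (1.0 / na + 1.0 / nb))
            t = diff / se if se > 0 else 0.0
            p = 2.0 * scipy.stats.t.sf(abs(t), anova.df_error)
            praw.append(p)
            meta.append((f"{a} vs {b}", diff, t))
        padj = holm_sidak_adjust(praw)
        for (contrast, diff, t), p, q in zip(meta, praw, padj):
            rows.append({"region": region, "contrast": contrast, "diff": diff,
                         "t": t, "p_raw": p, "p_adj": q,
                         "significant": q < alpha})
    return pd.DataFrame(rows)


def _map_stack(maps) -> np.ndarray:
    arrs = [m.data if hasattr(m, "data") else np.asarray(m, float) for m in maps]
    shape = arrs[0].shape
    for a in arrs:
        if a.shape != shape:
            raise ValidationError("map grids do not match")
    return np.stack(arrs)


def voxelwise_two_sample_map(maps_a, maps_b) -> tuple[np.ndarray, int]:
    """Pooled-variance two-sample t-map (A minus B) and its df.

    Voxels with any non-finite input are NaN.  Zero pooled variance yields
    signed infinity when the means differ and 0 when they coincide.
    """
    a = _map_stack(maps_a)
    b = _map_stack(maps_b)
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValidationError("need >= 2 maps per group")
    df = na + nb - 2
    valid = np.all(np.isfinite(a), axis=0) & np.all(np.isfinite(b), axis=0)
    diff = a.mean(axis=0) - b.mean(axis=0)
    sp2 = ((na - 1) * a.var(axis=0, ddof=1) + (nb - 1) * b.var(axis=0, ddof=1)) / df
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    t[(se == 0) & (diff == 0)] = 0.0
    t[(se == 0) & (diff > 0)] = np.inf
    t[(se == 0) & (diff < 0)] = -np.inf
    t[~valid] = np.nan
    return t, df


@dataclass(eq=False)
class ClusterTable:
    """Suprathreshold clusters: summary table plus the label image."""

    table: pd.DataFrame  # cluster_id, size, peak_t, peak_x/y/z
    labels: np.ndarray
    threshold_t: float
    voxels: dict = field(default_factory=dict)  # cluster_id -> (n, 3) coords


_CONNECTIVITY = {6: 1, 18: 2, 26: 3}


def extract_clusters(tmap: np.ndarray, df: int, p_thresh: float = 0.01,
                     k_min: int = 10, connectivity: int = 18,
                     direction: str = "increase",
                     strict: bool = True) -> ClusterTable:
    """Connected suprathreshold clusters of a t-map.

    Thresholds at the one-sided critical t for ``p_thresh``; components are
    joined under the chosen neighborhood (6, 18 or 26 in 3D); components
    with size > ``k_min`` survive (``strict=False`` keeps size >= k_min).
    """
    if df <= 0:
        raise ValidationError("df must be > 0")
    if connectivity not in _CONNECTIVITY:
        raise ValidationError("connectivity must be 6, 18 or 26")
    crit = float(scipy.stats.t.isf(p_thresh, df))
    tmap = np.asarray(tmap, dtype=float)
    signed = tmap if direction == "increase" else -tmap
    with np.errstate(invalid="ignore"):
        supra = signed > crit
    lab = cc_label(supra, connectivity=_CONNECTIVITY[connectivity])
    rows, voxels, keep_labels = [], {}, {}
    for cid in range(1, lab.max() + 1):
        coords = np.argwhere(lab == cid)
        size = coords.shape[0]
        if (size > k_min) if strict else (size >= k_min):
            vals = signed[tuple(coords.T)]
            peak = coords[np.argmax(vals)]
            new_id = len(rows) + 1
            rows.append({"cluster_id": new_id, "size": size,
                         "peak_t": float(vals.max()),
                         "peak_x": int(peak[0]), "peak_y": int(peak[1]),
                         "peak_z": int(peak[2])})
            voxels[new_id] = coords
            keep_labels[cid] = new_id
    out = np.zeros_like(lab)
    for old, new in keep_labels.items():
        out[lab == old] = new
    cols = ["cluster_id", "size", "peak_t", "peak_x", "peak_y", "peak_z"]
    return ClusterTable(table=pd.DataFrame(rows, columns=cols), labels=out,
                        threshold_t=crit, voxels=voxels)


def pearson_correlation(x, y) -> tuple[float, float]:
    """Sample Pearson r with a two-tailed t-test p-value (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need matched samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("values must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined: zero variance")
    res = scipy.stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
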