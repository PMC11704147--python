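"""Group statistics and report tables for the dilation study.

Mirrors the statistical battery of the source experiment design:

* paired two-tailed Student's t test per class, pre vs 1 min post the first
  dose, with the animal as the unit (per-animal mean normalized diameters),
* two-way ANOVA (condition x timepoint) on per-animal normalized diameters
  with Fisher's Least Significant Difference pairwise comparisons — the
  classical unadjusted pairwise t tests that reuse the pooled ANOVA error
  term,
* Mann-Whitney-Wilcoxon tests on depth-binned branch diameter distributions
  (branches, not animals, as units), exact for small samples and
  normal-approximated with tie correction otherwise,
* the summary table: rows class x condition, columns baseline diameter
  (mean +/- SD across branches) and normalized diameter at the three post
  timepoints (mean +/- SD across animals) with the paired-t p value.

The paired t statistic is computed from first principles (mean difference
over its standard error); ANOVA uses an OLS fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .phantom import CLASS_LABELS, TIMEPOINTS
from .longitudinal import per_animal_summary

__all__ = [
    "GroupResult",
    "DepthBinResult",
    "paired_t",
    "anova_lsd",
    "mannwhitney_depth",
    "build_group_table",
    "depth_report",
]


@dataclass
class GroupResult:
    """Per class x condition group summary."""

    class_label: str
    condition: str
    n_animals: int
    pre_diameter_mean_um: float
    pre_diameter_sd_um: float
    norm_mean: dict = field(default_factory=dict)
    norm_sd: dict = field(default_factory=dict)
    paired_t_stat: float | None = None
    paired_t_p: float | None = None


@dataclass
class DepthBinResult:
    """Pre/post diameter distributions within one 50-um depth bin."""

    bin_lo_um: float
    bin_hi_um: float
    pre: np.ndarray
    post: np.ndarray
    n_pre: int
    n_post: int
    mannwhitney_u: float | None
    mannwhitney_p: float | None
    median_pre: float | None
    median_post: float | None
    quartiles_pre: tuple[float, float] | None
    quartiles_post: tuple[float, float] | None


def paired_t(pre: np.ndarray, post: np.ndarray) -> tuple[float, float]:
    """Paired two-tailed Student's t test from first principles.

    ``t = mean(d) / (sd(d)/sqrt(n))`` with d = post - pre and n-1 degrees of
    freedom.  Returns ``(nan, nan)`` for zero-variance differences (p is
    undefined) — callers report NA.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("paired samples must be equal-length 1D arrays")
    n = pre.size
    if n < 2:
        raise ValueError("paired t needs n >= 2")
    d = post - pre
    sd = d.std(ddof=1)
    if sd == 0:
        if np.allclose(d, 0):
            return 0.0, 1.0
        return float("nan"), float("nan")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def anova_lsd(
    data: pd.DataFrame,
    value: str = "value",
    factor_a: str = "condition",
    factor_b: str = "timepoint",
) -> dict:
    """Two-way ANOVA with interaction and Fisher's LSD pairwise comparisons.

    Expects a long-format frame with one observation (e.g. per-animal mean
    normalized diameter) per row.  Returns the ANOVA table and unadjusted
    pairwise comparisons of factor-A levels within each level of factor B,
    using the pooled residual mean square as the error term:

    ``t = (m1 - m2) / sqrt(MSE * (1/n1 + 1/n2))``, df = residual df.

    Raises for factors with fewer than two levels or an empty design cell.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    for f in (factor_a, factor_b):
        if data[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs at least 2 levels")
    cells = data.groupby([factor_a, factor_b], observed=True)[value].count()
    for a in data[factor_a].unique():
        for b in data[factor_b].unique():
            if (a, b) not in cells.index or cells.loc[(a, b)] == 0:
                raise ValueError(f"empty design cell ({a}, {b})")
    df = data.rename(columns={value: "_y", factor_a: "_a", factor_b: "_b"})
    model = ols("_y ~ C(_a) * C(_b)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    mse = float(table.loc["Residual", "sum_sq"] / table.loc["Residual", "df"])
    df_resid = float(table.loc["Residual", "df"])
    pairwise = []
    levels_a = sorted(data[factor_a].unique())
    for b in sorted(data[factor_b].unique()):
        sub = data[data[factor_b] == b]
        for i, a1 in enumerate(levels_a):
            for a2 in levels_a[i + 1:]:
                g1 = sub.loc[sub[factor_a] == a1, value].to_numpy(dtype=float)
                g2 = sub.loc[sub[factor_a] == a2, value].to_numpy(dtype=float)
                if mse == 0 or df_resid <= 0:
                    t = np.nan
                    p = np.nan
                else:
                    se = np.sqrt(mse * (1.0 / g1.size + 1.0 / g2.size))
                    t = (g1.mean() - g2.mean()) / se
                    p = 2.0 * sps.t.sf(abs(t), df=df_resid)
                pairwise.append(
                    {
                        factor_b: b,
                        "level_1": a1,
                        "level_2": a2,
                        "mean_diff": float(g1.mean() - g2.mean()),
                        "t": float(t),
                        "p": float(p),
                    }
                )
    return {
        "anova_table": table,
        "mse": mse,
        "df_resid": df_resid,
        "lsd_pairwise": pd.DataFrame(pairwise),
    }


def mannwhitney_depth(
    pre: np.ndarray, post: np.ndarray, exact_max_n: int = 20
) -> tuple[float | None, float | None]:
    """Two-tailed Mann-Whitney U test between pre and post distributions.

    Exact null distribution when the combined sample size is <= 20 (and no
    ties force the approximation), otherwise normal approximation with tie
    correction.  Empty samples return (None, None).
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.size == 0 or post.size == 0:
        return None, None
    method = "exact" if (pre.size + post.size) <= exact_max_n else "asymptotic"
    res = sps.mannwhitneyu(pre, post, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _class_results(
    table: pd.DataFrame,
    condition: str,
    class_label: str | None,
    timepoints: tuple[str, ...] = TIMEPOINTS,
) -> GroupResult | None:
    sub = table if class_label is None else table[table["class"] == class_label]
    if len(sub) == 0:
        return None
    summ = per_animal_summary(sub, None, timepoints)
    if len(summ) == 0:
        return None
    res = GroupResult(
        class_label=class_label or "all",
        condition=condition,
        n_animals=int(summ["animal"].nunique()),
        pre_diameter_mean_um=float(sub["d_pre"].mean()),
        pre_diameter_sd_um=float(sub["d_pre"].std(ddof=1)) if len(sub) > 1 else 0.0,
    )
    for t in timepoints:
        vals = summ[f"norm_{t}"].dropna().to_numpy()
        res.norm_mean[t] = float(vals.mean()) if vals.size else np.nan
        res.norm_sd[t] = float(vals.std(ddof=1)) if vals.size > 1 else np.nan
    post1 = "post1_1min"
    paired = summ.dropna(subset=[f"norm_{post1}"])
    if len(paired) >= 2:
        t_stat, p = paired_t(
            np.ones(len(paired)), paired[f"norm_{post1}"].to_numpy()
        )
        res.paired_t_stat = t_stat
        res.paired_t_p = p
    return res


def build_group_table(
    tables_by_condition: dict[str, pd.DataFrame],
    timepoints: tuple[str, ...] = TIMEPOINTS,
) -> pd.DataFrame:
    """Summary table: rows = class x condition (plus an all-vessels row).

    The baseline-diameter column summarizes across branches (hence its large
    SD for pooled classes); normalized columns summarize across animals.
    The paired-t p value compares per-animal means at 1 min post the first
    dose against baseline.  Classes with no branches are omitted.
    """
    rows = []
    for condition, table in tables_by_condition.items():
        for cls in (None, *CLASS_LABELS):
            res = _class_results(table, condition, cls, timepoints)
            if res is None:
                continue
            row = {
                "class": res.class_label,
                "condition": condition,
                "n_animals": res.n_animals,
                "d_pre_mean_um": res.pre_diameter_mean_um,
                "d_pre_sd_um": res.pre_diameter_sd_um,
            }
            for t in timepoints:
                if t == "pre":
                    continue
                row[f"norm_{t}_mean"] = res.norm_mean.get(t, np.nan)
                row[f"norm_{t}_sd"] = res.norm_sd.get(t, np.nan)
            row["paired_t_p"] = res.paired_t_p if res.paired_t_p is not None else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def depth_report(
    branches_pre: pd.DataFrame,
    branches_post: pd.DataFrame,
    bin_um: float = 50.0,
    max_depth_um: float = 400.0,
    min_n: int = 3,
) -> list[DepthBinResult]:
    """Depth-resolved pre/post diameter distributions in 50-um bins.

    Inputs are branch tables with ``depth_um`` and ``mean_diameter_um``
    columns (one row per depth-attributed branch).  Bins with fewer than
    ``min_n`` branches on either side report counts but an NA p value.
    """
    out = []
    edges = np.arange(0.0, max_depth_um + bin_um, bin_um)
    for lo, hi in zip(edges[:-1], edges[1:]):
        pre = branches_pre.loc[
            (branches_pre["depth_um"] >= lo) & (branches_pre["depth_um"] < hi),
            "mean_diameter_um",
        ].to_numpy(dtype=float)
        post = branches_post.loc[
            (branches_post["depth_um"] >= lo) & (branches_post["depth_um"] < hi),
            "mean_diameter_um",
        ].to_numpy(dtype=float)
        if pre.size >= min_n and post.size >= min_n:
            u, p = mannwhitney_depth(pre, post)
        else:
            u, p = None, None
        out.append(
            DepthBinResult(
                bin_lo_um=float(lo),
                bin_hi_um=float(hi),
                pre=pre,
                post=post,
                n_pre=int(pre.size),
                n_post=int(post.size),
                mannwhitney_u=u,
                mannwhitney_p=p,
                median_pre=float(np.median(pre)) if pre.size else None,
                median_post=float(np.median(post)) if post.size else None,
                quartiles_pre=(
                    tuple(np.percentile(pre, [25, 75])) if pre.size else None
                ),
                quartiles_post=(
                    tuple(np.percentile(post, [25, 75])) if post.size else None
                ),
            )
        )
    return out


def depth_report_table(results: list[DepthBinResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "bin_lo_um": r.bin_lo_um,
                "bin_hi_um": r.bin_hi_um,
                "n_pre": r.n_pre,
                "n_post": r.n_post,
                "median_pre_um": r.median_pre,
                "median_post_um": r.median_post,
                "q25_pre": r.quartiles_pre[0] if r.quartiles_pre else None,
                "q75_pre": r.quartiles_pre[1] if r.quartiles_pre else None,
                "q25_post": r.quartiles_post[0] if r.quartiles_post else None,
                "q75_post": r.quartiles_post[1] if r.quartiles_post else None,
                "mannwhitney_u": r.mannwhitney_u,
                "mannwhitney_p": r.mannwhitney_p,
            }
        )
    return pd.DataFrame(rows)


def violin_long_table(results: list[DepthBinResult]) -> pd.DataFrame:
    """Long-format distributions for split-violin plotting."""
    rows = []
    for r in results:
        for phase, vals in (("pre", r.pre), ("post", r.post)):
            for v in vals:
                rows.append(
                    {
                        "bin_lo_um": r.bin_lo_um,
                        "bin_hi_um": r.bin_hi_um,
                        "phase": phase,
                        "diameter_um": float(v),
                    }
                )
    return pd.DataFrame(rows)
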