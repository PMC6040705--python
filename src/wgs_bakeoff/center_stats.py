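"""Statistical comparison of per-sample QC parameters across sequencing centers.

Three procedures, applied metric by metric:

* Kruskal-Wallis rank test across centers (all sequenced samples);
* randomized-block two-way ANOVA on the complete-case subset, center as the
  fixed factor and sample as the blocking factor — for a balanced design this
  F test coincides with the mixed-model F for the center effect;
* pairwise per-sample comparison of two centers: paired t with a 95%
  confidence interval of the mean difference, paired Wilcoxon alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def kruskal_wallis(groups: list[np.ndarray | list[float]]) -> tuple[float, float]:
    """Rank-based H with tie correction; p from chi-square with k-1 df.

    Identical values across all groups give H = 0, p = 1.
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


@dataclass
class BlockAnovaResult:
    f_center: float
    p_value: float
    df_center: int
    df_residual: int
    ss_center: float
    ss_sample: float
    ss_residual: float


def block_anova(table: pd.DataFrame, value: str = "value",
                center: str = "center", sample: str = "sample",
                ) -> BlockAnovaResult:
    """Randomized-block decomposition: F = MS_center / MS_residual.

    Requires a complete block (every sample measured in every center);
    an incomplete table is refused with instructions to subset to the
    shared samples first.
    """
    pivot = table.pivot_table(index=sample, columns=center, values=value,
                              aggfunc="first")
    if pivot.isna().any().any():
        raise ValueError("incomplete block design: restrict to samples "
                         "measured in every center before calling block_anova")
    y = pivot.to_numpy(dtype=float)
    n_s, n_c = y.shape
    if n_s < 2 or n_c < 2:
        raise ValueError("need >= 2 samples and >= 2 centers")
    gm = y.mean()
    ss_center = n_s * float(((y.mean(axis=0) - gm) ** 2).sum())
    ss_sample = n_c * float(((y.mean(axis=1) - gm) ** 2).sum())
    ss_total = float(((y - gm) ** 2).sum())
    ss_res = max(ss_total - ss_center - ss_sample, 0.0)
    df_c, df_r = n_c - 1, (n_c - 1) * (n_s - 1)
    if ss_center == 0.0:
        return BlockAnovaResult(0.0, 1.0, df_c, df_r, 0.0, ss_sample, ss_res)
    if ss_res == 0.0:
        return BlockAnovaResult(np.inf, 0.0, df_c, df_r, ss_center,
                                ss_sample, 0.0)
    f = (ss_center / df_c) / (ss_res / df_r)
    p = float(stats.f.sf(f, df_c, df_r))
    return BlockAnovaResult(float(f), p, df_c, df_r, ss_center, ss_sample, ss_res)


@dataclass
class PairedComparison:
    mean_diff: float
    ci_low: float
    ci_high: float
    t_statistic: float
    p_value: float
    wilcoxon_p: float | None
    n: int
    degenerate: bool = False


def paired_center_comparison(a: np.ndarray | list[float],
                             b: np.ndarray | list[float],
                             ci_level: float = 0.95) -> PairedComparison:
    """Paired t on per-sample differences a - b with a CI of the mean
    difference; the paired Wilcoxon p is reported alongside."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need >= 2 paired values")
    d = a - b
    n = d.size
    mean = float(d.mean())
    if np.allclose(d, d[0]):
        if d.std() == 0 and d[0] == 0:
            return PairedComparison(0.0, 0.0, 0.0, 0.0, 1.0, None, n,
                                    degenerate=True)
        return PairedComparison(mean, mean, mean, np.inf, 0.0, None, n,
                                degenerate=True)
    se = float(d.std(ddof=1) / np.sqrt(n))
    tcrit = float(stats.t.ppf(0.5 + ci_level / 2, n - 1))
    tstat, p = stats.ttest_rel(a, b)
    try:
        _, wp = stats.wilcoxon(d)
        wp = float(wp)
    except ValueError:
        wp = None
    return PairedComparison(mean, mean - tcrit * se, mean + tcrit * se,
                            float(tstat), float(p), wp, n)


def compare_centers(table: pd.DataFrame, metric: str,
                    shared_samples: list[str] | None = None) -> dict:
    """Run all three procedures for one metric of a long-form table with
    columns sample, center, metric, value."""
    sub = table[table["metric"] == metric]
    if sub.empty:
        raise ValueError(f"metric {metric!r} absent from table")
    groups = [g["value"].to_numpy() for _, g in sub.groupby("center")]
    h, kw_p = kruskal_wallis(groups)
    centers = sorted(sub["center"].unique())
    if shared_samples is None:
        counts = sub.groupby("sample")["center"].nunique()
        shared_samples = counts[counts == len(centers)].index.tolist()
    block = sub[sub["sample"].isin(shared_samples)]
    anova = block_anova(block)
    pairwise = {}
    wide = block.pivot_table(index="sample", columns="center", values="value",
                             aggfunc="first")
    for i, ca in enumerate(centers):
        for cb in centers[i + 1:]:
            pairwise[(ca, cb)] = paired_center_comparison(
                wide[ca].to_numpy(), wide[cb].to_numpy())
    return {"kruskal_wallis": (h, kw_p), "block_anova": anova,
            "pairwise": pairwise}
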