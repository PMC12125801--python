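"""One-way ANOVA with Fisher-LSD post-hoc pairwise comparisons.

The omnibus F is the classical between/within mean-square ratio. When the
omnibus test is significant at ``alpha``, unadjusted pairwise t-tests using
the pooled within-group mean square (the least-significant-difference
protocol) localize which groups differ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = ["AnovaResult", "LsdPair", "one_way_anova", "compare_reports"]


@dataclass(frozen=True)
class LsdPair:
    group_i: int
    group_j: int
    mean_diff: float
    t_stat: float
    p_value: float
    significant: bool


@dataclass
class AnovaResult:
    f_stat: float
    p_value: float
    df_between: int
    df_within: int
    group_means: list[float]
    ms_within: float
    lsd_pairs: list[LsdPair] = field(default_factory=list)
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def one_way_anova(groups: list[np.ndarray], alpha: float = 0.05,
                  lsd_always: bool = False) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA over >= 2 groups of >= 2 values.

    LSD pairwise p-values are computed only when the omnibus test rejects at
    ``alpha`` (or unconditionally with ``lsd_always``).
    """
    groups = [np.asarray(g, dtype=np.float64).ravel() for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for i, g in enumerate(groups):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 values")
        if not np.all(np.isfinite(g)):
            raise ValueError(f"group {i} contains non-finite values")

    k = len(groups)
    ns = np.array([g.size for g in groups])
    n_total = int(ns.sum())
    means = np.array([g.mean() for g in groups])
    grand = float(np.concatenate(groups).mean())

    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    df_between = k - 1
    df_within = n_total - k
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within if df_within > 0 else math.nan

    if ss_within == 0.0 and ss_between == 0.0:
        f_stat, p_value = 0.0, 1.0
    elif ss_within == 0.0:
        f_stat, p_value = math.inf, 0.0
    else:
        f_stat = ms_between / ms_within
        p_value = float(sps.f.sf(f_stat, df_between, df_within))

    result = AnovaResult(f_stat=f_stat, p_value=p_value, df_between=df_between,
                         df_within=df_within, group_means=means.tolist(),
                         ms_within=ms_within, alpha=alpha)

    if lsd_always or result.significant:
        for i in range(k):
            for j in range(i + 1, k):
                diff = float(means[i] - means[j])
                se = math.sqrt(ms_within * (1.0 / ns[i] + 1.0 / ns[j]))
                if se == 0:
                    t = math.inf if diff != 0 else 0.0
                    p = 0.0 if diff != 0 else 1.0
                else:
                    t = diff / se
                    p = float(2.0 * sps.t.sf(abs(t), df_within))
                result.lsd_pairs.append(LsdPair(i, j, diff, t, p, p < alpha))
    return result


def compare_reports(reports, metric_names=None, alpha: float = 0.05) -> "object":
    """ANOVA + LSD across >= 2 MetricsReports, one row per metric.

    Cases with undefined (NaN) values are excluded per metric; exclusion
    counts are reported. Returns a pandas DataFrame mirroring a
    mean±SD / F / p comparison table.
    """
    import pandas as pd

    from .metrics import METRIC_NAMES

    metric_names = metric_names or METRIC_NAMES
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    rows = []
    for m in metric_names:
        groups = []
        excluded = 0
        for rep in reports:
            vals = np.array([getattr(c, m) for c in rep.per_case], dtype=np.float64)
            finite = vals[np.isfinite(vals)]
            excluded += int(vals.size - finite.size)
            groups.append(finite)
        if any(g.size < 2 for g in groups):
            rows.append({"metric": m, "f_stat": math.nan, "p_value": math.nan,
                         "n_excluded": excluded})
            continue
        res = one_way_anova(groups, alpha=alpha)
        row = {"metric": m, "f_stat": res.f_stat, "p_value": res.p_value,
               "df_between": res.df_between, "df_within": res.df_within,
               "n_excluded": excluded,
               "significant": res.significant}
        for rep, mu in zip(reports, res.group_means):
            agg = rep.aggregate[m]
            row[f"{rep.group_label}_mean"] = agg[0]
            row[f"{rep.group_label}_sd"] = agg[1]
        for pair in res.lsd_pairs:
            gi = reports[pair.group_i].group_label
            gj = reports[pair.group_j].group_label
            row[f"lsd_{gi}_vs_{gj}_p"] = pair.p_value
        rows.append(row)
    return pd.DataFrame(rows)
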