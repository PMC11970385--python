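"""Cohort-level biomarker statistics.

Group comparisons use nonparametric tests (Kruskal-Wallis with Dunn's
post hoc z-tests), discrimination is summarized by the rank-based
(Mann-Whitney) AUC with stratified bootstrap percentile confidence
intervals, association by Spearman correlation, and assay repeatability
by the inter-assay coefficient of variation (mean of per-sample CVs).

The headline biomarker is the per-subject ratio of target % EV+ beads
to CD81 % EV+ beads, which normalizes target positivity by the number
of EVs captured.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ratio_biomarker", "compare_groups", "dunn_posthoc",
    "roc_analysis", "auc_mann_whitney", "correlation", "assay_cv",
    "GroupComparison", "RocResult",
]


def ratio_biomarker(table: pd.DataFrame,
                    numerator: str = "target_pos_percent",
                    denominator: str = "cd81_pos_percent") -> pd.DataFrame:
    """Append the per-subject numerator/denominator ratio.

    Subjects with a zero denominator cannot be normalized; they are
    dropped with a warning naming them.
    """
    out = table.copy()
    zero = out[denominator] == 0
    if zero.any():
        ids = (out.loc[zero, "subject_id"].tolist()
               if "subject_id" in out.columns else out.index[zero].tolist())
        warnings.warn(f"excluding {int(zero.sum())} subject(s) with zero "
                      f"{denominator}: {ids}", stacklevel=2)
        out = out.loc[~zero].copy()
    out["ratio"] = out[numerator] / out[denominator]
    return out


@dataclass
class GroupComparison:
    """Kruskal-Wallis omnibus result with Dunn pairwise tests."""

    h_statistic: float
    p_value: float
    group_summaries: pd.DataFrame  # group, n, median, iqr
    dunn: pd.DataFrame             # group1, group2, z, p, p_adjusted


def dunn_posthoc(groups: dict[str, np.ndarray],
                 adjust: str | None = None) -> pd.DataFrame:
    """Dunn's z-test for all group pairs on joint ranks.

    Uses the tie-corrected pooled variance
    sigma^2 = (N(N+1)/12 - sum(t^3 - t)/(12(N-1))) (1/n_i + 1/n_j).
    ``adjust`` is None (default) or any method accepted by
    ``statsmodels.stats.multitest.multipletests`` (e.g. "bonferroni",
    "holm").
    """
    names = list(groups)
    all_vals = np.concatenate([np.asarray(groups[g], dtype=float)
                               for g in names])
    n_total = len(all_vals)
    ranks = stats.rankdata(all_vals)
    mean_ranks, sizes = {}, {}
    i0 = 0
    for g in names:
        n = len(groups[g])
        mean_ranks[g] = ranks[i0:i0 + n].mean()
        sizes[g] = n
        i0 += n
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    base_var = (n_total * (n_total + 1) / 12.0
                - tie_term / (12.0 * (n_total - 1)))
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            se = np.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append((a, b, z, p))
    df = pd.DataFrame(rows, columns=["group1", "group2", "z", "p"])
    if adjust is not None:
        df["p_adjusted"] = multipletests(df["p"], method=adjust)[1]
    else:
        df["p_adjusted"] = df["p"]
    return df


def compare_groups(table: pd.DataFrame, measure: str,
                   group_col: str = "group",
                   adjust: str | None = None,
                   min_group_size: int = 3) -> GroupComparison:
    """Kruskal-Wallis across groups with Dunn post hoc and summaries."""
    groups = {g: sub[measure].to_numpy(dtype=float)
              for g, sub in table.groupby(group_col, sort=False)}
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    small = {g: len(v) for g, v in groups.items() if len(v) < min_group_size}
    if small:
        raise ValueError(f"groups below minimum size {min_group_size}: {small}")
    h, p = stats.kruskal(*groups.values())
    summaries = pd.DataFrame({
        "group": list(groups),
        "n": [len(v) for v in groups.values()],
        "median": [float(np.median(v)) for v in groups.values()],
        "iqr": [float(np.subtract(*np.percentile(v, [75, 25])))
                for v in groups.values()],
    })
    dunn = dunn_posthoc(groups, adjust=adjust)
    return GroupComparison(float(h), float(p), summaries, dunn)


def auc_mann_whitney(positive: np.ndarray, control: np.ndarray) -> float:
    """Rank-based AUC: P(pos > ctrl) + 0.5 P(pos == ctrl)."""
    pos = np.asarray(positive, dtype=float)
    ctl = np.asarray(control, dtype=float)
    if len(pos) == 0 or len(ctl) == 0:
        raise ValueError("both groups must be non-empty")
    ranks = stats.rankdata(np.concatenate([pos, ctl]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(ctl)))


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    n_positive: int
    n_control: int
    n_bootstrap: int


def roc_analysis(table: pd.DataFrame, measure: str,
                 positive_group: str, control_group: str,
                 group_col: str = "group",
                 n_bootstrap: int = 2000,
                 seed: int = 0) -> RocResult:
    """AUC for separating two groups, with a 95% bootstrap CI.

    The CI is the 2.5-97.5 percentile interval of AUCs over
    ``n_bootstrap`` resamples drawn with replacement within each group
    (stratified bootstrap).
    """
    pos = table.loc[table[group_col] == positive_group, measure].to_numpy(float)
    ctl = table.loc[table[group_col] == control_group, measure].to_numpy(float)
    if len(pos) == 0 or len(ctl) == 0:
        raise ValueError(
            f"empty group: {positive_group} n={len(pos)}, "
            f"{control_group} n={len(ctl)}")
    auc = auc_mann_whitney(pos, ctl)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        boots[b] = auc_mann_whitney(
            rng.choice(pos, size=len(pos), replace=True),
            rng.choice(ctl, size=len(ctl), replace=True))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return RocResult(auc, float(lo), float(hi), len(pos), len(ctl), n_bootstrap)


def roc_curve_points(table: pd.DataFrame, measure: str,
                     positive_group: str, control_group: str,
                     group_col: str = "group") -> pd.DataFrame:
    """(FPR, TPR) pairs over all observed thresholds, for plotting."""
    pos = table.loc[table[group_col] == positive_group, measure].to_numpy(float)
    ctl = table.loc[table[group_col] == control_group, measure].to_numpy(float)
    thresholds = np.concatenate(([np.inf], np.unique(np.concatenate([pos, ctl]))[::-1]))
    rows = [(float(np.mean(ctl >= t)), float(np.mean(pos >= t))) for t in thresholds]
    return pd.DataFrame(rows, columns=["fpr", "tpr"])


def correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation (rho, p).

    p comes from the t approximation on rho. Constant input has no
    defined rank correlation and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-D vectors")
    if len(x) < 4:
        raise ValueError("need n >= 4 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Spearman correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def assay_cv(replicates: pd.DataFrame, sample_col: str = "sample",
             value_col: str = "value") -> dict:
    """Inter-assay CV: mean over samples of per-sample 100*SD/mean.

    Each sample needs >= 2 replicates and a non-zero mean.
    """
    per_sample = {}
    for s, sub in replicates.groupby(sample_col):
        vals = sub[value_col].to_numpy(dtype=float)
        if len(vals) < 2:
            raise ValueError(f"sample {s!r} has {len(vals)} replicate(s); need >= 2")
        m = vals.mean()
        if m == 0:
            raise ValueError(f"sample {s!r} has zero mean: CV undefined")
        per_sample[s] = 100.0 * vals.std(ddof=1) / m
    return {
        "per_sample_cv_percent": per_sample,
        "inter_assay_cv_percent": float(np.mean(list(per_sample.values()))),
    }
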