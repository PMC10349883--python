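"""Evaluation statistics for cognitive-index models.

Pearson correlations, Fisher r-to-z comparison of two correlations,
rank-based tertile discriminability (Cuzick's trend test, low-vs-high
ROC/AUC in the Mann-Whitney form), and a nested-model likelihood-ratio test
under Gaussian residuals.

The Fisher comparison uses the independent-samples formula; when two
indices are evaluated on the same subjects this overstates independence,
but it is the standard two-correlation comparison and the magnitude of z is
the tested quantity.  Applying a chi-square likelihood-ratio test to
penalized fits is statistically heterodox (penalization breaks exact
nesting); the deviance is floored at zero with a warning when the "full"
model fits worse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

logger = logging.getLogger("sleepsci")


@dataclass
class CorrComparison:
    r1: float
    r2: float
    n1: int
    n2: int
    z: float
    p: float


@dataclass
class TrendResult:
    group_labels: list
    z: float
    p: float
    t_statistic: float


@dataclass
class LRTResult:
    loglik_sub: float
    loglik_full: float
    deviance_change: float
    df: int
    p: float


def pearson_corr(x, y):
    """Sample Pearson r with a two-sided t-distribution p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input")
    r, p = sstats.pearsonr(x, y)
    return float(r), float(p)


def fisher_compare(r1: float, n1: int, r2: float, n2: int) -> CorrComparison:
    """Compare two correlations via the Fisher z transform.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)), two-sided normal p.
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("|r| must be < 1 for the Fisher transform")
    if min(n1, n2) <= 3:
        raise ValueError("need n > 3 in both samples")
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (np.arctanh(r1) - np.arctanh(r2)) / se
    p = 2.0 * sstats.norm.sf(abs(z))
    return CorrComparison(r1, r2, n1, n2, float(z), float(p))


def tertile_split(scores) -> np.ndarray:
    """Rank-based split into 'low'/'medium'/'high' thirds.

    Sizes are as equal as possible with any remainder distributed from the
    low group upward; ties are broken by stable input order.
    """
    scores = np.asarray(scores, float)
    n = scores.size
    if n < 3:
        raise ValueError("need n >= 3")
    order = np.argsort(scores, kind="stable")
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    labels = np.empty(n, dtype=object)
    start = 0
    for name, size in zip(("low", "medium", "high"), sizes):
        labels[order[start:start + size]] = name
        start += size
    return labels


def cuzick_trend(values, group_labels, ordered_groups=None) -> TrendResult:
    """Cuzick's non-parametric test for trend across ordered groups.

    Mid-ranks R_i over the pooled sample, group scores l_j = 1..k,
    T = sum l(i) R_i; E[T] = (N+1)/2 * sum n_j l_j;
    Var[T] = (N+1)/12 * (N sum n_j l_j^2 - (sum n_j l_j)^2), multiplied by
    the usual tie-correction factor 1 - sum(t^3 - t)/(N^3 - N).
    """
    values = np.asarray(values, float)
    group_labels = np.asarray(group_labels, dtype=object)
    if ordered_groups is None:
        ordered_groups = list(dict.fromkeys(group_labels))
    k = len(ordered_groups)
    if k < 2:
        raise ValueError("need at least 2 ordered groups")
    l_of = {g: j + 1 for j, g in enumerate(ordered_groups)}
    counts = {g: int((group_labels == g).sum()) for g in ordered_groups}
    if any(c == 0 for c in counts.values()):
        empty = [g for g, c in counts.items() if c == 0]
        raise ValueError(f"empty group(s): {empty}")

    N = values.size
    ranks = sstats.rankdata(values)        # mid-ranks
    l = np.array([l_of[g] for g in group_labels], float)
    T = float(np.sum(l * ranks))
    sum_nl = sum(counts[g] * l_of[g] for g in ordered_groups)
    sum_nl2 = sum(counts[g] * l_of[g] ** 2 for g in ordered_groups)
    ET = (N + 1) / 2.0 * sum_nl
    var = (N + 1) / 12.0 * (N * sum_nl2 - sum_nl ** 2)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    var *= 1.0 - tie_term / (N ** 3 - N)
    if var <= 0:
        raise ValueError("degenerate trend variance (all values tied)")
    z = (T - ET) / np.sqrt(var)
    p = 2.0 * sstats.norm.sf(abs(z))
    return TrendResult(list(ordered_groups), float(z), float(p), T)


def roc_auc(index_values, group_labels, exclude_medium: bool = True):
    """Low-vs-high AUC in the Mann-Whitney form, positive class = 'high'.

    Returns (auc, (fpr, tpr) curve points).
    """
    index_values = np.asarray(index_values, float)
    group_labels = np.asarray(group_labels, dtype=object)
    keep = np.ones(index_values.size, bool)
    if exclude_medium:
        keep = group_labels != "medium"
    vals, labs = index_values[keep], group_labels[keep]
    hi = vals[labs == "high"]
    lo = vals[labs == "low"]
    if hi.size == 0 or lo.size == 0:
        raise ValueError("need at least one low and one high subject")
    # AUC = P(high > low) + 0.5 P(tie), computed from rank sums
    pooled = np.concatenate([lo, hi])
    ranks = sstats.rankdata(pooled)
    auc = (ranks[lo.size:].sum() - hi.size * (hi.size + 1) / 2.0) \
        / (hi.size * lo.size)
    from sklearn.metrics import roc_curve
    fpr, tpr, _ = roc_curve((labs == "high").astype(int), vals)
    return float(auc), (fpr, tpr)


def gaussian_loglik(residuals: np.ndarray) -> float:
    """Gaussian log-likelihood with variance = RSS/n (the MLE)."""
    residuals = np.asarray(residuals, float)
    n = residuals.size
    rss = float(residuals @ residuals)
    if rss <= 0:
        return float("inf")
    return -n / 2.0 * (np.log(2 * np.pi * rss / n) + 1.0)


def nested_lrt(submodel_residuals, fullmodel_residuals,
               df_added: int = 3) -> LRTResult:
    """Likelihood-ratio test for a nested Gaussian model comparison.

    deviance = n log(RSS_sub / RSS_full), chi-square with ``df_added`` df.
    The deviance is floored at 0 (with a warning) when penalized fitting
    leaves the richer model with the larger RSS.
    """
    r_sub = np.asarray(submodel_residuals, float)
    r_full = np.asarray(fullmodel_residuals, float)
    if r_sub.size != r_full.size:
        raise ValueError("both models must be evaluated on the same subjects")
    n = r_sub.size
    rss_sub = float(r_sub @ r_sub)
    rss_full = float(r_full @ r_full)
    dev = n * np.log(rss_sub / rss_full)
    if dev < 0:
        logger.warning("full model fits worse than submodel "
                       "(penalization artifact); flooring deviance at 0")
        dev = 0.0
    p = float(sstats.chi2.sf(dev, df_added)) if dev > 0 else 1.0
    return LRTResult(gaussian_loglik(r_sub), gaussian_loglik(r_full),
                     float(dev), df_added, p)


def evaluate_index(index_values, scores, index_name: str = "SCI",
                   bai_values=None) -> dict:
    """The per-target evaluation battery of a cognitive index.

    Held-out correlation and MAE are assumed computed upstream; this
    function adds the discriminability analyses (tertile trend and
    low-vs-high AUC) and, when a brain-age index is supplied, the Fisher
    comparison of the two correlations.
    """
    scores = np.asarray(scores, float)
    index_values = np.asarray(index_values, float)
    n = scores.size
    r, p = pearson_corr(index_values, scores)
    groups = tertile_split(scores)
    trend = cuzick_trend(index_values, groups, ["low", "medium", "high"])
    auc, _ = roc_auc(index_values, groups)
    out = {"n": n, "r": r, "r_p": p, "cuzick_z": trend.z,
           "cuzick_p": trend.p, "auc_low_vs_high": auc}
    if bai_values is not None:
        r_bai, _ = pearson_corr(bai_values, scores)
        cmp_ = fisher_compare(r, n, r_bai, n)
        out["r_bai"] = r_bai
        out["z_vs_bai"] = cmp_.z
        out["z_vs_bai_p"] = cmp_.p
    return out


def evaluation_report(predictions: pd.DataFrame,
                      cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-target report from a held-out predictions table.

    ``predictions`` columns: subject_id, target, fold, y_true, y_pred.
    """
    rows = []
    for target, grp in predictions.groupby("target"):
        merged = grp.merge(cohort, on="subject_id", how="inner")
        res = evaluate_index(merged["y_pred"], merged["y_true"])
        res["target"] = target
        res["mae"] = float(np.mean(np.abs(merged["y_true"]
                                          - merged["y_pred"])))
        rows.append(res)
    cols = ["target", "n", "r", "r_p", "mae", "cuzick_z", "cuzick_p",
            "auc_low_vs_high"]
    return pd.DataFrame(rows)[cols]
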