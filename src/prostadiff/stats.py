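"""Group-level cohort statistics.

Per-ROI parameter medians are compared between tissue classes with a
Wilcoxon signed-rank test preceded by a Shapiro-Wilk normality check
(p < 0.05 conventionally indicates significance).  The signed-rank test is
applied to patient-index-paired values, as in the study design this
package emulates, even though the two lesion groups come from different
patients; an unpaired rank-sum fallback is available behind a flag.
Diagnostic accuracy is summarized by ROC curves whose AUC is computed by
the rank (Mann-Whitney) formulation with half-credit for ties, and by the
classification thresholds that maximize the positive and negative
predictive values.  Parameter cross-correlations are reported as r^2 with
the sign of the association.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger("prostadiff")

#: parameter pairs examined in the correlation panel
DEFAULT_CORRELATION_PAIRS: tuple[tuple[str, str], ...] = (
    ("D_K", "f_IC"),
    ("D_K", "f_EES"),
    ("D", "f_IC"),
    ("D", "f_EES"),
    ("K", "f_IC"),
    ("K", "f_EES"),
    ("Dstar", "f_EES"),
    ("Dstar", "f_VASC"),
    ("D_K", "d_EES"),
    ("D", "d_EES"),
)


def _group_scores(table: pd.DataFrame, parameter: str, tissue_class: str) -> np.ndarray:
    """ROI medians of one parameter for one tissue class, in sorted patient order."""
    sub = table[(table["parameter"] == parameter) & (table["tissue_class"] == tissue_class)]
    sub = sub.sort_values("patient_id")
    if sub["patient_id"].duplicated().any():
        raise ValueError(
            f"multiple medians for one (patient, class) in {parameter}/{tissue_class}"
        )
    return sub["median"].to_numpy(dtype=float)


@dataclass
class GroupComparison:
    parameter: str
    class_a: str
    class_b: str
    test_name: str
    statistic: float
    p_value: float
    median_a: float
    median_b: float
    direction: int  # sign of median_a - median_b
    normality_p: tuple[float, float]
    degenerate: bool = False


def compare_groups(
    table: pd.DataFrame,
    parameter: str,
    class_a: str,
    class_b: str,
    unpaired: bool = False,
) -> GroupComparison:
    """Wilcoxon signed-rank comparison of ROI medians between two tissue classes.

    Values are paired by sorted patient index; zero differences are dropped
    (classic policy); the exact null distribution is used for n <= 25 pairs
    and the normal approximation above.  With ``unpaired=True`` a
    Mann-Whitney rank-sum test is used instead (required when group sizes
    differ).
    """
    a = _group_scores(table, parameter, class_a)
    b = _group_scores(table, parameter, class_b)
    if min(a.size, b.size) < 5:
        raise ValueError("need at least 5 ROI medians per class")
    norm_p = (float(sps.shapiro(a).pvalue), float(sps.shapiro(b).pvalue))
    med_a, med_b = float(np.median(a)), float(np.median(b))
    direction = int(np.sign(med_a - med_b))

    if unpaired:
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        return GroupComparison(
            parameter, class_a, class_b, "mann-whitney", float(res.statistic),
            float(res.pvalue), med_a, med_b, direction, norm_p,
        )

    if a.size != b.size:
        raise ValueError(
            f"paired test requires equal group sizes ({a.size} vs {b.size}); "
            "pass unpaired=True for the rank-sum fallback"
        )
    diff = a - b
    nonzero = diff[diff != 0]
    if nonzero.size == 0:
        logger.warning("all paired differences are zero for %s %s-vs-%s", parameter, class_a, class_b)
        return GroupComparison(
            parameter, class_a, class_b, "wilcoxon", 0.0, 1.0,
            med_a, med_b, direction, norm_p, degenerate=True,
        )
    method = "exact" if nonzero.size <= 25 else "approx"
    try:
        res = sps.wilcoxon(nonzero, zero_method="wilcox", alternative="two-sided", method=method)
    except ValueError:
        res = sps.wilcoxon(nonzero, zero_method="wilcox", alternative="two-sided", method="approx")
    return GroupComparison(
        parameter, class_a, class_b, "wilcoxon", float(res.statistic), float(res.pvalue),
        med_a, med_b, direction, norm_p,
    )


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


def rank_auc(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """Mann-Whitney AUC: P(pos > neg) + 0.5 P(pos == neg), via pooled ranks."""
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    pooled = np.concatenate([pos, neg])
    ranks = sps.rankdata(pooled)
    u = np.sum(ranks[: pos.size]) - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent sorted unique scores, plus -inf and +inf."""
    u = np.unique(scores)
    mids = (u[:-1] + u[1:]) / 2.0
    return np.concatenate([[-np.inf], mids, [np.inf]])


@dataclass
class ROCResult:
    parameter: str
    positive_class: str
    negative_class: str
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    ppv_max: dict
    npv_max: dict
    orientation: str  # 'higher' or 'lower': which score side predicts positive
    degenerate: bool = False


def predictive_value_thresholds(
    scores_pos: np.ndarray, scores_neg: np.ndarray, direction: str = "higher"
) -> tuple[dict, dict]:
    """Thresholds maximizing PPV and NPV over an exhaustive midpoint sweep.

    ``direction='higher'`` classifies scores above the threshold as
    positive.  Undefined ratios (empty predicted group) are skipped.  PPV
    ties break toward the larger predicted-positive count, NPV ties toward
    the larger predicted-negative count.
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be nonempty")
    if direction not in ("higher", "lower"):
        raise ValueError("direction must be 'higher' or 'lower'")
    best_ppv = {"threshold": np.nan, "ppv": -np.inf, "n_predicted": -1}
    best_npv = {"threshold": np.nan, "npv": -np.inf, "n_predicted": -1}
    for t in _candidate_thresholds(np.concatenate([pos, neg])):
        if direction == "higher":
            tp, fp = int(np.sum(pos > t)), int(np.sum(neg > t))
        else:
            tp, fp = int(np.sum(pos < t)), int(np.sum(neg < t))
        fn, tn = pos.size - tp, neg.size - fp
        if tp + fp > 0:
            ppv = tp / (tp + fp)
            if ppv > best_ppv["ppv"] or (ppv == best_ppv["ppv"] and tp + fp > best_ppv["n_predicted"]):
                best_ppv = {"threshold": float(t), "ppv": ppv, "n_predicted": tp + fp}
        if tn + fn > 0:
            npv = tn / (tn + fn)
            if npv > best_npv["npv"] or (npv == best_npv["npv"] and tn + fn > best_npv["n_predicted"]):
                best_npv = {"threshold": float(t), "npv": npv, "n_predicted": tn + fn}
    return (
        {"threshold": best_ppv["threshold"], "ppv": best_ppv["ppv"]},
        {"threshold": best_npv["threshold"], "npv": best_npv["npv"]},
    )


def roc_analysis(
    table: pd.DataFrame, parameter: str, positive_class: str, negative_class: str
) -> ROCResult:
    """ROC analysis of one parameter's ROI medians for a class pair.

    The orientation (whether the positive class scores high or low) is
    fixed once from the group medians and reported, never silently flipped.
    """
    pos = _group_scores(table, parameter, positive_class)
    neg = _group_scores(table, parameter, negative_class)
    if min(pos.size, neg.size) < 2:
        raise ValueError("need at least 2 ROI medians per class")

    degenerate = np.ptp(pos) == 0 and np.ptp(neg) == 0 and pos[0] == neg[0]
    orientation = "higher" if np.median(pos) >= np.median(neg) else "lower"
    s_pos = pos if orientation == "higher" else -pos
    s_neg = neg if orientation == "higher" else -neg
    auc = 0.5 if degenerate else rank_auc(s_pos, s_neg)
    if degenerate:
        logger.warning("ROC for %s: constant scores in both classes; AUC set to 0.5", parameter)

    thresholds = _candidate_thresholds(np.concatenate([pos, neg]))
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for k, t in enumerate(thresholds):
        if orientation == "higher":
            tp, fp = np.sum(pos > t), np.sum(neg > t)
        else:
            tp, fp = np.sum(pos < t), np.sum(neg < t)
        sens[k] = tp / pos.size
        spec[k] = 1.0 - fp / neg.size
    ppv_max, npv_max = predictive_value_thresholds(pos, neg, orientation)
    return ROCResult(
        parameter=parameter,
        positive_class=positive_class,
        negative_class=negative_class,
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        ppv_max=ppv_max,
        npv_max=npv_max,
        orientation=orientation,
        degenerate=bool(degenerate),
    )


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------


def parameter_correlations(
    values: pd.DataFrame, pairs=DEFAULT_CORRELATION_PAIRS
) -> pd.DataFrame:
    """Linear correlation (r^2 and slope sign) for each parameter pair.

    ``values`` holds one row per observation (voxel or ROI) and one column
    per parameter; pairs with a missing column are skipped, zero-variance
    pairs are flagged undefined.
    """
    rows = []
    for px, py in pairs:
        if px not in values.columns or py not in values.columns:
            continue
        sub = values[[px, py]].dropna()
        n = len(sub)
        if n < 3:
            raise ValueError(f"need at least 3 paired values for ({px}, {py})")
        x, y = sub[px].to_numpy(), sub[py].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append(dict(param_x=px, param_y=py, r_squared=np.nan, sign=0, n=n, undefined=True))
            continue
        r, _p = sps.pearsonr(x, y)
        rows.append(
            dict(param_x=px, param_y=py, r_squared=float(r**2), sign=int(np.sign(r)), n=n,
                 undefined=False)
        )
    return pd.DataFrame(rows)


def roi_median_frame(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a cohort table to one row per (patient, class), one column per parameter."""
    return table.pivot_table(
        index=["patient_id", "tissue_class"], columns="parameter", values="median"
    ).reset_index()
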