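"""Cohort-level statistics for spectrum parameters.

Nonparametric group comparisons (Kruskal-Wallis omnibus with Bonferroni-
corrected pairwise Mann-Whitney tests), 2x2 contingency analysis with an
exact two-sided Fisher test, Spearman rank correlation, and empirical
ROC/AUC discrimination of diabetic-retinopathy status, with the
Hanley-McNeil standard error for the AUC.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .spectrum import GRADES

__all__ = [
    "ROCResult",
    "GroupComparison",
    "ContingencyResult",
    "roc_auc",
    "fisher_exact",
    "kruskal_pairwise",
    "spearman",
    "severity_report",
    "GROUPING_SCHEMES",
    "SPECTRUM_PARAMETERS",
]


# ---------------------------------------------------------------------------
# ROC / AUC


@dataclass(frozen=True)
class ROCResult:
    """Empirical ROC curve with trapezoidal AUC.

    ``orientation`` records which direction of the raw score indicates
    disease ("higher" or "lower"); the curve is computed on the oriented
    score so AUC >= 0.5 means discriminative in the declared direction.
    """

    auc: float
    se: float
    ci95: Tuple[float, float]
    fpr: np.ndarray
    tpr: np.ndarray
    orientation: str
    n_pos: int
    n_neg: int


def _hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc * auc)
        + (n_neg - 1) * (q2 - auc * auc)
    ) / (n_pos * n_neg)
    return math.sqrt(max(var, 0.0))


def roc_auc(
    scores: Sequence[float],
    labels: Sequence[bool],
    orientation: str = "higher",
) -> ROCResult:
    """Empirical ROC by threshold sweep; AUC by the trapezoid rule.

    Ties are credited 0.5, making the AUC identical to the normalized
    Mann-Whitney U statistic.  ``orientation="lower"`` negates the score
    (markers that decrease with disease, e.g. total space count).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if orientation not in ("higher", "lower"):
        raise ValueError("orientation must be 'higher' or 'lower'")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes to be non-empty")
    s = scores if orientation == "higher" else -scores

    order = np.argsort(-s, kind="mergesort")
    y = labels[order]
    s_sorted = s[order]
    last_of_tie = np.r_[np.diff(s_sorted) != 0, True]
    tps = np.cumsum(y)[last_of_tie]
    fps = np.cumsum(~y)[last_of_tie]
    tpr = np.concatenate([[0.0], tps / n_pos])
    fpr = np.concatenate([[0.0], fps / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    se = _hanley_mcneil_se(auc, n_pos, n_neg)
    ci = (max(0.0, auc - 1.959964 * se), min(1.0, auc + 1.959964 * se))
    return ROCResult(
        auc=auc,
        se=se,
        ci95=ci,
        fpr=fpr,
        tpr=tpr,
        orientation=orientation,
        n_pos=n_pos,
        n_neg=n_neg,
    )


# ---------------------------------------------------------------------------
# contingency


@dataclass(frozen=True)
class ContingencyResult:
    """2x2 contingency analysis: exact Fisher p, odds ratio, row percentages."""

    table: Tuple[Tuple[int, int], Tuple[int, int]]
    odds_ratio: float
    p_exact: float
    p_chi2: Optional[float]
    row_pct: Tuple[float, float]  # % of first column within each row


def fisher_exact(table, chi2: bool = True) -> ContingencyResult:
    """Two-sided Fisher exact test by minimum-likelihood summation.

    With margins fixed, all tables whose hypergeometric probability does
    not exceed the observed table's are summed.  Probabilities are exact
    integer ratios (binomial coefficients over a common denominator), so
    the two-sided p is free of floating-point comparison artifacts.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(arr != np.floor(arr)) or np.any(arr < 0):
        raise ValueError("counts must be non-negative integers")
    a, b = int(arr[0, 0]), int(arr[0, 1])
    c, d = int(arr[1, 0]), int(arr[1, 1])
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    if n == 0:
        p = 1.0
    else:
        k_lo = max(0, c1 - r2)
        k_hi = min(r1, c1)
        nums = {k: comb(r1, k) * comb(r2, c1 - k) for k in range(k_lo, k_hi + 1)}
        denom = comb(n, c1)
        obs = nums[a]
        p = sum(v for v in nums.values() if v <= obs) / denom

    odds = math.nan
    if b * c > 0:
        odds = (a * d) / (b * c)
    elif a * d > 0:
        odds = math.inf

    p_chi2 = None
    if chi2 and min(r1, r2, c1, n - c1) > 0:
        p_chi2 = float(sps.chi2_contingency(arr, correction=True)[1])

    row_pct = (
        100.0 * a / r1 if r1 else math.nan,
        100.0 * c / r2 if r2 else math.nan,
    )
    return ContingencyResult(
        table=((a, b), (c, d)),
        odds_ratio=odds,
        p_exact=float(p),
        p_chi2=p_chi2,
        row_pct=row_pct,
    )


# ---------------------------------------------------------------------------
# rank tests


@dataclass(frozen=True)
class GroupComparison:
    """One rank test: statistic, raw and Bonferroni-adjusted p, medians (IQR)."""

    test: str
    groups: Tuple[str, ...]
    statistic: float
    p_raw: float
    p_adjusted: float
    medians: Dict[str, Tuple[float, float, float]]  # label -> (median, q1, q3)


def _median_iqr(x: np.ndarray) -> Tuple[float, float, float]:
    return (
        float(np.median(x)),
        float(np.percentile(x, 25)),
        float(np.percentile(x, 75)),
    )


def kruskal_pairwise(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
) -> List[GroupComparison]:
    """Kruskal-Wallis omnibus plus Bonferroni-corrected pairwise tests.

    The omnibus H uses the tie-corrected statistic; pairwise comparisons
    are two-sided Mann-Whitney U tests on midranks with the Bonferroni
    factor equal to the number of pairs actually compared.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    med = {lab: _median_iqr(g) for lab, g in zip(labels, groups)}

    if np.ptp(np.concatenate(groups)) == 0:
        h, p = 0.0, 1.0  # all values tied: scipy raises, but H is 0 by definition
    else:
        h, p = sps.kruskal(*groups)
    results = [
        GroupComparison(
            test="kruskal-wallis",
            groups=tuple(labels),
            statistic=float(h),
            p_raw=float(p),
            p_adjusted=float(p),
            medians=med,
        )
    ]
    pairs = list(combinations(range(len(groups)), 2))
    m = len(pairs)
    for i, j in pairs:
        u, praw = sps.mannwhitneyu(groups[i], groups[j], alternative="two-sided")
        results.append(
            GroupComparison(
                test="mann-whitney",
                groups=(labels[i], labels[j]),
                statistic=float(u),
                p_raw=float(praw),
                p_adjusted=float(min(1.0, m * praw)),
                medians={labels[i]: med[labels[i]], labels[j]: med[labels[j]]},
            )
        )
    return results


def spearman(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Spearman rank correlation (Pearson on midranks) with t-approximate p.

    Constant input yields (nan, nan) -- the coefficient is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan, math.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# severity report

#: grouping schemes: name -> (positive grades, negative grades)
GROUPING_SCHEMES: Dict[str, Tuple[Tuple[str, ...], Tuple[str, ...]]] = {
    "diabetic_vs_nondiabetic": (GRADES[1:], ("nondiabetic",)),
    "dr_vs_no_apparent": (GRADES[2:], ("no_apparent",)),
    "referable_vs_milder": (GRADES[3:], ("no_apparent", "mild_npdr")),
    "severe_or_pdr_vs_milder": (
        ("severe_npdr", "pdr"),
        ("no_apparent", "mild_npdr", "moderate_npdr"),
    ),
    "pdr_vs_npdr": (("pdr",), ("mild_npdr", "moderate_npdr", "severe_npdr")),
}

#: spectrum parameter -> score orientation indicating disease
SPECTRUM_PARAMETERS: Dict[str, str] = {
    "total_count": "lower",
    "mean_area_mm2": "higher",
    "mean_perimeter_mm": "higher",
    "mean_min_diameter_mm": "higher",
    "mean_max_diameter_mm": "higher",
    "count_area_above_0.03": "higher",
    "count_ap_above_0.025": "higher",
}


def _roc_to_dict(r: ROCResult) -> dict:
    return {
        "auc": r.auc,
        "se": r.se,
        "ci95": list(r.ci95),
        "orientation": r.orientation,
        "n_pos": r.n_pos,
        "n_neg": r.n_neg,
    }


def _comparison_to_dict(c: GroupComparison) -> dict:
    return {
        "test": c.test,
        "groups": list(c.groups),
        "statistic": c.statistic,
        "p_raw": c.p_raw,
        "p_adjusted": c.p_adjusted,
        "medians": {k: list(v) for k, v in c.medians.items()},
    }


def severity_report(
    cohort: pd.DataFrame,
    parameters: Optional[Dict[str, str]] = None,
    ap_criterion_column: str = "count_ap_above_0.025",
) -> dict:
    """Full statistical report of a cohort of EyeSpectrum rows.

    For each spectrum parameter: per-grade median (IQR), Kruskal-Wallis
    with Bonferroni-corrected pairwise tests (when >= 2 grades present),
    and a ROC/AUC block per grouping scheme.  A contingency block tests
    whether having >= 1 space with area/perimeter ratio above 0.025
    separates severe NPDR / PDR from milder diabetic grades (Fisher
    exact).  Groupings with an empty class are skipped with a warning.
    """
    if "grade" not in cohort.columns:
        raise ValueError("cohort table must have a 'grade' column")
    bad = set(cohort["grade"]) - set(GRADES)
    if bad:
        raise ValueError(f"unknown grades: {sorted(bad)}")
    if parameters is None:
        parameters = {
            k: v for k, v in SPECTRUM_PARAMETERS.items() if k in cohort.columns
        }

    grades_present = [g for g in GRADES if (cohort["grade"] == g).any()]
    report: dict = {"n_eyes": int(len(cohort)), "grades": grades_present, "parameters": {}}

    for param, orientation in parameters.items():
        block: dict = {"orientation": orientation, "by_grade": {}, "tests": [], "roc": {}}
        values = cohort[param].astype(float)
        for g in grades_present:
            block["by_grade"][g] = list(_median_iqr(values[cohort["grade"] == g].to_numpy()))
        if len(grades_present) >= 2:
            groups = [
                values[cohort["grade"] == g].to_numpy() for g in grades_present
            ]
            block["tests"] = [
                _comparison_to_dict(c)
                for c in kruskal_pairwise(groups, labels=grades_present)
            ]
        for scheme, (pos, neg) in GROUPING_SCHEMES.items():
            mask_pos = cohort["grade"].isin(pos)
            mask_neg = cohort["grade"].isin(neg)
            if not mask_pos.any() or not mask_neg.any():
                warnings.warn(f"grouping {scheme}: empty class, ROC skipped")
                continue
            sel = mask_pos | mask_neg
            r = roc_auc(
                values[sel].to_numpy(),
                mask_pos[sel].to_numpy(),
                orientation=orientation,
            )
            block["roc"][scheme] = _roc_to_dict(r)
        report["parameters"][param] = block

    if ap_criterion_column in cohort.columns:
        pos, neg = GROUPING_SCHEMES["severe_or_pdr_vs_milder"]
        in_pos = cohort["grade"].isin(pos)
        in_neg = cohort["grade"].isin(neg)
        if in_pos.any() and in_neg.any():
            has = cohort[ap_criterion_column].astype(float) >= 1
            tab = (
                (int((in_pos & has).sum()), int((in_pos & ~has).sum())),
                (int((in_neg & has).sum()), int((in_neg & ~has).sum())),
            )
            res = fisher_exact(tab)
            report["ap_criterion_contingency"] = {
                "criterion": f"{ap_criterion_column} >= 1",
                "groups": ["severe_npdr+pdr", "no_apparent+mild+moderate"],
                "table": [list(tab[0]), list(tab[1])],
                "pct_with_criterion": list(res.row_pct),
                "odds_ratio": res.odds_ratio,
                "p_fisher_two_sided": res.p_exact,
                "p_chi2": res.p_chi2,
            }
    return report
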