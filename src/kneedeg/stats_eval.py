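"""Statistical evaluation of paired model results and cohort outcomes.

Covers the evaluation toolkit of the workflow: Bland-Altman agreement
between constitutive models, ROC/AUC classification of progression
scores (healthy vs. osteoarthritic knees), non-parametric group tests
(Mann-Whitney U between KL groups, Wilcoxon signed-rank between model
arms), and the Pearson regression of model differences against the
cartilage thickness scaling factor.

Conventions: AUC is computed with the rank (Mann-Whitney) formulation
with midranks for ties; "R^2" is the squared Pearson correlation with
its sign reported separately; all tests are two-sided; no
multiple-testing correction is applied (reported in the output).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedModelResults",
    "bland_altman",
    "roc_auc",
    "group_tests",
    "scaling_regression",
    "paired_from_results",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class PairedModelResults:
    """Per-knee aligned summaries for two material models.

    ``table`` has one row per knee with columns ``knee_id``,
    ``kl_group``, ``pain``, ``thickness_factor``, ``<resp>_a``,
    ``<resp>_b`` (window summaries for each arm) and ``D_a``/``D_b``
    (predicted degeneration progression).  Knees missing from either
    arm are excluded and listed in ``excluded`` -- never dropped
    silently.
    """

    model_a: str
    model_b: str
    table: pd.DataFrame
    excluded: list[str] = field(default_factory=list)


def paired_from_results(results_a: dict, results_b: dict,
                        model_a: str, model_b: str,
                        response: str = "tensile_stress",
                        D_a: dict | None = None,
                        D_b: dict | None = None) -> PairedModelResults:
    """Align two per-knee result dictionaries into one paired table."""
    common = sorted(set(results_a) & set(results_b))
    excluded = sorted(set(results_a) ^ set(results_b))
    rows = []
    for kid in common:
        ra, rb = results_a[kid], results_b[kid]
        pa, pb = ra.peak_summary(response), rb.peak_summary(response)
        row = {
            "knee_id": kid, "kl_group": ra.kl_group, "pain": ra.pain,
            "thickness_factor": ra.thickness_factor,
            f"{response}_mean_a": pa["mean"], f"{response}_peak_a": pa["peak"],
            f"{response}_mean_b": pb["mean"], f"{response}_peak_b": pb["peak"],
        }
        if D_a is not None:
            row["D_a"] = D_a.get(kid, np.nan)
        if D_b is not None:
            row["D_b"] = D_b.get(kid, np.nan)
        rows.append(row)
    return PairedModelResults(model_a, model_b, pd.DataFrame(rows), excluded)


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------

def bland_altman(a, b) -> dict[str, float]:
    """Agreement between paired measurements.

    Returns the mean difference ``a - b`` and the limits of agreement
    (mean +- 1.96 sample SD of the differences).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-d and paired")
    if len(a) < 2:
        raise ValueError("Bland-Altman needs at least two pairs")
    d = a - b
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    return {"mean_diff": md, "sd_diff": sd,
            "lower_limit": md - 1.96 * sd, "upper_limit": md + 1.96 * sd,
            "mean_of_pairs": (a + b) / 2.0, "differences": d}


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(scores, labels) -> dict:
    """AUC via the rank (Mann-Whitney) formulation with midranks for ties.

    ``labels`` are binary with 1 = disease-positive; higher scores must
    indicate higher predicted risk.  Also returns ROC curve points
    (computed independently by threshold sweeping).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("both classes must be present")
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    ranks = stats.rankdata(scores)          # midranks
    auc = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    # threshold sweep for the curve
    thresh = np.unique(scores)[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for t in thresh:
        pred = scores >= t
        tpr.append(float((pred & (labels == 1)).sum()) / n1)
        fpr.append(float((pred & (labels == 0)).sum()) / n0)
    return {"auc": float(auc),
            "fpr": np.asarray(fpr), "tpr": np.asarray(tpr)}


# ---------------------------------------------------------------------------
# group tests
# ---------------------------------------------------------------------------

def group_tests(groups: dict[str, np.ndarray],
                paired_arms: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
                ) -> pd.DataFrame:
    """Mann-Whitney U between groups; Wilcoxon signed-rank within arms.

    ``groups`` maps group name to progression scores; every unordered
    pair of groups is tested (two-sided, exact for small samples
    without ties).  ``paired_arms`` maps a label (e.g. a KL group) to
    the two aligned model arms to compare with the Wilcoxon signed-rank
    test; all-zero differences are flagged degenerate rather than
    raised.  Significance flags: * p < 0.05, ** p < 0.01.
    """
    rows = []
    names = sorted(groups)
    for i, ga in enumerate(names):
        for gb in names[i + 1:]:
            x, y = np.asarray(groups[ga]), np.asarray(groups[gb])
            if len(x) < 2 or len(y) < 2:
                raise ValueError("group sizes must be at least 2")
            res = stats.mannwhitneyu(x, y, alternative="two-sided")
            rows.append({"test": "mannwhitney", "pair": f"{ga} vs {gb}",
                         "stat": float(res.statistic), "p": float(res.pvalue),
                         "flag": _stars(res.pvalue), "degenerate": False})
    for label, (a, b) in (paired_arms or {}).items():
        a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
        if a.shape != b.shape:
            raise ValueError("paired arms must align")
        d = a - b
        if np.allclose(d, 0.0):
            rows.append({"test": "wilcoxon", "pair": label, "stat": np.nan,
                         "p": np.nan, "flag": "", "degenerate": True})
            continue
        res = stats.wilcoxon(a, b, alternative="two-sided")
        rows.append({"test": "wilcoxon", "pair": label,
                     "stat": float(res.statistic), "p": float(res.pvalue),
                     "flag": _stars(res.pvalue), "degenerate": False})
    return pd.DataFrame(rows)


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# thickness-scaling regression
# ---------------------------------------------------------------------------

def scaling_regression(differences, scaling_factors) -> dict[str, float]:
    """Pearson correlation of per-knee model differences vs. thickness scaling.

    Returns R^2 (squared correlation), the correlation sign, and the
    two-sided p-value.  Zero variance in either variable is reported as
    undefined instead of raising.
    """
    d = np.asarray(differences, dtype=float)
    s = np.asarray(scaling_factors, dtype=float)
    if len(d) != len(s) or len(d) < 3:
        raise ValueError("need at least three paired knees")
    if np.ptp(d) == 0.0 or np.ptp(s) == 0.0:
        return {"r2": np.nan, "sign": 0.0, "p": np.nan, "defined": False}
    r, p = stats.pearsonr(d, s)
    return {"r2": float(r * r), "sign": float(np.sign(r)),
            "p": float(p), "defined": True}
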