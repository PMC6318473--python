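"""Session-covariate analyses: fasting contrasts and lifestyle regressions.

Fasting/non-fasting session scores are compared with a pooled-variance
two-sample t-test (df = n1 + n2 − 2); within-group brain–behavior score
correlations are compared with Fisher's z; and lifestyle variables are
screened with simple per-covariate linear regressions under
Benjamini–Hochberg FDR control across the whole covariate × score-type
family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupContrast",
    "CorrelationComparison",
    "fisher_z_test",
    "group_compare_scores",
    "per_group_score_correlation",
    "lifestyle_regression",
]


def fisher_z_test(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Fisher z test for the difference of two independent correlations.

    z = (atanh r1 − atanh r2) / sqrt(1/(n1−3) + 1/(n2−3)); two-sided
    normal p.
    """
    if min(n1, n2) <= 3:
        raise ValueError("Fisher transform needs more than 3 observations per group")
    if max(abs(r1), abs(r2)) >= 1:
        raise ValueError("|r| = 1: Fisher transform undefined")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    return float(z), float(2 * stats.norm.sf(abs(z)))


@dataclass
class GroupContrast:
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    group_means: tuple[float, float]
    group_ns: tuple[int, int]


@dataclass
class CorrelationComparison:
    r1: float
    n1: int
    r2: float
    n2: int
    fisher_z: float
    p_value: float


def group_compare_scores(scores: np.ndarray, group: np.ndarray) -> GroupContrast:
    """Pooled-variance two-sample t-test of session scores between two groups.

    ``group`` is a binary indicator; group 1 minus group 0 ordering for
    the sign of t.
    """
    scores = np.asarray(scores, dtype=float)
    group = np.asarray(group).astype(bool)
    a, b = scores[group], scores[~group]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 sessions")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return GroupContrast(
        t_statistic=float(t),
        degrees_of_freedom=a.size + b.size - 2,
        p_value=float(p),
        group_means=(float(a.mean()), float(b.mean())),
        group_ns=(a.size, b.size),
    )


def per_group_score_correlation(
    x_scores: np.ndarray, y_scores: np.ndarray, group: np.ndarray
) -> CorrelationComparison:
    """Within-group score correlations and a Fisher z test of their difference.

    z = (atanh r1 − atanh r2) / sqrt(1/(n1−3) + 1/(n2−3)), two-sided
    normal p.
    """
    x_scores = np.asarray(x_scores, dtype=float)
    y_scores = np.asarray(y_scores, dtype=float)
    group = np.asarray(group).astype(bool)
    r_n = []
    for g in (group, ~group):
        if g.sum() <= 3:
            raise ValueError("Fisher transform needs more than 3 sessions per group")
        r = stats.pearsonr(x_scores[g], y_scores[g])[0]
        r_n.append((float(r), int(g.sum())))
    (r1, n1), (r2, n2) = r_n
    z, p = fisher_z_test(r1, n1, r2, n2)
    return CorrelationComparison(r1, n1, r2, n2, z, p)


def lifestyle_regression(
    scores: Mapping[str, np.ndarray] | pd.DataFrame,
    covariate_table: pd.DataFrame,
) -> pd.DataFrame:
    """Simple per-covariate regressions of each score type, BH-corrected.

    ``scores`` maps score-type name (e.g. ``network``, ``mood``) to a
    per-session vector.  One ordinary least-squares fit is run per
    (covariate, score type) pair; Benjamini–Hochberg q-values are
    computed across the whole family.  Constant covariates are excluded
    with a warning.
    """
    if isinstance(scores, pd.DataFrame):
        scores = {c: scores[c].to_numpy() for c in scores.columns}
    rows = []
    for cov in covariate_table.columns:
        x = covariate_table[cov].to_numpy(dtype=float)
        if np.std(x) == 0:
            warnings.warn(f"constant covariate {cov!r} excluded from the family")
            continue
        for score_name, y in scores.items():
            res = stats.linregress(x, np.asarray(y, dtype=float))
            rows.append(
                {
                    "covariate": cov,
                    "score_type": score_name,
                    "slope": res.slope,
                    "r": res.rvalue,
                    "p_value": res.pvalue,
                }
            )
    out = pd.DataFrame(rows)
    if out.empty:
        raise ValueError("no usable covariates")
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out
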