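"""Contingency-table and rank-based tests for cohort characteristic tables.

These reproduce the desk-checkable statistics of a study's "Table 1":
Pearson's chi-squared test on categorical characteristics by exposure group
and the Wilcoxon rank-sum test on continuous ones.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .types import ValidationError


def pearson_chi2(table, continuity_correction: bool = False
                 ) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence on an r x c count table.

    Returns (chi2, df, p).  Expected counts come from the independence
    margins; df = (r-1)(c-1).  The optional Yates continuity correction is
    allowed for 2x2 tables only.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValidationError("table must be at least 2 x 2")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValidationError("table entries must be non-negative integer counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValidationError("every row and column sum must be positive")
    if continuity_correction and t.shape != (2, 2):
        raise ValidationError("continuity correction applies to 2x2 tables only")
    chi2, p, df, _ = stats.chi2_contingency(t, correction=continuity_correction)
    return float(chi2), int(df), float(p)


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Returns (rank-sum statistic of the first sample, p).  The exact null
    distribution is used for small tie-free samples; otherwise the
    tie-corrected normal approximation applies.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both samples must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    # report the classical rank-sum W of x: U + n_x (n_x + 1) / 2
    w = float(res.statistic) + len(x) * (len(x) + 1) / 2.0
    return w, float(res.pvalue)
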