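"""Group-level hypothesis tests and clinical correlation.

Metric distributions are compared between groups with the two-sample
two-sided Kolmogorov–Smirnov test on pooled per-component values (Z-scores
by default in the pipeline, raw values equally accepted), with family-wise
significance flagged by the Šidák correction: a raw P value is significant
at family level alpha when it falls below 1 - (1 - alpha)^(1/m) for a
family of m tests.

Clinical correlation is aggregated per subject: the
metric is averaged over that subject's components of one configured size
(subjects lacking such components are dropped), and the per-subject means
are correlated with the UPDRS score by Pearson's r with the usual
t-distributed two-sided P value.

Robustness utilities for imbalanced groups: leave-one-subject-out metric
stability and random subsampling of the larger group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mitotopo.errors import InvalidParameterError

__all__ = [
    "TestResult",
    "ks_compare",
    "sidak_threshold",
    "apply_sidak",
    "correlate_clinical",
    "subject_mean_at_size",
    "loso_stability",
    "subsample_stability",
]

# exact two-sample KS p-values below this per-side n, asymptotic above
_EXACT_KS_MAX_N = 25


@dataclass
class TestResult:
    """One metric's two-group comparison."""

    metric: str
    statistic: float
    p_raw: float
    n1: int
    n2: int
    significant_after_sidak: bool | None = None


def ks_compare(
    values_a: Sequence[float], values_b: Sequence[float], metric: str = ""
) -> TestResult:
    """Two-sample two-sided Kolmogorov–Smirnov test on pooled values."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise InvalidParameterError("both samples must be non-empty")
    method = (
        "exact"
        if max(a.size, b.size) <= _EXACT_KS_MAX_N
        else "asymp"
    )
    res = stats.ks_2samp(a, b, alternative="two-sided", method=method)
    return TestResult(
        metric=metric,
        statistic=float(res.statistic),
        p_raw=float(res.pvalue),
        n1=int(a.size),
        n2=int(b.size),
    )


def sidak_threshold(alpha: float = 0.05, m: int = 1) -> float:
    """Per-test threshold 1 - (1 - alpha)^(1/m) for a family of m tests."""
    if m < 1:
        raise InvalidParameterError("family size m must be >= 1")
    if not 0 < alpha < 1:
        raise InvalidParameterError("alpha must lie in (0, 1)")
    return 1.0 - (1.0 - alpha) ** (1.0 / m)


def apply_sidak(
    results: Sequence[TestResult], alpha: float = 0.05
) -> list[TestResult]:
    """Flag each raw P value against the Šidák family threshold (in place).

    The family size is the number of tests passed in — one family per
    comparison panel.
    """
    thr = sidak_threshold(alpha, len(results))
    for r in results:
        r.significant_after_sidak = r.p_raw <= thr
    return list(results)


def subject_mean_at_size(
    table: pd.DataFrame, metric: str, size: int
) -> pd.Series:
    """Per-subject mean of a metric over components of exactly one size.

    Subjects without any size-``size`` component (or with only undefined
    values there) are absent from the result.
    """
    sel = table[table["size"] == size]
    means = sel.groupby("subject_id")[metric].mean()
    return means.dropna()


def correlate_clinical(
    per_subject_values: Sequence[float], updrs_scores: Sequence[float]
) -> tuple[float, float]:
    """Pearson r between per-subject metric means and UPDRS, with P value.

    Pairs with a missing entry on either side are dropped; at least 3
    complete pairs are required.
    """
    x = np.asarray(per_subject_values, dtype=float)
    y = np.asarray(updrs_scores, dtype=float)
    if x.shape != y.shape:
        raise InvalidParameterError("paired arrays must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise InvalidParameterError(
            f"need >= 3 complete subject pairs, got {x.size}"
        )
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def loso_stability(
    table: pd.DataFrame, metric: str, group_col: str = "group"
) -> pd.DataFrame:
    """Leave-one-subject-out group means: metric stability report.

    For each subject, recompute each group's pooled mean of ``metric``
    with that subject removed.  Small spread across rows indicates the
    group contrast is not driven by any single subject.
    """
    rows = []
    for sid in table["subject_id"].unique():
        rest = table[table["subject_id"] != sid]
        means = rest.groupby(group_col)[metric].mean()
        rows.append({"left_out": sid, **means.to_dict()})
    return pd.DataFrame(rows)


def subsample_stability(
    table: pd.DataFrame,
    metric: str,
    group: str,
    n_subjects: int,
    n_repeats: int = 100,
    rng: np.random.Generator | int | None = None,
    group_col: str = "group",
) -> pd.DataFrame:
    """Random subject subsamples of one (larger) group: mean stability.

    Repeats ``n_repeats`` times: draw ``n_subjects`` subjects of ``group``
    without replacement and record the pooled metric mean — the balanced
    re-comparison used when group sizes are unequal.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    sids = table.loc[table[group_col] == group, "subject_id"].unique()
    if n_subjects > sids.size:
        raise InvalidParameterError(
            f"cannot draw {n_subjects} of {sids.size} subjects"
        )
    rows = []
    for rep in range(n_repeats):
        chosen = rng.choice(sids, size=n_subjects, replace=False)
        sel = table[table["subject_id"].isin(chosen)]
        rows.append(
            {"repeat": rep, "mean": sel[metric].mean(), "n_components":
             len(sel)}
        )
    return pd.DataFrame(rows)
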