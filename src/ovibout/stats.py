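"""Pairwise group comparisons with automated test selection.

The selection rule, applied per comparison:

1. test each sample for normality with Shapiro–Wilk *and* D'Agostino's
   K² (both must pass in both samples, at ``alpha_assumptions``);
2. for normal data, test variance homogeneity with Bartlett's test:
   equal variances → Student's t, unequal → Welch's t;
3. any normality failure → two-sided Mann–Whitney U.

Fisher's exact test handles 2×2 contingency endpoints.  No
multiple-testing correction is applied anywhere: results are
per-comparison p-values, exactly as reported, and callers comparing many
metrics should account for that themselves.

Significance stars follow the usual convention: ``*`` p<0.05, ``**``
p<0.01, ``***`` p<0.001, ``****`` p<0.0001, ``ns`` otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["ComparisonResult", "compare_groups", "fisher_2x2", "stars"]


def stars(p_value: float) -> str:
    """Significance stars at the conventional printed thresholds."""
    if not 0.0 <= p_value <= 1.0:
        raise ValueError(f"p-value must be in [0, 1], got {p_value}")
    for threshold, mark in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")):
        if p_value < threshold:
            return mark
    return "ns"


@dataclass
class ComparisonResult:
    """A chosen test, its outcome, and the decision trail that picked it."""

    metric: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    test: str  # mann_whitney | t | t_welch | fisher_exact
    statistic: float
    p_value: float
    stars: str
    normal_a: Optional[bool] = None
    normal_b: Optional[bool] = None
    equal_variance: Optional[bool] = None
    n_dropped: int = 0
    decisions: list = field(default_factory=list)

    def to_row(self) -> dict:
        return {
            "metric": self.metric,
            "group_a": self.group_a,
            "group_b": self.group_b,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "stars": self.stars,
            "decision_trail": " | ".join(self.decisions),
        }


def _drop_undefined(values: Sequence) -> tuple:
    kept = [float(v) for v in values if v is not None and not math.isnan(float(v))]
    return np.asarray(kept, dtype=float), len(values) - len(kept)


def _is_normal(sample: np.ndarray, alpha: float, decisions: list, label: str) -> bool:
    """Normal iff Shapiro–Wilk AND D'Agostino K² both fail to reject."""
    if np.ptp(sample) == 0:
        decisions.append(f"{label}: constant sample, treated as non-normal")
        return False
    p_shapiro = sps.shapiro(sample).pvalue
    if len(sample) >= 8:
        p_dagostino = sps.normaltest(sample).pvalue
    else:
        # K² needs n >= 8; Shapiro alone decides for smaller samples
        p_dagostino = math.inf
    ok = p_shapiro > alpha and p_dagostino > alpha
    decisions.append(
        f"{label}: shapiro p={p_shapiro:.4g}, dagostino "
        f"{'skipped (n<8)' if p_dagostino == math.inf else f'p={p_dagostino:.4g}'}"
        f" -> {'normal' if ok else 'non-normal'}"
    )
    return ok


def compare_groups(
    values_a: Sequence,
    values_b: Sequence,
    *,
    metric: str = "",
    group_a: str = "a",
    group_b: str = "b",
    alpha_assumptions: float = 0.05,
) -> ComparisonResult:
    """Compare two samples with the normality-gated test-selection rule.

    ``None``/NaN entries (undefined per-fly metrics) are dropped first and
    the dropped count is reported.  Samples smaller than 3 after dropping
    raise ``ValueError`` — normality testing is undefined there.
    """
    a, dropped_a = _drop_undefined(values_a)
    b, dropped_b = _drop_undefined(values_b)
    if len(a) < 3 or len(b) < 3:
        raise ValueError(
            f"need >= 3 defined values per group, got {len(a)} and {len(b)}"
        )
    decisions: list = []
    if dropped_a or dropped_b:
        decisions.append(f"dropped undefined: {dropped_a} from {group_a}, {dropped_b} from {group_b}")

    normal_a = _is_normal(a, alpha_assumptions, decisions, group_a)
    normal_b = _is_normal(b, alpha_assumptions, decisions, group_b)
    equal_var: Optional[bool] = None
    if normal_a and normal_b:
        p_bartlett = sps.bartlett(a, b).pvalue
        equal_var = bool(p_bartlett > alpha_assumptions)
        decisions.append(
            f"bartlett p={p_bartlett:.4g} -> "
            f"{'equal' if equal_var else 'unequal'} variances"
        )
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        test = "t" if equal_var else "t_welch"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        test = "mann_whitney"
    decisions.append(f"selected {test}")
    p = min(float(res.pvalue), 1.0)  # guard float round-up past 1
    return ComparisonResult(
        metric=metric,
        group_a=group_a,
        group_b=group_b,
        n_a=len(a),
        n_b=len(b),
        test=test,
        statistic=float(res.statistic),
        p_value=p,
        stars=stars(p),
        normal_a=normal_a,
        normal_b=normal_b,
        equal_variance=equal_var,
        n_dropped=dropped_a + dropped_b,
        decisions=decisions,
    )


def fisher_2x2(table, *, metric: str = "", group_a: str = "a", group_b: str = "b") -> ComparisonResult:
    """Two-sided Fisher's exact test on a 2×2 count table.

    Rows are groups, columns are outcome counts (e.g. flies with /
    without retained eggs).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"table must be 2x2, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("table entries must be non-negative")
    if t.sum() == 0:
        raise ValueError("table total must be positive")
    if not np.array_equal(t, np.floor(t)):
        raise ValueError("table entries must be integer counts")
    odds, p = sps.fisher_exact(t.astype(int), alternative="two-sided")
    p = min(float(p), 1.0)
    return ComparisonResult(
        metric=metric,
        group_a=group_a,
        group_b=group_b,
        n_a=int(t[0].sum()),
        n_b=int(t[1].sum()),
        test="fisher_exact",
        statistic=float(odds),
        p_value=p,
        stars=stars(p),
        decisions=["fisher exact, two-sided"],
    )
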