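"""Two-sided Mann-Whitney rank-sum comparison and summary tables.

The rank-sum test is implemented natively: exact null enumeration for small
tie-free samples, otherwise the normal approximation with tie and continuity
corrections.  No external statistics package is called on this path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata  # ranking utility only, not a test

_EXACT_LIMIT = 12  # exact enumeration when n1 + n2 <= this and no ties


@dataclass
class GroupComparison:
    metric: str
    group_labels: tuple[str, str]
    n: tuple[int, int]
    medians: tuple[float, float]
    u_statistic: float  # U of the first sample
    p_two_sided: float
    method: str  # "exact" | "normal_approx_tie_corrected"

    def significance(self, alpha: float = 0.05) -> str:
        return "ns" if self.p_two_sided > alpha else "*"


def _exact_two_sided_p(u: float, n1: int, n2: int) -> float:
    """Two-sided p by full enumeration of rank assignments (tie-free)."""
    n = n1 + n2
    ranks = range(1, n + 1)
    min_r1 = n1 * (n1 + 1) // 2
    lo = min(u, n1 * n2 - u)
    hi = n1 * n2 - lo
    count = total = 0
    for combo in combinations(ranks, n1):
        total += 1
        u_i = sum(combo) - min_r1
        if u_i <= lo + 1e-9 or u_i >= hi - 1e-9:
            count += 1
    return count / total


def rank_sum_test(
    x: Sequence[float],
    y: Sequence[float],
    metric: str = "",
    labels: tuple[str, str] = ("x", "y"),
) -> GroupComparison:
    """Two-sided Mann-Whitney rank-sum test of two independent samples."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0  # U statistic of x

    has_ties = np.unique(pooled).size < pooled.size
    if n1 + n2 <= _EXACT_LIMIT and not has_ties:
        p = _exact_two_sided_p(u, n1, n2)
        method = "exact"
    else:
        mu = n1 * n2 / 2.0
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts).sum()))
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if sigma2 <= 0:  # all values identical
            p = 1.0
        else:
            z = max(abs(u - mu) - 0.5, 0.0) / math.sqrt(sigma2)
            p = min(1.0, math.erfc(z / math.sqrt(2.0)))
        method = "normal_approx_tie_corrected"
    return GroupComparison(
        metric=metric,
        group_labels=labels,
        n=(n1, n2),
        medians=(float(np.median(x)), float(np.median(y))),
        u_statistic=float(u),
        p_two_sided=float(p),
        method=method,
    )


def summarize(groups: Mapping[str, Sequence[float]]):
    """mean, sample SD (n-1), median and n per group, in the 'mean +/- SD'
    reporting style.  Single-value groups get SD 0 and a flag."""
    import pandas as pd

    rows = []
    for name, values in groups.items():
        v = np.asarray(list(values), dtype=float)
        if v.size == 0:
            raise ValueError(f"group {name!r} has no values")
        rows.append(
            {
                "group": name,
                "n": int(v.size),
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
                "median": float(np.median(v)),
                "single_value": bool(v.size == 1),
            }
        )
    return pd.DataFrame(rows)


def comparisons_to_frame(comparisons: Sequence[GroupComparison]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "metric": c.metric,
                "group_a": c.group_labels[0],
                "group_b": c.group_labels[1],
                "n_a": c.n[0],
                "n_b": c.n[1],
                "median_a": c.medians[0],
                "median_b": c.medians[1],
                "U": c.u_statistic,
                "p_two_sided": c.p_two_sided,
                "method": c.method,
                "significance": c.significance(),
            }
            for c in comparisons
        ]
    )
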