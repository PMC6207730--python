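"""Nonparametric comparison of precursor descriptor distributions.

Species or family groups of pre-miRNAs are compared variable-by-variable
(MFE, AMFE, MFEI, GC%, length, ...) with the Wilcoxon-Mann-Whitney rank-sum
test; medians summarise each group. The U statistic uses midranks for ties.
The two-sided p-value is computed by exact enumeration of rank assignments
for small untied samples (n_a + n_b <= 16) and otherwise by the normal
approximation with tie and continuity corrections. No multiplicity
adjustment is applied by default, matching common practice in descriptor
surveys; Benjamini-Hochberg is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, sqrt
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    median_a: float
    median_b: float
    significant: bool
    alpha: float


def _exact_two_sided_p(ranks: np.ndarray, n_a: int, u_obs: float) -> float:
    """Exact two-sided p by full enumeration of the C(N, n_a) assignments.

    Only called for untied pooled samples, where ranks are a permutation of
    1..N and U is integral: p = 2 * P(U <= min(U_a, U_b)), capped at 1.
    """
    n = ranks.size
    n_b = n - n_a
    offset = n_a * (n_a + 1) / 2.0
    u_min = min(u_obs, n_a * n_b - u_obs)
    count = 0
    for idx in combinations(range(n), n_a):
        u = sum(ranks[list(idx)]) - offset
        if min(u, n_a * n_b - u) <= u_min + 1e-9:
            count += 1
    return min(1.0, count / comb(n, n_a))


def mann_whitney(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    alpha: float = 0.1,
    variable: str = "",
    group_a: str = "a",
    group_b: str = "b",
    exact_limit: int = 16,
) -> GroupComparison:
    """Wilcoxon-Mann-Whitney rank-sum comparison of two samples.

    U is computed by rank summation with midranks for ties. The p-value is
    two-sided: exact enumeration when the pooled size is at most
    ``exact_limit`` and there are no ties, else the normal approximation
    with tie correction and a 0.5 continuity correction. Degenerate pooled
    samples (zero rank variance) give p = 1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_a = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0)

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = np.any(tie_counts > 1)
    n = n_a + n_b
    if not has_ties and n <= exact_limit:
        p = _exact_two_sided_p(ranks, n_a, u_a)
    else:
        mu = n_a * n_b / 2.0
        tie_term = float(((tie_counts ** 3 - tie_counts)).sum()) / (n * (n - 1)) if n > 1 else 0.0
        var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            p = 1.0
        else:
            diff = u_a - mu
            cc = 0.5 if diff != 0 else 0.0
            z = (abs(diff) - cc) / sqrt(var)
            p = min(1.0, 2.0 * sps.norm.sf(max(z, 0.0)))
    return GroupComparison(
        variable=variable,
        group_a=group_a,
        group_b=group_b,
        n_a=n_a,
        n_b=n_b,
        u_statistic=u_a,
        p_value=float(p),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        significant=p < alpha,
        alpha=alpha,
    )


def compare_descriptor_tables(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    variables: Sequence[str],
    alpha: float = 0.1,
    group_a: str = "a",
    group_b: str = "b",
    adjust: Optional[str] = None,
) -> List[GroupComparison]:
    """One Mann-Whitney comparison per descriptor variable.

    ``adjust="bh"`` applies Benjamini-Hochberg across the variable list
    (re-deriving the significance flags); the default applies none.
    """
    for var in variables:
        for name, tab in ((group_a, table_a), (group_b, table_b)):
            if var not in tab.columns:
                raise ValueError(f"variable {var!r} missing from table {name!r}")
    comparisons = [
        mann_whitney(
            table_a[var].dropna().to_numpy(),
            table_b[var].dropna().to_numpy(),
            alpha=alpha, variable=var, group_a=group_a, group_b=group_b,
        )
        for var in variables
    ]
    if adjust == "bh":
        ps = np.array([c.p_value for c in comparisons])
        order = np.argsort(ps)
        m = len(ps)
        adj = np.empty(m)
        running = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            running = min(running, ps[i] * m / (rank_idx + 1))
            adj[i] = running
        comparisons = [
            GroupComparison(
                variable=c.variable, group_a=c.group_a, group_b=c.group_b,
                n_a=c.n_a, n_b=c.n_b, u_statistic=c.u_statistic,
                p_value=float(adj[i]), median_a=c.median_a, median_b=c.median_b,
                significant=adj[i] < alpha, alpha=alpha,
            )
            for i, c in enumerate(comparisons)
        ]
    return comparisons


def comparisons_to_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in comparisons])
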