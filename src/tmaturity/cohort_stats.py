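"""Two-arm cohort comparison: medians, Mann-Whitney U, Fisher's exact test.

Comparisons are two-sided throughout and reported as raw significance
tiers (NS, <0.05, <0.01) without multiple-testing correction, matching
standard clinical immunophenotyping reports; Benjamini-Hochberg q-values
can be added as an extra column on request.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._errors import ConfigurationError

__all__ = ["mann_whitney", "fisher_exact", "compare_cohorts", "SUBSET_ORDER"]

#: Output ordering: basic subsets, then the maturation pathway.
_MATURATION = ("RTE", "TN", "TSCM", "TCM", "TEM", "LTEMRA", "HTEMRA",
               "TEMRA", "TD", "CD57", "KLRG1", "PD1")
SUBSET_ORDER: tuple[str, ...] = (
    ("lymphocytes", "T", "B", "NK", "CD4", "CD8")
    + tuple(f"{b}_CD4" for b in _MATURATION)
    + tuple(f"{b}_CD8" for b in _MATURATION)
)

#: Exact null enumeration is used up to this product of sample sizes.
_EXACT_LIMIT = 400


def mann_whitney(x, y, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U, p)`` with ``U = min(U_x, U_y)``.  ``mode='auto'`` uses the
    exact null distribution when ``n_x * n_y <= 400`` and the pooled sample
    is tie-free, otherwise the normal approximation with tie-corrected
    variance and continuity correction.  Identical samples degenerate to
    ``p = 1`` with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ConfigurationError("both samples must be non-empty")
    if mode not in ("auto", "exact", "normal"):
        raise ConfigurationError(f"unknown mann_whitney mode {mode!r}")
    nxy = x.size * y.size
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("degenerate data: all values identical; p = 1",
                      stacklevel=2)
        return nxy / 2.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "exact" or (mode == "auto" and nxy <= _EXACT_LIMIT and not has_ties):
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u = min(float(res.statistic), nxy - float(res.statistic))
    return u, float(min(res.pvalue, 1.0))


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 count table.

    Two-sided by summation of hypergeometric probabilities not exceeding
    the observed table's probability.  A zero margin carries no
    information: p = 1 with a warning.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ConfigurationError("fisher_exact expects a 2x2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if np.any(t < 0) or np.any(t != np.round(t)):
            raise ConfigurationError("table entries must be non-negative integers")
        t = t.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        warnings.warn("zero margin in 2x2 table; p = 1", stacklevel=2)
        return 1.0
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def _tier(p: float) -> str:
    if p < 0.01:
        return "<0.01"
    if p < 0.05:
        return "<0.05"
    return "NS"


def _order_key(subset: str) -> tuple:
    try:
        return (0, SUBSET_ORDER.index(subset))
    except ValueError:
        return (1, 0)


def compare_cohorts(results_a, results_b, measures=("pct", "abs"),
                    add_bh: bool = False) -> pd.DataFrame:
    """Subset-by-subset two-arm comparison table.

    ``results_a``/``results_b`` are lists of
    :class:`~tmaturity.quantify.SubjectResult`.  For every subset present in
    both arms and each measure (percent of parent, absolute count) the
    table reports arm medians, sample sizes, the Mann-Whitney U statistic,
    its two-sided p, and the significance tier.  Rows follow the
    maturation pathway ordering.  Subsets present in only one arm are
    excluded with a warning.
    """
    if not results_a or not results_b:
        raise ConfigurationError("both cohorts must be non-empty")
    group_a = results_a[0].group or "a"
    group_b = results_b[0].group or "b"

    def collect(results, subset, measure):
        vals = []
        for r in results:
            st = r.stats.get(subset)
            if st is None:
                continue
            v = st.pct_of_parent if measure == "pct" else st.abs_count
            if v is not None:
                vals.append(v)
        return np.array(vals, dtype=float)

    subsets_a = set().union(*(r.stats for r in results_a))
    subsets_b = set().union(*(r.stats for r in results_b))
    for lonely in sorted(subsets_a ^ subsets_b):
        warnings.warn(f"subset {lonely!r} present in only one arm; excluded",
                      stacklevel=2)
    shared = sorted(subsets_a & subsets_b,
                    key=lambda s: (_order_key(s), s))
    rows = []
    for subset in shared:
        for measure in measures:
            va = collect(results_a, subset, measure)
            vb = collect(results_b, subset, measure)
            if va.size == 0 or vb.size == 0:
                continue
            u, p = mann_whitney(va, vb)
            rows.append({
                "subset": subset, "measure": measure,
                f"median_{group_a}": float(np.median(va)),
                f"median_{group_b}": float(np.median(vb)),
                "n_a": va.size, "n_b": vb.size,
                "U": u, "p": p, "tier": _tier(p),
            })
    df = pd.DataFrame(rows)
    if add_bh and len(df):
        m = len(df)
        order = np.argsort(df["p"].to_numpy())
        q = np.empty(m)
        prev = 1.0
        for rank, i in list(enumerate(order, start=1))[::-1]:
            prev = min(prev, df["p"].iloc[i] * m / rank)
            q[i] = prev
        df["q_bh"] = q
    return df
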