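"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the code paths (and libraries) they check:
Mann-Whitney by full enumeration of rank assignments, Fisher's exact by
hypergeometric table enumeration, and a per-event Monte-Carlo acquisition
model for the bead-count formula.
"""

from itertools import combinations
from math import comb

import numpy as np


def mann_whitney_enumeration(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all label assignments.

    Assumes a tie-free pooled sample.  Returns (min-U, p) where p is the
    probability, under random assignment, of a min(U, nm-U) at least as
    extreme (small) as observed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    M = n * m

    def min_u(idx_x):
        xs = pooled[list(idx_x)]
        ys = pooled[[i for i in range(n + m) if i not in idx_x]]
        u = int((xs[:, None] > ys[None, :]).sum())
        return min(u, M - u)

    observed = min_u(tuple(range(n)))
    us = [min_u(c) for c in combinations(range(n + m), n)]
    p = sum(u <= observed for u in us) / len(us)
    return observed, p


def fisher_enumeration(table):
    """Two-sided Fisher p by summing hypergeometric probabilities of all
    tables with the observed margins that are no more probable."""
    (a, b), (c, d) = np.asarray(table, dtype=int)
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if min(r1, r2, c1, n - c1) < 0 or n == 0 or r1 == 0 or r2 == 0 \
            or c1 == 0 or c1 == n:
        return 1.0

    def prob(aa):
        return comb(r1, aa) * comb(r2, c1 - aa) / comb(n, c1)

    p_obs = prob(a)
    return float(sum(prob(aa) for aa in range(max(0, c1 - r2), min(r1, c1) + 1)
                     if prob(aa) <= p_obs * (1 + 1e-9)))


def bead_count_mc_oracle(true_conc, volume_ul, beads_per_tube, acquired_frac,
                         rng, n_reps=40):
    """Monte-Carlo acquisition model of a counting tube.

    Each cell and bead in the tube is acquired independently with
    probability ``acquired_frac``; the estimate is the bead-ratio formula
    applied per repetition.  Returns the mean estimated concentration.
    """
    n_cells = int(round(true_conc * volume_ul))
    ests = []
    for _ in range(n_reps):
        cells = rng.binomial(n_cells, acquired_frac)
        beads = rng.binomial(beads_per_tube, acquired_frac)
        ests.append(cells / beads * beads_per_tube / volume_ul)
    return float(np.mean(ests))


def mann_whitney_permutation_p(x, y, n_resamples, rng):
    """Monte-Carlo permutation two-sided p for the Mann-Whitney statistic.

    Uses the rank-sum identity U = R_x - n(n+1)/2 on the pooled (tie-free)
    sample, so each resample is a single indexed sum.
    """
    from scipy.stats import rankdata

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    M = n * m
    ranks = rankdata(np.concatenate([x, y]))
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    stat_obs = min(u_obs, M - u_obs)
    perms = np.array([rng.permutation(n + m)[:n] for _ in range(n_resamples)])
    u = ranks[perms].sum(axis=1) - n * (n + 1) / 2
    stats = np.minimum(u, M - u)
    return float((stats <= stat_obs + 1e-9).mean())
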