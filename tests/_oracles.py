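"""Independent brute-force oracles, kept free of the package's own code paths."""

import itertools

import numpy as np


def brute_force_bh(p):
    """BH step-up adjusted p-values straight from the definition."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adjusted[i] = running_min
    return np.minimum(adjusted, 1.0)


def exact_permutation_spearman_p(x, y):
    """Two-sided permutation p for Spearman rho by full enumeration."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    rx = _avg_ranks(x)
    ry = _avg_ranks(y)
    rxc = rx - rx.mean()

    def rho_of(ranks):
        rc = ranks - ranks.mean()
        return float(rc @ rxc / np.sqrt((rc ** 2).sum() * (rxc ** 2).sum()))

    observed = abs(rho_of(ry))
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(rho_of(np.array(perm))) >= observed - 1e-12:
            count += 1
    return count / total


def _avg_ranks(v):
    """Average ranks without scipy."""
    v = np.asarray(v, dtype=float)
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(v.size)
    i = 0
    while i < v.size:
        j = i
        while j + 1 < v.size and v[order[j + 1]] == v[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


# Hand-computed UPGMA dendrogram for 1-D points 0, 2, 5, 11:
#   d(a,b)=2 -> merge {a,b} at 2
#   d({ab},c) = mean(5,3) = 4; d(c,d)=6; d({ab},d)=mean(11,9)=10 -> merge at 4
#   d({abc},d) = mean(11,9,6) = 26/3 -> merge at 26/3
UPGMA_4POINT_COORDS = [0.0, 2.0, 5.0, 11.0]
UPGMA_4POINT_HEIGHTS = [2.0, 4.0, 26.0 / 3.0]
SINGLE_LINKAGE_4POINT_HEIGHTS = [2.0, 3.0, 6.0]
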