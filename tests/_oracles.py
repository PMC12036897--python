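"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive: explicit enumeration and factorials
only, no reuse of the package's computational paths.
"""

from __future__ import annotations

import itertools
from math import comb, factorial

import networkx as nx
import numpy as np


def exact_fixed_margin_p(observed: np.ndarray) -> float:
    """Exact Monte-Carlo-target p for the margins-mode omnibus test.

    Enumerates every 3×3 table with the observed margins; each table has
    conditional probability ∏r_i!·∏c_j!/(N!·∏O_ij!) under independence
    with both margins fixed.  Returns the total probability of tables
    whose Pearson X² (margin-based expectations) is >= the observed X².
    """
    O = np.asarray(observed, dtype=int)
    r = O.sum(axis=1)
    c = O.sum(axis=0)
    N = int(O.sum())
    E = np.outer(r, c) / N

    def x2(t: np.ndarray) -> float:
        mask = E > 0
        return float(((t[mask] - E[mask]) ** 2 / E[mask]).sum())

    obs_stat = x2(O.astype(float))
    log_norm = sum(np.log(float(factorial(int(x)))) for x in r) + sum(
        np.log(float(factorial(int(x)))) for x in c
    ) - np.log(float(factorial(N)))

    p = 0.0
    for a in range(min(r[0], c[0]) + 1):
        for b in range(min(r[0] - a, c[1]) + 1):
            g = r[0] - a - b
            if g > c[2]:
                continue
            for d in range(min(r[1], c[0] - a) + 1):
                for e in range(min(r[1] - d, c[1] - b) + 1):
                    f = r[1] - d - e
                    if f > c[2] - g:
                        continue
                    g2 = c[0] - a - d
                    h = c[1] - b - e
                    i = c[2] - g - f
                    if min(g2, h, i) < 0 or g2 + h + i != r[2]:
                        continue
                    t = np.array([[a, b, g], [d, e, f], [g2, h, i]], dtype=float)
                    logp = log_norm - sum(
                        np.log(float(factorial(int(x)))) for x in t.ravel()
                    )
                    if x2(t) >= obs_stat - 1e-9:
                        p += float(np.exp(logp))
    return min(p, 1.0)


def exact_permutation_jaccard_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided permutation p for the centered Jaccard/Tanimoto.

    Enumerates every distinct arrangement of y (all are equally likely
    under a uniform permutation) and counts those whose |cJ/T| is at least
    the observed value.
    """
    x = np.asarray(x, dtype=int)
    y = np.asarray(y, dtype=int)
    n = len(x)
    mA, mB = int(x.sum()), int(y.sum())
    p_, q_ = mA / n, mB / n
    ej = p_ * q_ / (p_ + q_ - p_ * q_)

    def cjt(yy: np.ndarray) -> float:
        n11 = int(np.sum((x == 1) & (yy == 1)))
        denom = mA + mB - n11
        return (n11 / denom if denom else 0.0) - ej

    obs = abs(cjt(y))
    hits = total = 0
    for ones in itertools.combinations(range(n), mB):
        yy = np.zeros(n, dtype=int)
        yy[list(ones)] = 1
        total += 1
        if abs(cjt(yy)) >= obs - 1e-12:
            hits += 1
    return hits / total


def grid_affinity_mle(n11: int, n: int, mA: int, mB: int, cap: float = 10.0,
                      step: float = 1e-3) -> float:
    """Dense-grid maximiser of the noncentral hypergeometric likelihood.

    Evaluates the (unnormalised) log-likelihood
    log C(mA, k) + log C(n-mA, mB-k) + k·a  minus the log partition sum,
    on a grid of log-odds values a.
    """
    kmin = max(0, mA + mB - n)
    kmax = min(mA, mB)
    ks = np.arange(kmin, kmax + 1)
    logw = np.array(
        [np.log(comb(mA, int(k))) + np.log(comb(n - mA, int(mB - k))) for k in ks]
    )
    grid = np.arange(-cap, cap + step, step)
    best_a, best_ll = grid[0], -np.inf
    for a in grid:
        terms = logw + ks * a
        ll = (np.log(comb(mA, n11)) + np.log(comb(n - mA, mB - n11)) + n11 * a
              - (terms.max() + np.log(np.exp(terms - terms.max()).sum())))
        if ll > best_ll:
            best_ll, best_a = ll, a
    return float(best_a)


def brute_force_motif_census(g: nx.Graph) -> dict[str, int]:
    """Census of connected induced subgraphs on 3 and 4 nodes by explicit
    subset enumeration and degree-sequence classification."""
    names = {
        (3, (1, 1, 2)): "path_3",
        (3, (2, 2, 2)): "triangle",
        (4, (1, 1, 1, 3)): "star_4",
        (4, (1, 1, 2, 2)): "path_4",
        (4, (1, 2, 2, 3)): "tadpole",
        (4, (2, 2, 2, 2)): "cycle_4",
        (4, (2, 2, 3, 3)): "diamond",
        (4, (3, 3, 3, 3)): "clique_4",
    }
    counts = {name: 0 for name in names.values()}
    nodes = list(g.nodes)
    for k in (3, 4):
        for subset in itertools.combinations(nodes, k):
            sub = g.subgraph(subset)
            if nx.is_connected(sub):
                key = (k, tuple(sorted(d for _, d in sub.degree())))
                counts[names[key]] += 1
    return counts
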