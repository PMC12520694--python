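"""Independent brute-force reference implementations used only by tests.

Everything here is written with explicit loops and enumeration, sharing no
code path with the package, so agreement is evidence of correctness rather
than tautology.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def average_ranks(values) -> list[float]:
    """Ascending average ranks by pairwise counting (no sorting library)."""
    n = len(values)
    ranks = []
    for v in values:
        below = sum(1 for w in values if w < v)
        ties = sum(1 for w in values if w == v)
        ranks.append(below + (ties + 1) / 2.0)
    return ranks


def ssgsea_brute(expr, gene_ids, member_genes, alpha) -> float:
    """Enrichment score by direct evaluation of the two running sums."""
    n = len(expr)
    member = [g in set(member_genes) for g in gene_ids]
    weights = average_ranks(expr)  # highest expression -> weight n
    order = sorted(range(n), key=lambda i: (-expr[i], gene_ids[i]))
    denom_in = sum(weights[i] ** alpha for i in range(n) if member[i])
    n_out = n - sum(member)
    es = 0.0
    running_in = 0.0
    running_out = 0
    for i in order:
        if member[i]:
            running_in += weights[i] ** alpha
        else:
            running_out += 1
        es += running_in / denom_in - running_out / n_out
    return es


def mann_whitney_u(x, y) -> float:
    """U statistic of x by pairwise comparison, ties credited 0.5."""
    u = 0.0
    for a in x:
        for b in y:
            if a > b:
                u += 1.0
            elif a == b:
                u += 0.5
    return u


def rank_sum_exact_p(x, y) -> float:
    """Two-sided exact p by full enumeration over label assignments."""
    pooled = list(x) + list(y)
    n1, n = len(x), len(pooled)
    mu = n1 * (n - n1) / 2.0
    u_obs = mann_whitney_u(x, y)
    extreme = total = 0
    for idx in combinations(range(n), n1):
        chosen = set(idx)
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n) if i not in chosen]
        total += 1
        if abs(mann_whitney_u(xs, ys) - mu) >= abs(u_obs - mu) - 1e-12:
            extreme += 1
    return extreme / total


def auroc_brute(truth, scores) -> float:
    """AUROC by enumerating every positive-negative pair."""
    pos = [s for t, s in zip(truth, scores) if t]
    neg = [s for t, s in zip(truth, scores) if not t]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def gmm_grid_best_ll(x) -> float:
    """Best log-likelihood over a coarse parameter grid (lower bound for EM)."""
    x = np.asarray(x, dtype=float)
    best = -np.inf
    for mu1 in np.arange(-1.0, 1.01, 0.25):
        for mu2 in np.arange(5.0, 7.01, 0.25):
            for sigma in (0.5, 1.0, 1.5):
                for w in (0.3, 0.5, 0.7):
                    pdf1 = np.exp(-0.5 * ((x - mu1) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
                    pdf2 = np.exp(-0.5 * ((x - mu2) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
                    ll = float(np.log(w * pdf1 + (1 - w) * pdf2).sum())
                    best = max(best, ll)
    return best
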