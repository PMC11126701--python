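"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's pruning/likelihood code paths:
likelihoods come from explicit enumeration over internal-node state
assignments, distances from explicit root-path sums, Wilcoxon p-values
from full enumeration of group assignments.
"""

import itertools
import math

import numpy as np
from scipy.linalg import expm


def enum_loglik(tree, partials, Q, pi):
    """Sum over all internal-node state assignments (tips marginalized)."""
    k = Q.shape[0]
    P = {v: expm(Q * float(tree.lengths[v]))
         for v in range(tree.n_nodes) if tree.parent[v] >= 0}
    internal = [v for v in range(tree.n_nodes) if not tree.is_tip(v)]
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internal)):
        st = dict(zip(internal, assign))
        prob = pi[st[tree.root]]
        for v in internal:
            p = tree.parent[v]
            if p >= 0:
                prob *= P[v][st[p], st[v]]
        for tip in range(tree.n_tips):
            p = tree.parent[tip]
            prob *= float(P[tip][st[p], :] @ partials[tip])
        total += prob
    return math.log(total)


def enum_marginals(tree, partials, Q, pi):
    """Marginal state probabilities at every node by enumeration."""
    k = Q.shape[0]
    P = {v: expm(Q * float(tree.lengths[v]))
         for v in range(tree.n_nodes) if tree.parent[v] >= 0}
    internal = [v for v in range(tree.n_nodes) if not tree.is_tip(v)]
    weights = np.zeros((tree.n_nodes, k))
    for assign in itertools.product(range(k), repeat=len(internal)):
        st = dict(zip(internal, assign))
        prob = pi[st[tree.root]]
        for v in internal:
            p = tree.parent[v]
            if p >= 0:
                prob *= P[v][st[p], st[v]]
        # tip marginals via per-assignment factorization (avoids
        # enumerating tip states jointly)
        tip_factors = []
        for tip in range(tree.n_tips):
            p = tree.parent[tip]
            tip_factors.append(P[tip][st[p], :] * partials[tip])
        base = prob * np.prod([f.sum() for f in tip_factors])
        for v in internal:
            weights[v, st[v]] += base
        for tip in range(tree.n_tips):
            others = prob
            for j, f in enumerate(tip_factors):
                if j != tip:
                    others *= f.sum()
            weights[tip] += others * tip_factors[tip]
    return weights / weights.sum(axis=1, keepdims=True)


def pairwise_distance(tree, a, b):
    """Patristic distance by explicit root-path sums."""

    def path(v):
        out = {}
        d = 0.0
        while v != -1:
            out[v] = d
            d += float(tree.lengths[v]) if tree.parent[v] >= 0 else 0.0
            v = tree.parent[v]
        return out

    pa, pb = path(a), path(b)
    best = np.inf
    for v, da in pa.items():
        if v in pb:
            best = min(best, da + pb[v])
    return best


def exact_rank_sum_p(a, b):
    """Two-sided Wilcoxon rank-sum p by full enumeration of assignments."""
    a, b = list(a), list(b)
    pooled = a + b
    n, m = len(a), len(b)
    ranks = {}
    s = sorted(pooled)
    # midranks for ties
    import collections

    positions = collections.defaultdict(list)
    for i, x in enumerate(s):
        positions[x].append(i + 1)
    rank_of = {x: np.mean(pos) for x, pos in positions.items()}
    obs = sum(rank_of[x] for x in a)
    mean = n * (len(pooled) + 1) / 2.0
    count = 0
    total = 0
    for comb in itertools.combinations(range(len(pooled)), n):
        w = sum(rank_of[pooled[i]] for i in comb)
        total += 1
        if abs(w - mean) >= abs(obs - mean) - 1e-9:
            count += 1
    return count / total


def transition_tally(real, k):
    """Recount segment boundaries of a simmap realization."""
    counts = np.zeros((k, k), dtype=int)
    for segs in real.segments:
        for (s1, _), (s2, _) in zip(segs, segs[1:]):
            counts[s1, s2] += 1
    return counts


def slice_count(real, tree, ages, focal, age):
    """Lineages in the focal state at one time slice, counted directly."""
    from nectarevo.mk import state_at_age

    n = 0
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p < 0:
            continue
        if ages[p] > age >= ages[v]:
            if state_at_age(real, tree, ages, v, age) == focal:
                n += 1
    return n
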