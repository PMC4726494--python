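"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the coalescent sample
probability is solved exactly by memoized recursion over configurations;
Ewens' θ by naive bisection; JC69 likelihoods by scipy matrix
exponentials; subtree rate means by explicit path enumeration.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.linalg import expm


# ---------------------------------------------------------------------------
# exact infinite-sites sample probability (ordered sample, sites unlabeled)

def _canon(cfg: dict) -> tuple:
    return tuple(sorted(((tuple(sorted(h)), m) for h, m in cfg.items())))


def exact_sample_probability(state: dict, theta: float) -> float:
    """Solve n(n-1+θ) p(C) = Σ coalescence terms + θ Σ mutation-removal terms.

    ``state`` maps frozenset-of-site-ids -> multiplicity.  Exhaustive over
    all event histories via dynamic programming; feasible for small n and
    few sites.
    """

    @lru_cache(maxsize=None)
    def p(cfg_key: tuple) -> float:
        cfg = {frozenset(h): m for h, m in cfg_key}
        n = sum(cfg.values())
        if n == 1:
            ((h, _),) = cfg.items()
            return 1.0 if not h else 0.0
        total = 0.0
        for h, m in cfg.items():
            if m >= 2:
                new = dict(cfg)
                new[h] = m - 1
                total += m * (m - 1) * p(_canon(new))
        if theta > 0:
            for h, m in cfg.items():
                if m == 1 and h:
                    others = set()
                    for other in cfg:
                        if other is not h:
                            others |= other
                    private = h - others
                    if private:
                        newh = h - {max(private)}
                        new = dict(cfg)
                        del new[h]
                        new[newh] = new.get(newh, 0) + 1
                        total += theta * p(_canon(new))
        return total / (n * (n - 1 + theta))

    return p(_canon(state))


def state_of_sample(sample) -> dict:
    """Configuration dict of a HaplotypeSample for the exact recursion."""
    out = {}
    for j in range(sample.n_distinct):
        hap = frozenset(np.nonzero(sample.site_matrix[:, j])[0].tolist())
        out[hap] = int(sample.multiplicities[j])
    return out


# ---------------------------------------------------------------------------
# configuration canonicalization for rejection sampling (tiny n only)

def canonical_configuration(matrix: np.ndarray) -> tuple:
    """Row+column permutation-invariant form of a binary sites x n matrix."""
    n = matrix.shape[1]
    if matrix.shape[0] == 0:
        return ("empty", n)
    from itertools import permutations

    best = None
    for perm in permutations(range(n)):
        m = matrix[:, perm]
        cols = sorted(tuple(int(x) for x in m[i]) for i in range(m.shape[0]))
        key = tuple(cols)
        if best is None or key < best:
            best = key
    return ("m", best)


# ---------------------------------------------------------------------------
# Ewens theta by bisection

def ewens_theta_bisect(n: int, k: int, tol: float = 1e-10) -> float:
    def f(theta: float) -> float:
        return sum(theta / (theta + i) for i in range(n)) - k

    lo, hi = 1e-9, 1.0
    while f(hi) < 0:
        hi *= 2
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            hi = mid
        else:
            lo = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# JC69 likelihood by matrix exponential

JC_Q = np.full((4, 4), 1.0 / 3.0) - np.eye(4) * (1.0 + 1.0 / 3.0 - 1.0 / 3.0)
JC_Q = np.full((4, 4), 1.0 / 3.0)
np.fill_diagonal(JC_Q, -1.0)


def jc69_loglik_expm(tree, alignment) -> float:
    """Pruning with explicit expm(Q t) matrices (independent of the fast path)."""
    patterns, counts = alignment.site_patterns()
    if patterns.shape[1] == 0:
        return 0.0
    name_to_row = {nm: i for i, nm in enumerate(alignment.names)}
    scalar = alignment.rate_scalar

    def partial(v: int) -> np.ndarray:
        if not tree.children[v]:
            obs = patterns[name_to_row[tree.tip_labels[v]]]
            out = np.zeros((patterns.shape[1], 4))
            for i, b in enumerate(obs):
                if b < 0:
                    out[i] = 1.0
                else:
                    out[i, b] = 1.0
            return out
        prod = np.ones((patterns.shape[1], 4))
        for c in tree.children[v]:
            P = expm(JC_Q * (tree.time[v] - tree.time[c]) * scalar)
            prod = prod * (partial(c) @ P.T)
        return prod

    site_lik = 0.25 * partial(tree.root).sum(axis=1)
    return float(np.dot(counts, np.log(site_lik)))


# ---------------------------------------------------------------------------
# brute-force spanning-subtree rate mean

def subtree_rate_mean(chronogram, tip_set) -> float:
    """Enumerate branches on root-ward paths from each tip to the MRCA."""
    tree = chronogram.tree
    leaves = [tree.find_node_with_taxon_label(t) for t in tip_set]
    # MRCA by intersecting ancestor chains
    chains = []
    for lf in leaves:
        chain = []
        nd = lf
        while nd is not None:
            chain.append(nd)
            nd = nd.parent_node
        chains.append(chain)
    common = set(id(n) for n in chains[0])
    for ch in chains[1:]:
        common &= {id(n) for n in ch}
    mrca = next(n for n in chains[0] if id(n) in common)
    edges = {}
    for lf in leaves:
        nd = lf
        while nd is not mrca:
            edges[id(nd)] = nd.edge.rate
            nd = nd.parent_node
    return float(np.mean(list(edges.values())))
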