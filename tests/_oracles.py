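"""Independent brute-force oracles for the statistical battery tests."""

from itertools import combinations

import numpy as np
import pandas as pd


def exact_ranksum_p(x, y):
    """Two-sided rank-sum p by exhaustive enumeration of all arrangements."""
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    ranks = pd.Series(pooled).rank().to_numpy()
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    us = []
    for idx in combinations(range(n + m), n):
        us.append(ranks[list(idx)].sum() - n * (n + 1) / 2)
    us = np.asarray(us)
    lo, hi = min(u_obs, n * m - u_obs), max(u_obs, n * m - u_obs)
    p = (np.count_nonzero(us <= lo) + np.count_nonzero(us >= hi)) / len(us)
    return min(p, 1.0)


def brute_force_min_letters(labels, sig_pairs):
    """Smallest number of letters for a valid display, by exhaustive
    search over clique subsets of the non-significant graph."""
    sig = {frozenset(p) for p in sig_pairs}
    nonsig_edges = {frozenset(p) for p in combinations(labels, 2)} - sig
    # all cliques of the non-significance graph
    cliques = []
    for r in range(1, len(labels) + 1):
        for subset in combinations(labels, r):
            if all(frozenset(p) in nonsig_edges
                   for p in combinations(subset, 2)):
                cliques.append(set(subset))
    for r in range(1, len(cliques) + 1):
        for chosen in combinations(cliques, r):
            covered_edges = {frozenset(p) for c in chosen
                             for p in combinations(sorted(c), 2)}
            covered_nodes = set().union(*chosen)
            if nonsig_edges <= covered_edges and covered_nodes == set(labels):
                return r
    raise AssertionError("no valid letter assignment found")


def check_letter_invariants(letters, sig_pairs, labels):
    sig = {frozenset(p) for p in sig_pairs}
    for a, b in combinations(labels, 2):
        shared = set(letters[a]) & set(letters[b])
        if frozenset((a, b)) in sig:
            assert not shared, f"significant pair {a},{b} shares {shared}"
        else:
            assert shared, f"non-significant pair {a},{b} shares no letter"
    for g in labels:
        assert letters[g], f"group {g} got no letter"
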