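"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results from first principles along code paths
that are separate from the package implementation: sphere-exclusion
clustering by literal rule application on dict/set structures, and Shapley
values by exhaustive subset enumeration over the path-dependent conditional
expectation.
"""

from itertools import combinations
from math import factorial

import numpy as np


def oracle_butina(fps, cutoff):
    """Literal sphere-exclusion: neighbor lists within the cutoff, repeatedly
    pick the unassigned compound with most unassigned neighbors (lowest index
    on ties) and absorb its unassigned neighbors."""
    n = len(fps)

    def dist(a, b):
        a, b = np.asarray(a, bool), np.asarray(b, bool)
        union = (a | b).sum()
        sim = 1.0 if union == 0 else (a & b).sum() / union
        return 1.0 - sim

    nbrs = {i: {j for j in range(n) if j != i and dist(fps[i], fps[j]) <= cutoff}
            for i in range(n)}
    unassigned = set(range(n))
    clusters = []
    while unassigned:
        counts = {i: len(nbrs[i] & unassigned) for i in unassigned}
        best = min(unassigned, key=lambda i: (-counts[i], i))
        members = sorted({best} | (nbrs[best] & unassigned))
        clusters.append(members)
        unassigned -= set(members)
    return clusters


def expvalue(node, x, S):
    """Path-dependent conditional expectation of one tree given feature set S."""
    if node.feature < 0:
        return node.value
    if node.feature in S:
        child = node.yes if x[node.feature] < node.threshold else node.no
        return expvalue(child, x, S)
    wl = node.yes.cover / node.cover
    return wl * expvalue(node.yes, x, S) + (1 - wl) * expvalue(node.no, x, S)


def brute_force_shap(ensemble, x, n_features):
    """Exhaustive subset-enumeration Shapley values over the used features."""
    D = sorted(ensemble.used_features())
    phi = np.zeros(n_features)
    for i in D:
        rest = [d for d in D if d != i]
        for k in range(len(rest) + 1):
            for S in combinations(rest, k):
                w = factorial(k) * factorial(len(D) - k - 1) / factorial(len(D))
                v_s = sum(expvalue(t, x, set(S)) for t in ensemble.trees)
                v_si = sum(expvalue(t, x, set(S) | {i}) for t in ensemble.trees)
                phi[i] += w * (v_si - v_s)
    return phi
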