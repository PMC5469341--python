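"""Brute-force oracles used by the acceptance script (independent of
the library's implementations)."""

from __future__ import annotations

import numpy as np


def ward_oracle_merges(X):
    """Exhaustive Ward agglomeration: evaluate the within-cluster
    sum-of-squares increase of every possible merge at every step."""
    X = np.asarray(X, dtype=float)
    clusters = {i: [i] for i in range(len(X))}
    merges = []
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if b <= a:
                    continue
                pa, pb = X[clusters[a]], X[clusters[b]]
                na, nb = len(pa), len(pb)
                cost = (na * nb / (na + nb)
                        * np.sum((pa.mean(0) - pb.mean(0)) ** 2))
                if best is None or cost < best[0] - 1e-12:
                    best = (cost, a, b)
        _, a, b = best
        merges.append(frozenset([frozenset(clusters[a]),
                                 frozenset(clusters[b])]))
        clusters[a] = clusters[a] + clusters.pop(b)
    return merges


def linkage_merges(tree, n):
    """Merge sets in order from a SciPy linkage matrix."""
    members = {i: frozenset([i]) for i in range(n)}
    merges = []
    for k, (a, b, _, _) in enumerate(tree):
        a, b = int(a), int(b)
        merges.append(frozenset([members[a], members[b]]))
        members[n + k] = members[a] | members[b]
    return merges
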