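"""Independent brute-force reference for clustering and classification.

Deliberately naive and structurally different from the library code:
clusters are connected components of the pairwise-gap graph, and DSB
counting enumerates every set of disjoint opposite-strand break pairs to
find the true maximum matching.
"""

from itertools import combinations

from grenzray.damage import BASE_DAMAGE, FORWARD, Lesion


def brute_force_clusters(lesions, n_min_bp):
    """Connected components under 'gap < n_min_bp' adjacency."""
    lesions = sorted(lesions)
    n = len(lesions)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in combinations(range(n), 2):
        if abs(lesions[i].position - lesions[j].position) < n_min_bp:
            parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(lesions[i])
    return sorted(groups.values(), key=lambda g: g[0].position)


def _max_dsb_pairs(breaks, window):
    """Maximum number of disjoint opposite-strand pairs within window,
    by exhaustive recursion over every pairing."""
    if len(breaks) < 2:
        return 0
    first, rest = breaks[0], breaks[1:]
    best = _max_dsb_pairs(rest, window)  # leave `first` unpaired
    for k, other in enumerate(rest):
        if other.strand != first.strand and abs(
            other.position - first.position
        ) <= window:
            best = max(best, 1 + _max_dsb_pairs(rest[:k] + rest[k + 1 :], window))
    return best


def brute_force_classify(cluster, window):
    breaks = [l for l in cluster if l.kind != BASE_DAMAGE]
    if not breaks:
        return "BD"
    if len(breaks) == 1:
        return "SSB"
    if len({l.strand for l in breaks}) == 1:
        return "SSB+"
    pairs = _max_dsb_pairs(breaks, window)
    if pairs == 0:
        return "2SSB"
    if pairs >= 2:
        return "DSB++"
    return "DSB+" if len(breaks) > 2 else "DSB"
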