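"""Independent brute-force oracles used to validate the fast implementations.

These deliberately re-derive every quantity from first principles — pair
enumeration for the Rand index, direct formula evaluation for the F-measure,
and from-scratch recomputation of all cluster-mean distances at every UPGMA
step — and share no code with the package internals they check.
"""

from itertools import combinations

from sigdistill.partition import Partition


def rand_oracle(u: Partition, v: Partition) -> float:
    """Classify every element pair explicitly."""
    ids = list(u.element_ids)
    agree = 0
    for x, y in combinations(ids, 2):
        same_u = u.class_of[x] == u.class_of[y]
        same_v = v.class_of[x] == v.class_of[y]
        if same_u == same_v:
            agree += 1
    n = len(ids)
    return agree / (n * (n - 1) // 2)


def f_oracle(u: Partition, v: Partition) -> float:
    """Direct evaluation of the class-size-weighted best-match F-measure."""
    n = len(u.element_ids)
    total = 0.0
    for u_members in u.classes.values():
        u_set = set(u_members)
        best = 0.0
        for v_members in v.classes.values():
            v_set = set(v_members)
            inter = len(u_set & v_set)
            if inter == 0:
                continue
            p = inter / len(v_set)
            r = inter / len(u_set)
            best = max(best, 2 * p * r / (p + r))
        total += len(u_set) / n * best
    return total


def set_partitions(items):
    """All set partitions of a sequence (Bell-number many)."""
    items = list(items)
    if not items:
        yield []
        return
    head, rest = items[0], items[1:]
    for partial in set_partitions(rest):
        for i in range(len(partial)):
            yield partial[:i] + [[head] + partial[i]] + partial[i + 1 :]
        yield [[head]] + partial


def upgma_oracle(dist):
    """UPGMA merge sequence, recomputing every cluster-mean distance from the
    original matrix at each step; ties broken on the sorted pair of smallest
    member indices.

    Returns a list of (frozenset_a, frozenset_b, height).
    """
    n = dist.shape[0]
    clusters = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in combinations(clusters, 2):
            d = sum(dist[i, j] for i in a for j in b) / (len(a) * len(b))
            tie = tuple(sorted((min(a), min(b))))
            if best is None or (d, tie) < (best[0], best[1]):
                best = (d, tie, a, b)
        d, _, a, b = best
        clusters = [c for c in clusters if c is not a and c is not b] + [a | b]
        if min(b) < min(a):
            a, b = b, a
        merges.append((a, b, d))
    return merges
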