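"""Brute-force re-implementation of the rank-based edge selection.

Deliberately naive and independent of the package internals: plain-Python
sums for the correlation, list sorts for the ranks, and an explicit scan of
all unordered pairs for the edges.  Used to cross-check build_network on
small random instances.
"""

import math


def brute_pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    if sxx == 0 or syy == 0:
        return None  # undefined
    return max(-1.0, min(1.0, sxy / math.sqrt(sxx * syy)))


def brute_ranks(profiles):
    """ranks[g][h] = 1-based position of h in g's descending-cc list."""
    genes = sorted(profiles)
    ranks = {g: {} for g in genes}
    for g in genes:
        scored = []
        for h in genes:
            if h == g:
                continue
            cc = brute_pearson(profiles[g], profiles[h])
            if cc is not None:
                scored.append((h, cc))
        scored.sort(key=lambda t: (-t[1], t[0]))
        for pos, (h, _) in enumerate(scored, start=1):
            ranks[g][h] = pos
    return ranks


def brute_network(profiles, min_cc=0.95, max_rank=50, mode="either_direction"):
    """Edge set {(a, b), a < b} under the cc floor plus rank condition."""
    genes = sorted(profiles)
    ranks = brute_ranks(profiles)
    edges = set()
    for i, g in enumerate(genes):
        for h in genes[i + 1:]:
            cc = brute_pearson(profiles[g], profiles[h])
            if cc is None or not cc > min_cc:
                continue
            fwd = ranks[g].get(h, math.inf) <= max_rank
            bwd = ranks[h].get(g, math.inf) <= max_rank
            ok = (fwd or bwd) if mode == "either_direction" else (fwd and bwd)
            if ok:
                edges.add((g, h))
    return edges
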