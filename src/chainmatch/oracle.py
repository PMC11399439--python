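"""Exhaustive reference solver for tiny chain-matching instances.

Enumerates every disjoint set of valid chains and reports the maximal
chain count together with the minimal summed pairwise distance among
maximal sets.  Exponential — intended purely as an independent check of
the flow-based matcher on instances with a handful of particles per
channel.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import product

import numpy as np

from .points import PointCloudSet, pairwise_distances

MAX_CANDIDATES = 10**5


def brute_force_matching_oracle(
    clouds: PointCloudSet, t: float, span: tuple[int, int] | None = None
) -> tuple[int, float]:
    """(max chain count, min summed distance among maximal matchings).

    Chains run over the contiguous channel ``span`` (default: all
    channels) with every adjacent pair within distance ``t``.  Refuses
    instances with more than ~1e5 candidate chains.
    """
    k = clouds.k
    if span is None:
        span = (0, k - 1)
    j0, j1 = span
    counts = [clouds.counts[j] for j in range(j0, j1 + 1)]
    if any(c == 0 for c in counts):
        return 0, 0.0
    if int(np.prod([float(c) for c in counts])) > MAX_CANDIDATES:
        raise ValueError("instance too large for exhaustive enumeration")

    dists = [pairwise_distances(clouds, (j, j + 1)) for j in range(j0, j1)]
    candidates = []  # (index tuple, cost)
    for combo in product(*(range(c) for c in counts)):
        cost = 0.0
        ok = True
        for step, d in enumerate(dists):
            dd = d[combo[step], combo[step + 1]]
            if dd > t:
                ok = False
                break
            cost += dd
        if ok:
            candidates.append((combo, cost))

    n_layers = len(counts)
    full_masks = tuple((1 << c) - 1 for c in counts)

    @lru_cache(maxsize=None)
    def best(i1: int, masks: tuple[int, ...]) -> tuple[int, float]:
        """Best (count, -cost ordering) using first-channel particles >= i1."""
        if i1 >= counts[0]:
            return 0, 0.0
        # option: leave particle i1 of the first channel unmatched
        res_count, res_cost = best(i1 + 1, masks)
        for combo, cost in candidates:
            if combo[0] != i1:
                continue
            if any(masks[s] >> combo[s] & 1 for s in range(1, n_layers)):
                continue
            new_masks = tuple(
                masks[s] | (1 << combo[s]) if s else masks[s]
                for s in range(n_layers)
            )
            cnt, c = best(i1 + 1, new_masks)
            cnt, c = cnt + 1, c + cost
            if cnt > res_count or (cnt == res_count and c < res_cost):
                res_count, res_cost = cnt, c
        return res_count, res_cost

    count, cost = best(0, tuple(0 for _ in counts))
    best.cache_clear()
    return count, cost
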