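"""Chain matchings, abundance vectors and abundance curves.

Two matching semantics are provided.  Mode I prioritizes a predefined
chain structure: it first solves the full k-marginal problem (maximizing
the number of complete chains), removes the matched particles, and then
re-matches the leftovers with shorter-chain problems in a user-defined
priority order.  Mode II solves the k-1 adjacent-pair problems
independently and couples pairs that share a particle into longer chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import (
    ChainSet,
    MatchConfig,
    build_flow_network,
    extract_chain_matching,
    solve_min_cost_flow,
)
from .points import CHANNEL_LETTERS, PointCloudSet, pairwise_distances, span_name


def structure_spans(k: int) -> list[tuple[int, int]]:
    """All contiguous channel spans incl. singlets, longest first, left to right."""
    return [
        (j0, j0 + length - 1)
        for length in range(k, 0, -1)
        for j0 in range(k - length + 1)
    ]


def structure_names(k: int) -> list[str]:
    """Canonical structure order, e.g. k=3: ABC, AB, BC, A, B, C."""
    return [span_name(s) for s in structure_spans(k)]


def parse_structure(name: str, k: int) -> tuple[int, int]:
    """Span of a structure name; rejects non-contiguous names like 'AC'."""
    idx = [CHANNEL_LETTERS.index(c) for c in name]
    if not idx or any(b - a != 1 for a, b in zip(idx, idx[1:])) or idx[-1] >= k:
        raise ValueError(
            f"structure {name!r} is not a contiguous channel span for k={k}"
        )
    return (idx[0], idx[-1])


@dataclass
class ChainMatching:
    """Disjoint detected structures: full chains plus shorter leftovers.

    ``structures`` maps a structure name to a list of chains, each chain a
    tuple of per-channel particle indices over the structure's span.
    """

    k: int
    structures: dict[str, list[tuple[int, ...]]]
    cost: float = 0.0  # summed pairwise distances over all matched chains

    def abundances(self) -> "AbundanceVector":
        w = {name: len(self.structures.get(name, [])) for name in structure_names(self.k)}
        return AbundanceVector(k=self.k, w=w)


@dataclass
class AbundanceVector:
    """Counts per structure type, e.g. (w_ABC, w_AB, w_BC, w_A, w_B, w_C)."""

    k: int
    w: dict[str, int]

    def as_array(self) -> np.ndarray:
        return np.array([self.w[name] for name in structure_names(self.k)], dtype=float)

    def relative(self, n_scale: int) -> dict[str, float]:
        """Counts scaled by the particle count of the scaling channel."""
        if n_scale <= 0:
            raise ValueError("scaling channel has no particles; relative "
                             "abundances undefined")
        return {name: cnt / n_scale for name, cnt in self.w.items()}

    def channel_total(self, j: int) -> int:
        """Number of structures whose span contains channel j (conservation check)."""
        total = 0
        for name, cnt in self.w.items():
            j0, j1 = parse_structure(name, self.k)
            if j0 <= j <= j1:
                total += cnt
        return total


def _solve_span(clouds: PointCloudSet, cfg: MatchConfig,
                span: tuple[int, int]) -> ChainSet:
    net = build_flow_network(clouds, cfg, span)
    return extract_chain_matching(solve_min_cost_flow(net), net)


def _default_priority(k: int) -> list[str]:
    """Longest-first, left-to-right, excluding the full chain and singlets."""
    return [span_name(s) for s in structure_spans(k) if 1 < s[1] - s[0] + 1 < k]


def match_mode1(clouds: PointCloudSet, cfg: MatchConfig
                ) -> tuple[ChainMatching, AbundanceVector]:
    """Chain-first matching: full chains, then leftovers by priority."""
    k = clouds.k
    priority = cfg.priority if cfg.priority is not None else _default_priority(k)
    spans = [parse_structure(name, k) for name in priority]

    free = [np.ones(n, dtype=bool) for n in clouds.counts]
    structures: dict[str, list[tuple[int, ...]]] = {}
    total_cost = 0.0

    for span in [(0, k - 1)] + spans:
        sub = clouds.subset(free)
        # map sub-cloud indices back to the original clouds
        lookup = [np.nonzero(m)[0] for m in free]
        res = _solve_span(sub, cfg, span)
        total_cost += res.cost
        name = span_name(span)
        out = structures.setdefault(name, [])
        for chain in res.chains:
            glob = tuple(int(lookup[span[0] + off][i]) for off, i in enumerate(chain))
            out.append(glob)
            for off, i in enumerate(glob):
                free[span[0] + off][i] = False

    for j in range(k):
        name = CHANNEL_LETTERS[j]
        structures[name] = [(int(i),) for i in np.nonzero(free[j])[0]]

    matching = ChainMatching(k=k, structures=structures, cost=total_cost)
    return matching, matching.abundances()


class _UnionFind:
    def __init__(self):
        self.parent = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _couple_pairs(k: int, pair_links: list[list[tuple[int, int]]],
                  counts: tuple[int, ...], cost: float) -> ChainMatching:
    """Couple adjacent-channel pair matchings into maximal chains.

    ``pair_links[j]`` holds matched index pairs between channels j and j+1.
    Particles shared between consecutive pair matchings merge the pairs
    into longer structures (union-find over (channel, index) labels);
    because each particle carries at most one left and one right link the
    components are simple contiguous chains.
    """
    uf = _UnionFind()
    right = {}  # (j, i) -> partner index in channel j+1
    for j, links in enumerate(pair_links):
        for a, b in links:
            uf.union((j, a), (j + 1, b))
            right[(j, a)] = b

    components: dict[tuple, list[tuple[int, int]]] = {}
    for j in range(k):
        for i in range(counts[j]):
            components.setdefault(uf.find((j, i)), []).append((j, i))

    structures: dict[str, list[tuple[int, ...]]] = {}
    for members in components.values():
        members.sort()
        channels = [j for j, _ in members]
        span = (channels[0], channels[-1])
        name = span_name(span)
        structures.setdefault(name, []).append(tuple(i for _, i in members))
    return ChainMatching(k=k, structures=structures, cost=cost)


def match_mode2(clouds: PointCloudSet, cfg: MatchConfig
                ) -> tuple[ChainMatching, AbundanceVector]:
    """Pairwise matching of every adjacent channel pair, then coupling."""
    k = clouds.k
    pair_links: list[list[tuple[int, int]]] = []
    cost = 0.0
    for j in range(k - 1):
        res = _solve_span(clouds, cfg, (j, j + 1))
        pair_links.append([(a, b) for a, b in res.chains])
        cost += res.cost
    matching = _couple_pairs(k, pair_links, clouds.counts, cost)
    return matching, matching.abundances()


def match(clouds: PointCloudSet, cfg: MatchConfig
          ) -> tuple[ChainMatching, AbundanceVector]:
    if cfg.mode == "I":
        return match_mode1(clouds, cfg)
    if cfg.mode == "II":
        return match_mode2(clouds, cfg)
    raise ValueError(f"unknown mode {cfg.mode!r}")


@dataclass
class AbundanceCurve:
    """Abundance vectors over a strictly increasing threshold grid."""

    k: int
    t_grid: np.ndarray
    vectors: list[AbundanceVector]
    mode: str
    relative: list[dict[str, float]] | None = None

    def counts(self, structure: str) -> np.ndarray:
        return np.array([v.w[structure] for v in self.vectors], dtype=float)


def abundance_curve(clouds: PointCloudSet, t_grid, cfg: MatchConfig,
                    relative: bool = False) -> AbundanceCurve:
    """Run the configured mode at every threshold of the grid.

    λ is re-derived per t unless fixed in the config.  With
    ``relative=True`` counts are additionally scaled by the particle count
    of ``cfg.scale_channel``.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or np.any(np.diff(t_grid) <= 0) or np.any(t_grid < 0):
        raise ValueError("t_grid must be strictly increasing and nonnegative")
    vectors = []
    rel = [] if relative else None
    n_scale = clouds.counts[cfg.scale_channel]
    for t in t_grid:
        cfg_t = MatchConfig(t=float(t), lam=cfg.lam, mode=cfg.mode,
                            priority=cfg.priority, scale_channel=cfg.scale_channel)
        _, w = match(clouds, cfg_t)
        vectors.append(w)
        if relative:
            rel.append(w.relative(n_scale))
    return AbundanceCurve(k=clouds.k, t_grid=t_grid, vectors=vectors,
                          mode=cfg.mode, relative=rel)


def nearest_neighbor_matching(clouds: PointCloudSet, t: float) -> AbundanceVector:
    """Greedy baseline: repeatedly link the globally closest unmatched
    adjacent-channel pair within t, then couple links as in Mode II.

    Deterministic: ties are broken by (distance, pair index, indices).
    Locally optimal pairing is known to break apart chains that the global
    OT matching keeps intact, underestimating full chains in dense scenes.
    """
    k = clouds.k
    candidates = []
    for j in range(k - 1):
        d = pairwise_distances(clouds, (j, j + 1))
        for a, b in zip(*np.nonzero(d <= t)):
            candidates.append((float(d[a, b]), j, int(a), int(b)))
    candidates.sort()
    right_free = [np.ones(n, dtype=bool) for n in clouds.counts]
    left_free = [np.ones(n, dtype=bool) for n in clouds.counts]
    pair_links: list[list[tuple[int, int]]] = [[] for _ in range(k - 1)]
    cost = 0.0
    for dist, j, a, b in candidates:
        if right_free[j][a] and left_free[j + 1][b]:
            right_free[j][a] = False
            left_free[j + 1][b] = False
            pair_links[j].append((a, b))
            cost += dist
    return _couple_pairs(k, pair_links, clouds.counts, cost).abundances()
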