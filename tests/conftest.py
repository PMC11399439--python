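import numpy as np
import pytest
from scipy.optimize import linprog

from chainmatch import MatchConfig, PointCloudSet, pairwise_distances


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_instance(rng, k=None, n_max=5, box=3.0):
    """Small random multi-channel instance for oracle cross-checks."""
    if k is None:
        k = int(rng.integers(2, 5))
    clouds = [rng.uniform(0, box, size=(int(rng.integers(0, n_max + 1)), 2))
              for _ in range(k)]
    t = float(rng.uniform(0.2, 1.8))
    return PointCloudSet(clouds), t


def lp_chain_matching(clouds: PointCloudSet, t: float, lam: float):
    """Generic-LP solution of the unbalanced multi-marginal transport
    problem: one variable per feasible chain (all adjacent distances <= t),
    objective sum of chain distances minus lam per chain, marginal
    constraints <= 1 per particle.  Independent of the flow formulation.
    """
    from itertools import product

    k = clouds.k
    counts = clouds.counts
    if min(counts) == 0:
        return 0.0
    dists = [pairwise_distances(clouds, (j, j + 1)) for j in range(k - 1)]
    chains, costs = [], []
    for combo in product(*(range(n) for n in counts)):
        d = [dists[j][combo[j], combo[j + 1]] for j in range(k - 1)]
        if max(d) <= t:
            chains.append(combo)
            costs.append(sum(d) - lam)
    if not chains:
        return 0.0
    # marginal constraints: each particle in at most one chain
    n_rows = sum(counts)
    offsets = np.cumsum([0] + list(counts[:-1]))
    A = np.zeros((n_rows, len(chains)))
    for v, combo in enumerate(chains):
        for j, i in enumerate(combo):
            A[offsets[j] + i, v] = 1
    res = linprog(c=np.array(costs), A_ub=A, b_ub=np.ones(n_rows),
                  bounds=(0, None), method="highs")
    assert res.status == 0
    return float(res.fun)


def full_chain_cost(clouds: PointCloudSet, chains, span=None):
    """Summed adjacent-channel distances over a list of chains."""
    k = clouds.k
    j0 = 0 if span is None else span[0]
    total = 0.0
    for chain in chains:
        for off in range(len(chain) - 1):
            a = clouds.clouds[j0 + off][chain[off]]
            b = clouds.clouds[j0 + off + 1][chain[off + 1]]
            total += float(np.linalg.norm(a - b))
    return total
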