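"""Shared fixtures and independent brute-force oracles.

The oracles recompute social stress and minimum frustration by direct
enumeration (pairs, triangles, set partitions) without touching the
package's vectorised or incremental code paths, so every comparison is a
genuine dual-route check.
"""

import itertools

import numpy as np
import pytest
from hypothesis import settings

from heidersim import ModelParams, SignedOpinionNetwork

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


def oracle_stress(net: SignedOpinionNetwork, g: float, h: float) -> float:
    """H by direct summation: each linked pair once, each triangle once."""
    s = net.opinions
    H = 0.0
    for a, b, sgn in net.links():
        H -= sgn * int(s[a]) * int(s[b])
        H += (h / 2.0) * (1 - sgn)
    for i, j, k in itertools.combinations(range(net.n_agents), 3):
        if net.has_link(i, j) and net.has_link(j, k) and net.has_link(k, i):
            H -= g * net.link_sign(i, j) * net.link_sign(j, k) * net.link_sign(k, i)
    return H


def oracle_min_stress(edges: list[tuple[int, int]], n: int, g: float, h: float) -> float:
    """Exhaustive minimum of H over all 2^n opinion x 2^E sign configurations."""
    best = np.inf
    for signs in itertools.product((-1, 1), repeat=len(edges)):
        for ops in itertools.product((-1, 1), repeat=n):
            net = SignedOpinionNetwork(n)
            net.opinions = np.array(ops, dtype=np.int8)
            for (a, b), sg in zip(edges, signs):
                net.add_link(a, b, sg)
            best = min(best, oracle_stress(net, g, h))
    return best


def oracle_min_frustration(net: SignedOpinionNetwork) -> int:
    """Exhaustive minimum frustration over all set partitions (N <= 9)."""
    n = net.n_agents
    edges = list(net.links())
    best = len(edges)
    for labels in itertools.product(range(n), repeat=n):
        c = 0
        for a, b, sgn in edges:
            same = labels[a] == labels[b]
            if (sgn > 0 and not same) or (sgn < 0 and same):
                c += 1
        best = min(best, c)
        if best == 0:
            return 0
    return best


def make_net(n: int, edges: list[tuple[int, int, int]], opinions=None) -> SignedOpinionNetwork:
    net = SignedOpinionNetwork(n)
    for a, b, s in edges:
        net.add_link(a, b, s)
    if opinions is not None:
        net.opinions = np.array(opinions, dtype=np.int8)
    return net


def random_net(rng: np.random.Generator, n: int, p_edge: float = 0.5) -> SignedOpinionNetwork:
    """Random signed graph with i.i.d. edges, signs and opinions."""
    net = SignedOpinionNetwork(n)
    net.opinions = np.where(rng.random(n) < 0.5, 1, -1).astype(np.int8)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                net.add_link(i, j, 1 if rng.random() < 0.5 else -1)
    return net


@pytest.fixture
def k4_all_positive() -> SignedOpinionNetwork:
    return make_net(4, [(i, j, 1) for i in range(4) for j in range(i + 1, 4)])


@pytest.fixture
def params_g1() -> ModelParams:
    return ModelParams(g=1.0, T=1.0)
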