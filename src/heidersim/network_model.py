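"""Microstate of a signed opinion network and its social-stress Hamiltonian.

A society of ``N`` agents carries two kinds of binary state: an opinion
``s_i ∈ {-1, +1}`` per agent and a sign ``J_ij ∈ {-1, +1}`` per social tie
(``J_ij = 0`` means *i* and *j* are not linked).  The global social stress is

    H = - Σ_(i,j) J_ij s_i s_j  -  g Σ_(i,j,k) J_ij J_jk J_ki
        + (h/2) Σ_(i,j) (1 - J_ij)

where the first sum runs once over each linked pair (homophily: friends
prefer to agree), the second once over each closed triangle (Heider balance:
triads whose sign product is +1 are tension-free) and the third is an
optional pro-social field that penalises hostile ties.  Pair and triangle
sums count each pair/triangle exactly once; this convention is normative
because double counting would silently rescale ``g``, ``T`` and ``h``.

This module defines the microstate container, topology generators (regular
ring lattices and connectivity-preserving small-world rewirings), exact and
incremental stress evaluation, and plain-text I/O.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import networkx as nx
import numpy as np

__all__ = [
    "ModelParams",
    "TopologySpec",
    "SignedOpinionNetwork",
    "build_regular_ring",
    "build_small_world",
    "randomize_state",
    "total_stress",
    "ground_state_stress",
    "delta_stress_opinion_flip",
    "delta_stress_link_flip",
]


@dataclass(frozen=True)
class ModelParams:
    """Hamiltonian and dynamics parameters.

    Parameters
    ----------
    g : float
        Strength of the triadic balance term relative to the homophily term.
        Must be non-negative.
    T : float
        Social temperature of the Metropolis acceptance rule; higher values
        accept more stress-increasing changes.  Must be positive.
    h : float
        Pro-social external field suppressing negative ties (default 0).
    n : float
        Relative opinion/link update rate: one time step performs
        ``round(n * N)`` opinion attempts followed by one link attempt.
        May be fractional; ``n * N < 1`` yields probabilistic opinion
        attempts (fast-link regime).
    p : float
        Probability that a link update is a rewiring move (delete a random
        link, create a random new one) instead of a sign flip.
    rewiring_mode : str
        ``"random_sign"`` draws the new link's sign ±1 equiprobably;
        ``"homophilious"`` sets it to +1 iff the endpoints agree.
    """

    g: float = 1.0
    T: float = 1.0
    h: float = 0.0
    n: float = 1.0
    p: float = 0.0
    rewiring_mode: str = "random_sign"

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError(f"social temperature T must be > 0, got {self.T}")
        if self.g < 0:
            raise ValueError(f"balance strength g must be >= 0, got {self.g}")
        if self.h < 0:
            raise ValueError(f"external field h must be >= 0, got {self.h}")
        if self.n <= 0:
            raise ValueError(f"relative update rate n must be > 0, got {self.n}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"rewiring probability p must lie in [0, 1], got {self.p}")
        if self.rewiring_mode not in ("random_sign", "homophilious"):
            raise ValueError(
                "rewiring_mode must be 'random_sign' or 'homophilious', "
                f"got {self.rewiring_mode!r}"
            )


@dataclass(frozen=True)
class TopologySpec:
    """Parameters of the generated topology.

    ``k`` is the (even) mean degree of the underlying ring lattice and
    ``epsilon`` the small-world parameter: the probability that one endpoint
    of each lattice link is re-attached to a random non-neighbour.
    """

    n_agents: int
    k: int
    epsilon: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents < 2:
            raise ValueError("need at least two agents")
        if self.k % 2 != 0 or self.k <= 0:
            raise ValueError(f"mean degree k must be a positive even integer, got {self.k}")
        if self.k >= self.n_agents:
            raise ValueError(f"k={self.k} must be smaller than N={self.n_agents}")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError(f"epsilon must lie in [0, 1], got {self.epsilon}")


class SignedOpinionNetwork:
    """The full microstate: N agents, their opinions and signed ties.

    Internally the signed adjacency is a dense symmetric ``int8`` matrix
    (values -1, 0, +1) plus an indexable edge registry, which keeps both
    incremental stress evaluation and uniform link sampling O(1)-ish at the
    desk scales this simulator targets (N up to a few thousand).

    Invariants: no self-links, exact symmetry, and every stored link sign
    is exactly -1 or +1.  ``validate()`` checks all three.
    """

    def __init__(self, n_agents: int):
        if n_agents < 1:
            raise ValueError("n_agents must be positive")
        self.n_agents = int(n_agents)
        self.opinions = np.ones(self.n_agents, dtype=np.int8)
        self._J = np.zeros((self.n_agents, self.n_agents), dtype=np.int8)
        # edge registry: parallel arrays with swap-delete, supports O(1)
        # uniform sampling while rewiring moves churn the link set
        self._ei: list[int] = []
        self._ej: list[int] = []
        self._epos: dict[tuple[int, int], int] = {}

    # -- link bookkeeping ---------------------------------------------------

    @property
    def n_links(self) -> int:
        return len(self._ei)

    def has_link(self, i: int, j: int) -> bool:
        return self._J[i, j] != 0

    def link_sign(self, i: int, j: int) -> int:
        s = int(self._J[i, j])
        if s == 0:
            raise KeyError(f"agents {i} and {j} are not linked")
        return s

    def add_link(self, i: int, j: int, sign: int = 1) -> None:
        if i == j:
            raise ValueError("self-links are not allowed")
        if sign not in (-1, 1):
            raise ValueError(f"link sign must be -1 or +1, got {sign}")
        if self._J[i, j] != 0:
            raise ValueError(f"agents {i} and {j} are already linked")
        a, b = (i, j) if i < j else (j, i)
        self._J[i, j] = self._J[j, i] = sign
        self._epos[(a, b)] = len(self._ei)
        self._ei.append(a)
        self._ej.append(b)

    def remove_link(self, i: int, j: int) -> int:
        """Remove the tie between *i* and *j*; returns its sign."""
        sign = self.link_sign(i, j)
        a, b = (i, j) if i < j else (j, i)
        pos = self._epos.pop((a, b))
        last = len(self._ei) - 1
        if pos != last:
            self._ei[pos] = self._ei[last]
            self._ej[pos] = self._ej[last]
            self._epos[(self._ei[pos], self._ej[pos])] = pos
        self._ei.pop()
        self._ej.pop()
        self._J[i, j] = self._J[j, i] = 0
        return sign

    def flip_link(self, i: int, j: int) -> None:
        self.link_sign(i, j)  # raises if unlinked
        self._J[i, j] = -self._J[i, j]
        self._J[j, i] = self._J[i, j]

    def links(self) -> Iterator[tuple[int, int, int]]:
        """Iterate over (i, j, sign) with i < j, each tie once."""
        for a, b in zip(self._ei, self._ej):
            yield a, b, int(self._J[a, b])

    def link_at(self, idx: int) -> tuple[int, int]:
        return self._ei[idx], self._ej[idx]

    def neighbors(self, i: int) -> np.ndarray:
        return np.nonzero(self._J[i])[0]

    def degree(self, i: int) -> int:
        return int(np.count_nonzero(self._J[i]))

    @property
    def mean_degree(self) -> float:
        return 2.0 * self.n_links / self.n_agents

    def adjacency_signed(self) -> np.ndarray:
        """Dense signed adjacency (a copy; values in {-1, 0, +1})."""
        return self._J.copy()

    # -- construction / validation -----------------------------------------

    def copy(self) -> "SignedOpinionNetwork":
        new = SignedOpinionNetwork(self.n_agents)
        new.opinions = self.opinions.copy()
        new._J = self._J.copy()
        new._ei = list(self._ei)
        new._ej = list(self._ej)
        new._epos = dict(self._epos)
        return new

    def validate(self) -> None:
        J = self._J
        if np.any(np.diagonal(J) != 0):
            raise AssertionError("self-link present")
        if not np.array_equal(J, J.T):
            raise AssertionError("signed adjacency not symmetric")
        vals = J[J != 0]
        if not np.all(np.isin(vals, (-1, 1))):
            raise AssertionError("link value outside {-1, +1}")
        if not np.all(np.isin(self.opinions, (-1, 1))):
            raise AssertionError("opinion outside {-1, +1}")
        if 2 * self.n_links != int(np.count_nonzero(J)):
            raise AssertionError("edge registry out of sync with adjacency")

    @classmethod
    def from_graph(cls, graph: nx.Graph, opinions=None) -> "SignedOpinionNetwork":
        """Build from a networkx graph whose nodes are 0..N-1; edge attribute
        ``sign`` defaults to +1."""
        n = graph.number_of_nodes()
        net = cls(n)
        for u, v, data in graph.edges(data=True):
            net.add_link(int(u), int(v), int(data.get("sign", 1)))
        if opinions is not None:
            ops = np.asarray(opinions, dtype=np.int8)
            if ops.shape != (n,) or not np.all(np.isin(ops, (-1, 1))):
                raise ValueError("opinions must be length-N with values in {-1, +1}")
            net.opinions = ops.copy()
        return net

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_agents))
        for i in range(self.n_agents):
            g.nodes[i]["opinion"] = int(self.opinions[i])
        for a, b, s in self.links():
            g.add_edge(a, b, sign=s)
        return g

    # -- plain-text I/O ------------------------------------------------------

    def to_edgelist_csv(self, path) -> None:
        """Write ties as CSV rows (source, target, sign), 0-based, one
        undirected tie per row."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["source", "target", "sign"])
            for a, b, s in self.links():
                w.writerow([a, b, s])

    def to_opinions_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["node", "opinion"])
            for i, s in enumerate(self.opinions):
                w.writerow([i, int(s)])

    @classmethod
    def from_edgelist_csv(cls, edge_path, opinions_path=None, n_agents=None):
        rows = []
        with open(edge_path, newline="") as fh:
            for row in csv.DictReader(fh):
                rows.append((int(row["source"]), int(row["target"]), int(row["sign"])))
        max_node = max((max(a, b) for a, b, _ in rows), default=-1)
        n = n_agents if n_agents is not None else max_node + 1
        net = cls(n)
        for a, b, s in rows:
            net.add_link(a, b, s)
        if opinions_path is not None:
            with open(opinions_path, newline="") as fh:
                for row in csv.DictReader(fh):
                    val = int(row["opinion"])
                    if val not in (-1, 1):
                        raise ValueError(f"opinion must be -1 or +1, got {val}")
                    net.opinions[int(row["node"])] = val
        return net

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.to_graph(), Path(path))

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"SignedOpinionNetwork(N={self.n_agents}, links={self.n_links}, "
            f"positive={sum(1 for _, _, s in self.links() if s > 0)})"
        )


# ---------------------------------------------------------------------------
# topology generators
# ---------------------------------------------------------------------------


def build_regular_ring(spec: TopologySpec) -> SignedOpinionNetwork:
    """Ring lattice: each agent tied to its k/2 nearest neighbours on either
    side.  Links start positive; call :func:`randomize_state` to draw signs."""
    N, k = spec.n_agents, spec.k
    net = SignedOpinionNetwork(N)
    for i in range(N):
        for d in range(1, k // 2 + 1):
            j = (i + d) % N
            net.add_link(i, j, 1)
    return net


def build_small_world(spec: TopologySpec) -> SignedOpinionNetwork:
    """Small-world rewiring of the ring lattice.

    Each lattice link, independently with probability ``epsilon``, has one
    uniformly chosen endpoint detached and re-attached to a uniformly random
    non-adjacent node.  Moves that would create a self-link, a duplicate
    link, or disconnect the graph are rejected and resampled (up to 100
    attempts, then the link is left in place), so the link count is exactly
    N·k/2 and the graph stays connected for any epsilon.
    """
    rng = np.random.default_rng(spec.seed)
    net = build_regular_ring(spec)
    if spec.epsilon == 0.0:
        return net
    g = nx.Graph()
    g.add_nodes_from(range(spec.n_agents))
    g.add_edges_from((a, b) for a, b, _ in net.links())
    for a, b in list(g.edges()):
        if rng.random() >= spec.epsilon:
            continue
        for _ in range(100):
            keep, move = (a, b) if rng.random() < 0.5 else (b, a)
            target = int(rng.integers(spec.n_agents))
            if target == keep or target == move or g.has_edge(keep, target):
                continue
            g.remove_edge(a, b)
            g.add_edge(keep, target)
            if nx.is_connected(g):
                break
            g.remove_edge(keep, target)
            g.add_edge(a, b)
        # all attempts failed: original link kept
    out = SignedOpinionNetwork(spec.n_agents)
    for u, v in g.edges():
        out.add_link(int(u), int(v), 1)
    return out


def randomize_state(
    net: SignedOpinionNetwork,
    p_plus: float = 0.5,
    p_up: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> SignedOpinionNetwork:
    """Draw i.i.d. link signs (+1 w.p. ``p_plus``) and opinions (+1 w.p.
    ``p_up``) in place; the topology is untouched.  Returns ``net``."""
    if not (0.0 <= p_plus <= 1.0 and 0.0 <= p_up <= 1.0):
        raise ValueError("p_plus and p_up must lie in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    net.opinions = np.where(
        rng.random(net.n_agents) < p_up, 1, -1
    ).astype(np.int8)
    for a, b in zip(net._ei, net._ej):
        s = 1 if rng.random() < p_plus else -1
        net._J[a, b] = net._J[b, a] = s
    return net


# ---------------------------------------------------------------------------
# stress evaluation
# ---------------------------------------------------------------------------


def _signed_triangle_sums(J: np.ndarray) -> tuple[int, int]:
    """(Σ_triangles J_ij J_jk J_ki, total triangle count), each triangle once.

    Uses trace identities: tr(J³) = 6 Σ_Δ sign-product and tr(A³) = 6 N_Δ
    for the unsigned adjacency A = |J|.  Integer matmul keeps this exact.
    """
    Jl = J.astype(np.int64)
    A = np.abs(Jl)
    signed6 = int(np.trace(Jl @ Jl @ Jl))
    total6 = int(np.trace(A @ A @ A))
    assert signed6 % 6 == 0 and total6 % 6 == 0
    return signed6 // 6, total6 // 6


def total_stress(net: SignedOpinionNetwork, params: ModelParams) -> float:
    """Exact social stress H of the current microstate.

    Each linked pair and each triangle is counted once.  When ``g`` and
    ``h`` are integers the result is exact integer arithmetic.
    """
    J = net._J.astype(np.int64)
    s = net.opinions.astype(np.int64)
    edge_sum = int(s @ J @ s) // 2  # Σ_(i,j) J_ij s_i s_j, each pair once
    tri_sum, _ = _signed_triangle_sums(net._J)
    n_neg = sum(1 for _, _, sg in net.links() if sg < 0)
    # (h/2) Σ (1 - J_ij) over linked pairs = h * (#negative links)
    return -edge_sum - params.g * tri_sum + params.h * n_neg


def ground_state_stress(net: SignedOpinionNetwork, params: ModelParams) -> float:
    """Global minimum of H for this topology: -(E + g·N_Δ).

    The all-positive, all-aligned configuration minimises every edge term,
    every triangle term and the h-term simultaneously, so the bound is
    attained exactly and no search is needed.
    """
    _, n_tri = _signed_triangle_sums(net._J)
    return -(net.n_links + params.g * n_tri)


def delta_stress_opinion_flip(
    net: SignedOpinionNetwork, params: ModelParams, i: int
) -> float:
    """ΔH for flipping opinion s_i, from i's incident ties only.

    Only the homophily term contains opinions, so
    ΔH = 2 s_i Σ_j J_ij s_j over the neighbours j of i.
    """
    if not 0 <= i < net.n_agents:
        raise IndexError(f"agent index {i} out of range")
    row = net._J[i].astype(np.int64)
    return float(2 * int(net.opinions[i]) * int(row @ net.opinions.astype(np.int64)))


def delta_stress_link_flip(
    net: SignedOpinionNetwork, params: ModelParams, i: int, j: int
) -> float:
    """ΔH for flipping the sign of tie J_ij.

    Flipping J negates the edge term, the sign product of every triangle
    through (i, j) (common neighbours of i and j), and shifts the h-term by
    h·J_ij:  ΔH = 2 J s_i s_j + 2 g J Σ_k J_jk J_ki + h J.
    """
    Jij = net.link_sign(i, j)  # raises if unlinked
    row_i = net._J[i].astype(np.int64)
    row_j = net._J[j].astype(np.int64)
    common = int(row_i @ row_j)  # Σ_k J_ik J_jk, zero unless k common
    si, sj = int(net.opinions[i]), int(net.opinions[j])
    return 2 * Jij * si * sj + 2.0 * params.g * Jij * common + params.h * Jij
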