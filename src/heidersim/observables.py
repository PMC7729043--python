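"""Order parameters and cluster structure of signed opinion networks.

Measures of social fragmentation:

* triangle census and the balance index ``f = (n₊ − n₋)/(n₊ + n₋)``,
* relative stress ``e_f = H / |H_ground|`` (−1 iff no tension remains),
* opinion alignment ``m = |Σ_i s_i| / N``,
* positive clusters (connected components of the positive-tie subgraph),
* the frustration-minimising partition of the signed graph (the signed
  blockmodel objective: positive ties between clusters plus negative ties
  within them), whose minimum value is the line index of balance,
* echo chambers: clusters of that partition whose members all hold the
  same opinion.

The partition objective is NP-hard; :func:`signed_partition` runs a greedy
node-move local search with random restarts, while
:func:`exhaustive_partition` provides the exact optimum for N ≤ 12 and
serves as the test oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .network_model import ModelParams, SignedOpinionNetwork, ground_state_stress, total_stress, _signed_triangle_sums

logger = logging.getLogger(__name__)

__all__ = [
    "UndefinedObservableError",
    "TriangleCensus",
    "Partition",
    "ClusterSizeReport",
    "triangle_census",
    "balance_f",
    "relative_stress_e_f",
    "opinion_alignment_m",
    "positive_clusters",
    "frustration_count",
    "signed_partition",
    "exhaustive_partition",
    "line_index",
    "echo_chambers",
]


class UndefinedObservableError(ValueError):
    """Raised when an order parameter is undefined for the given state
    (e.g. the balance index f on a triangle-free topology)."""


@dataclass(frozen=True)
class TriangleCensus:
    """Counts of balanced (sign product +1) and unbalanced triangles."""

    n_plus: int
    n_minus: int

    @property
    def total(self) -> int:
        return self.n_plus + self.n_minus


@dataclass
class Partition:
    """Cluster labels over agents plus the exact frustration of the
    labelling (positive inter-cluster ties + negative intra-cluster ties)."""

    labels: np.ndarray
    frustration: int


@dataclass
class ClusterSizeReport:
    """Sizes of positive clusters S(C_k) and echo chambers S(E)."""

    positive_cluster_sizes: list[int]
    echo_chamber_sizes: list[int]


def triangle_census(net: SignedOpinionNetwork) -> TriangleCensus:
    """Classify every triangle of the topology by its sign product."""
    signed, total = _signed_triangle_sums(net.adjacency_signed())
    n_plus = (total + signed) // 2
    return TriangleCensus(n_plus=n_plus, n_minus=total - n_plus)


def balance_f(census: TriangleCensus) -> float:
    """Balance index f = (n₊ − n₋)/(n₊ + n₋) ∈ [−1, 1].

    Triangle-free topologies leave f undefined (raised, not reported as 0,
    so they are never misread as maximally frustrated).  Negative values
    are possible in principle but not expected in stationary states; they
    are logged when encountered.
    """
    if census.total == 0:
        raise UndefinedObservableError("balance index f undefined: no triangles")
    f = (census.n_plus - census.n_minus) / census.total
    if f < 0:
        logger.warning("negative balance index f=%.3f observed", f)
    return f


def relative_stress_e_f(net: SignedOpinionNetwork, params: ModelParams) -> float:
    """Relative stress e_f = H / |H_ground| ≥ −1 for the current topology."""
    gs = ground_state_stress(net, params)
    if gs == 0:
        raise ValueError("relative stress undefined: empty topology")
    return total_stress(net, params) / abs(gs)


def opinion_alignment_m(net: SignedOpinionNetwork) -> float:
    """Overall opinion m = |Σ_i s_i| / N ∈ [0, 1]."""
    return abs(int(net.opinions.sum(dtype=np.int64))) / net.n_agents


def positive_clusters(net: SignedOpinionNetwork) -> ClusterSizeReport:
    """Connected components of the positive-tie subgraph; sizes sum to N."""
    J = net.adjacency_signed()
    pos = csr_matrix((J > 0).astype(np.int8))
    _, labels = connected_components(pos, directed=False)
    sizes = np.bincount(labels).tolist()
    return ClusterSizeReport(
        positive_cluster_sizes=sorted(sizes, reverse=True), echo_chamber_sizes=[]
    )


# ---------------------------------------------------------------------------
# frustration-minimising partition (signed blockmodel objective)
# ---------------------------------------------------------------------------


def frustration_count(net: SignedOpinionNetwork, labels: np.ndarray) -> int:
    """Positive ties between clusters plus negative ties within clusters."""
    labels = np.asarray(labels)
    count = 0
    for a, b, s in net.links():
        same = labels[a] == labels[b]
        if (s > 0 and not same) or (s < 0 and same):
            count += 1
    return count


@njit(cache=True)
def _greedy_moves(nbr, sgn, deg, labels, order, max_passes):
    """Local search: move single nodes to the incident-cluster (or fresh
    singleton) label that most reduces frustration, until a full pass makes
    no improving move.  `order` holds one shuffled node order per pass."""
    N = labels.shape[0]
    for pss in range(max_passes):
        improved = False
        for oi in range(N):
            v = order[pss, oi]
            dv = deg[v]
            if dv == 0:
                continue
            # score(l) = (#negative nbrs with label l) - (#positive nbrs with label l);
            # node cost in cluster l is P + score(l), so minimise score
            cand = np.empty(dv, np.int64)
            score = np.empty(dv, np.int64)
            nc = 0
            for t in range(dv):
                lu = labels[nbr[v, t]]
                w = 1 if sgn[v, t] < 0 else -1
                found = False
                for q in range(nc):
                    if cand[q] == lu:
                        score[q] += w
                        found = True
                        break
                if not found:
                    cand[nc] = lu
                    score[nc] = w
                    nc += 1
            cur = 0  # score of v's current label (0 if no neighbour shares it)
            for q in range(nc):
                if cand[q] == labels[v]:
                    cur = score[q]
                    break
            best_lab = np.int64(N + v)  # fresh singleton scores 0
            best = 0
            for q in range(nc):
                if score[q] < best:
                    best = score[q]
                    best_lab = cand[q]
            if best < cur:
                labels[v] = best_lab
                improved = True
        if not improved:
            break
    return labels


def _flat_adjacency(net: SignedOpinionNetwork):
    N = net.n_agents
    J = net.adjacency_signed()
    deg = np.count_nonzero(J, axis=1).astype(np.int64)
    cap = max(1, int(deg.max()))
    nbr = np.zeros((N, cap), dtype=np.int64)
    sgn = np.zeros((N, cap), dtype=np.int64)
    for i in range(N):
        nz = np.nonzero(J[i])[0]
        nbr[i, : nz.size] = nz
        sgn[i, : nz.size] = J[i, nz]
    return nbr, sgn, deg


def signed_partition(
    net: SignedOpinionNetwork,
    restarts: int = 20,
    seed: int | np.random.Generator = 0,
    max_passes: int = 50,
) -> Partition:
    """Heuristic frustration minimisation over partitions with a free
    number of clusters; best of ``restarts`` initialisations refined by
    greedy node moves.

    Single-node moves alone cannot merge two medium clusters even when a
    merge lowers frustration, so the first restart is seeded from the
    positive components (the natural coarse solution: splitting a positive
    component only creates positive cut ties), the second from
    all-singleton labels, and the rest from uniform random labels.  The
    returned frustration is recomputed exactly for the returned labelling.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    N = net.n_agents
    nbr, sgn, deg = _flat_adjacency(net)
    pos = csr_matrix((net.adjacency_signed() > 0).astype(np.int8))
    _, pos_labels = connected_components(pos, directed=False)
    best: Partition | None = None
    for r in range(max(1, restarts)):
        if r == 0:
            labels = pos_labels.astype(np.int64)
        elif r == 1:
            labels = np.arange(N, dtype=np.int64)
        else:
            labels = rng.integers(0, N, N)
        order = np.empty((max_passes, N), dtype=np.int64)
        for pss in range(max_passes):
            order[pss] = rng.permutation(N)
        labels = _greedy_moves(nbr, sgn, deg, labels.astype(np.int64), order, max_passes)
        frus = frustration_count(net, labels)
        if best is None or frus < best.frustration:
            # relabel clusters 0..c-1 for readability
            _, compact = np.unique(labels, return_inverse=True)
            best = Partition(labels=compact.astype(np.int64), frustration=frus)
            if frus == 0:
                break
    return best


def exhaustive_partition(net: SignedOpinionNetwork) -> Partition:
    """Exact minimum-frustration partition by enumerating all set
    partitions (restricted growth strings); feasible for N ≤ 12."""
    N = net.n_agents
    if N > 12:
        raise ValueError("exhaustive partition search limited to N <= 12")
    edges = [(a, b, s) for a, b, s in net.links()]

    best_labels = None
    best_frus = None

    def frus_of(labels) -> int:
        c = 0
        for a, b, s in edges:
            same = labels[a] == labels[b]
            if (s > 0 and not same) or (s < 0 and same):
                c += 1
        return c

    # iterate restricted growth strings
    a = [0] * N
    b = [1] * N  # b[i] = 1 + max(a[0..i-1])
    while True:
        f = frus_of(a)
        if best_frus is None or f < best_frus:
            best_frus = f
            best_labels = list(a)
        # next RGS
        i = N - 1
        while i > 0 and a[i] == b[i]:
            i -= 1
        if i == 0:
            break
        a[i] += 1
        for j in range(i + 1, N):
            a[j] = 0
        for j in range(1, N):
            b[j] = max(b[j - 1], a[j - 1] + 1)
    return Partition(labels=np.array(best_labels, dtype=np.int64), frustration=int(best_frus))


def line_index(partition: Partition) -> int:
    """Frustration of the partition: an upper bound on the line index of
    balance, exact when the partition is the exhaustive optimum."""
    return int(partition.frustration)


def echo_chambers(
    net: SignedOpinionNetwork,
    partition: Partition,
    largest_only: bool = False,
    include_singletons: bool = True,
) -> ClusterSizeReport:
    """Echo chambers: clusters of the frustration-minimising partition
    whose agents all hold the same opinion.

    Singleton clusters are trivially like-minded and count as size-1
    chambers unless ``include_singletons`` is False.  Positive-component
    sizes S(C_k) are reported alongside for reference.
    """
    labels = np.asarray(partition.labels)
    sizes = []
    for lab in np.unique(labels):
        members = np.nonzero(labels == lab)[0]
        if members.size == 1 and not include_singletons:
            continue
        ops = net.opinions[members]
        if np.all(ops == ops[0]):
            sizes.append(int(members.size))
    sizes.sort(reverse=True)
    if largest_only and sizes:
        sizes = sizes[:1]
    return ClusterSizeReport(
        positive_cluster_sizes=positive_clusters(net).positive_cluster_sizes,
        echo_chamber_sizes=sizes,
    )
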