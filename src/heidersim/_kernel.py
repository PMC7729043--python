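"""Numba-compiled inner loop of the Metropolis coevolution.

The kernel keeps the full microstate in flat arrays (opinions, dense signed
adjacency, neighbour lists with swap-delete, an indexable edge registry) and
maintains the social stress H, the signed triangle sum Σ_Δ J J J, the
triangle count and Σ_i s_i incrementally, so every order parameter is
available per time step at O(degree) cost per attempted move.

All bookkeeping here is integer-exact for integer g, h; the Python-level
operations in :mod:`heidersim.network_model` recompute the same quantities
from scratch and serve as the independent reference in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["seed_kernel", "simulate_chunk"]


@njit(cache=True)
def seed_kernel(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _common_sums(a, b, J, nbr, deg):
    """Σ_k J_ak J_bk over common neighbours k of a and b, plus their count."""
    if deg[b] < deg[a]:
        a, b = b, a
    ssum = 0
    cnt = 0
    for t in range(deg[a]):
        k = nbr[a, t]
        if k != b and J[b, k] != 0:
            ssum += J[a, k] * J[b, k]
            cnt += 1
    return ssum, cnt


@njit(cache=True, inline="always")
def _nbr_add(nbr, deg, a, b):
    nbr[a, deg[a]] = b
    deg[a] += 1
    nbr[b, deg[b]] = a
    deg[b] += 1


@njit(cache=True, inline="always")
def _nbr_remove(nbr, deg, a, b):
    for t in range(deg[a]):
        if nbr[a, t] == b:
            nbr[a, t] = nbr[a, deg[a] - 1]
            deg[a] -= 1
            break
    for t in range(deg[b]):
        if nbr[b, t] == a:
            nbr[b, t] = nbr[b, deg[b] - 1]
            deg[b] -= 1
            break


@njit(cache=True)
def simulate_chunk(
    s,            # int64[N] opinions, mutated in place
    J,            # int8[N, N] signed adjacency, mutated in place
    nbr,          # int32[N, cap] neighbour lists
    deg,          # int32[N] degrees
    ei, ej,       # int64[M] edge registry (endpoints of every tie)
    g, T, h,      # Hamiltonian / temperature parameters
    n_att,        # opinion attempts per step (0 when fractional regime)
    att_prob,     # per-step probability of a single attempt when n_att == 0
    p,            # probability a link update is a rewiring move
    homoph,       # True: new link sign +1 iff opinions agree
    fast_links,   # True: link update precedes the opinion attempts
    n_steps,
    fstate,       # float64[1]: running H
    istate,       # int64[3]: signed triangle sum, triangle count, Σ s_i
    out_H, out_tri_signed, out_tri_total, out_sum_s,  # per-step records
):
    N = s.shape[0]
    M = ei.shape[0]
    H = fstate[0]
    tri_s = istate[0]
    tri_t = istate[1]
    sum_s = istate[2]
    for step in range(n_steps):
        for phase in range(2):
            do_opinions = (phase == 0) != fast_links
            if do_opinions:
                na = n_att
                if na == 0 and np.random.random() < att_prob:
                    na = 1
                for _ in range(na):
                    i = np.random.randint(N)
                    acc = 0
                    for t in range(deg[i]):
                        j = nbr[i, t]
                        acc += J[i, j] * s[j]
                    dH = 2.0 * s[i] * acc
                    if dH <= 0.0 or np.random.random() < np.exp(-dH / T):
                        s[i] = -s[i]
                        H += dH
                        sum_s += 2 * s[i]
            else:
                if p > 0.0 and np.random.random() < p:
                    # compound rewiring proposal: delete one random tie,
                    # create one between a random currently-unlinked pair
                    e = np.random.randint(M)
                    a = ei[e]
                    b = ej[e]
                    Jab = J[a, b]
                    csum, ccnt = _common_sums(a, b, J, nbr, deg)
                    dH_rem = Jab * s[a] * s[b] + g * Jab * csum - 0.5 * h * (1 - Jab)
                    J[a, b] = 0
                    J[b, a] = 0
                    _nbr_remove(nbr, deg, a, b)
                    while True:
                        c = np.random.randint(N)
                        d = np.random.randint(N)
                        if c != d and J[c, d] == 0:
                            break
                    if homoph:
                        sign = 1 if s[c] == s[d] else -1
                    else:
                        sign = 1 if np.random.random() < 0.5 else -1
                    csum2, ccnt2 = _common_sums(c, d, J, nbr, deg)
                    dH_add = -sign * s[c] * s[d] - g * sign * csum2 + 0.5 * h * (1 - sign)
                    dH = dH_rem + dH_add
                    if dH <= 0.0 or np.random.random() < np.exp(-dH / T):
                        J[c, d] = sign
                        J[d, c] = sign
                        _nbr_add(nbr, deg, c, d)
                        ei[e] = c
                        ej[e] = d
                        H += dH
                        tri_s += sign * csum2 - Jab * csum
                        tri_t += ccnt2 - ccnt
                    else:
                        J[a, b] = Jab
                        J[b, a] = Jab
                        _nbr_add(nbr, deg, a, b)
                else:
                    e = np.random.randint(M)
                    a = ei[e]
                    b = ej[e]
                    Jab = J[a, b]
                    csum, _ = _common_sums(a, b, J, nbr, deg)
                    dH = 2.0 * Jab * s[a] * s[b] + 2.0 * g * Jab * csum + h * Jab
                    if dH <= 0.0 or np.random.random() < np.exp(-dH / T):
                        J[a, b] = -Jab
                        J[b, a] = -Jab
                        H += dH
                        tri_s += -2 * Jab * csum
        out_H[step] = H
        out_tri_signed[step] = tri_s
        out_tri_total[step] = tri_t
        out_sum_s[step] = sum_s
    fstate[0] = H
    istate[0] = tri_s
    istate[1] = tri_t
    istate[2] = sum_s
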