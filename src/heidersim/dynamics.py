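"""Metropolis coevolution of opinions and signed ties.

One time step performs ``round(n·N)`` single-opinion Metropolis attempts on
uniformly random agents, followed by one link update (a sign flip, or with
probability ``p`` a rewiring move).  Moves that lower the social stress H
are always accepted; stress-raising moves are accepted with probability
``exp(-ΔH/T)``, where T is the social temperature.  ΔH = 0 moves are
accepted deterministically.

Two execution paths implement the same chain: transparent Python operations
(:func:`opinion_sweep`, :func:`link_update`, :func:`step`) acting directly
on a :class:`~heidersim.network_model.SignedOpinionNetwork`, and a compiled
kernel used by :func:`run_to_stationarity` for production-scale runs.  The
tests hold the two against each other.

Convergence is declared by a sliding-window rule: at multiples of the
window length W (default ``k·N/10`` steps) the means of H over the two most
recent non-overlapping windows must differ by less than ``tol`` (default
0.5) with no monotone drift across the half-windows.  The convergence time
τ is reported in units of k·N time steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel
from .network_model import (
    ModelParams,
    SignedOpinionNetwork,
    delta_stress_link_flip,
    delta_stress_opinion_flip,
    total_stress,
    _signed_triangle_sums,
)

__all__ = [
    "Trajectory",
    "metropolis_accept",
    "opinion_sweep",
    "link_update",
    "step",
    "run_to_stationarity",
]


def metropolis_accept(delta_H: float, T: float, rng: np.random.Generator) -> bool:
    """Accept iff ΔH ≤ 0, else with probability exp(−ΔH/T)."""
    if T <= 0:
        raise ValueError(f"social temperature T must be > 0, got {T}")
    if delta_H <= 0:
        return True
    return rng.random() < np.exp(-delta_H / T)


def _n_attempts(params: ModelParams, N: int, rng: np.random.Generator) -> int:
    x = params.n * N
    if x >= 1:
        return int(round(x))
    return 1 if rng.random() < x else 0


def opinion_sweep(
    net: SignedOpinionNetwork, params: ModelParams, rng: np.random.Generator
) -> int:
    """round(n·N) single-opinion Metropolis attempts; returns accepted count.

    For n·N < 1 a single attempt is made with probability n·N (fast-link
    regime).  Links are untouched.
    """
    accepted = 0
    for _ in range(_n_attempts(params, net.n_agents, rng)):
        i = int(rng.integers(net.n_agents))
        dH = delta_stress_opinion_flip(net, params, i)
        if metropolis_accept(dH, params.T, rng):
            net.opinions[i] = -net.opinions[i]
            accepted += 1
    return accepted


def link_update(
    net: SignedOpinionNetwork, params: ModelParams, rng: np.random.Generator
) -> dict:
    """One link update: sign flip, or rewiring move with probability p.

    A rewiring move deletes a uniformly random tie, proposes a tie between a
    uniformly random currently-unlinked pair (sign per ``rewiring_mode``)
    and Metropolis-accepts the compound move on its exact ΔH.  The link
    count is conserved in every branch.
    """
    if net.n_links == 0:
        raise ValueError("link update requires at least one link")
    if params.p > 0 and rng.random() < params.p:
        idx = int(rng.integers(net.n_links))
        a, b = net.link_at(idx)
        H0 = total_stress(net, params)
        sign_ab = net.remove_link(a, b)
        while True:
            c, d = (int(x) for x in rng.integers(net.n_agents, size=2))
            if c != d and not net.has_link(c, d):
                break
        if params.rewiring_mode == "homophilious":
            sign_new = 1 if net.opinions[c] == net.opinions[d] else -1
        else:
            sign_new = 1 if rng.random() < 0.5 else -1
        net.add_link(c, d, sign_new)
        dH = total_stress(net, params) - H0
        accepted = metropolis_accept(dH, params.T, rng)
        if not accepted:
            net.remove_link(c, d)
            net.add_link(a, b, sign_ab)
        return {
            "kind": "rewire",
            "accepted": accepted,
            "removed": (a, b),
            "added": (c, d),
            "sign": sign_new,
            "delta_H": dH,
        }
    idx = int(rng.integers(net.n_links))
    a, b = net.link_at(idx)
    dH = delta_stress_link_flip(net, params, a, b)
    accepted = metropolis_accept(dH, params.T, rng)
    if accepted:
        net.flip_link(a, b)
    return {"kind": "flip", "accepted": accepted, "link": (a, b), "delta_H": dH}


def step(
    net: SignedOpinionNetwork,
    params: ModelParams,
    rng: np.random.Generator,
    fast_links: bool = False,
) -> SignedOpinionNetwork:
    """One time step: an opinion sweep then one link update (reversed under
    ``fast_links``)."""
    if fast_links:
        link_update(net, params, rng)
        opinion_sweep(net, params, rng)
    else:
        opinion_sweep(net, params, rng)
        link_update(net, params, rng)
    return net


# ---------------------------------------------------------------------------
# trajectory container and the compiled production path
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Time series of order parameters from one run.

    ``records`` holds (t, H, f, e_f, m) sampled every ``record_every``
    steps; ``tau`` is the convergence time in units of k·N time steps (None
    when the run hit ``max_steps`` unconverged).  ``stationary_*`` are means
    over the final window of per-step values.
    """

    records: pd.DataFrame
    tau: float | None
    converged: bool
    n_steps: int
    window: int
    mean_degree: float
    stationary_H: float = np.nan
    stationary_f: float = np.nan
    stationary_e_f: float = np.nan
    stationary_m: float = np.nan

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


class _KernelState:
    """Flat-array view of a network for the compiled kernel."""

    def __init__(self, net: SignedOpinionNetwork, params: ModelParams):
        N = net.n_agents
        self.net = net
        self.params = params
        self.s = net.opinions.astype(np.int64)
        self.J = net.adjacency_signed()
        self.deg = np.count_nonzero(self.J, axis=1).astype(np.int32)
        cap = max(int(self.deg.max()) + 8, 16) if params.p == 0 else N
        self.nbr = np.zeros((N, cap), dtype=np.int32)
        for i in range(N):
            nz = np.nonzero(self.J[i])[0]
            self.nbr[i, : nz.size] = nz
        M = net.n_links
        self.ei = np.empty(M, dtype=np.int64)
        self.ej = np.empty(M, dtype=np.int64)
        for idx, (a, b, _) in enumerate(net.links()):
            self.ei[idx] = a
            self.ej[idx] = b
        tri_signed, tri_total = _signed_triangle_sums(self.J)
        self.fstate = np.array([total_stress(net, params)], dtype=np.float64)
        self.istate = np.array(
            [tri_signed, tri_total, int(self.s.sum())], dtype=np.int64
        )
        x = params.n * N
        self.n_att = int(round(x)) if x >= 1 else 0
        self.att_prob = 0.0 if x >= 1 else x

    def run(self, n_steps: int, fast_links: bool):
        out_H = np.empty(n_steps, dtype=np.float64)
        out_ts = np.empty(n_steps, dtype=np.int64)
        out_tt = np.empty(n_steps, dtype=np.int64)
        out_ss = np.empty(n_steps, dtype=np.int64)
        p = self.params
        _kernel.simulate_chunk(
            self.s, self.J, self.nbr, self.deg, self.ei, self.ej,
            float(p.g), float(p.T), float(p.h),
            self.n_att, self.att_prob, float(p.p),
            p.rewiring_mode == "homophilious", fast_links,
            n_steps, self.fstate, self.istate,
            out_H, out_ts, out_tt, out_ss,
        )
        return out_H, out_ts, out_tt, out_ss

    def write_back(self) -> None:
        net = self.net
        net.opinions = self.s.astype(np.int8)
        net._J = self.J
        net._ei = []
        net._ej = []
        net._epos = {}
        for a, b in zip(self.ei, self.ej):
            a, b = (int(a), int(b)) if a < b else (int(b), int(a))
            net._epos[(a, b)] = len(net._ei)
            net._ei.append(a)
            net._ej.append(b)


def _drifting(H: np.ndarray) -> bool:
    """True when the four half-window means are strictly monotone."""
    q = len(H) // 4
    if q == 0:
        return False
    m = [H[i * q : (i + 1) * q].mean() for i in range(4)]
    return (m[0] > m[1] > m[2] > m[3]) or (m[0] < m[1] < m[2] < m[3])


def run_to_stationarity(
    net: SignedOpinionNetwork,
    params: ModelParams,
    max_steps: int | None = None,
    seed: int = 0,
    window: int | None = None,
    tol: float = 0.5,
    record_every: int | None = None,
    fast_links: bool = False,
    min_steps: int = 0,
) -> Trajectory:
    """Iterate time steps until the windowed stationarity criterion fires.

    The criterion fires at the first step t where the means of H over the
    two most recent non-overlapping windows of length W (``window``,
    default k·N/10) differ by less than ``tol`` and H shows no monotone
    drift across the half-windows.  At that point the whole stretch
    [t − 2W, t] has been stationary, so the convergence time is its onset:
    τ = (t − 2W)/(k·N).  Default ``max_steps = 50·k·N``.  ``net`` is
    evolved in place to the final state.

    Non-convergence within ``max_steps`` is signalled by ``tau is None``;
    stationary means are still reported over the final window.  The
    criterion is not consulted before ``min_steps``.
    """
    if max_steps is not None and max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    if net.n_links == 0:
        raise ValueError("dynamics require at least one link")
    N = net.n_agents
    kN = net.mean_degree * N  # = 2 * n_links
    kN_int = max(1, int(round(kN)))
    if window is None:
        window = max(10, kN_int // 10)
    if max_steps is None:
        max_steps = 50 * kN_int
    if record_every is None:
        record_every = max(1, window // 10)

    _kernel.seed_kernel(int(seed) & 0x7FFFFFFF)
    state = _KernelState(net, params)

    H_all = np.empty(max_steps, dtype=np.float64)
    ts_all = np.empty(max_steps, dtype=np.int64)
    tt_all = np.empty(max_steps, dtype=np.int64)
    ss_all = np.empty(max_steps, dtype=np.int64)
    done = 0
    converged = False
    t_fire = None
    # smallest step at which the criterion can fire; min_steps guards
    # observables (e.g. consensus formation under h) whose relaxation is
    # much slower than that of H
    checked = max(2 * window, int(min_steps))
    cumsum = np.zeros(max_steps + 1, dtype=np.float64)
    while done < max_steps:
        chunk = min(window, max_steps - done)
        oH, ots, ott, oss = state.run(chunk, fast_links)
        H_all[done : done + chunk] = oH
        ts_all[done : done + chunk] = ots
        tt_all[done : done + chunk] = ott
        ss_all[done : done + chunk] = oss
        cumsum[done + 1 : done + chunk + 1] = cumsum[done] + np.cumsum(oH)
        done += chunk
        if done >= checked:
            # sliding check at every step t in the newly available range
            ts = np.arange(checked, done + 1)
            m2 = (cumsum[ts] - cumsum[ts - window]) / window
            m1 = (cumsum[ts - window] - cumsum[ts - 2 * window]) / window
            for idx in np.nonzero(np.abs(m1 - m2) < tol)[0]:
                t = int(ts[idx])
                if not _drifting(H_all[t - 2 * window : t]):
                    converged = True
                    t_fire = t
                    break
            checked = done + 1
        if converged:
            break
    state.write_back()

    M = net.n_links
    with np.errstate(invalid="ignore", divide="ignore"):
        f_all = np.where(
            tt_all[:done] > 0, ts_all[:done] / np.maximum(tt_all[:done], 1), np.nan
        )
        gs_abs = M + params.g * tt_all[:done]
        ef_all = H_all[:done] / gs_abs
    m_all = np.abs(ss_all[:done]) / N

    rec_idx = np.arange(record_every - 1, done, record_every)
    if rec_idx.size == 0 or rec_idx[-1] != done - 1:
        rec_idx = np.append(rec_idx, done - 1)
    records = pd.DataFrame(
        {
            "t": rec_idx + 1,
            "H": H_all[rec_idx],
            "f": f_all[rec_idx],
            "e_f": ef_all[rec_idx],
            "m": m_all[rec_idx],
        }
    )
    tail_end = t_fire if t_fire is not None else done
    tail = slice(max(0, tail_end - window), tail_end)
    return Trajectory(
        records=records,
        tau=(t_fire - 2 * window) / kN if converged else None,
        converged=converged,
        n_steps=done,
        window=window,
        mean_degree=net.mean_degree,
        stationary_H=float(H_all[tail].mean()),
        stationary_f=float(np.nanmean(f_all[tail])) if np.any(~np.isnan(f_all[tail])) else np.nan,
        stationary_e_f=float(ef_all[tail].mean()),
        stationary_m=float(m_all[tail].mean()),
    )
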