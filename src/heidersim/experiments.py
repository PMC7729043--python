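"""Experiment drivers: phase-diagram scans, hysteresis sweeps, external
field scans and convergence-time distributions, plus worked-example
fixtures.

Each driver builds topologies, randomises initial opinions and link signs
(i.i.d. equiprobable by default), runs the Metropolis coevolution to
stationarity and aggregates the stationary order parameters over R
independent realizations.  All randomness derives from a single integer
seed via ``numpy.random.SeedSequence`` spawning, so every result table is
bit-reproducible given (config, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import Trajectory, run_to_stationarity
from .network_model import (
    ModelParams,
    SignedOpinionNetwork,
    TopologySpec,
    build_regular_ring,
    build_small_world,
    randomize_state,
)
from .observables import echo_chambers, positive_clusters, signed_partition, triangle_census

__all__ = [
    "Fixture",
    "ScanResult",
    "HysteresisResult",
    "TauResult",
    "fixture_k4_fig2",
    "simulate_run",
    "phase_diagram_scan",
    "hysteresis_sweep",
    "external_field_scan",
    "convergence_time_experiment",
]


@dataclass
class Fixture:
    name: str
    state: SignedOpinionNetwork
    params: ModelParams


@dataclass
class ScanResult:
    """Grid scan of stationary order parameters.

    ``cells`` is a long-format table with one row per grid cell carrying
    means and standard errors over R realizations.
    """

    axes: dict
    cells: pd.DataFrame
    realizations: int


@dataclass
class HysteresisResult:
    """Balance index f along an ascending then descending temperature path,
    the final state of each temperature seeding the next."""

    t_path: np.ndarray
    f_up: np.ndarray
    f_down: np.ndarray
    se_up: np.ndarray
    se_down: np.ndarray
    realizations: int


@dataclass
class TauResult:
    """Convergence times of independent realizations, in k·N step units."""

    taus: np.ndarray
    n_censored: int
    mean: float
    variance: float


def fixture_k4_fig2() -> Fixture:
    """Four mutually acquainted agents with two balanced and two unbalanced
    triangles — the worked starting point for stress relaxation to H = −10.

    All opinions +1; the single negative tie (0, 1) frustrates exactly the
    two triangles through it, so the census is (2, 2) and H = −4 > −10.
    """
    net = SignedOpinionNetwork(4)
    for i in range(4):
        for j in range(i + 1, 4):
            net.add_link(i, j, -1 if (i, j) == (0, 1) else 1)
    census = triangle_census(net)
    assert (census.n_plus, census.n_minus) == (2, 2)
    return Fixture(name="k4_worked_example", state=net, params=ModelParams(g=1.0, T=0.5))


def _build_topology(n_agents: int, k: int, epsilon: float, seed: int) -> SignedOpinionNetwork:
    spec = TopologySpec(n_agents=n_agents, k=k, epsilon=epsilon, seed=seed)
    return build_regular_ring(spec) if epsilon == 0 else build_small_world(spec)


def simulate_run(
    n_agents: int,
    k: int,
    params: ModelParams,
    epsilon: float = 0.0,
    p_plus: float = 0.5,
    p_up: float = 0.5,
    seed: int = 0,
    max_steps: int | None = None,
    **run_kwargs,
) -> tuple[SignedOpinionNetwork, Trajectory]:
    """Build topology, randomise the state and run to stationarity."""
    ss = np.random.SeedSequence(seed)
    topo_seed, state_seed, run_seed = (int(s) for s in ss.generate_state(3) >> 1)
    net = _build_topology(n_agents, k, epsilon, topo_seed)
    randomize_state(net, p_plus=p_plus, p_up=p_up, seed=state_seed)
    traj = run_to_stationarity(net, params, max_steps=max_steps, seed=run_seed, **run_kwargs)
    return net, traj


def _cell_runs(n_agents, k, params, epsilon, p_plus, p_up, R, child_seeds, max_steps, **kw):
    for r in range(R):
        yield simulate_run(
            n_agents, k, params, epsilon=epsilon, p_plus=p_plus, p_up=p_up,
            seed=int(child_seeds[r]), max_steps=max_steps, **kw,
        )


def phase_diagram_scan(
    k_values,
    T_values,
    n_agents: int = 400,
    epsilon: float = 0.0,
    g: float = 1.0,
    h: float = 0.0,
    n: float = 1.0,
    p: float = 0.0,
    rewiring_mode: str = "random_sign",
    p_plus: float = 0.5,
    p_up: float = 0.5,
    R: int = 50,
    seed: int = 0,
    max_steps: int | None = None,
) -> ScanResult:
    """Stationary f, e_f, m on a (k, T) grid, averaged over R realizations.

    The stationary value of each run is its mean over the post-convergence
    window.  Grid cells that cannot be built (odd k, k ≥ N) are marked
    invalid rather than aborting the scan.
    """
    ss = np.random.SeedSequence(int(seed))
    rows = []
    for k in k_values:
        for T in T_values:
            child = ss.spawn(1)[0].generate_state(R) >> 1
            try:
                TopologySpec(n_agents=n_agents, k=int(k), epsilon=epsilon)
            except ValueError:
                rows.append(
                    dict(k=k, T=T, valid=False, mean_f=np.nan, se_f=np.nan,
                         mean_e_f=np.nan, mean_m=np.nan, R=0)
                )
                continue
            params = ModelParams(g=g, T=float(T), h=h, n=n, p=p, rewiring_mode=rewiring_mode)
            fs, efs, ms = [], [], []
            for _, traj in _cell_runs(
                n_agents, int(k), params, epsilon, p_plus, p_up, R, child, max_steps
            ):
                fs.append(traj.stationary_f)
                efs.append(traj.stationary_e_f)
                ms.append(traj.stationary_m)
            fs = np.asarray(fs)
            rows.append(
                dict(
                    k=k, T=T, valid=True,
                    mean_f=float(np.nanmean(fs)),
                    se_f=float(np.nanstd(fs) / np.sqrt(max(1, len(fs)))),
                    mean_e_f=float(np.mean(efs)),
                    mean_m=float(np.mean(ms)),
                    R=R,
                )
            )
    return ScanResult(
        axes={"k": list(k_values), "T": list(T_values)},
        cells=pd.DataFrame(rows),
        realizations=R,
    )


def hysteresis_sweep(
    k: int,
    T_path,
    n_agents: int = 50,
    g: float = 1.0,
    h: float = 0.0,
    n: float = 1.0,
    p_plus: float = 0.5,
    p_up: float = 0.5,
    R: int = 50,
    seed: int = 0,
    steps_per_T: int | None = None,
) -> HysteresisResult:
    """Sweep T up the given grid and back down, carrying the final state of
    each temperature into the next; f is measured over the final window at
    each temperature.  Demonstrates the first-order character of the
    fragmentation transition (branch separation at high connectivity).
    """
    T_path = np.asarray(sorted(T_path), dtype=float)
    kN = k * n_agents
    if steps_per_T is None:
        steps_per_T = 5 * kN
    window = max(10, kN // 10)
    ss = np.random.SeedSequence(int(seed))
    f_up = np.full((R, len(T_path)), np.nan)
    f_down = np.full((R, len(T_path)), np.nan)
    for r, child in enumerate(ss.spawn(R)):
        seeds = child.generate_state(2 * len(T_path) + 2) >> 1
        net = _build_topology(n_agents, k, 0.0, int(seeds[0]))
        randomize_state(net, p_plus=p_plus, p_up=p_up, seed=int(seeds[1]))
        si = 2
        for ti, T in enumerate(T_path):
            params = ModelParams(g=g, T=float(T), h=h, n=n)
            traj = run_to_stationarity(
                net, params, max_steps=steps_per_T, seed=int(seeds[si]), window=window
            )
            f_up[r, ti] = traj.stationary_f
            si += 1
        for ti in range(len(T_path) - 1, -1, -1):
            params = ModelParams(g=g, T=float(T_path[ti]), h=h, n=n)
            traj = run_to_stationarity(
                net, params, max_steps=steps_per_T, seed=int(seeds[si]), window=window
            )
            f_down[r, ti] = traj.stationary_f
            si += 1
    return HysteresisResult(
        t_path=T_path,
        f_up=np.nanmean(f_up, axis=0),
        f_down=np.nanmean(f_down, axis=0),
        se_up=np.nanstd(f_up, axis=0) / np.sqrt(R),
        se_down=np.nanstd(f_down, axis=0) / np.sqrt(R),
        realizations=R,
    )


def external_field_scan(
    h_values,
    T_values,
    n_agents: int = 200,
    k: int = 10,
    g: float = 1.0,
    n: float = 1.0,
    epsilon: float = 0.0,
    p_plus: float = 0.5,
    p_up: float = 0.5,
    R: int = 20,
    seed: int = 0,
    max_steps: int | None = None,
) -> ScanResult:
    """Stationary opinion alignment m (and the fraction of negative ties)
    on an (h, T) grid; beyond a critical field most negative ties are
    eliminated and m → 1 (global consensus).

    Consensus formation is an order of magnitude slower than stress
    equilibration, so each run is held for at least 10·k·N steps before the
    stationarity criterion may fire.
    """
    ss = np.random.SeedSequence(int(seed))
    min_steps = 10 * k * n_agents
    rows = []
    for h in h_values:
        for T in T_values:
            child = ss.spawn(1)[0].generate_state(R) >> 1
            params = ModelParams(g=g, T=float(T), h=float(h), n=n)
            ms, fs, negs = [], [], []
            for net, traj in _cell_runs(
                n_agents, k, params, epsilon, p_plus, p_up, R, child, max_steps,
                min_steps=min_steps,
            ):
                ms.append(traj.stationary_m)
                fs.append(traj.stationary_f)
                n_neg = sum(1 for _, _, s in net.links() if s < 0)
                negs.append(n_neg / net.n_links)
            rows.append(
                dict(
                    h=h, T=T, valid=True,
                    mean_m=float(np.mean(ms)),
                    se_m=float(np.std(ms) / np.sqrt(R)),
                    mean_f=float(np.nanmean(fs)),
                    mean_neg_frac=float(np.mean(negs)),
                    R=R,
                )
            )
    return ScanResult(
        axes={"h": list(h_values), "T": list(T_values)},
        cells=pd.DataFrame(rows),
        realizations=R,
    )


def convergence_time_experiment(
    n_agents: int = 200,
    k: int = 10,
    T: float = 1.0,
    g: float = 1.0,
    h: float = 0.0,
    n: float = 1.0,
    epsilon: float = 0.0,
    p_plus: float = 0.5,
    p_up: float = 0.5,
    R: int = 100,
    seed: int = 0,
    max_steps: int | None = None,
) -> TauResult:
    """Distribution of convergence times τ (k·N step units) over R
    independent realizations; runs hitting max_steps are reported as
    censored and excluded from the moments with a warning."""
    if R < 2:
        raise ValueError("need at least 2 realizations")
    ss = np.random.SeedSequence(int(seed))
    child = ss.generate_state(R) >> 1
    params = ModelParams(g=g, T=T, h=h, n=n)
    taus = []
    censored = 0
    for _, traj in _cell_runs(
        n_agents, k, params, epsilon, p_plus, p_up, R, child, max_steps
    ):
        if traj.tau is None:
            censored += 1
        else:
            taus.append(traj.tau)
    if censored:
        warnings.warn(
            f"{censored}/{R} runs hit max_steps unconverged; excluded from moments"
        )
    taus = np.asarray(taus)
    return TauResult(
        taus=taus,
        n_censored=censored,
        mean=float(taus.mean()) if taus.size else np.nan,
        variance=float(taus.var(ddof=1)) if taus.size > 1 else np.nan,
    )
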