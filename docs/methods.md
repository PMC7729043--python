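# Methods

## Model

The microstate is a signed graph with node opinions: `s_i ∈ {−1, +1}` per
agent, `J_ij ∈ {−1, +1}` per tie, `J_ij = 0` for unconnected pairs.  The
social stress is

```
H = − Σ_(i,j) J_ij s_i s_j − g Σ_(i,j,k) J_ij J_jk J_ki + (h/2) Σ_(i,j) (1 − J_ij)
```

with the pair sums over each linked pair once and the triangle sum over
each closed triangle once.  This single-counting convention is normative:
double counting would rescale `g`, `T` and `h` and silently move every
phase boundary.  When `g` and `h` are integers all three terms are
integers and the implementation keeps the arithmetic exact (int64 trace
identities for the triangle terms), which makes the small-instance
enumeration oracles bit-exact.

Model assumptions worth making explicit: opinions are binary and scalar;
ties are symmetric, unweighted and conserved in number; agents accept or
reject single local changes as if they could evaluate the global stress
difference (which reduces to an O(degree) local computation for every move
type); and one social temperature `T` governs both opinion and tie
volatility.

## Parameters

| name | meaning | default | notes |
|------|---------|---------|-------|
| `g`  | balance-term weight relative to homophily | 1 | ≥ 0; `g = 1` is the study condition everywhere |
| `T`  | social temperature of the Metropolis rule | 1 | > 0; phase transition in `T` at fixed `k` |
| `h`  | pro-social field suppressing negative ties | 0 | ≥ 0; competes with `g` |
| `n`  | opinion/link relative update rate | 1 | one step = round(`n·N`) opinion attempts + 1 link attempt; `n·N < 1` handled probabilistically (fast-link regime, `fast_links` reverses the order) |
| `p`  | probability a link update rewires instead of flipping | 0 | compound delete+add move, evaluated as one Metropolis proposal on its exact ΔH |
| `rewiring_mode` | sign of a created tie | `random_sign` | `homophilious`: +1 iff endpoints agree |
| `p_plus`, `p_up` | initial fraction of positive ties / up opinions | 0.5, 0.5 | i.i.d. draws; the symmetric values are the study's random initial condition |
| `epsilon` | small-world rewiring probability | 0 | 0 = ring lattice, 1 = random graph |

## Dynamics and acceptance rule

Moves that do not increase `H` (including ΔH = 0) are always accepted;
stress-raising moves with probability `exp(−ΔH/T)`.  Accepting ΔH = 0
deterministically matters at low `T`, where zero-cost opinion drift inside
aligned clusters is the only surviving motion.

Incremental stress differences are closed-form local sums:

* opinion flip: `ΔH = 2 s_i Σ_j J_ij s_j` (the balance and field terms
  contain no `s`),
* tie sign flip: `ΔH = 2 J_ij s_i s_j + 2 g J_ij Σ_k J_ik J_jk + h J_ij`
  with `k` over common neighbours,
* rewiring: the deletion and addition contributions evaluated in sequence
  on the intermediate state.

The compiled kernel maintains `H`, the signed triangle sum `Σ_Δ J J J`,
the triangle count and `Σ_i s_i` incrementally, so `f`, `e_f` and `m` are
available every step at no extra cost.  The Python-level operations
recompute everything from scratch and the test suite holds the two paths
against each other exactly (integer arithmetic, 10⁴ random flips).

Uniform link selection under rewiring uses an indexable edge registry with
swap-delete, so proposals stay O(1) while the link set churns.

## Stationarity criterion and τ

The criterion (the model itself defines none) is a sliding-window rule:
with `W = k·N/10` steps (`window`) and `tol = 0.5`, the chain is declared
stationary at the first step `t` where the means of `H` over `[t−2W, t−W)`
and `[t−W, t)` differ by less than `tol` and the four half-window means
are not strictly monotone (a drift guard).  Because the whole stretch
`[t−2W, t]` is then stationary, the convergence time is reported as its
onset, `τ = (t − 2W)/(k·N)` — the detection step would include the 2W
verification lag, a measurement artifact.  Runs are capped at
`max_steps = 50·k·N`; hitting the cap leaves `τ` absent (censored) and
stationary means are taken over the final window.  At the reference
conditions (`N = 200`, `k = 10`, `T = 1`, `g = 1`) this yields a mean τ of
about 2.4 `kN` steps.

"Stationary f/e_f/m" of a run are per-step means over the detected
stationary window; scans then average across independent realizations.

Consensus formation under an external field is an order of magnitude
slower than `H` equilibration (alignment proceeds by near-zero-cost
opinion drift), so `external_field_scan` holds every run for at least
`10·k·N` steps (`min_steps`) before the criterion may fire; otherwise the
scan reports transient mixtures as stationary.

## Observables

* Triangle census via exact integer trace identities
  (`tr J³ = 6 Σ_Δ J J J`, `tr |J|³ = 6 N_Δ`); `f = (n₊ − n₋)/(n₊ + n₋)`.
  On triangle-free topologies `f` is undefined and raised as such, never
  reported as 0.
* `e_f = H / (E + g N_Δ)`: the ground state of a fixed topology is exactly
  `−(E + g N_Δ)` because the all-positive, all-aligned configuration
  minimises every term simultaneously (verified against exhaustive
  enumeration for all connected topologies with N ≤ 4 and spot checks at
  N = 5).
* Positive clusters: connected components of the positive-tie subgraph
  (scipy union-find).
* Signed partition: minimises frustration (positive ties between clusters
  + negative ties within) over partitions with a free number of clusters.
  The objective is NP-hard; the heuristic is greedy single-node moves to
  the incident-cluster or fresh-singleton label that most reduces
  frustration, iterated to a local optimum, best of 20 restarts.  Node
  moves alone cannot merge two medium clusters even when a merge pays, so
  the first restart is seeded from the positive components (splitting a
  positive component only creates positive cut ties, so they are a natural
  coarse optimum), the second from singletons, the rest from uniform
  random labels.  An exhaustive restricted-growth-string search (N ≤ 12)
  serves as the exact reference; on random graphs with N ≤ 8 the heuristic
  matches it in well over 90% of cases and can never beat it.
* Echo chambers: clusters of the frustration-minimising partition whose
  members all hold one opinion; singletons count (size 1) unless excluded.
  All chambers per state are reported; a `largest_only` flag restricts to
  the maximum.  The line index of balance is the partition's frustration
  (an upper bound; exact with the exhaustive search).

## Synthetic topologies and initial states

`build_regular_ring` gives the regular benchmark topology (every agent
tied to its k/2 nearest neighbours per side).  `build_small_world`
detaches one uniformly chosen endpoint of each tie with probability ε and
re-attaches it to a uniform non-neighbour, rejecting self-links, duplicate
links and disconnecting moves (≤ 100 resamples per tie, then the tie stays
put); link count is conserved exactly and the graph stays connected.
Initial opinions and signs are i.i.d. (`p_up`, `p_plus`).

These generators emulate the study conditions, not real social networks:
degree distributions are narrow, clustering is geometric (ring
neighbourhoods), there is no community structure, degree assortativity or
heavy tail, and ties are binary and static in number.  Passing tests
therefore demonstrate the model's collective behaviour on controlled
topologies; they do not certify behaviour on empirical signed networks,
which users can load via the CSV edge-list interface.

## Numerical choices and degenerate inputs

* Exact integer stress whenever `g`, `h` are integers; float comparisons
  elsewhere use ≤ 1e−9 tolerances.
* Kernel RNG is numba's Mersenne Twister seeded per run from the supplied
  seed (masked to < 2³¹); all experiment drivers derive per-realization
  seeds from one `SeedSequence`, making every result table bit-reproducible
  given (config, seed).
* Triangle-free topologies: the balance term is inert; dynamics with any
  `g` coincide with `g = 0` at equal seeds (tested), and `f` is undefined.
* Agents without ties flip freely (ΔH = 0); empty-topology relative stress
  is an error.
* Ties in the greedy partition move are broken toward keeping the current
  label; cluster ids are compacted before returning.

## Problem sizes used by tests and the acceptance script

Phase-extreme means use N = 400 with 50 realizations per cell, cluster
extremes 100 realizations, convergence times N = 200 with 100
realizations, and the hysteresis demonstration N = 50, k = 30 with 20
realizations on a T = 4…20 grid — sizes chosen so the full suite and the
acceptance script each complete in minutes on one core while keeping
standard errors a small fraction of the effects measured.  Published
heat-map-scale statistics (hundreds to thousands of realizations per grid
cell) are reproduced qualitatively, not cell by cell.

## Known limitations

* Dense int8 adjacency plus N×N neighbour capacity under rewiring bounds
  practical sizes to N ≈ a few thousand (ample for the desk-scale studies
  the drivers target).
* One temperature for opinions and ties; no Glauber/heat-bath variants; no
  weighted, directed or multilayer ties; opinions are binary scalars.
* The hysteresis protocol (state carried across adjacent temperatures,
  fixed `5·k·N` steps per temperature before measuring) is a convention;
  branch positions depend on sweep rate as in any first-order transition.
* The signed partition is a heuristic; its frustration is an upper bound
  on the line index for N > 12.
* The compound rewiring proposal draws its target pair and sign as part of
  the proposal; Metropolis acceptance on its exact ΔH conserves link count
  but detailed balance w.r.t. exp(−H/T) is only guaranteed for the
  fixed-topology move set (p = 0), which is the regime of every
  quantitative claim here.
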