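# Methods

## Model and assumptions

The weighted voter model runs in continuous time on a simple undirected
graph of `N` agents. Each agent holds an opinion (a site index), a
measured quality `T > 0` for that site (a mean holding time), and signals
the opinion for an `Exp(1/T)` period before copying a uniformly random
neighbour and re-measuring the adopted site's quality — a fresh,
independent draw even when the opinion is unchanged. Measurements are
i.i.d. across agents and across an agent's own re-measurements; there is
no agent heterogeneity. Consensus is the first time all agents agree
(on any option, in the best-of-*n* setting).

Units: the better site's mean signalling time is normalised to 1, so all
times are reported in that unit and `λ = 1/q_B > 1` is the worse-option
update rate (noise-free) or `λ = 1/E[T_B]` (noisy).

Key structural facts the package relies on:

* On connected regular graphs the better-option count is a martingale
  transform with state-independent jump odds `λ : 1`, giving the exact
  gambler's-ruin fixation probability; topology enters only the time to
  consensus, through the isoperimetric constant `η`.
* On the complete graph the count is itself a birth–death chain with
  residence means `(N−1)/((1+λ) j (N−j))` in state `j` (derived from the
  per-agent rates: total exit rate `j(N−j)(1+λ)/(N−1)`; validated in the
  tests against simulated sojourn times). Expected absorption times follow
  from one banded solve of `(I−P)x = τ` on the transient states — the
  fundamental-matrix computation without forming the inverse.
* With noisy measurements and a rare better-option lineage in a large
  well-mixed population, the lineage is a multitype branching process:
  type = measured rate `r = 1/T`, lifetime `Exp(r)`, births at rate
  `λ = 1/E[T_B]` (the renewal rate of worse-option signalling cycles,
  which depends on noise only through its mean), child types i.i.d. fresh
  measurements.

## Numerical choices

* **Fixation formulas** are evaluated in the `λ^(−x)` parameterisation
  (`expm1` differences), so `λ^N` never overflows; `N = 10^6` at
  `λ = 1.1` is exact to machine precision and fixation + error
  probabilities sum to 1 to ~1e−15. `λ = 1` is handled as the classical
  voter limit `l/N`; qualities in either order are accepted and relabelled
  so the focal option is the better one.
* **Fixed point `c*`**: the map `h(c) = E[λcT/(λcT+1)]` is evaluated in
  T-space, so heavy rate tails (`E[1/T] = ∞` for gamma shapes ≤ 1) are
  harmless — only `λE[T_A] > 1` decides supercriticality, with
  `|λE[T_A] − 1| < 1e−12` treated as critical (extinction certain).
  Iterating `h` from `min(1e−12, tol)` (since `h(0) = 0` is itself a fixed
  point) and from 1 gives monotone lower/upper brackets; the solver stops
  when the bracket is below `tol` (default 1e−12) and returns the
  midpoint, optionally with the full bracket history. Gamma expectations
  use adaptive quadrature at 1e−13 absolute / 1e−12 relative tolerance;
  finite supports and point masses are closed-form.
* **Finite-support oracle**: the generating-function iteration
  `u_i ← r_i/(r_i + λ(1 − Σ p_j u_j))` from the zero vector converges to
  the minimal solution (the per-type extinction probabilities) and is kept
  as an independent cross-check of the scalar route; the two agree to
  1e−9 on randomised supports in the tests.
* **Isoperimetric constant**: exact enumeration visits one representative
  of each `{S, S^c}` bipartition (2^(N−1) subsets, vectorised over bit
  masks) and divides each cut by its smaller side; hard cap `N ≤ 20` —
  exactness beats scale for an oracle, and the general problem is NP-hard.
  Closed forms: `⌈N/2⌉` for complete graphs; for the expanded cycle the
  minimising cut is a contiguous arc of `⌊N/2⌋` nodes with `m(m+1)`
  crossing edges (`m = d/2`), so the closed form `2m(m+1)/N` is exact for
  even `N` (the case the protocols use) and the brute-force oracle covers
  odd `N`. For random `d`-regular graphs the high-probability lower bound
  `d/2 − √(d ln 2)` (natural log) is used; substituted into the
  regular-graph time bound it yields `4(1+ln N)/((λ−1)(1−√(ln2/d)))`, the
  form evaluated by `bollobas_time_bound`.

## Simulator design

Scheduling exploits a structural property: an agent's update rate changes
only when the agent itself fires. The simulator therefore keeps exactly
one pending firing event per agent in a binary heap — equal in law to
racing all exponential clocks, O(log N) per event, and with no event
invalidation. A measurement lag is an independent `Exp(lag_mean)` delay
added to the agent's own next firing time (its update clock is frozen
while it measures); with the copy-current-preference convention (a
lagging agent exposes its already-adopted opinion to neighbours) this is
exactly the side-queue semantics folded into the agent's schedule. The
readable single-event path (`Simulation.step`) and the tight replicate
loop (`run`) consume the random stream identically; a test asserts
bit-identical trajectories.

**Lag semantics and fixation.** Freezing the update clock during the lag
makes each opinion-holding cycle `Exp(L) + Exp(q)`, so the per-jump odds
shift from `q_A/q_B` to `(L+q_A)/(L+q_B)`: a common measurement lag
*dilutes* the quality signal, and fixation tracks the gambler's-ruin value
at the effective ratio (tested). A protocol in which the lag enters only
the reported clock while update order still follows the `1/q` weights
would leave fixation exactly invariant, but it does not correspond to a
self-consistent continuous-time agent model, so this package implements
the physical semantics and documents the difference. Consensus time
increases strictly with the lag either way.

**Dynamic rewiring.** When enabled, the updating agent severs its `d`
edges, connects to `d` uniformly chosen non-neighbours, and each severed
neighbour `v` is matched to a new neighbour `w`: a random edge `(w, x)`
with `x ∉ {u, v}` and `x` not already adjacent to `v` is removed and
`(x, v)` added, preserving every degree. Collisions are resampled up to 64
times, after which the whole move is rolled back (the graph also stays
unchanged when fewer than `d` candidate neighbours exist, e.g. on the
complete graph). Connectivity is not enforced — the move preserves the
degree sequence, which is what the theory's robustness statement needs —
and the tests assert regularity and simplicity across thousands of moves.

**Initial conditions.** `fresh` draws each agent's initial quality from
the measurement distribution; `size_biased` draws from the
size-biased transform (point → itself, gamma(a, θ) → gamma(a+1, θ),
finite support reweighted by `t`), which is the steady-state distribution
of the quality held by a randomly inspected agent — the stationary regime,
since the residual of an exponential holding time is again exponential.
Modes may be set per option: the regime the branching approximation
describes is a *fresh* measurement for the rare better-option seed inside
a *size-biased* (equilibrated) majority, because `π` is defined for a
root type drawn from the measurement distribution while the equilibrium
majority supplies the birth rate `λ`. The validation runs use that mixed
initialisation; at `N = 200` it reproduces `1 − π` within Monte-Carlo
error (measured bias < 0.002 at 10^4 replicates for gamma shapes 1–5),
whereas size-biasing the seed as well inflates fixation by ~0.03–0.04.

**Branching Monte Carlo** simulates the multitype process event-by-event
(per-individual death times and birth streams in one heap). A path counts
as surviving when the population reaches `pop_cap` (library default 1000);
a lineage that large dies later with probability ≤ π^pop_cap. Validation
runs use `pop_cap = 250`, for which that misclassification probability is
below 1e−24 in every case tested, at a quarter of the cost.

## Replication protocol sizes

Per-replicate seeds derive from `SeedSequence((base_seed, rep))`, so
sweeps are reproducible bit-for-bit and parallelisable without collisions.
Experiment sweeps default to 1000 replicates per point; the validation
suite uses the following problem sizes, chosen to keep the full run in a
few minutes while leaving Monte-Carlo bands (3 binomial standard errors,
99% confidence for means) well below the effects being checked:
fixation vs closed form at `N = 20` (complete and random 4-regular,
10^4 replicates); mean consensus time on `K_10` (2×10^4); noisy fixation
at `N = 200`, `k = 1`, gamma shapes {1, 2, 5} (2000); branching Monte
Carlo at 2×10^4 paths; best-of-10 on `K_50` (2000); the near-regular
bound on a deterministic `N = 20`, `d_min = 3`, `d_max = 4` circulant
variant (10^4).

## What the synthetic protocols do and do not show

All inputs are generated programmatically — graphs from the stated
families, qualities from point/gamma/finite-support distributions — so
passing tests demonstrate internal consistency between the simulator and
the closed-form/fixed-point theory under the model's assumptions. They do
not probe: correlated or agent-specific measurement errors (the theory
assumes exchangeable i.i.d. noise), opinion-dependent network evolution
(rewiring here is opinion-blind), physical robot motion or interference,
or non-exponential signalling times. The `1 − π^k` fixation value for
noisy measurements is a large-population approximation whose finite-`N`
error is only verified empirically here (it is conjectural in general);
its sign and size at `N ≈ 200` are within Monte-Carlo noise, but smaller
populations will show visible depletion bias. Consensus-time bounds are
proved bounds, not estimates — simulations run one to two orders of
magnitude faster than the expanded-cycle bound in particular.

## Known limitations

* Exact isoperimetric constants stop at `N = 20`; beyond that only the
  closed-form families and the random-regular lower bound are available.
* Exact mean consensus times are complete-graph only (the embedded count
  is Markov only there) and capped at `N = 5000` by the dense solve.
* The noisy theory is complete-graph only; extending it to sparse
  topologies is open.
* `compare_noise` certifies the convex-order direction analytically only
  within the gamma family and against point masses; for other same-mean
  pairs it reports both extinction probabilities without asserting an
  ordering.
* The expanded-cycle closed form for `η` assumes even `N` (see above).
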