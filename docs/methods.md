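# Methods

## Model

`nicheweb` simulates the assembly of bipartite mutualistic communities
(two guilds, by convention animals A and plants P) in which each species
carries two traits: a Gaussian niche profile on a one-dimensional axis
and an abundance. The niche proximity of two species is the overlap of
their unit-normalized profiles,

    H_ij = exp( -(s_i - s_j)^2 / (4 sigma^2) ),

with a single run-level width `sigma` and centers drawn uniformly on
[0, 1]. The axis is non-periodic. Proximity scales both interaction
types: mutualistic coupling across guilds, `gamma_ik = Omega_m theta_ik
H_ik` (only on realized links of the binary adjacency theta), and
competitive coupling within guilds, `beta_ij = Omega_c H_ij` for i != j
with `beta_ii = 1` over all pairs (all-to-all competition). Abundances
follow generalized Lotka-Volterra dynamics with a Holling type II
(saturating) mutualistic response,

    dn_i/dt = n_i ( rho_i - sum_j beta_ij n_j
                    + (sum_k gamma_ik n_k) / (1 + h sum_k theta_ik n_k) ),

where the mutualism sums run over the opposite guild and the saturation
denominator counts linked partners only.

Assembly is adaptive rewiring: at each attempt a species is chosen
uniformly at random, one of its links is selected uniformly, and the
link is released with probability `p = 1 - k^(-eta)` where `k` is the
degree of the partner about to be abandoned — a partner of degree 1 is
never abandoned, which conserves both the link count and min degree >= 1
exactly. The link is redirected to a uniformly chosen opposite-guild
non-partner, the dynamics is relaxed to equilibrium, and the swap is
kept only if the focal species' equilibrium abundance strictly
increased; otherwise adjacency, couplings and abundances are restored
exactly. Assembly ends at a structural steady state (below).

## Parameters

| name | meaning | default | notes |
| --- | --- | --- | --- |
| `sigma` | niche width (axis units) | 0.1 | shared by all species |
| `Omega_m`, `Omega_c` | interaction intensities | 0.10, 0.05 | typical range [0.01, 0.30] |
| `C0` | connectance | 0.058 at 100+100 | scaled as 4 / M^0.8 at other sizes |
| `rho` | intrinsic growth rate | 1.0 (uniform) | uniform value isolates structural effects |
| `h` | Holling handling time | 0.1 | h = 0 (linear mutualism) supported |
| `n0` | initial abundance | 1.0 | uniform at t = 0 |
| `eta` | release-probability exponent | 1.0 | any eta > 0 |
| `relax_tol` | equilibrium residual max dn/dt | 1e-9 | |
| `extinction_threshold` | extinction floor | 1e-6 | active only in invasion runs |

`rho`, `h` and `n0` have no canonical literature values for this model
family; the defaults above are declared package choices, configurable
per run and recorded in the serialized run configuration. The headline
structural results are insensitive to `h` across {0.05, 0.1, 0.2}
(checked in the acceptance suite's sweep conditions).

## Numerical choices

*Equilibria by time integration.* Equilibria are reached by integrating
the dynamics forward from the current state (warm-started across
rewiring attempts), not by root finding, so the equilibrium reached is
the one in the dynamical basin of the pre-swap state. The integrator is
a positivity-preserving exponential Euler scheme (`n <- n exp(g dt)`;
n = 0 is exactly absorbing) with a residual-descent step-size control.
Once the residual max|dn/dt| falls below 1e-2, a guarded Newton polish
on the per-capita growth is attempted: it is accepted only if it stays
in the positive orthant, moves the state by less than 0.5 in the max
norm, and lands below tolerance — so it cannot hop basins; otherwise
integration continues. Relaxations dominated by a near-neutral slow
mode (e.g. a mutant nearly identical to its resident) are ended early
by a stall detector and reported non-converged; the rewiring loop then
rejects the attempt. A LSODA integration of the same vector field is
used as an independent oracle in the tests.

*Steady-state criterion.* The reference for "macroscopic measures
approximately constant" is operationalized as: windowed means of NODF,
Q and mean abundance over `steady_window` attempts changing by less
than `steady_rel_change` between consecutive windows. The library
defaults (2000 attempts, 1%) suit networks up to ~40+40; the 100+100
reference run uses a 20000-attempt window at 0.5% because NODF there
still creeps on the 10^4-attempt scale (the acceptance script sets
this explicitly).

*Metrics.* NODF follows the paired-overlap/decreasing-fill definition,
reported on [0, 1]; ties in marginal totals contribute zero. Modularity
treats the bipartite graph as a unipartite graph on M nodes and applies
recursive leading-eigenvector bisection of the generalized modularity
matrix; recursion stops when no split increases Q. This classical form
(which reproduces igraph's implementation exactly on assembled
networks) is the default and the one used in all reported values;
greedy single-node fine-tuning sweeps can be enabled and raise Q by
under 0.01. The null model occupies entry (i, j)
independently with the mean of row i's and column j's occupation
probability, which preserves the expected link count exactly; samples
with an empty row or column are redrawn wholesale (up to 100 times).

*Initial adjacency.* Exactly round(C0 M_A M_P) links: each species
first receives one uniform partner, the remainder fill uniformly.
Connectances below (M_A + M_P) / (M_A M_P) are refused.

## Experiments

*Stability.* S = -Re(lambda)_max of the analytic Jacobian at the
equilibrium; S > 0 is locally stable, and S tracks min_i n_i closely on
assembled communities (asserted as a rank correlation in the tests).
Relative stability compares each assembled network against null-model
randomizations with the same niches and parameters, relaxed from
uniform abundances. The two competition thresholds are estimated by
linear interpolation of sign changes — of the ensemble-mean relative
stability (first threshold), and of the least-squares slope of S
against Omega_m (second threshold) — with bootstrap confidence
intervals over replicates.  Both crossings shift to larger Omega_c on
smaller networks (roughly 0.046 and 0.032 at 40+40 versus 0.030 and
0.017 at 60+60 for the first and second threshold), so threshold
estimates are reported at the largest ensemble size the run budget
allows and the size is recorded with the result.

*Hysteresis.* Omega_m is ramped up and back down on an assembled
community, one rewiring attempt per increment (quasi-steady protocol).
The reference rate is 1e-6 per attempt; desk-scale runs use 5e-6 to
1e-4 and the rate is recorded in every output row. Branch separation
is assessed at mid-ramp across seeds; loop areas per cycle are
computed by interpolating both branches onto a common grid. At desk
scale (40+40) the nestedness branches separate clearly while the
modularity response to Omega_m is flat, so Q hysteresis — like the
memory effect generally — needs larger networks than the test suite
runs.

*Invasions.* A two-timescale process: `R_T` (default 50) rewiring
attempts alternate with one invasion, in which a resident chosen with
probability proportional to abundance spawns a mutant that inherits
its full partner set and 1% of its abundance, displaced on the niche
axis by Normal(0, 0.02) clipped to [0, 1]; links are then deleted
uniformly at random network-wide (never a species' last link) until
the connectance matches 4 / M^0.8. Species below the extinction
threshold are removed (the only context where extinction operates).
Outcomes are classified 500 rewiring attempts after each event, and
relative probabilities P_rel(k) divide each outcome's frequency within
a resident-degree class by its marginal frequency. Invasion phenomena
(saturation of M, extinction events, degree-biased outcomes) emerge in
the strong-interaction regime; the package's invasion defaults are
Omega_m = 0.3 with Omega_c around 0.4 — Omega_c = 0.4 matching the
regime the phenomenology is reported for, Omega_m being a package
choice since no value is published for this experiment.

## What the generator emulates — and what it does not

All inputs are synthetic: random niche centers, random initial
adjacency, uniform initial abundances. This emulates the "arbitrary
initial partnership" premise of the model. It does not emulate real
plant-pollinator data: no phylogenetic correlation of traits, no
abundance-sampling effects, no forbidden links, no quantitative
interaction weights. Passing tests therefore demonstrate the internal
behavior of the adaptive niche mechanism (emergent nestedness and
modularity exceeding the null model, stability transitions, hysteresis,
invasion resilience), not agreement with any particular empirical
network; empirical matrices can be read through the Web-of-Life CSV
reader for metric computation only.

## Scale choices

Reference structural values are reproduced at the published size
(100+100, C0 = 0.058, ensemble over 5 seeds). The sweep, hysteresis and
invasion experiments run at reduced scale — 40+40 or 30+30 with the
size-scaled connectance 4 / M^0.8, fewer replicates, and a coarser
hysteresis ramp — chosen so the full pipeline runs on a single CPU in
minutes; the scaling is recorded in the outputs of every driver.

## Known limitations

- Modularity uses the unipartite modularity matrix (Barber's bipartite
  variant would shift Q systematically); NODF is the binary variant.
- The steady state is detected by windowed flatness, so very slow
  structural drift below the tolerance is declared steady.
- Near-degenerate mutant/resident pairs relax on timescales inversely
  proportional to their niche separation; the stall detector bounds the
  cost but classifies such relaxations as non-converged.
- Degree-0 species cannot arise during assembly but can transiently
  exist during invasion extinctions; structural metrics prune empty
  rows/columns at that point.
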