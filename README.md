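# nicheweb

Adaptive niche model of mutualistic network assembly: bipartite
Lotka-Volterra communities whose species rewire their mutualistic
partnerships to maximize their own equilibrium abundance. Nestedness
and modularity emerge together from this single adaptive mechanism,
and the package reproduces the model's dynamical signatures: the
competition-controlled transition in how mutualism affects local
stability, hysteresis of network structure under slow environmental
change, and the resilience of generalists under evolutionary invasions.

The package is for researchers in community ecology and network
science who want a fast, tested simulator of niche-based adaptive
rewiring — to regenerate the model's phase diagrams, to run structural
metrics (NODF, modularity, null models) on their own bipartite
matrices, or to extend the mechanism.

## Model

Each species i in two guilds (animals A, plants P) has a Gaussian
niche profile with center s_i on [0, 1] and shared width sigma. The
niche proximity

    H_ij = exp( -(s_i - s_j)^2 / (4 sigma^2) )

scales mutualistic coupling across guilds, gamma_ik = Omega_m theta_ik H_ik
(theta the binary adjacency), and competitive coupling within guilds,
beta_ij = Omega_c H_ij (i != j), beta_ii = 1. Abundances follow
generalized Lotka-Volterra dynamics with a Holling type II response,

    dn_i/dt = n_i ( rho_i - sum_j beta_ij n_j
                    + sum_k gamma_ik n_k / (1 + h sum_k theta_ik n_k) ).

At each rewiring attempt a random species releases one of its links
with probability p = 1 - k^(-eta) (k the current partner's degree) and
redirects it to a random non-partner; the dynamics is relaxed to
equilibrium and the swap is kept iff the focal species' equilibrium
abundance strictly increased. Link count and minimum degree 1 are
conserved exactly. Local stability is S = -Re(lambda)_max of the
Jacobian at equilibrium. See `docs/methods.md` for parameters,
numerics and scale choices.

## Worked example

```python
import numpy as np
import nicheweb as nw

rng = np.random.default_rng(1)
comm = nw.BipartiteCommunity.random(M_A=40, M_P=40, C0=0.12, width=0.1, rng=rng)
traj = nw.assemble(
    comm,
    nw.InteractionIntensities(omega_m=0.10, omega_c=0.05),
    nw.DynamicsParams(),
    nw.RewiringConfig(max_attempts=25_000, steady_window=4_000,
                      steady_rel_change=0.005, checkpoint_every=400),
    rng,
)
st = nw.stability(traj.equilibrium, comm, traj.couplings, nw.DynamicsParams())
comp = nw.null_comparison(comm.theta, 100, np.random.default_rng(0))
print(f"converged={traj.converged} after {traj.attempts} attempts")
print(f"NODF={comp['nodf']:.4f} (null mean {comp['null_means']['nodf']:.4f})")
print(f"Q   ={comp['Q']:.4f} (null mean {comp['null_means']['Q']:.4f})")
print(f"S={st.S:.4f}  min_n={st.min_abundance:.4f}")
```

prints

```
converged=False after 25000 attempts
NODF=0.1707 (null mean 0.1526)
Q   =0.6901 (null mean 0.3449)
S=0.4652  min_n=0.4872
```

A 40+40 community at the size-scaled connectance 4 / M^0.8 = 0.12
assembles into a network whose nestedness and modularity both exceed
the null-model means (randomizations preserving expected row/column
fill) — the joint nested-and-modular structure the mechanism produces —
and whose stability S tracks the minimum abundance closely.
(`converged=False` here only means the windowed flatness criterion was
not yet met at the attempt cap; the structural excess over the null is
already fully developed.)

The same pipeline is scriptable from the shell:

```sh
nicheweb assemble --seed 1 --out run1          # assembles, writes CSV/JSON
nicheweb metrics run1/network.csv              # NODF/Q + null z-scores
nicheweb sweep --seed 2 --out sweep1           # stability grid
nicheweb hysteresis --seed 3 --out hyst1       # up/down Omega_m ramp
nicheweb invade --seed 4 --out inv1            # two-timescale invasions
```

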