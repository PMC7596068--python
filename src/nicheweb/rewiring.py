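"""Adaptive rewiring: the assembly loop of the niche model.

At each attempt a species is chosen uniformly at random, one of its
mutualistic links is selected, and the link is released with probability
p_ij = 1 - k_j^(-eta), where k_j is the degree of the *current* partner —
so partners that are themselves specialists (k_j = 1) are never
abandoned, which keeps every species at degree >= 1 and the connectance
exactly constant.  The released link is rewired to a uniformly chosen
non-partner in the opposite guild, the dynamics is relaxed to its new
equilibrium, and the swap is kept only if the focal species' equilibrium
abundance strictly increased; otherwise the previous link and abundances
are restored exactly.  Assembly stops when the windowed means of the
macroscopic observables (NODF, Q, mean abundance) are flat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics as _metrics
from ._kernels import relax
from .dynamics import DynamicsParams, EquilibriumState, relax_to_equilibrium
from .niche import (
    BipartiteCommunity,
    CouplingSet,
    InteractionIntensities,
    build_couplings,
    update_proximity_on_rewire,
)

log = logging.getLogger(__name__)


@dataclass
class RewiringConfig:
    """Controls of the assembly loop.

    eta : exponent of the release probability p_ij = 1 - k_j^(-eta).
    max_attempts : hard cap on rewiring attempts.
    steady_window : number of recent attempts over which the windowed
        means of NODF, Q and mean abundance must be flat to declare a
        steady state.
    steady_rel_change : relative flatness tolerance between consecutive
        windows.
    checkpoint_every : attempts between recorded observable checkpoints.
    """

    eta: float = 1.0
    max_attempts: int = 50_000
    steady_window: int = 2_000
    steady_rel_change: float = 0.01
    checkpoint_every: int = 200

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("eta must be > 0")
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be >= 1")
        if self.steady_window % self.checkpoint_every:
            raise ValueError("steady_window must be a multiple of checkpoint_every")


@dataclass
class Proposal:
    """A candidate partner swap; ``None`` from propose_rewire means no-op."""

    focal: int          # global species index
    old_partner: int    # global index, opposite guild
    new_partner: int    # global index, opposite guild


@dataclass
class AssemblyTrajectory:
    """Checkpointed observables and the final state of one assembly."""

    checkpoints: pd.DataFrame
    community: BipartiteCommunity
    couplings: CouplingSet
    equilibrium: EquilibriumState
    converged: bool
    attempts: int
    accepted: int
    config: RewiringConfig = field(repr=False)


def random_bipartite(
    M_A: int, M_P: int, C0: float, rng: np.random.Generator
) -> np.ndarray:
    """Random binary bipartite adjacency with exact link count and
    minimum degree 1.

    Realizes exactly round(C0 * M_A * M_P) links: each species is first
    given one uniformly random partner, then the remaining links are
    placed uniformly over the unoccupied cells.

    Raises
    ------
    ValueError
        If the requested link count cannot accommodate degree >= 1 for
        every species (C0 * M_A * M_P < M_A + M_P is always refused).
    """
    L = int(round(C0 * M_A * M_P))
    if C0 * M_A * M_P < M_A + M_P:
        raise ValueError(
            f"connectance {C0} too low for min degree 1 on {M_A}+{M_P} species"
        )
    if L > M_A * M_P:
        raise ValueError("connectance above 1")
    theta = np.zeros((M_A, M_P), dtype=bool)
    for i in range(M_A):
        theta[i, rng.integers(M_P)] = True
    for j in np.flatnonzero(theta.sum(axis=0) == 0):
        theta[rng.integers(M_A), j] = True
    placed = int(theta.sum())
    if placed > L:
        raise ValueError(
            f"cannot realize {L} links with min degree 1 (needs >= {placed})"
        )
    empty = np.flatnonzero(~theta.ravel())
    extra = rng.choice(empty, size=L - placed, replace=False)
    theta.ravel()[extra] = True
    return theta


def propose_rewire(
    community: BipartiteCommunity, rng: np.random.Generator, eta: float = 1.0
) -> Proposal | None:
    """Draw one rewiring proposal; ``None`` when the attempt is a no-op.

    The focal species is uniform over all M species; one of its links is
    uniform over its current partners; the link is released with
    probability 1 - k^(-eta) in the degree k of the partner about to be
    abandoned; the new partner is uniform over opposite-guild
    non-partners.  A failed release draw or a saturated focal (no
    non-partners left) yields a no-op.
    """
    M_A = community.M_A
    focal = int(rng.integers(community.M))
    if focal < M_A:
        row = community.theta[focal]
        partners = np.flatnonzero(row)
        if partners.size == 0:
            return None  # isolated focal (possible only under extinctions)
        j = int(partners[rng.integers(partners.size)])
        k_j = int(community.theta[:, j].sum())
        if rng.random() >= 1.0 - k_j ** (-eta):
            return None
        non_partners = np.flatnonzero(~row)
        if non_partners.size == 0:
            return None
        k = int(non_partners[rng.integers(non_partners.size)])
        return Proposal(focal=focal, old_partner=M_A + j, new_partner=M_A + k)
    col = community.theta[:, focal - M_A]
    partners = np.flatnonzero(col)
    if partners.size == 0:
        return None
    j = int(partners[rng.integers(partners.size)])
    k_j = int(community.theta[j].sum())
    if rng.random() >= 1.0 - k_j ** (-eta):
        return None
    non_partners = np.flatnonzero(~col)
    if non_partners.size == 0:
        return None
    k = int(non_partners[rng.integers(non_partners.size)])
    return Proposal(focal=focal, old_partner=j, new_partner=k)


def attempt_step(
    community: BipartiteCommunity,
    couplings: CouplingSet,
    proposal: Proposal,
    params: DynamicsParams,
) -> tuple[bool, EquilibriumState]:
    """Apply one proposal: swap, relax, accept iff the focal species'
    equilibrium abundance strictly increased; otherwise restore the
    previous link, couplings and equilibrium abundances exactly.

    Returns (accepted, equilibrium-after-the-step); on rejection the
    returned equilibrium is the restored pre-proposal one.
    """
    n_before = community.abundances
    focal_before = n_before[proposal.focal]
    update_proximity_on_rewire(
        community, couplings, proposal.focal, proposal.old_partner, proposal.new_partner
    )
    eq = relax_to_equilibrium(community, couplings, params)
    if eq.converged and eq.abundances[proposal.focal] > focal_before:
        return True, eq
    if not eq.converged:
        log.debug("relaxation did not converge; proposal rejected")
    # restore: reverse swap and put the previous equilibrium back
    update_proximity_on_rewire(
        community, couplings, proposal.focal, proposal.new_partner, proposal.old_partner
    )
    community.abundances = n_before
    return False, EquilibriumState(
        abundances=n_before, residual=0.0, feasible=True, converged=True
    )


def assemble(
    community: BipartiteCommunity,
    intensities: InteractionIntensities,
    params: DynamicsParams,
    config: RewiringConfig,
    rng: np.random.Generator,
) -> AssemblyTrajectory:
    """Run the adaptive assembly loop to a structural steady state.

    Relaxes the initial community, then repeats propose/attempt until the
    windowed means of NODF, Q and mean abundance change by less than
    ``config.steady_rel_change`` between consecutive windows of
    ``config.steady_window`` attempts, or ``config.max_attempts`` is hit
    (returned with ``converged=False``).  The adjacency's link count and
    min degree >= 1 are conserved throughout by the release rule.
    """
    couplings = build_couplings(community, intensities)
    M_A, M_P = community.M_A, community.M_P
    rho_A, rho_P = params.rho_split(M_A, M_P)
    theta_f = community.theta.astype(np.float64)   # float copy for the kernel
    nA = community.abundance_A.copy()
    nP = community.abundance_P.copy()
    relax(nA, nP, rho_A, rho_P, couplings.beta_A, couplings.beta_P,
          couplings.gamma, theta_f, params.handling,
          params.relax_tol, params.max_relax_time)

    omega_m = intensities.omega_m
    H = couplings.H_cross
    gamma = couplings.gamma
    theta = community.theta

    records: list[tuple] = []
    accepted_total = 0
    accepted_window = 0
    window_means: list[np.ndarray] = []
    converged = False
    attempts_done = 0
    per_window = config.steady_window // config.checkpoint_every

    for attempt in range(1, config.max_attempts + 1):
        attempts_done = attempt
        prop = propose_rewire(community, rng, config.eta)
        if prop is not None:
            focal = prop.focal
            if focal < M_A:
                r, co, cn = focal, prop.old_partner - M_A, prop.new_partner - M_A
                swaps = ((r, co), (r, cn))
            else:
                co_r, cn_r = prop.old_partner, prop.new_partner
                swaps = ((co_r, focal - M_A), (cn_r, focal - M_A))
            (r0, c0), (r1, c1) = swaps
            # apply swap directly on the shared arrays (hot path)
            theta[r0, c0] = False
            theta[r1, c1] = True
            theta_f[r0, c0] = 0.0
            theta_f[r1, c1] = 1.0
            g0 = gamma[r0, c0]
            gamma[r0, c0] = 0.0
            gamma[r1, c1] = omega_m * H[r1, c1]
            tA, tP = nA.copy(), nP.copy()
            res, _, ok = relax(
                tA, tP, rho_A, rho_P, couplings.beta_A, couplings.beta_P,
                gamma, theta_f, params.handling,
                params.relax_tol, params.max_relax_time,
            )
            new_focal = tA[focal] if focal < M_A else tP[focal - M_A]
            old_focal = nA[focal] if focal < M_A else nP[focal - M_A]
            if ok and new_focal > old_focal:
                nA, nP = tA, tP
                accepted_total += 1
                accepted_window += 1
            else:
                theta[r0, c0] = True
                theta[r1, c1] = False
                theta_f[r0, c0] = 1.0
                theta_f[r1, c1] = 0.0
                gamma[r0, c0] = g0
                gamma[r1, c1] = 0.0

        if attempt % config.checkpoint_every == 0:
            nodf = _metrics.nodf(theta)
            Q, _ = _metrics.modularity(theta)
            n_all = np.concatenate([nA, nP])
            records.append((
                attempt, nodf, Q, float(n_all.mean()), float(n_all.min()),
                accepted_window / config.checkpoint_every,
            ))
            accepted_window = 0
            if attempt % config.steady_window == 0:
                recent = np.array([r[1:4] for r in records[-per_window:]])
                window_means.append(recent.mean(axis=0))
                if len(window_means) >= 2:
                    prev, cur = window_means[-2], window_means[-1]
                    rel = np.abs(cur - prev) / np.maximum(np.abs(prev), 1e-12)
                    if (rel < config.steady_rel_change).all():
                        converged = True
                        break

    community.abundance_A = nA.copy()
    community.abundance_P = nP.copy()
    eq = relax_to_equilibrium(community, couplings, params)
    checkpoints = pd.DataFrame(
        records,
        columns=["attempt", "nodf", "Q", "mean_n", "min_n", "acceptance_rate"],
    )
    return AssemblyTrajectory(
        checkpoints=checkpoints,
        community=community,
        couplings=couplings,
        equilibrium=eq,
        converged=converged,
        attempts=attempts_done,
        accepted=accepted_total,
        config=config,
    )
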