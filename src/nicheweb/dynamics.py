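"""Generalized Lotka-Volterra dynamics with Holling type II mutualism.

Abundances obey, per guild (A shown; P is symmetric):

    dn_i/dt = n_i * ( rho_i - sum_j beta_ij n_j
                      + (sum_k gamma_ik n_k) / (1 + h sum_k theta_ik n_k) )

Competition is within-guild and all-to-all; the mutualistic benefit
saturates with the summed abundance of *linked* partners (handling time
``h``).  Equilibria are found by time integration (warm-started from the
current state, with a basin-respecting Newton polish near convergence),
and local stability is S = -Re(lambda)_max of the analytic Jacobian at
the equilibrium: S > 0 means locally stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import percapita_growth, relax
from .niche import BipartiteCommunity, CouplingSet


@dataclass
class DynamicsParams:
    """Parameters of the population dynamics.

    rho : intrinsic growth rate, uniform 1.0 by default (scalar or
        per-species array over the M = M_A + M_P species, guild A first).
    handling : Holling II handling time h >= 0; h = 0 degenerates to
        linear mutualism and is supported.
    n0 : initial abundance assigned uniformly to all species.
    extinction_threshold : abundances below this are treated as extinct,
        only in experiments that allow extinction (invasions); assembly
        keeps all species.
    relax_tol : equilibrium residual tolerance on max|dn_i/dt|.
    max_relax_time : integration-time budget for one relaxation.
    """

    rho: float | np.ndarray = 1.0
    handling: float = 0.1
    n0: float = 1.0
    extinction_threshold: float = 1e-6
    relax_tol: float = 1e-9
    max_relax_time: float = 1e5

    def __post_init__(self) -> None:
        if self.handling < 0:
            raise ValueError("handling time must be >= 0")
        if self.relax_tol <= 0:
            raise ValueError("relax_tol must be > 0")
        if self.n0 <= 0:
            raise ValueError("n0 must be > 0")

    def rho_split(self, M_A: int, M_P: int) -> tuple[np.ndarray, np.ndarray]:
        """Per-guild growth-rate vectors (guild A first in array input)."""
        rho = np.asarray(self.rho, dtype=float)
        if rho.ndim == 0:
            return np.full(M_A, float(rho)), np.full(M_P, float(rho))
        if rho.size != M_A + M_P:
            raise ValueError(f"rho has size {rho.size}, expected {M_A + M_P}")
        return rho[:M_A].copy(), rho[M_A:].copy()


@dataclass
class EquilibriumState:
    """Outcome of a relaxation: abundances plus convergence bookkeeping."""

    abundances: np.ndarray          # concatenated, guild A first
    residual: float                 # max |dn_i/dt| at the final state
    feasible: bool                  # all abundances above extinction threshold
    converged: bool
    elapsed: float = 0.0


@dataclass
class StabilityResult:
    """Local stability S = -Re(lambda)_max at an equilibrium."""

    S: float
    leading_eigenvalue: complex
    min_abundance: float


def growth_rate(
    community: BipartiteCommunity,
    couplings: CouplingSet,
    params: DynamicsParams,
    abundances: np.ndarray | None = None,
) -> np.ndarray:
    """dn/dt for every species (guild A first).

    Zero abundance gives a zero rate: n = 0 is absorbing.
    """
    n = community.abundances if abundances is None else np.asarray(abundances, float)
    if (n < 0).any():
        raise ValueError("abundances must be nonnegative")
    nA, nP = n[: community.M_A], n[community.M_A :]
    rho_A, rho_P = params.rho_split(community.M_A, community.M_P)
    gA, gP = percapita_growth(
        nA, nP, rho_A, rho_P, couplings.beta_A, couplings.beta_P,
        couplings.gamma, community.theta.astype(np.float64), params.handling,
    )
    return np.concatenate([nA * gA, nP * gP])


def relax_to_equilibrium(
    community: BipartiteCommunity,
    couplings: CouplingSet,
    params: DynamicsParams,
    update_community: bool = True,
) -> EquilibriumState:
    """Integrate the dynamics from the current abundances to equilibrium.

    Runs the compiled exponential-Euler/Newton scheme until
    max|dn_i/dt| < ``params.relax_tol`` or the time budget is exhausted;
    a non-converged state is returned flagged, not raised.  When
    ``update_community`` is true the community's abundances are replaced
    by the equilibrium values.
    """
    nA = community.abundance_A.copy()
    nP = community.abundance_P.copy()
    rho_A, rho_P = params.rho_split(community.M_A, community.M_P)
    res, elapsed, ok = relax(
        nA, nP, rho_A, rho_P, couplings.beta_A, couplings.beta_P,
        couplings.gamma, community.theta.astype(np.float64), params.handling,
        params.relax_tol, params.max_relax_time,
    )
    n = np.concatenate([nA, nP])
    if update_community:
        community.abundances = n
    return EquilibriumState(
        abundances=n,
        residual=float(res),
        feasible=bool((n > params.extinction_threshold).all()),
        converged=bool(ok),
        elapsed=float(elapsed),
    )


def jacobian(
    community: BipartiteCommunity,
    couplings: CouplingSet,
    params: DynamicsParams,
    abundances: np.ndarray | None = None,
) -> np.ndarray:
    """Analytic Jacobian d(dn_i/dt)/dn_j of the dynamics at a state.

    With f_i = n_i g_i this is J = diag(g) + diag(n) dg/dn, where dg/dn
    is -beta within guilds and, across guilds, the quotient-rule
    derivative of the saturating mutualism term.
    """
    MA, MP = community.M_A, community.M_P
    n = community.abundances if abundances is None else np.asarray(abundances, float)
    nA, nP = n[:MA], n[MA:]
    rho_A, rho_P = params.rho_split(MA, MP)
    theta = community.theta.astype(np.float64)
    h = params.handling
    gamma = couplings.gamma

    gA, gP = percapita_growth(
        nA, nP, rho_A, rho_P, couplings.beta_A, couplings.beta_P, gamma, theta, h
    )
    uA = theta @ nP
    uP = theta.T @ nA
    sA = gamma @ nP
    sP = gamma.T @ nA
    dA = 1.0 + h * uA
    dP = 1.0 + h * uP

    # per-capita growth Jacobian, guild-blocked
    dg = np.zeros((MA + MP, MA + MP))
    dg[:MA, :MA] = -couplings.beta_A
    dg[MA:, MA:] = -couplings.beta_P
    dg[:MA, MA:] = gamma / dA[:, None] - h * theta * (sA / dA**2)[:, None]
    dg[MA:, :MA] = gamma.T / dP[:, None] - h * theta.T * (sP / dP**2)[:, None]

    g = np.concatenate([gA, gP])
    return np.diag(g) + n[:, None] * dg


def stability(
    equilibrium: EquilibriumState,
    community: BipartiteCommunity,
    couplings: CouplingSet,
    params: DynamicsParams,
) -> StabilityResult:
    """S = -max Re(lambda) over Jacobian eigenvalues at the equilibrium.

    Also records min_i n_i, to which S is approximately equal for
    assembled communities.  Raises on a non-converged equilibrium.
    """
    if not equilibrium.converged:
        raise ValueError("stability requires a converged equilibrium")
    J = jacobian(community, couplings, params, equilibrium.abundances)
    eig = np.linalg.eigvals(J)
    lead = eig[np.argmax(eig.real)]
    return StabilityResult(
        S=float(-lead.real),
        leading_eigenvalue=complex(lead),
        min_abundance=float(equilibrium.abundances.min()),
    )
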