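"""Gaussian niche profiles and proximity-scaled interaction couplings.

Each species occupies a Gaussian profile on a one-dimensional niche axis,
with a per-run shared width ``sigma`` and a center in [0, 1].  The niche
proximity of two species is the overlap integral of their profiles,
normalized so that identical centers give proximity 1:

    H_ij = exp(-(s_i - s_j)^2 / (4 sigma^2))

Proximity scales both coupling types of the bipartite community:
mutualistic strength across guilds, gamma_ik = Omega_m * theta_ik * H_ik
(only for realized links theta_ik = 1), and competitive strength within
guilds, beta_ij = Omega_c * H_ij for i != j with beta_ii = 1 (all-to-all).
The axis is non-periodic: proximity uses the plain Euclidean center
difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class NicheProfile:
    """A species' Gaussian occupancy on the niche axis."""

    center: float
    width: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"niche width must be > 0, got {self.width}")
        if not 0.0 <= self.center <= 1.0:
            raise ValueError(f"niche center must lie in [0, 1], got {self.center}")


@dataclass(frozen=True)
class InteractionIntensities:
    """Per-unit-proximity interaction factors.

    ``omega_m`` scales mutualism across guilds, ``omega_c`` competition
    within guilds.  Typical values lie in [0.01, 0.30].
    """

    omega_m: float
    omega_c: float

    def __post_init__(self) -> None:
        if self.omega_m < 0 or self.omega_c < 0:
            raise ValueError("interaction intensities must be nonnegative")


def niche_proximity(center_i, center_j, width):
    """Overlap of two unit-normalized Gaussian niche profiles.

    Parameters
    ----------
    center_i, center_j : float or ndarray
        Niche centers; broadcast against each other.
    width : float
        Shared Gaussian niche width ``sigma`` (> 0).

    Returns
    -------
    float or ndarray in (0, 1]
        ``exp(-(center_i - center_j)**2 / (4 * width**2))``; symmetric in
        its first two arguments and equal to 1 at zero separation.
    """
    if width <= 0:
        raise ValueError(f"niche width must be > 0, got {width}")
    d = np.asarray(center_i, dtype=float) - np.asarray(center_j, dtype=float)
    out = np.exp(-(d * d) / (4.0 * width * width))
    return float(out) if np.ndim(out) == 0 else out


def proximity_matrix(centers_a: np.ndarray, centers_b: np.ndarray, width: float) -> np.ndarray:
    """Pairwise proximities between two center arrays (outer broadcast)."""
    return niche_proximity(np.asarray(centers_a)[:, None], np.asarray(centers_b)[None, :], width)


class BipartiteCommunity:
    """Two guilds of species with niche profiles, abundances and adjacency.

    Guild A (by convention the animal guild) indexes rows of the binary
    adjacency ``theta`` (shape ``M_A x M_P``); guild P indexes columns.
    Global species indices run 0..M_A-1 for guild A and M_A..M-1 for
    guild P.  Mutualism acts only across guilds on realized links;
    competition acts all-to-all within each guild.
    """

    def __init__(
        self,
        centers_A: np.ndarray,
        centers_P: np.ndarray,
        width: float,
        theta: np.ndarray,
        abundance_A: np.ndarray | None = None,
        abundance_P: np.ndarray | None = None,
        n0: float = 1.0,
    ) -> None:
        if width <= 0:
            raise ValueError(f"niche width must be > 0, got {width}")
        self.centers_A = np.asarray(centers_A, dtype=float).copy()
        self.centers_P = np.asarray(centers_P, dtype=float).copy()
        self.width = float(width)
        theta = np.asarray(theta)
        if theta.shape != (self.centers_A.size, self.centers_P.size):
            raise ValueError(
                f"theta shape {theta.shape} does not match guild sizes "
                f"({self.centers_A.size}, {self.centers_P.size})"
            )
        self.theta = (theta != 0).astype(bool).copy()
        self.abundance_A = (
            np.full(self.M_A, float(n0)) if abundance_A is None
            else np.asarray(abundance_A, dtype=float).copy()
        )
        self.abundance_P = (
            np.full(self.M_P, float(n0)) if abundance_P is None
            else np.asarray(abundance_P, dtype=float).copy()
        )
        if (self.abundance_A < 0).any() or (self.abundance_P < 0).any():
            raise ValueError("abundances must be nonnegative")

    # ---- sizes and views -------------------------------------------------
    @property
    def M_A(self) -> int:
        return self.centers_A.size

    @property
    def M_P(self) -> int:
        return self.centers_P.size

    @property
    def M(self) -> int:
        return self.M_A + self.M_P

    @property
    def centers(self) -> np.ndarray:
        """Concatenated centers, guild A first."""
        return np.concatenate([self.centers_A, self.centers_P])

    @property
    def abundances(self) -> np.ndarray:
        """Concatenated abundances, guild A first."""
        return np.concatenate([self.abundance_A, self.abundance_P])

    @abundances.setter
    def abundances(self, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        self.abundance_A = values[: self.M_A].copy()
        self.abundance_P = values[self.M_A :].copy()

    @property
    def connectance(self) -> float:
        """Fraction of realized cross-guild links."""
        return float(self.theta.sum()) / (self.M_A * self.M_P)

    @property
    def degrees_A(self) -> np.ndarray:
        return self.theta.sum(axis=1)

    @property
    def degrees_P(self) -> np.ndarray:
        return self.theta.sum(axis=0)

    def guild_of(self, species: int) -> str:
        if not 0 <= species < self.M:
            raise IndexError(f"species index {species} out of range")
        return "A" if species < self.M_A else "P"

    def local_index(self, species: int) -> int:
        """Within-guild index of a global species index."""
        return species if species < self.M_A else species - self.M_A

    def copy(self) -> "BipartiteCommunity":
        return BipartiteCommunity(
            self.centers_A, self.centers_P, self.width, self.theta,
            self.abundance_A, self.abundance_P,
        )

    def add_species(
        self, guild: str, center: float, abundance: float, partner_mask: np.ndarray
    ) -> int:
        """Append a species to a guild (used by invasion experiments).

        ``partner_mask`` is a boolean vector over the opposite guild.
        Returns the new species' global index (end of its guild block).
        """
        if guild == "A":
            self.centers_A = np.append(self.centers_A, center)
            self.abundance_A = np.append(self.abundance_A, abundance)
            self.theta = np.vstack([self.theta, np.asarray(partner_mask, bool)[None, :]])
            return self.M_A - 1
        elif guild == "P":
            self.centers_P = np.append(self.centers_P, center)
            self.abundance_P = np.append(self.abundance_P, abundance)
            self.theta = np.hstack([self.theta, np.asarray(partner_mask, bool)[:, None]])
            return self.M - 1
        raise ValueError(f"unknown guild {guild!r}")

    def remove_species(self, global_indices) -> None:
        """Drop species by global index (invasion extinctions)."""
        idx = np.atleast_1d(np.asarray(global_indices, dtype=int))
        drop_A = idx[idx < self.M_A]
        drop_P = idx[idx >= self.M_A] - self.M_A
        keep_A = np.setdiff1d(np.arange(self.M_A), drop_A)
        keep_P = np.setdiff1d(np.arange(self.M_P), drop_P)
        self.centers_A = self.centers_A[keep_A]
        self.abundance_A = self.abundance_A[keep_A]
        self.centers_P = self.centers_P[keep_P]
        self.abundance_P = self.abundance_P[keep_P]
        self.theta = self.theta[np.ix_(keep_A, keep_P)]

    @classmethod
    def random(
        cls,
        M_A: int,
        M_P: int,
        C0: float,
        width: float,
        rng: np.random.Generator,
        n0: float = 1.0,
    ) -> "BipartiteCommunity":
        """Random community: uniform centers on [0, 1], random adjacency
        at connectance ``C0`` with every species holding at least one link."""
        from .rewiring import random_bipartite  # local import avoids a cycle

        centers_A = rng.uniform(0.0, 1.0, size=M_A)
        centers_P = rng.uniform(0.0, 1.0, size=M_P)
        theta = random_bipartite(M_A, M_P, C0, rng)
        return cls(centers_A, centers_P, width, theta, n0=n0)


@dataclass
class CouplingSet:
    """Derived interaction matrices for a community.

    ``gamma`` holds mutualistic strengths Omega_m * theta * H on the
    cross-guild proximity matrix ``H_cross``; ``beta_A``/``beta_P`` hold
    within-guild competition with exact ones on the diagonal.  ``H_cross``
    is cached so single-link rewires can update ``gamma`` in O(1).
    """

    gamma: np.ndarray
    beta_A: np.ndarray
    beta_P: np.ndarray
    H_cross: np.ndarray
    intensities: InteractionIntensities = field(repr=False)

    def copy(self) -> "CouplingSet":
        return CouplingSet(
            self.gamma.copy(), self.beta_A.copy(), self.beta_P.copy(),
            self.H_cross.copy(), self.intensities,
        )


def build_couplings(
    community: BipartiteCommunity, intensities: InteractionIntensities
) -> CouplingSet:
    """Construct gamma and beta from niche proximities.

    gamma_ik = Omega_m * theta_ik * H_ik across guilds; beta_ij has ones on
    the diagonal and Omega_c * H_ij off-diagonal over all within-guild
    pairs (competition is all-to-all, not restricted to linked species).
    """
    H_cross = proximity_matrix(community.centers_A, community.centers_P, community.width)
    gamma = intensities.omega_m * community.theta * H_cross

    def _beta(centers: np.ndarray) -> np.ndarray:
        H = proximity_matrix(centers, centers, community.width)
        b = intensities.omega_c * H
        np.fill_diagonal(b, 1.0)
        return b

    return CouplingSet(
        gamma=gamma,
        beta_A=_beta(community.centers_A),
        beta_P=_beta(community.centers_P),
        H_cross=H_cross,
        intensities=intensities,
    )


def update_proximity_on_rewire(
    community: BipartiteCommunity,
    couplings: CouplingSet,
    focal: int,
    old_partner: int,
    new_partner: int,
) -> None:
    """Apply a single partner swap focal: old_partner -> new_partner.

    Flips the two affected adjacency entries and updates the matching
    gamma entries in place (gamma_i,old -> 0, gamma_i,new ->
    Omega_m * H_i,new); every other coupling entry is untouched.  Indices
    are global; the focal may sit in either guild, the partners must both
    lie in the opposite guild.

    Raises
    ------
    ValueError
        If a partner is in the focal's own guild, the old link does not
        exist, or the new link already exists.
    """
    g = community.guild_of(focal)
    if community.guild_of(old_partner) == g or community.guild_of(new_partner) == g:
        raise ValueError("rewiring partners must lie in the opposite guild")
    if old_partner == new_partner:
        raise ValueError("new partner must differ from the old partner")
    f = community.local_index(focal)
    jo = community.local_index(old_partner)
    jn = community.local_index(new_partner)
    if g == "A":
        if not community.theta[f, jo]:
            raise ValueError("old link does not exist")
        if community.theta[f, jn]:
            raise ValueError("proposed partner is already linked")
        community.theta[f, jo] = False
        community.theta[f, jn] = True
        couplings.gamma[f, jo] = 0.0
        couplings.gamma[f, jn] = (
            couplings.intensities.omega_m * couplings.H_cross[f, jn]
        )
    else:
        if not community.theta[jo, f]:
            raise ValueError("old link does not exist")
        if community.theta[jn, f]:
            raise ValueError("proposed partner is already linked")
        community.theta[jo, f] = False
        community.theta[jn, f] = True
        couplings.gamma[jo, f] = 0.0
        couplings.gamma[jn, f] = (
            couplings.intensities.omega_m * couplings.H_cross[jn, f]
        )
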