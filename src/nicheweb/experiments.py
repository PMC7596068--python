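"""Experiment drivers: stability sweeps, hysteresis ramps, invasions.

Three result sets sit on top of the assembly loop:

* ``stability_sweep`` — assemble ensembles over a grid of interaction
  intensities and compare the local stability S of each assembled
  network against matched null-model randomizations (same niches and
  dynamics, randomized adjacency).  ``estimate_threshold`` interpolates
  the competition intensity at which the relative stability, or the
  mutualism-trend of S, changes sign.
* ``hysteresis_run`` — slowly raise and then restore the mutualistic
  intensity on an assembled community, one rewiring attempt per
  increment, recording structure and demography on both branches.
* ``evolve_with_invasions`` — a two-timescale adaptive-evolutionary
  process: bursts of adaptive rewiring alternate with invasion events in
  which a niche-displaced mutant inherits a resident's links and 1% of
  its abundance; the network's connectance follows C_0 = 4 / M^0.8.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .dynamics import (
    DynamicsParams,
    relax_to_equilibrium,
    stability,
)
from .niche import (
    BipartiteCommunity,
    InteractionIntensities,
    build_couplings,
)
from .rewiring import (
    AssemblyTrajectory,
    Proposal,
    RewiringConfig,
    assemble,
    attempt_step,
    propose_rewire,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# stability sweeps and thresholds
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    """Ensemble table of a (omega_m, omega_c) grid sweep.

    ``table`` has one row per grid cell with ensemble means and SDs of
    NODF, Q, S, mean/min abundance, the matched null-model stability and
    the relative stability S - S_null; ``reps`` keeps the per-replicate
    values for bootstrap work.
    """

    table: pd.DataFrame
    reps: pd.DataFrame


def stability_sweep(
    omega_m_values,
    omega_c_values,
    n_reps: int,
    rng: np.random.Generator,
    M_A: int = 40,
    M_P: int = 40,
    C0: float | None = None,
    width: float = 0.1,
    params: DynamicsParams | None = None,
    config: RewiringConfig | None = None,
    n_null: int = 1,
) -> SweepResult:
    """Assemble ensembles over an intensity grid; measure S against nulls.

    For every cell, ``n_reps`` independent communities are assembled and
    their stability S = -Re(lambda)_max computed; each is paired with
    ``n_null`` null-model randomizations of its adjacency (same niches
    and parameters) relaxed from uniform abundances.  Cells whose
    equilibria are infeasible (a species below the extinction threshold)
    are flagged and excluded from the means, with counts reported.

    ``C0`` defaults to the size-connectance relation 4 / M^0.8.
    """
    params = params or DynamicsParams()
    config = config or RewiringConfig()
    if C0 is None:
        C0 = 4.0 / (M_A + M_P) ** 0.8
    rows = []
    for om in np.atleast_1d(omega_m_values):
        for oc in np.atleast_1d(omega_c_values):
            for rep in range(int(n_reps)):
                comm = BipartiteCommunity.random(M_A, M_P, C0, width, rng, n0=params.n0)
                traj = assemble(
                    comm, InteractionIntensities(float(om), float(oc)),
                    params, config, rng,
                )
                eq = traj.equilibrium
                st = stability(eq, comm, traj.couplings, params)
                nulls = []
                for _ in range(n_null):
                    null_comm = comm.copy()
                    null_comm.theta = _metrics.null_model_sample(comm.theta, rng)
                    null_comm.abundances = np.full(comm.M, params.n0)
                    ncoup = build_couplings(null_comm, traj.couplings.intensities)
                    neq = relax_to_equilibrium(null_comm, ncoup, params)
                    if neq.converged:
                        nulls.append(stability(neq, null_comm, ncoup, params).S)
                S_null = float(np.mean(nulls)) if nulls else np.nan
                rows.append({
                    "omega_m": float(om), "omega_c": float(oc), "rep": rep,
                    "nodf": traj.checkpoints["nodf"].iloc[-1],
                    "Q": traj.checkpoints["Q"].iloc[-1],
                    "S": st.S, "S_null": S_null,
                    "rel_S": st.S - S_null,
                    "mean_n": float(eq.abundances.mean()),
                    "min_n": float(eq.abundances.min()),
                    "feasible": bool(eq.feasible),
                    "assembly_converged": bool(traj.converged),
                })
    reps = pd.DataFrame(rows)
    feas = reps[reps["feasible"]]
    table = (
        feas.groupby(["omega_m", "omega_c"])
        .agg(
            nodf_mean=("nodf", "mean"), nodf_sd=("nodf", "std"),
            Q_mean=("Q", "mean"), Q_sd=("Q", "std"),
            S_mean=("S", "mean"), S_sd=("S", "std"),
            S_null_mean=("S_null", "mean"), S_null_sd=("S_null", "std"),
            rel_S_mean=("rel_S", "mean"), rel_S_sd=("rel_S", "std"),
            mean_n=("mean_n", "mean"), min_n=("min_n", "mean"),
            n_feasible=("feasible", "size"),
        )
        .reset_index()
    )
    counts = reps.groupby(["omega_m", "omega_c"]).size().rename("n_total")
    table = table.merge(counts.reset_index(), on=["omega_m", "omega_c"])
    return SweepResult(table=table, reps=reps)


def estimate_threshold(x, y) -> float:
    """Linearly interpolated sign-change location of y(x).

    Raises ``ValueError("threshold not bracketed")`` when y has no sign
    change on the grid.  The first bracketing interval (ascending x) is
    used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.argsort(x)
    x, y = x[order], y[order]
    sign = np.sign(y)
    for i in range(len(x) - 1):
        if sign[i] == 0:
            return float(x[i])
        if sign[i] * sign[i + 1] < 0:
            return float(x[i] - y[i] * (x[i + 1] - x[i]) / (y[i + 1] - y[i]))
    if sign[-1] == 0:
        return float(x[-1])
    raise ValueError("threshold not bracketed")


def threshold_bootstrap_ci(
    x,
    y_reps: np.ndarray,
    rng: np.random.Generator,
    n_boot: int = 200,
    level: float = 0.95,
) -> tuple[float, float, float]:
    """Threshold estimate with a bootstrap confidence interval.

    ``y_reps`` has shape (n_reps, len(x)): per-replicate curves.  Returns
    (estimate from the mean curve, CI low, CI high); bootstrap resamples
    replicates with replacement, skipping unbracketed resamples.
    """
    y_reps = np.asarray(y_reps, dtype=float)
    est = estimate_threshold(x, np.nanmean(y_reps, axis=0))
    boots = []
    n = y_reps.shape[0]
    for _ in range(n_boot):
        pick = rng.integers(0, n, size=n)
        try:
            boots.append(estimate_threshold(x, np.nanmean(y_reps[pick], axis=0)))
        except ValueError:
            continue
    if not boots:
        return est, float("nan"), float("nan")
    lo, hi = np.quantile(boots, [(1 - level) / 2, 1 - (1 - level) / 2])
    return est, float(lo), float(hi)


def omega_m_trend_slope(omega_m, S_mean) -> float:
    """Least-squares slope of mean stability against omega_m (the sign of
    which defines the second stability transition)."""
    om = np.asarray(omega_m, dtype=float)
    S = np.asarray(S_mean, dtype=float)
    ok = np.isfinite(S)
    return float(np.polyfit(om[ok], S[ok], 1)[0])


# ---------------------------------------------------------------------------
# hysteresis
# ---------------------------------------------------------------------------

@dataclass
class HysteresisConfig:
    """Slow up-then-down ramp of the mutualistic intensity.

    ``ramp_rate`` is the Omega_m increment per rewiring attempt; the
    reference protocol uses 1e-6, desk-scale runs may use a coarser rate
    (recorded in the output).  One rewiring attempt is made per
    increment, so the community stays at quasi-steady state.
    """

    omega_m_start: float
    omega_m_max: float
    ramp_rate: float = 1e-6
    n_cycles: int = 1
    record_every: int = 50
    stability_every: int = 500

    def __post_init__(self) -> None:
        if self.ramp_rate < 0:
            raise ValueError("ramp_rate must be >= 0")
        if self.omega_m_max < self.omega_m_start:
            raise ValueError("omega_m_max must be >= omega_m_start")


def hysteresis_run(
    trajectory: AssemblyTrajectory,
    hcfg: HysteresisConfig,
    params: DynamicsParams,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Ramp Omega_m up and back down on an assembled community.

    Each increment of ``ramp_rate`` is followed by one rewiring attempt
    (quasi-steady protocol); NODF, Q, mean abundance and periodically S
    are recorded on both branches of every cycle.  Returns a tidy frame
    with columns (cycle, branch, omega_m, attempt, nodf, Q, mean_n, S,
    ramp_rate).  A zero ramp_rate degenerates to rewiring at fixed
    Omega_m on both branches.
    """
    community = trajectory.community
    couplings = trajectory.couplings
    omega_c = couplings.intensities.omega_c
    eta = trajectory.config.eta

    n_steps = (
        int(round((hcfg.omega_m_max - hcfg.omega_m_start) / hcfg.ramp_rate))
        if hcfg.ramp_rate > 0 else 1
    )
    records = []
    attempt = 0
    om = hcfg.omega_m_start

    def _set_omega_m(value: float) -> None:
        nonlocal om
        om = value
        ints = InteractionIntensities(value, omega_c)
        couplings.intensities = ints
        np.multiply(community.theta, couplings.H_cross, out=couplings.gamma)
        couplings.gamma *= value

    _set_omega_m(hcfg.omega_m_start)
    relax_to_equilibrium(community, couplings, params)

    for cycle in range(hcfg.n_cycles):
        for branch, direction in (("up", 1.0), ("down", -1.0)):
            for step in range(n_steps):
                _set_omega_m(om + direction * hcfg.ramp_rate)
                prop = propose_rewire(community, rng, eta)
                if prop is not None:
                    attempt_step(community, couplings, prop, params)
                else:
                    relax_to_equilibrium(community, couplings, params)
                attempt += 1
                if attempt % hcfg.record_every == 0 or step == n_steps - 1:
                    S = np.nan
                    if attempt % hcfg.stability_every == 0 or step == n_steps - 1:
                        eq = relax_to_equilibrium(community, couplings, params)
                        S = stability(eq, community, couplings, params).S
                    records.append({
                        "cycle": cycle, "branch": branch, "omega_m": om,
                        "attempt": attempt,
                        "nodf": _metrics.nodf(community.theta),
                        "Q": _metrics.modularity(community.theta)[0],
                        "mean_n": float(community.abundances.mean()),
                        "S": S,
                        "ramp_rate": hcfg.ramp_rate,
                    })
    return pd.DataFrame(records)


def hysteresis_loop_area(frame: pd.DataFrame, column: str = "nodf") -> pd.Series:
    """Signed area enclosed by the up and down branches, per cycle.

    Both branches are interpolated onto a common Omega_m grid and the
    integral of (up - down) taken; used to check that the loop settles
    under cyclic ramping.
    """
    areas = {}
    for cycle, sub in frame.groupby("cycle"):
        up = sub[sub["branch"] == "up"].sort_values("omega_m")
        down = sub[sub["branch"] == "down"].sort_values("omega_m")
        if len(up) < 2 or len(down) < 2:
            areas[cycle] = np.nan
            continue
        lo = max(up["omega_m"].min(), down["omega_m"].min())
        hi = min(up["omega_m"].max(), down["omega_m"].max())
        grid = np.linspace(lo, hi, 101)
        u = np.interp(grid, up["omega_m"], up[column])
        d = np.interp(grid, down["omega_m"], down[column])
        areas[cycle] = float(np.trapezoid(u - d, grid))
    return pd.Series(areas, name=f"{column}_loop_area")


# ---------------------------------------------------------------------------
# invasions
# ---------------------------------------------------------------------------

@dataclass
class InvasionConfig:
    """Two-timescale invasion protocol.

    R_T : rewiring attempts between successive invasion events.
    mutant_fraction : share of the resident's abundance handed to the
        mutant (the resident keeps the rest).
    displacement_sd : SD of the Gaussian niche-center displacement of
        the mutant on the unit axis.
    delta_m : rewiring attempts after an invasion at which its outcome
        (mutant extinct / resident extinct / coexistence) is classified.
    connectance_exponent : the network-size relation C_0 = 4 / M^exp
        enforced by random link deletion after each invasion.
    """

    R_T: int = 50
    mutant_fraction: float = 0.01
    displacement_sd: float = 0.02
    delta_m: int = 500
    connectance_exponent: float = 0.8

    def target_connectance(self, M: int) -> float:
        return min(1.0, 4.0 / M ** self.connectance_exponent)


@dataclass
class InvasionEvent:
    """Bookkeeping for one invasion awaiting classification."""

    epoch: int
    attempt: int
    resident_id: int
    mutant_id: int
    resident_degree: int
    displacement: float
    outcome: str | None = None


@dataclass
class InvasionLog:
    """Per-event records plus aggregated relative outcome probabilities."""

    events: pd.DataFrame
    timeseries: pd.DataFrame
    p_rel: pd.DataFrame


class _TrackedCommunity:
    """Community with persistent species ids (survives add/remove)."""

    def __init__(self, community: BipartiteCommunity):
        self.community = community
        self.ids_A = list(range(community.M_A))
        self.ids_P = list(range(community.M_A, community.M))
        self._next_id = community.M

    def new_id(self) -> int:
        self._next_id += 1
        return self._next_id - 1

    @property
    def ids(self) -> list[int]:
        return self.ids_A + self.ids_P

    def global_index(self, species_id: int) -> int | None:
        if species_id in self.ids_A:
            return self.ids_A.index(species_id)
        if species_id in self.ids_P:
            return self.community.M_A + self.ids_P.index(species_id)
        return None

    def remove(self, global_indices) -> None:
        idx = sorted(np.atleast_1d(np.asarray(global_indices, int)), reverse=True)
        M_A = self.community.M_A
        for i in idx:
            if i < M_A:
                del self.ids_A[i]
            else:
                del self.ids_P[i - M_A]
        self.community.remove_species(list(idx))


def create_mutant(
    tracked: _TrackedCommunity,
    resident_global: int,
    config: InvasionConfig,
    rng: np.random.Generator,
) -> tuple[int, float]:
    """Insert a mutant of a resident species (in place).

    The mutant joins the resident's guild with a niche center displaced
    by Normal(0, displacement_sd) clipped to [0, 1], copies the
    resident's full partner set, and receives ``mutant_fraction`` of the
    resident's abundance (the resident keeps the remainder, so total
    abundance is conserved at the instant of invasion).  Afterwards links
    are deleted uniformly at random network-wide — never a species' last
    link — until the connectance matches 4 / M^0.8 for the enlarged M.

    Returns (mutant persistent id, displacement drawn).
    """
    comm = tracked.community
    guild = comm.guild_of(resident_global)
    loc = comm.local_index(resident_global)
    displacement = float(rng.normal(0.0, config.displacement_sd))
    if guild == "A":
        center = float(np.clip(comm.centers_A[loc] + displacement, 0.0, 1.0))
        inherited = comm.theta[loc].copy()
        n_res = comm.abundance_A[loc]
        comm.abundance_A[loc] = n_res * (1 - config.mutant_fraction)
    else:
        center = float(np.clip(comm.centers_P[loc] + displacement, 0.0, 1.0))
        inherited = comm.theta[:, loc].copy()
        n_res = comm.abundance_P[loc]
        comm.abundance_P[loc] = n_res * (1 - config.mutant_fraction)
    comm.add_species(guild, center, n_res * config.mutant_fraction, inherited)
    mutant_id = tracked.new_id()
    if guild == "A":
        tracked.ids_A.append(mutant_id)
    else:
        tracked.ids_P.append(mutant_id)

    # enforce the size-connectance relation by random link deletion
    target_L = int(round(config.target_connectance(comm.M) * comm.M_A * comm.M_P))
    deg_A = comm.theta.sum(axis=1)
    deg_P = comm.theta.sum(axis=0)
    while comm.theta.sum() > target_L:
        rows, cols = np.nonzero(comm.theta)
        deletable = (deg_A[rows] >= 2) & (deg_P[cols] >= 2)
        if not deletable.any():
            log.warning("connectance rule infeasible; stopping at min-degree floor")
            break
        pick = rng.choice(np.flatnonzero(deletable))
        r, c = rows[pick], cols[pick]
        comm.theta[r, c] = False
        deg_A[r] -= 1
        deg_P[c] -= 1
    return mutant_id, displacement


def classify_outcome(
    tracked: _TrackedCommunity, event: InvasionEvent, threshold: float
) -> str:
    """Outcome of an invasion at its classification horizon.

    Based on which of the pair survives (abundance above the extinction
    threshold, species still present): ``resident-extinct`` means the
    mutant replaced the resident, ``mutant-extinct`` the reverse,
    ``coexistence`` both alive, ``both-extinct`` the rare double loss.
    """
    n = tracked.community.abundances
    res_idx = tracked.global_index(event.resident_id)
    mut_idx = tracked.global_index(event.mutant_id)
    res_alive = res_idx is not None and n[res_idx] > threshold
    mut_alive = mut_idx is not None and n[mut_idx] > threshold
    if res_alive and mut_alive:
        return "coexistence"
    if res_alive:
        return "mutant-extinct"
    if mut_alive:
        return "resident-extinct"
    return "both-extinct"


#: the three (overlapping) event indicators whose degree profiles are
#: reported: the mutant survived, the invaded resident went extinct,
#: and both persisted
_INDICATORS = {
    "mutant-survives": ("coexistence", "resident-extinct"),
    "resident-extinct": ("resident-extinct", "both-extinct"),
    "coexistence": ("coexistence",),
}


def relative_outcome_probabilities(events: pd.DataFrame) -> pd.DataFrame:
    """P_rel(k): outcome frequency within resident degree class k divided
    by the outcome's marginal frequency.

    The three reported indicators overlap (mutant survival counts both
    replacement and coexistence; resident extinction counts replacement
    and double loss), so each is normalized by its own marginal.  Values
    above 1 mean the outcome is over-represented at that degree.
    """
    done = events.dropna(subset=["outcome"])
    if done.empty:
        return pd.DataFrame(columns=["k", "outcome", "p_rel", "n_events"])
    rows = []
    for name, classes in _INDICATORS.items():
        flag = done["outcome"].isin(classes)
        marginal = flag.mean()
        if marginal == 0:
            continue
        for k, sub in flag.groupby(done["resident_degree"]):
            rows.append({
                "k": int(k), "outcome": name,
                "p_rel": float(sub.mean() / marginal),
                "n_events": len(sub),
            })
    return pd.DataFrame(rows)


def core_community(width: float, rng: np.random.Generator, n0: float = 1.0) -> BipartiteCommunity:
    """The minimal seed for invasion evolution: two species per guild,
    all cross-guild links present, centers uniform on [0, 1]."""
    return BipartiteCommunity(
        centers_A=rng.uniform(0, 1, 2),
        centers_P=rng.uniform(0, 1, 2),
        width=width,
        theta=np.ones((2, 2), dtype=bool),
        n0=n0,
    )


def evolve_with_invasions(
    community: BipartiteCommunity,
    intensities: InteractionIntensities,
    params: DynamicsParams,
    config: InvasionConfig,
    n_epochs: int,
    rng: np.random.Generator,
    eta: float = 1.0,
    rewiring_enabled: bool = True,
) -> InvasionLog:
    """Two-timescale evolution: R_T rewiring attempts, then one invasion.

    Invading residents are drawn with probability proportional to
    abundance.  Between and after events the dynamics is relaxed and
    species below the extinction threshold are removed (the only place
    extinction operates).  Each event is classified ``delta_m`` rewiring
    attempts after it happened.  ``rewiring_enabled=False`` runs the
    control in which the short-timescale adaptation is switched off.

    Returns an ``InvasionLog`` with the per-event table, a per-epoch time
    series of (M, connectance, NODF, Q, mean_n) and the aggregated
    relative outcome probabilities P_rel(k).
    """
    tracked = _TrackedCommunity(community)
    couplings = build_couplings(community, intensities)
    relax_to_equilibrium(community, couplings, params)
    _prune_extinct(tracked, params)
    couplings = build_couplings(community, intensities)

    events: list[InvasionEvent] = []
    pending: list[InvasionEvent] = []
    series = []
    attempt = 0

    for epoch in range(n_epochs):
        if community.M_A == 0 or community.M_P == 0:
            log.warning("guild extinct at epoch %d; terminating", epoch)
            break
        # --- short timescale: adaptive rewiring with extinction active ---
        for _ in range(config.R_T):
            attempt += 1
            if rewiring_enabled:
                prop = propose_rewire(community, rng, eta)
                if prop is not None:
                    accepted, _eq = attempt_step(community, couplings, prop, params)
                    if accepted and _prune_extinct(tracked, params):
                        couplings = build_couplings(community, intensities)
            _classify_due(tracked, pending, attempt, params, config)
        # --- long timescale: one invasion event ---
        n = community.abundances
        if n.sum() <= 0:
            break
        resident_global = int(rng.choice(community.M, p=n / n.sum()))
        resident_id = tracked.ids[resident_global]
        resident_degree = int(
            community.degrees_A[resident_global]
            if resident_global < community.M_A
            else community.degrees_P[resident_global - community.M_A]
        )
        mutant_id, displacement = create_mutant(tracked, resident_global, config, rng)
        couplings = build_couplings(community, intensities)
        relax_to_equilibrium(community, couplings, params)
        if _prune_extinct(tracked, params):
            couplings = build_couplings(community, intensities)
        ev = InvasionEvent(
            epoch=epoch, attempt=attempt, resident_id=resident_id,
            mutant_id=mutant_id, resident_degree=resident_degree,
            displacement=displacement,
        )
        pending.append(ev)
        events.append(ev)
        series.append(_epoch_record(epoch, attempt, community))

    # classify whatever is still pending at the end of the run
    for ev in pending:
        if ev.outcome is None:
            ev.outcome = None  # unresolved: horizon not reached
    ev_frame = pd.DataFrame([vars(e) for e in events])
    return InvasionLog(
        events=ev_frame,
        timeseries=pd.DataFrame(series),
        p_rel=relative_outcome_probabilities(ev_frame) if len(ev_frame) else pd.DataFrame(),
    )


def _prune_extinct(tracked: _TrackedCommunity, params: DynamicsParams) -> bool:
    """Remove species below the extinction threshold; True if any went."""
    comm = tracked.community
    gone = np.flatnonzero(comm.abundances < params.extinction_threshold)
    if gone.size == 0:
        return False
    tracked.remove(gone)
    return True


def _classify_due(
    tracked: _TrackedCommunity,
    pending: list[InvasionEvent],
    attempt: int,
    params: DynamicsParams,
    config: InvasionConfig,
) -> None:
    for ev in list(pending):
        if attempt - ev.attempt >= config.delta_m:
            ev.outcome = classify_outcome(tracked, ev, params.extinction_threshold)
            pending.remove(ev)


def _epoch_record(epoch: int, attempt: int, community: BipartiteCommunity) -> dict:
    theta = community.theta
    keep_r = theta.any(axis=1)
    keep_c = theta.any(axis=0)
    pruned = theta[np.ix_(np.flatnonzero(keep_r), np.flatnonzero(keep_c))]
    nodf = Q = np.nan
    if min(pruned.shape) >= 2:
        nodf = _metrics.nodf(pruned)
        Q = _metrics.modularity(pruned)[0]
    return {
        "epoch": epoch, "attempt": attempt, "M": community.M,
        "M_A": community.M_A, "M_P": community.M_P,
        "connectance": community.connectance,
        "nodf": nodf, "Q": Q,
        "mean_n": float(community.abundances.mean()),
    }
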