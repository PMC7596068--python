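import numpy as np
import pandas as pd
import pytest

import nicheweb as nw
from nicheweb.experiments import _TrackedCommunity, classify_outcome, create_mutant


class TestThresholdEstimation:
    def test_linear_crossing_identity(self):
        x = [0.01, 0.02, 0.03]
        y = [0.01, 0.0, -0.01]
        assert nw.estimate_threshold(x, y) == pytest.approx(0.02)
        assert nw.estimate_threshold([0.0, 0.04], [0.02, -0.02]) == pytest.approx(0.02)

    def test_unbracketed_raises(self):
        with pytest.raises(ValueError, match="not bracketed"):
            nw.estimate_threshold([0.1, 0.2, 0.3], [1.0, 2.0, 0.5])

    def test_bootstrap_ci_contains_estimate(self, rng):
        x = np.array([0.01, 0.02, 0.03, 0.04])
        y_reps = 0.025 - x[None, :] + rng.normal(0, 0.002, (20, 4))
        est, lo, hi = nw.threshold_bootstrap_ci(x, y_reps, rng)
        assert lo <= est <= hi
        assert est == pytest.approx(0.025, abs=0.005)

    def test_trend_slope_sign(self):
        assert nw.omega_m_trend_slope([0.1, 0.2, 0.3], [1.0, 1.5, 2.0]) > 0
        assert nw.omega_m_trend_slope([0.1, 0.2, 0.3], [2.0, 1.5, 1.0]) < 0


class TestSweepPlumbing:
    def test_single_rep_grid_runs(self, rng):
        res = nw.stability_sweep(
            [0.1, 0.2], [0.02, 0.05], n_reps=1, rng=rng, M_A=8, M_P=8,
            C0=0.25, config=nw.RewiringConfig(max_attempts=300, steady_window=100,
                                              checkpoint_every=50),
        )
        assert len(res.table) == 4
        assert {"S_mean", "S_null_mean", "rel_S_mean"} <= set(res.table.columns)
        assert res.table["S_mean"].notna().all()


class TestHysteresis:
    @pytest.fixture()
    def assembled_small(self):
        # function-scoped: hysteresis_run mutates the trajectory in place
        rng = np.random.default_rng(13)
        comm = nw.BipartiteCommunity.random(10, 10, 0.25, 0.1, rng)
        traj = nw.assemble(
            comm, nw.InteractionIntensities(0.10, 0.05), nw.DynamicsParams(),
            nw.RewiringConfig(max_attempts=2000, steady_window=500,
                              checkpoint_every=100), rng,
        )
        return traj

    def test_zero_ramp_keeps_omega_fixed(self, assembled_small, rng):
        hcfg = nw.HysteresisConfig(0.10, 0.10, ramp_rate=0.0, record_every=1)
        frame = nw.hysteresis_run(assembled_small, hcfg, nw.DynamicsParams(), rng)
        assert np.allclose(frame["omega_m"], 0.10)

    def test_branches_recorded_and_labeled(self, assembled_small, rng):
        hcfg = nw.HysteresisConfig(0.10, 0.13, ramp_rate=1e-3, record_every=10)
        frame = nw.hysteresis_run(assembled_small, hcfg, nw.DynamicsParams(), rng)
        assert set(frame["branch"]) == {"up", "down"}
        assert (frame["ramp_rate"] == 1e-3).all()
        up = frame[frame.branch == "up"]
        assert up["omega_m"].iloc[-1] == pytest.approx(0.13, abs=1e-9)

    def test_loop_area_computable(self, assembled_small, rng):
        hcfg = nw.HysteresisConfig(0.10, 0.12, ramp_rate=1e-3, record_every=5,
                                   n_cycles=2)
        frame = nw.hysteresis_run(assembled_small, hcfg, nw.DynamicsParams(), rng)
        areas = nw.hysteresis_loop_area(frame, "nodf")
        assert len(areas) == 2 and areas.notna().all()


class TestInvasionMechanics:
    @staticmethod
    def _tracked(rng, M=8, C0=0.3):
        comm = nw.BipartiteCommunity.random(M, M, C0, 0.1, rng)
        cp = nw.build_couplings(comm, nw.InteractionIntensities(0.1, 0.05))
        nw.relax_to_equilibrium(comm, cp, nw.DynamicsParams())
        return _TrackedCommunity(comm)

    def test_abundance_split_one_percent(self, rng):
        tracked = self._tracked(rng)
        comm = tracked.community
        comm.abundance_A[2] = 2.0
        total_before = comm.abundances.sum()
        cfg = nw.InvasionConfig(displacement_sd=0.0)
        create_mutant(tracked, 2, cfg, rng)
        assert comm.abundance_A[2] == pytest.approx(2.0 * 0.99)
        assert comm.abundance_A[-1] == pytest.approx(0.02)
        # total abundance conserved at the instant of invasion
        assert comm.abundances.sum() == pytest.approx(total_before, rel=1e-12)

    def test_zero_displacement_copies_niche_and_links(self, rng):
        tracked = self._tracked(rng)
        comm = tracked.community
        links_before = comm.theta[3].copy()
        center = comm.centers_A[3]
        # disable deletion pressure with a tiny exponent (target C0 > current)
        cfg = nw.InvasionConfig(displacement_sd=0.0, connectance_exponent=0.0)
        create_mutant(tracked, 3, cfg, rng)
        assert comm.centers_A[-1] == center
        np.testing.assert_array_equal(comm.theta[-1], links_before)

    def test_connectance_rule_applied(self, rng):
        tracked = self._tracked(rng, M=12, C0=0.4)
        comm = tracked.community
        cfg = nw.InvasionConfig(displacement_sd=0.01)
        create_mutant(tracked, 0, cfg, rng)
        target = cfg.target_connectance(comm.M)
        expected_L = round(target * comm.M_A * comm.M_P)
        assert comm.theta.sum() == expected_L
        assert comm.degrees_A.min() >= 1 and comm.degrees_P.min() >= 1

    def test_target_connectance_printed_relation(self):
        # M = 112 gives 4 / 112^0.8
        cfg = nw.InvasionConfig()
        assert cfg.target_connectance(112) == pytest.approx(4 / 112**0.8)
        assert cfg.target_connectance(112) == pytest.approx(0.0916, abs=2e-4)
        # the 4-species core saturates at a complete graph
        assert cfg.target_connectance(4) == 1.0

    def test_classify_outcomes(self, rng):
        tracked = self._tracked(rng)
        comm = tracked.community
        cfg = nw.InvasionConfig(displacement_sd=0.0, connectance_exponent=0.0)
        mutant_id, _ = create_mutant(tracked, 1, cfg, rng)
        ev = nw.experiments.InvasionEvent(
            epoch=0, attempt=0, resident_id=tracked.ids_A[1],
            mutant_id=mutant_id, resident_degree=3, displacement=0.0,
        )
        thr = 1e-6
        assert classify_outcome(tracked, ev, thr) == "coexistence"
        comm.abundance_A[-1] = 0.0       # mutant dies
        assert classify_outcome(tracked, ev, thr) == "mutant-extinct"
        comm.abundance_A[-1] = 0.5
        comm.abundance_A[1] = 0.0        # resident replaced
        assert classify_outcome(tracked, ev, thr) == "resident-extinct"

    def test_relative_probabilities_normalization(self):
        events = pd.DataFrame({
            "resident_degree": [1, 1, 1, 5, 5, 5],
            "outcome": ["resident-extinct"] * 2 + ["coexistence"]
                       + ["coexistence"] * 3,
        })
        p = nw.experiments.relative_outcome_probabilities(events)
        piv = p.pivot(index="k", columns="outcome", values="p_rel")
        # specialists (k=1) are enriched for resident extinction
        assert piv.loc[1, "resident-extinct"] > piv.loc[5, "resident-extinct"]
        assert piv.loc[5, "coexistence"] > piv.loc[1, "coexistence"]
        # indicators are each normalized to marginal 1 over all events
        for name in ("resident-extinct", "coexistence", "mutant-survives"):
            sub = p[p.outcome == name]
            weighted = (sub.p_rel * sub.n_events).sum() / sub.n_events.sum()
            assert weighted == pytest.approx(1.0)

    @pytest.mark.parametrize("sd", [0.01, 0.02, 0.05])
    def test_displacement_scale_sensitivity(self, sd):
        """Mutant displacement magnitudes track the configured SD."""
        rng = np.random.default_rng(1)
        tracked = self._tracked(rng)
        cfg = nw.InvasionConfig(displacement_sd=sd, connectance_exponent=0.0)
        disps = [create_mutant(tracked, 0, cfg, rng)[1] for _ in range(60)]
        assert np.std(disps) == pytest.approx(sd, rel=0.35)


class TestEvolveSmoke:
    def test_short_run_from_core(self, rng):
        comm = nw.core_community(0.1, rng)
        res = nw.evolve_with_invasions(
            comm, nw.InteractionIntensities(0.2, 0.3), nw.DynamicsParams(),
            nw.InvasionConfig(R_T=5, delta_m=10), 15, rng,
        )
        assert len(res.timeseries) == 15
        assert res.timeseries["M"].iloc[-1] >= 4
        # connectance tracks the size rule after every invasion
        last = res.timeseries.iloc[-1]
        cfg = nw.InvasionConfig()
        assert last["connectance"] == pytest.approx(
            cfg.target_connectance(int(last["M"])), abs=0.06
        )
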