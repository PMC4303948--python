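import numpy as np
import pandas as pd
import pytest

from gapcircuit.data import ExpressionDataset
from gapcircuit.dynamics import (CompiledCircuit, KineticParams,
                                 SimulationGrid, decay_from_halflife,
                                 interpolate_inputs, simulate)
from gapcircuit.regions import BindingSite, RegulatoryRegion
from gapcircuit.thermo import ThermoParams, activation_dp


def constant_inputs(grid, value=50.0, tf="X"):
    rows = [(tf, c, i, value) for c in grid.class_labels
            for i in range(grid.nuclei_of(c))]
    return ExpressionDataset(
        pd.DataFrame(rows, columns=["gene", "time_class", "nucleus",
                                    "conc"]),
        grid.class_times)


def single_gene_setup(grid, q_btm=0.2, n_sites=0, r_u=10.0, lam_u=0.1,
                      diffusion=0.0, lam_v=0.05, r_v=0.0, tau=0.0):
    sites = [BindingSite("X", 30 * j, 30 * j + 8, "+", "A" * 8, 0.0)
             for j in range(n_sites)]
    region = RegulatoryRegion("g", "A" * 400, sites=sites)
    tp = ThermoParams("g", {"X": 2.0}, {"X": 0.01}, q_btm=q_btm)
    kp = KineticParams(r_u, r_v, {13: diffusion, 14: diffusion},
                       {13: diffusion, 14: diffusion}, lam_u, lam_v, tau)
    return {"g": region}, {"g": tp}, {"g": kp}


class TestDecay:
    def test_halflife_ln2_gives_unit_rate(self):
        assert decay_from_halflife(np.log(2.0)) == pytest.approx(1.0)

    def test_example_value(self):
        assert decay_from_halflife(6.93) == pytest.approx(
            np.log(2.0) / 6.93)
        assert decay_from_halflife(6.93) == pytest.approx(0.1000,
                                                          abs=2e-4)

    def test_identity(self, rng):
        for h in rng.uniform(0.5, 100, 10):
            assert decay_from_halflife(h) * h == pytest.approx(np.log(2))

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            decay_from_halflife(0.0)


class TestGrid:
    def test_nuclei_double_into_cycle_14(self):
        grid = SimulationGrid(n_nuclei_c13=29)
        assert grid.n_nuclei_c14 == 58

    def test_class_count_from_duration(self):
        grid = SimulationGrid.from_c14_duration(52.0)
        assert grid.n_classes_c14 == 8
        assert grid.class_labels == ["c13"] + [f"T{k}"
                                               for k in range(1, 9)]


class TestInterpolation:
    def grid(self):
        return SimulationGrid(n_nuclei_c13=2, n_classes_c14=2)

    def make(self, v1, v2):
        grid = self.grid()
        rows = [("X", "T1", i, v1) for i in range(4)]
        rows += [("X", "T2", i, v2) for i in range(4)]
        return ExpressionDataset(
            pd.DataFrame(rows, columns=["gene", "time_class", "nucleus",
                                        "conc"]),
            {"T1": grid.class_times["T1"], "T2": grid.class_times["T2"]})

    def test_exact_at_class_time(self):
        data = self.make(10.0, 20.0)
        out = interpolate_inputs(data, data.class_times["T1"])
        assert np.allclose(out["X"], 10.0)

    def test_midpoint_average(self):
        data = self.make(10.0, 20.0)
        t_mid = 0.5 * (data.class_times["T1"] + data.class_times["T2"])
        assert np.allclose(interpolate_inputs(data, t_mid)["X"], 15.0)

    def test_constant_extrapolation_and_bounds(self):
        data = self.make(10.0, 20.0)
        assert np.allclose(interpolate_inputs(data, -100.0)["X"], 10.0)
        assert np.allclose(interpolate_inputs(data, 1e4)["X"], 20.0)
        mid = interpolate_inputs(
            data, data.class_times["T1"] + 1.0)["X"]
        assert ((mid >= 10.0) & (mid <= 20.0)).all()


class TestSimulate:
    def test_zero_synthesis_stays_zero(self):
        grid = SimulationGrid(n_nuclei_c13=3, n_classes_c14=2)
        regions, tps, kps = single_gene_setup(grid, r_u=0.0)
        traj = simulate(regions, tps, kps, constant_inputs(grid), grid,
                        {"X": 0.0})
        for cls in grid.class_labels:
            assert np.allclose(traj.u[cls], 0.0)
            assert np.allclose(traj.v[cls], 0.0)

    def test_single_nucleus_closed_form(self):
        # constant E (no sites), no diffusion, tau = 0:
        # u(t) = (R E / lambda)(1 - exp(-lambda t))
        grid = SimulationGrid(n_nuclei_c13=1)
        regions, tps, kps = single_gene_setup(grid, q_btm=0.2, r_u=10.0,
                                              lam_u=0.1)
        traj = simulate(regions, tps, kps, constant_inputs(grid), grid,
                        {"X": 0.0})
        e = 0.2 / 1.2
        for cls, t in grid.class_times.items():
            expected = 10.0 * e / 0.1 * (1.0 - np.exp(-0.1 * t))
            assert traj.u[cls][0, 0] == pytest.approx(expected,
                                                      rel=1e-3)

    def test_diffusion_only_conserves_mass(self, rng):
        grid = SimulationGrid(n_nuclei_c13=8, n_classes_c14=4)
        regions, tps, kps = single_gene_setup(grid, r_u=0.0, lam_u=0.0,
                                              lam_v=0.0, diffusion=0.3)
        u0 = {"g": rng.uniform(0, 100, 8)}
        compiled = CompiledCircuit(regions, ["X"],
                                   constant_inputs(grid), grid,
                                   {"X": 0.0})
        traj = compiled.run(tps, kps, initial_u=u0)
        # compare within cycle 14 (each nucleus has divided into two)
        totals = [traj.u[c][0].sum() for c in grid.class_labels[1:]]
        assert np.allclose(totals, 2.0 * u0["g"].sum(), atol=1e-8)

    def test_halving_dt_changes_little(self, toy):
        coarse = toy.model.trajectory(toy.truth)
        fine_grid = SimulationGrid(
            n_nuclei_c13=toy.model.grid.n_nuclei_c13,
            n_classes_c14=toy.model.grid.n_classes_c14,
            dt=toy.model.grid.dt / 2)
        compiled = CompiledCircuit(toy.model.regions, toy.config.tfs,
                                   toy.external, fine_grid,
                                   toy.model.llr_max)
        fine = compiled.run(toy.truth.all_thermo(),
                            toy.truth.all_kinetics())
        last = toy.model.grid.class_labels[-1]
        scale = np.abs(coarse.v[last]).max()
        rel = np.abs(fine.v[last] - coarse.v[last]).max() / scale
        assert rel < 0.005

    def test_non_negative_at_default_dt(self, toy):
        traj = toy.model.trajectory(toy.truth)
        for cls in toy.model.grid.class_labels:
            assert (traj.u[cls] >= 0).all()
            assert (traj.v[cls] >= 0).all()

    def test_delay_shifts_protein_response(self):
        # pulse of activation: protein lags mRNA by ~tau_v
        grid = SimulationGrid(n_nuclei_c13=1, cycle13_duration=16.0,
                              n_classes_c14=6, dt=0.0625)
        tau = 4.0
        regions, tps, kps0 = single_gene_setup(
            grid, q_btm=0.5, r_u=10.0, lam_u=0.3, lam_v=0.3, r_v=1.0,
            tau=0.0)
        _, _, kps1 = single_gene_setup(
            grid, q_btm=0.5, r_u=10.0, lam_u=0.3, lam_v=0.3, r_v=1.0,
            tau=tau)
        t0 = simulate(regions, tps, kps0, constant_inputs(grid), grid,
                      {"X": 0.0})
        t1 = simulate(regions, tps, kps1, constant_inputs(grid), grid,
                      {"X": 0.0})
        # delayed protein at time t equals undelayed at t - tau once
        # the history window has passed
        for cls in ["T4", "T5", "T6"]:
            t = grid.class_times[cls]
            ref_cls = None
            for c2, t2 in grid.class_times.items():
                if abs(t2 - (t - tau)) < 1e-9:
                    ref_cls = c2
            if ref_cls is None:
                continue
            assert t1.v[cls][0, 0] == pytest.approx(
                t0.v[ref_cls][0, 0], rel=0.02)

    def test_instability_reported(self):
        # explicit diffusion far beyond the stability limit blows up
        grid = SimulationGrid(n_nuclei_c13=2, n_classes_c14=2, dt=0.05)
        regions, tps, kps = single_gene_setup(grid, r_u=10.0, lam_u=0.0,
                                              lam_v=0.0, r_v=1.0,
                                              diffusion=1e6)
        compiled = CompiledCircuit(regions, ["X"],
                                   constant_inputs(grid), grid,
                                   {"X": 0.0})
        with pytest.raises(RuntimeError, match="non-finite"):
            compiled.run(tps, kps,
                         initial_u={"g": np.array([100.0, 0.0])})

    def test_kernel_activation_matches_reference_dp(self, toy, rng):
        # the jitted activation inside the integrator reproduces the
        # pure-python DP on the toy regions
        conc = {tf: rng.uniform(0, 200, toy.model.grid.n_nuclei_c14)
                for tf in toy.config.tfs}
        e = toy.model.compiled().activation(toy.truth.all_thermo(), conc)
        for gi, g in enumerate(toy.config.genes):
            tp = toy.truth.thermo_params(g)
            for i in [0, 7, 19]:
                point = {tf: conc[tf][i] for tf in conc}
                expected = activation_dp(toy.regions[g].sites, tp,
                                         point, toy.model.llr_max)
                assert e[gi, i] == pytest.approx(expected, rel=1e-10)
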