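"""Dynamic solver behaviour against physical oracles: Poiseuille friction
limit, linearized pulse-wave speed, junction coupling, stenosis jump,
closed-loop conservation and grid convergence."""

import math

import numpy as np
import pytest
from scipy.optimize import root

import willisflow as wf
import willisflow.units as U
from willisflow.network import ArterySegment, StenosisSpec, eh_from_radius
from willisflow.solver import (SolverSettings, TubeSimulator, solve_junction,
                               wave_speed, run_to_periodic,
                               simulate_output_vector, InstabilityError,
                               NetworkSimulation)
from conftest import TOY_DX


class TestSingleTube:
    def test_steady_poiseuille_pressure_drop(self):
        """Constant flow through a near-rigid uniform tube: the pressure
        drop equals the friction-model closed form 22*pi*mu*L*Q/A^2."""
        seg = ArterySegment(id=0, name="t", length=100.0, diameter=4.0,
                            Eh=eh_from_radius(2e-3) * 50)
        q = 5.0e-6
        sim = TubeSimulator(seg, 121, inflow=q,
                            outflow_pressure=U.mmhg_to_pa(85.0))
        sim.run(1.0)
        dp = sim.pressure[0] - sim.pressure[-1]
        area = seg.A0 * 1e-6
        dp_theory = 22 * math.pi * U.BLOOD_VISCOSITY * 0.1 * q / area ** 2
        assert dp == pytest.approx(dp_theory, rel=0.01)

    def test_small_pulse_travels_at_linearized_wave_speed(self):
        seg = ArterySegment(id=0, name="t", length=1000.0, diameter=5.0,
                            Eh=eh_from_radius(2.5e-3))
        n = 401
        sim = TubeSimulator(seg, n)
        x = np.linspace(0.0, 1.0, n)
        a0 = seg.A0 * 1e-6
        sim.A = a0 * (1.0 + 0.01 * np.exp(-((x - 0.2) / 0.05) ** 2 / 2))
        c0 = wave_speed(a0, seg)
        # right-going simple wave: u = 4(c - c0)
        sim.Q = sim.A * 4.0 * (sim._c(sim.A) - c0)
        peak0 = x[np.argmax(sim.A)]
        sim.run(0.05)
        speed = (x[np.argmax(sim.A)] - peak0) / 0.05
        assert speed == pytest.approx(c0, rel=0.03)

    def test_time_step_violating_cfl_raises(self):
        seg = ArterySegment(id=0, name="t", length=100.0, diameter=4.0,
                            Eh=eh_from_radius(2e-3))
        sim = TubeSimulator(seg, 41, inflow=1e-6,
                            outflow_pressure=U.mmhg_to_pa(85.0))
        with pytest.raises(InstabilityError):
            sim.step(10.0 * sim.max_dt())

    def test_rest_state_is_preserved(self):
        seg = ArterySegment(id=0, name="t", length=100.0, diameter=4.0,
                            Eh=eh_from_radius(2e-3))
        sim = TubeSimulator(seg, 41)   # non-reflecting ends, A = A0, Q = 0
        a_init = sim.A.copy()
        sim.run(0.2)
        assert np.allclose(sim.A, a_init, rtol=1e-12)
        assert np.allclose(sim.Q, 0.0, atol=1e-15)


class TestNetworkStepper:
    def test_single_steps_stay_finite_and_positive(self, toy_net):
        sim = NetworkSimulation(toy_net, SolverSettings(target_dx=10.0))
        for _ in range(50):
            sim.advance(0.9 * sim.max_dt())
        assert np.all(np.isfinite(sim.flat.A)) and np.all(sim.flat.A > 0)
        assert sim.t > 0

    def test_cfl_violation_raises_before_diverging(self, toy_net):
        sim = NetworkSimulation(toy_net, SolverSettings(target_dx=10.0))
        with pytest.raises(InstabilityError):
            sim.advance(20.0 * sim.max_dt())


class TestJunctionSolve:
    def test_symmetric_bifurcation_splits_flow_equally(self):
        rho = 1060.0
        beta = np.array([6e6, 9e6, 9e6])
        a0 = np.array([2e-5, 1e-5, 1e-5])
        c_par = math.sqrt(beta[0] * math.sqrt(a0[0]) / (2 * rho))
        c_ch = math.sqrt(beta[1] * math.sqrt(a0[1]) / (2 * rho))
        w = np.array([0.4 + 4 * c_par, -4 * c_ch + 0.0, -4 * c_ch + 0.0])
        A, Q, P = solve_junction(w, [1, -1, -1], beta, a0, a0.copy())
        assert Q[1] == pytest.approx(Q[2], rel=1e-12)
        assert Q[0] == pytest.approx(Q[1] + Q[2], abs=1e-10)

    def test_converged_solve_conserves_mass_to_newton_tolerance(self):
        beta = np.array([5e6, 8e6, 9e6])
        a0 = np.array([2e-5, 1.2e-5, 0.9e-5])
        rho = 1060.0
        cs = np.sqrt(beta * np.sqrt(a0) / (2 * rho))
        w = np.array([0.3 + 4 * cs[0], 0.1 - 4 * cs[1], 0.05 - 4 * cs[2]])
        A, Q, P = solve_junction(w, [1, -1, -1], beta, a0, a0.copy())
        assert abs(Q[0] - Q[1] - Q[2]) < 1e-10

    def test_matches_independent_root_find(self):
        """Our Newton solve equals a generic scipy root-find on the same
        mass + total-pressure residual system."""
        rho = 1060.0
        p0 = U.mmhg_to_pa(85.0)
        beta = np.array([5e6, 8e6, 9e6])
        a0 = np.array([2e-5, 1.2e-5, 0.9e-5])
        sgn = np.array([1.0, -1.0, -1.0])
        cs = np.sqrt(beta * np.sqrt(a0) / (2 * rho))
        w = np.array([0.3 + 4 * cs[0], 0.1 - 4 * cs[1], 0.05 - 4 * cs[2]])
        A, Q, P = solve_junction(w, sgn, beta, a0, a0.copy())

        def resid(a):
            c = np.sqrt(beta * np.sqrt(a) / (2 * rho))
            u = w - sgn * 4 * c
            pt = p0 + beta * (np.sqrt(a) - np.sqrt(a0)) + 0.5 * rho * u ** 2
            return [np.sum(sgn * a * u), pt[1] - pt[0], pt[2] - pt[0]]

        ref = root(resid, a0.copy(), tol=1e-14)
        assert ref.success
        assert np.allclose(A, ref.x, rtol=1e-10)


class TestClosedLoop:
    def test_periodic_state_reached(self, toy_baseline):
        assert toy_baseline.converged
        assert toy_baseline.cycles_run <= 30

    def test_junction_flow_balance_at_periodicity(self, toy_baseline):
        q_in = toy_baseline.mean_flow(0, "dist")
        q_out = (toy_baseline.mean_flow(1, "prox")
                 + toy_baseline.mean_flow(2, "prox"))
        assert q_out == pytest.approx(q_in, rel=1e-3)

    def test_cardiac_output_equals_summed_outlet_flows(self, toy_baseline):
        co = toy_baseline.cardiac_output
        total = sum(toy_baseline.outlet_flows.values())
        assert total == pytest.approx(co, rel=0.01)

    def test_outputs_are_physiological(self, toy_baseline):
        d = toy_baseline.as_dict()
        assert 60.0 < d["MAP"] < 130.0
        assert all(v > 0 for k, v in d.items() if k.startswith("Qbar"))

    def test_grid_convergence_of_outputs(self, toy_net):
        coarse = run_to_periodic(toy_net, SolverSettings(target_dx=5.0))
        fine = run_to_periodic(toy_net, SolverSettings(target_dx=2.5))
        rel = np.abs(fine.values - coarse.values) / \
            np.maximum(np.abs(coarse.values), 1.0)
        assert float(rel.max()) < 0.005

    def test_stenosis_jump_matches_model_at_interface(self, toy_net,
                                                      toy_settings):
        """With a purely viscous stenosis (SR = 0, Kt = 0) the cycle-mean
        pressure difference across the interface equals Rv * Qbar."""
        import copy
        net = copy.deepcopy(toy_net)
        rv = 2.0
        net.stenoses = [StenosisSpec(host_segment_id=1, Rv=rv, Dn=4.6,
                                     SR=0.0, Kt=0.0)]
        res = run_to_periodic(net, toy_settings)
        assert res.converged
        fl = res.flat
        up, dn = fl.flat_of[1]
        i_up = int(fl.seg_first[up] + fl.seg_n[up] - 1)
        i_dn = int(fl.seg_first[dn])
        pt = res.mean_p_node + res.mean_dyn_node                 # total
        dp = pt[i_up] - pt[i_dn]                                 # mmHg
        qbar = res.mean_q_node[i_up] / 60.0                      # mL/s
        assert dp == pytest.approx(rv * qbar, rel=0.005)


class TestOutputVectorResponses:
    def test_symmetric_inputs_give_symmetric_outputs(self, toy_net,
                                                     toy_baseline):
        d = toy_baseline.as_dict()
        assert d["Qbar: L. branch"] == pytest.approx(
            d["Qbar: R. branch"], rel=0.005)
        assert d["Pbar: L. outlet artery"] == pytest.approx(
            d["Pbar: R. outlet artery"], rel=0.005)

    def test_doubling_outlet_pr_reduces_cow_outflow(self, toy_net,
                                                    toy_settings,
                                                    toy_baseline):
        x = wf.extract_input_vector(toy_net)
        i_pr = next(i for i, s in enumerate(toy_net.input_manifest)
                    if s.kind == "pr_cow")
        x[i_pr] *= 2.0
        y = simulate_output_vector(x, toy_net, toy_settings)
        base = toy_baseline.as_dict()["Qbar: L. outlet artery"]
        i_q = next(i for i, s in enumerate(toy_net.output_manifest)
                   if s.kind == "qbar" and s.target == 3)
        assert y[i_q] < base

    def test_severe_stenosis_reduces_ipsilateral_flow(self, toy_net,
                                                      toy_settings,
                                                      toy_baseline):
        x = wf.extract_input_vector(toy_net)
        for i, s in enumerate(toy_net.input_manifest):
            if s.kind == "sten_rv":
                x[i] = 20.0
            elif s.kind == "sten_sr":
                x[i] = 0.9
            elif s.kind == "sten_dn":
                x[i] = 4.6
            elif s.kind == "sten_kt":
                x[i] = 1.52
        y = simulate_output_vector(x, toy_net, toy_settings)
        names = [s.name for s in toy_net.output_manifest]
        base = toy_baseline.as_dict()
        assert y[names.index("Qbar: L. branch")] < 0.5 * base["Qbar: L. branch"]
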