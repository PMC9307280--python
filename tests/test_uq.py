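"""Uncertainty modeling and Monte Carlo propagation of the postoperative
flow increase."""

import numpy as np
import pytest
from scipy import stats

import willisflow as wf
from willisflow.uq import (PatientRecord, StenosisGeometry,
                           build_uncertainty_model, virtual_stenting,
                           delta_q, run_uq)
from test_calibration import analytic_predictor
from conftest import output_indices


@pytest.fixture(scope="module")
def full_net():
    return wf.build_default_network()


def full_record(**kwargs):
    defaults = dict(
        diameters={74: 3.0, 75: 2.9, 80: 1.5},
        pixel_size=0.4, stenosis_side="right",
        stenosis={"right": StenosisGeometry(Dn=5.0, SR=0.6, Ls=15.0)},
        spect_flows=np.array([70.0, 70.0, 130.0, 130.0, 50.0, 50.0]),
        total_inflow=700.0, inflow_modality="PC-MRI", map_mmhg=95.0)
    defaults.update(kwargs)
    return PatientRecord(**defaults)


class TestUncertaintyModel:
    def test_diameter_interval_is_plus_minus_two_pixels(self, full_net):
        model = build_uncertainty_model(full_record(), full_net)
        p = next(p for p in model.params if p.name == "D: R. mid. cerebral")
        assert (p.lower, p.upper) == (3.0 - 0.8, 3.0 + 0.8)

    def test_diameter_interval_clamped_to_sampling_range(self, full_net):
        model = build_uncertainty_model(
            full_record(diameters={80: 0.3}), full_net)
        p = next(p for p in model.params if p.name == "D: Ant. comm.")
        assert p.lower == 0.1    # clamped at the published lower bound

    def test_pcmri_total_inflow_interval(self, full_net):
        model = build_uncertainty_model(full_record(), full_net)
        p = next(p for p in model.params if p.kind == "total_flow")
        assert p.lower == pytest.approx(700.0 * 0.84)
        assert p.upper == pytest.approx(700.0 * 1.16)

    def test_ultrasound_widens_total_inflow(self, full_net):
        model = build_uncertainty_model(
            full_record(inflow_modality="ultrasound"), full_net)
        p = next(p for p in model.params if p.kind == "total_flow")
        assert p.lower == pytest.approx(700.0 * 0.65)

    def test_possibly_absent_acoa_spans_full_interval(self, full_net):
        model = build_uncertainty_model(
            full_record(acoa_possibly_absent=True), full_net)
        p = next(p for p in model.params if p.name == "D: Ant. comm.")
        assert (p.lower, p.upper) == (0.1, 2.6)

    def test_stenosis_offset_interval_is_two_pixels(self, full_net):
        model = build_uncertainty_model(full_record(), full_net)
        p = next(p for p in model.params if p.kind == "sten_delta")
        assert (p.lower, p.upper) == (-0.8, 0.8)

    def test_stenosis_offset_moves_all_derived_parameters(self, full_net):
        model = build_uncertainty_model(full_record(), full_net)
        i_delta = next(i for i, p in enumerate(model.params)
                       if p.kind == "sten_delta")
        lo = np.array([0.5 * (p.lower + p.upper) for p in model.params])
        hi = lo.copy()
        lo[i_delta] = -0.8
        hi[i_delta] = 0.8
        x_lo, _ = model.realize(lo)
        x_hi, _ = model.realize(hi)
        sl = {s.kind: i for i, s in enumerate(full_net.input_manifest)
              if s.side == "right"}
        # narrower lumen: higher Rv and higher stenosis ratio
        assert x_lo[sl["sten_rv"]] > x_hi[sl["sten_rv"]]
        assert x_lo[sl["sten_sr"]] > x_hi[sl["sten_sr"]]
        assert x_lo[sl["sten_dn"]] < x_hi[sl["sten_dn"]]

    def test_zero_width_record_has_no_random_parameters(self, toy_net):
        rec = PatientRecord(
            diameters={}, pixel_size=0.0, stenosis_side="left",
            stenosis={"left": StenosisGeometry(Dn=4.6, SR=0.5, Ls=15.0)},
            spect_flows=np.array([300.0]), total_inflow=300.0,
            inflow_modality="exact", map_mmhg=90.0,
            kt_range=(1.52, 1.52), spect_uncertainty=0.0)
        model = build_uncertainty_model(rec, toy_net)
        assert model.params == []
        rng = np.random.default_rng(0)
        x1, t1 = model.sample_case(rng)
        x2, t2 = model.sample_case(rng)
        assert np.array_equal(x1, x2)
        assert np.array_equal(t1.targets, t2.targets)

    def test_drawn_targets_sum_to_drawn_total(self, full_net):
        model = build_uncertainty_model(full_record(), full_net)
        rng = np.random.default_rng(1)
        for _ in range(20):
            _, t = model.sample_case(rng)
            assert t.targets.sum() == pytest.approx(t.total_flow, rel=1e-9)

    def test_marginals_uniform_on_intervals(self, full_net):
        model = build_uncertainty_model(full_record(), full_net)
        rng = np.random.default_rng(2)
        b = model.bounds
        draws = np.array([rng.uniform(b[:, 0], b[:, 1]) for _ in range(8000)])
        for j in [0, len(model.params) - 1]:
            u = (draws[:, j] - b[j, 0]) / (b[j, 1] - b[j, 0])
            assert stats.kstest(u, "uniform").pvalue > 0.01


class TestVirtualStenting:
    def test_slots_set_to_intact_values(self, toy_net):
        x = wf.extract_input_vector(toy_net)
        sl = {s.kind: i for i, s in enumerate(toy_net.input_manifest)
              if s.side == "left"}
        i_d = next(i for i, s in enumerate(toy_net.input_manifest)
                   if s.kind == "diameter" and s.target == 1)
        x[sl["sten_rv"]] = 12.0
        x[sl["sten_sr"]] = 0.8
        x[sl["sten_kt"]] = 1.52
        x[sl["sten_dn"]] = 4.0
        x[i_d] = 4.9
        post = virtual_stenting(x, toy_net, "left")
        assert post[sl["sten_rv"]] == 0.0
        assert post[sl["sten_sr"]] == 0.0
        assert post[sl["sten_kt"]] == 0.0
        assert post[sl["sten_dn"]] == 4.9   # sampled host-ICA diameter

    def test_idempotent(self, toy_net):
        x = wf.extract_input_vector(toy_net)
        once = virtual_stenting(x, toy_net, "left")
        twice = virtual_stenting(once, toy_net, "left")
        assert np.array_equal(once, twice)

    def test_other_slots_unchanged(self, toy_net):
        x = wf.extract_input_vector(toy_net)
        post = virtual_stenting(x, toy_net, "left")
        sten = {i for i, s in enumerate(toy_net.input_manifest)
                if s.side == "left"}
        for i in range(len(x)):
            if i not in sten:
                assert post[i] == x[i]


class TestDeltaQ:
    def test_identity_gives_zero(self, toy_net):
        y = np.full(toy_net.n_outputs, 50.0)
        assert np.allclose(delta_q(y, y, toy_net), 0.0)

    def test_doubling_is_the_hyperperfusion_threshold(self, toy_net):
        pre = np.full(toy_net.n_outputs, 50.0)
        assert np.allclose(delta_q(pre, 2 * pre, toy_net), 100.0)

    def test_hand_arithmetic_150_percent(self, toy_net):
        q_idx, _ = output_indices(toy_net)
        pre = np.full(toy_net.n_outputs, 100.0)
        post = pre.copy()
        post[q_idx] = 250.0
        assert np.allclose(delta_q(pre, post, toy_net), 150.0)

    def test_nonpositive_preoperative_flow_rejected(self, toy_net):
        pre = np.zeros(toy_net.n_outputs)
        with pytest.raises(ValueError):
            delta_q(pre, pre, toy_net)


class TestRunUQ:
    def _toy_record(self, toy_net, pred, total=None, **kwargs):
        geom = StenosisGeometry(Dn=4.6, SR=0.6, Ls=15.0)
        defaults = dict(
            diameters={}, pixel_size=0.0, stenosis_side="left",
            stenosis={"left": geom}, spect_flows=np.array([total or 290.0]),
            total_inflow=total or 290.0, inflow_modality="PC-MRI",
            map_mmhg=90.0, kt_range=(1.52, 1.52), spect_uncertainty=0.0)
        defaults.update(kwargs)
        return PatientRecord(**defaults)

    def test_degenerate_uncertainty_gives_zero_variance(self, toy_net):
        pred = analytic_predictor(toy_net)
        rec = self._toy_record(toy_net, pred, inflow_modality="exact")
        res = run_uq(pred, toy_net, rec, seed=0, increment=200,
                     max_samples=400)
        assert np.all(res.variance <= 1e-12)
        assert np.all(np.isin(res.p_hyperperfusion, [0.0, 1.0]))
        assert np.all(res.interval[:, 0] == res.interval[:, 1])

    def test_probability_matches_analytic_value(self, toy_net):
        """With only the total inflow uncertain, the flow-increase law is a
        monotone map of one uniform variable: P(increase > 100%) has a
        closed form, and the Monte Carlo estimate must sit within three
        binomial standard errors of it."""
        pred = analytic_predictor(toy_net)
        geom = StenosisGeometry(Dn=4.6, SR=0.8, Ls=20.0)
        r0 = geom.rv(0.0)
        # threshold total flow where the increase reaches 100%: the post/pre
        # ratio is 1 + r0/PR*, PR* = 60*MAP/q - r0  =>  q* = 30*MAP/r0
        q_star = 30.0 * 90.0 / r0
        total = q_star / 1.05     # place the threshold at 1.05 * total
        p_true = (1.16 - 1.05) / 0.32
        rec = self._toy_record(toy_net, pred, total=total,
                               stenosis={"left": geom})
        res = run_uq(pred, toy_net, rec, seed=1, increment=4000,
                     max_samples=8000, tol_flow=1e-4, tol_map=0.05)
        se = np.sqrt(p_true * (1 - p_true) / res.n_mc)
        assert res.p_hyperperfusion[0] == pytest.approx(p_true, abs=3 * se)

    def test_estimates_scatter_within_binomial_error(self, toy_net):
        pred = analytic_predictor(toy_net)
        geom = StenosisGeometry(Dn=4.6, SR=0.8, Ls=20.0)
        total = 30.0 * 90.0 / geom.rv(0.0) / 1.05
        p_true = (1.16 - 1.05) / 0.32
        rec = self._toy_record(toy_net, pred, total=total,
                               stenosis={"left": geom})
        for seed in (11, 12, 13):
            res = run_uq(pred, toy_net, rec, seed=seed, increment=2000,
                         max_samples=2000, tol_flow=1e-4, tol_map=0.05)
            se = np.sqrt(p_true * (1 - p_true) / res.n_mc)
            assert abs(res.p_hyperperfusion[0] - p_true) < 3 * se

    def test_reproducible_under_seed(self, toy_net):
        pred = analytic_predictor(toy_net)
        rec = self._toy_record(toy_net, pred)
        a = run_uq(pred, toy_net, rec, seed=7, increment=500, max_samples=1000)
        b = run_uq(pred, toy_net, rec, seed=7, increment=500, max_samples=1000)
        assert np.array_equal(a.samples, b.samples)
        assert a.n_mc == b.n_mc

    def test_flow_increase_positive_when_resistance_removed(self, toy_net):
        """Removing a strictly positive stenosis resistance while holding
        the calibrated loads fixed must increase the outlet flow."""
        pred = analytic_predictor(toy_net)
        rec = self._toy_record(toy_net, pred)
        res = run_uq(pred, toy_net, rec, seed=3, increment=500,
                     max_samples=1000)
        assert np.all(res.samples > 0.0)

    def test_through_the_trained_surrogate(self, toy_net, toy_surrogate):
        """The full loop (sample, calibrate, stent, predict) runs through a
        trained surrogate and yields a positive median flow increase."""
        pred = lambda x: toy_surrogate.predict(x)[0]
        geom = StenosisGeometry(Dn=4.6, SR=0.6, Ls=15.0)
        rec = PatientRecord(
            diameters={1: 4.6, 2: 4.6, 3: 3.2, 4: 3.2}, pixel_size=0.3,
            stenosis_side="left", stenosis={"left": geom},
            spect_flows=np.array([270.0]), total_inflow=270.0,
            inflow_modality="PC-MRI", map_mmhg=92.0)
        # pipeline-mechanics check: the small fixture surrogate needs
        # looser calibration tolerances than a production model
        res = run_uq(pred, toy_net, rec, seed=5, increment=1000,
                     max_samples=2000, tol_flow=0.05, tol_map=5.0)
        assert res.n_mc >= 1000
        assert np.median(res.samples) > 0.0
        assert res.interval[0, 0] <= res.mode[0] <= res.interval[0, 1]
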