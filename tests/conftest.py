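"""Shared fixtures: toy network, simulator predictor, a small generated
dataset and a surrogate trained on it (session-scoped; the expensive
periodic solves run once)."""

import numpy as np
import pytest

import willisflow as wf
from willisflow.solver import SolverSettings, simulate_output_vector
from willisflow.design import generate_dataset, split_dataset
from willisflow.surrogate import Hyperparameters, build_model, train
from willisflow.uq import PatientRecord, StenosisGeometry


TOY_DX = 10.0   # mm; toy-network grid used throughout the suite


@pytest.fixture(scope="session")
def toy_net():
    return wf.build_toy_network()


@pytest.fixture(scope="session")
def toy_settings():
    return SolverSettings(target_dx=TOY_DX)


@pytest.fixture(scope="session")
def sim_predictor(toy_net, toy_settings):
    return lambda x: simulate_output_vector(x, toy_net, toy_settings)


@pytest.fixture(scope="session")
def toy_baseline(toy_net, toy_settings):
    return wf.run_to_periodic(toy_net, toy_settings)


@pytest.fixture(scope="session")
def toy_dataset(toy_net, sim_predictor):
    rng = np.random.default_rng(11)
    return generate_dataset(toy_net, 60, sim_predictor, rng,
                            metadata={"seed": 11})


@pytest.fixture(scope="session")
def toy_splits(toy_dataset):
    return split_dataset(toy_dataset, seed=1)


@pytest.fixture(scope="session")
def toy_surrogate(toy_net, toy_splits):
    tr, va, _ = toy_splits
    lo = np.array([s.lower for s in toy_net.input_manifest])
    hi = np.array([s.upper for s in toy_net.input_manifest])
    model = build_model(Hyperparameters(3, 64, 100, 10 ** -2.5),
                        toy_net.n_inputs, toy_net.n_outputs, seed=2)
    model, report = train(model, tr.X, tr.Y, va.X, va.Y, seed=2,
                          max_epochs=800, x_lower=lo, x_upper=hi)
    model.training_meta["val_r2"] = report.best_val_r2
    return model


def output_indices(net):
    """(CoW outlet flow indices, MAP index) in the output manifest."""
    q_idx = [i for i, s in enumerate(net.output_manifest)
             if s.kind == "qbar" and s.target in net.cow_outlet_ids]
    map_idx = next(i for i, s in enumerate(net.output_manifest)
                   if s.kind == "map")
    return q_idx, map_idx


def make_truth_record(net, predictor, geom=None, pixel_size=0.35, **kwargs):
    """Synthetic patient record whose measured flows/MAP come from a
    simulator run at the measured geometry (so calibration targets are
    attainable by construction)."""
    geom = geom or StenosisGeometry(Dn=4.6, SR=0.6, Ls=15.0)
    x = wf.extract_input_vector(net)
    diameters = {}
    for i, s in enumerate(net.input_manifest):
        if s.kind == "diameter":
            diameters[s.target] = x[i]
        elif s.kind == "sten_rv" and s.side == "left":
            x[i] = geom.rv()
        elif s.kind == "sten_dn" and s.side == "left":
            x[i] = geom.Dn
        elif s.kind == "sten_sr" and s.side == "left":
            x[i] = geom.SR
        elif s.kind == "sten_kt" and s.side == "left":
            x[i] = 1.85
    y = predictor(x)
    q_idx, map_idx = output_indices(net)
    defaults = dict(
        diameters=diameters, pixel_size=pixel_size, stenosis_side="left",
        stenosis={"left": geom}, spect_flows=np.asarray(y)[q_idx].copy(),
        total_inflow=float(np.asarray(y)[q_idx].sum()),
        inflow_modality="PC-MRI", map_mmhg=float(np.asarray(y)[map_idx]))
    defaults.update(kwargs)
    return PatientRecord(**defaults)
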