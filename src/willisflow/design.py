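"""Input-space sampling and learning-dataset assembly.

Input vectors are drawn uniformly and independently within published
physiological ranges (per-artery diameter/length intervals, outlet
peripheral resistances, total-PR scaling, age, and stenosis parameters),
under four scenarios: intact, left ICA stenosis, right ICA stenosis, or
bilateral stenosis.  The viscous resistance of a sampled stenosis is capped
by a geometry-derived upper bound that grows with the stenosis ratio.
Samples whose simulated outputs are unphysical (negative mean pressure,
reversed terminal flow, or failure to reach a periodic state) are rejected
and redrawn.
"""

from __future__ import annotations

import math
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import units as U
from .network import VascularNetwork
from .solver import SolverError

SCENARIOS = ("intact", "left_stenosis", "right_stenosis", "bilateral")

# Per-artery sampling ranges: diameter (mm), length (mm) and, for the six
# circle-of-Willis outlets, peripheral resistance (mmHg.s/mL).  Open-at-zero
# PR intervals are implemented as [1, upper].
DIAMETER_RANGES = {
    "R. com. carotid": (3.9, 11.6), "L. com. carotid": (3.9, 11.6),
    "R. int. carotid I": (2.3, 6.8), "L. int. carotid I": (2.3, 6.8),
    "R. int. carotid II": (1.9, 6.0), "L. int. carotid II": (1.9, 6.0),
    "R. vertebral": (1.4, 4.9), "L. vertebral": (1.4, 4.9),
    "Basilar": (1.6, 4.9),
    "R. ant. cerebral I": (0.1, 3.6), "L. ant. cerebral I": (0.1, 3.6),
    "R. ant. cerebral II": (1.2, 3.6), "L. ant. cerebral II": (1.2, 3.6),
    "R. mid. cerebral": (1.4, 4.3), "L. mid. cerebral": (1.4, 4.3),
    "R. post. cerebral I": (0.1, 3.2), "L. post. cerebral I": (0.1, 3.2),
    "R. post. cerebral II": (1.1, 3.2), "L. post. cerebral II": (1.1, 3.2),
    "Ant. comm.": (0.1, 2.6),
    "R. post. comm.": (0.1, 2.7), "L. post. comm.": (0.1, 2.7),
}
LENGTH_RANGES = {
    "R. com. carotid": (78.0, 222.0), "L. com. carotid": (109.0, 252.0),
    "R. int. carotid I": (120.0, 195.0), "L. int. carotid I": (120.0, 195.0),
    "R. int. carotid II": (2.0, 12.0), "L. int. carotid II": (2.0, 12.0),
    "R. vertebral": (113.0, 276.0), "L. vertebral": (113.0, 276.0),
    "Basilar": (15.0, 36.0),
    "R. ant. cerebral I": (7.0, 31.0), "L. ant. cerebral I": (7.0, 31.0),
    "R. ant. cerebral II": (6.0, 45.0), "L. ant. cerebral II": (6.0, 45.0),
    "R. mid. cerebral": (10.0, 51.0), "L. mid. cerebral": (10.0, 51.0),
    "R. post. cerebral I": (2.0, 23.0), "L. post. cerebral I": (2.0, 23.0),
    "R. post. cerebral II": (2.0, 54.0), "L. post. cerebral II": (2.0, 54.0),
    "Ant. comm.": (2.0, 7.0),
    "R. post. comm.": (4.0, 27.0), "L. post. comm.": (4.0, 27.0),
}
PR_RANGES = {
    "R. ant. cerebral II": (1.0, 200.0), "L. ant. cerebral II": (1.0, 200.0),
    "R. mid. cerebral": (1.0, 100.0), "L. mid. cerebral": (1.0, 100.0),
    "R. post. cerebral II": (1.0, 250.0), "L. post. cerebral II": (1.0, 250.0),
}

RV_CAP = 500.0         # mmHg.s/mL
LS_MAX_MM = 40.0
DN_MIN_MM = 2.9


def rv_upper_bound(SR: float, mu: float = U.BLOOD_VISCOSITY) -> float:
    """Upper bound on the stenosis viscous resistance as a function of the
    stenosis ratio: 128*mu*Ls_max / (pi*Dn_min^4*(1-SR)^4), capped at
    500 mmHg.s/mL."""
    if not 0.0 <= SR < 1.0:
        raise ValueError("SR must be in [0, 1)")
    dn = DN_MIN_MM * U.MM_M
    ls = LS_MAX_MM * U.MM_M
    rv = 128.0 * mu * ls / (math.pi * dn ** 4 * (1.0 - SR) ** 4) / U.RES_SI
    return min(rv, RV_CAP)


def _stenosed_sides(scenario: str) -> set:
    return {"intact": set(), "left_stenosis": {"left"},
            "right_stenosis": {"right"},
            "bilateral": {"left", "right"}}[scenario]


def sample_input_vector(net: VascularNetwork, scenario: str,
                        rng: np.random.Generator) -> np.ndarray:
    """Draw one input vector uniformly within the manifest bounds.

    Stenosis slots for sides the scenario leaves intact are set to
    Rv = SR = Kt = 0 with Dn equal to the sampled host-ICA diameter; for
    stenosed sides Rv is drawn within [0, rv_upper_bound(SR)].
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    stenosed = _stenosed_sides(scenario)
    slots = net.input_manifest
    x = np.empty(len(slots))
    host_diam_idx = {}
    for i, s in enumerate(slots):
        if s.kind == "diameter":
            host_diam_idx[s.target] = i
    sr_by_side = {}
    for i, s in enumerate(slots):
        if s.kind.startswith("sten_"):
            if s.side not in stenosed:
                if s.kind == "sten_dn":
                    x[i] = x[host_diam_idx[s.target]]
                else:
                    x[i] = 0.0
            elif s.kind == "sten_sr":
                x[i] = rng.uniform(0.0, 0.99)
                sr_by_side[s.side] = x[i]
            elif s.kind == "sten_rv":
                x[i] = np.nan   # filled below, needs SR
            else:
                x[i] = rng.uniform(s.lower, s.upper)
        else:
            x[i] = rng.uniform(s.lower, s.upper)
    for i, s in enumerate(slots):
        if s.kind == "sten_rv" and np.isnan(x[i]):
            x[i] = rng.uniform(0.0, rv_upper_bound(sr_by_side[s.side]))
    return x


@dataclass
class Dataset:
    """Paired input/output tables with scenario labels and provenance."""
    inputs: pd.DataFrame
    outputs: pd.DataFrame
    scenarios: list
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.inputs) != len(self.outputs) or \
                len(self.inputs) != len(self.scenarios):
            raise ValueError("inputs, outputs and scenarios must align")

    def __len__(self):
        return len(self.inputs)

    @property
    def X(self) -> np.ndarray:
        return self.inputs.to_numpy(dtype=float)

    @property
    def Y(self) -> np.ndarray:
        return self.outputs.to_numpy(dtype=float)

    def subset(self, idx) -> "Dataset":
        idx = np.asarray(idx)
        return Dataset(self.inputs.iloc[idx].reset_index(drop=True),
                       self.outputs.iloc[idx].reset_index(drop=True),
                       [self.scenarios[i] for i in idx], dict(self.metadata))

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        try:
            self.inputs.to_parquet(d / "inputs.parquet")
            self.outputs.to_parquet(d / "outputs.parquet")
        except ImportError:
            self.inputs.to_csv(d / "inputs.csv", index=False)
            self.outputs.to_csv(d / "outputs.csv", index=False)
        meta = dict(self.metadata)
        meta["scenarios"] = self.scenarios
        (d / "meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, directory) -> "Dataset":
        d = Path(directory)
        if (d / "inputs.parquet").exists():
            xi = pd.read_parquet(d / "inputs.parquet")
            yo = pd.read_parquet(d / "outputs.parquet")
        else:
            xi = pd.read_csv(d / "inputs.csv")
            yo = pd.read_csv(d / "outputs.csv")
        meta = json.loads((d / "meta.json").read_text())
        scen = meta.pop("scenarios")
        return cls(xi, yo, scen, meta)


class GenerationError(RuntimeError):
    pass


def is_physiological(y: np.ndarray, net: VascularNetwork) -> bool:
    """Acceptance rule for simulated outputs: finite, no negative mean
    pressure, and no reversed cycle-averaged flow in outlet-bearing
    (terminal) arteries."""
    if not np.all(np.isfinite(y)):
        return False
    outlet_sids = {o.segment_id for o in net.outlets}
    for i, slot in enumerate(net.output_manifest):
        if slot.kind in ("pbar", "map") and y[i] < 0:
            return False
        if slot.kind == "qbar" and slot.target in outlet_sids and y[i] < 0:
            return False
    return True


def generate_dataset(net: VascularNetwork, n_per_scenario: int,
                     predictor, rng: np.random.Generator,
                     scenarios=None, metadata=None,
                     max_reject_ratio: float = 9.0) -> Dataset:
    """Sample inputs per scenario, evaluate ``predictor`` (an x -> y map,
    normally the 1D-0D simulator), reject unphysical or non-converged
    samples and redraw until ``n_per_scenario`` accepted rows exist per
    scenario."""
    if n_per_scenario < 1:
        raise ValueError("n_per_scenario must be >= 1")
    if scenarios is None:
        sides = set(net.stenosis_hosts)
        scenarios = [s for s in SCENARIOS if _stenosed_sides(s) <= sides]
    rows_x, rows_y, labels = [], [], []
    rejected = 0
    for scen in scenarios:
        accepted = 0
        while accepted < n_per_scenario:
            if rejected > max_reject_ratio * (len(rows_x) + 1) + 20:
                raise GenerationError(
                    f"sustained rejection rate above "
                    f"{max_reject_ratio / (max_reject_ratio + 1):.0%}; "
                    "check the network configuration")
            x = sample_input_vector(net, scen, rng)
            try:
                y = predictor(x)
            except SolverError:
                rejected += 1
                continue
            if not is_physiological(y, net):
                rejected += 1
                continue
            rows_x.append(x)
            rows_y.append(y)
            labels.append(scen)
            accepted += 1
    meta = dict(metadata or {})
    meta["rejected"] = rejected
    xi = pd.DataFrame(np.array(rows_x),
                      columns=[s.name for s in net.input_manifest])
    yo = pd.DataFrame(np.array(rows_y),
                      columns=[s.name for s in net.output_manifest])
    return Dataset(xi, yo, labels, meta)


def split_dataset(ds: Dataset, seed: int):
    """Deterministic stratified 6:2:2 split into (train, validation, test);
    the remainder of each stratum goes to train."""
    if len(ds) < 10:
        raise ValueError("need at least 10 rows to split 6:2:2")
    rng = np.random.default_rng(seed)
    scen = np.asarray(ds.scenarios)
    tr, va, te = [], [], []
    for s in sorted(set(ds.scenarios)):
        idx = np.flatnonzero(scen == s)
        rng.shuffle(idx)
        n = len(idx)
        n_va = n // 5
        n_te = n // 5
        n_tr = n - n_va - n_te
        tr.extend(idx[:n_tr])
        va.extend(idx[n_tr:n_tr + n_va])
        te.extend(idx[n_tr + n_va:])
    return ds.subset(sorted(tr)), ds.subset(sorted(va)), ds.subset(sorted(te))
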