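"""Monte Carlo uncertainty quantification of the postoperative flow increase.

A synthetic patient record supplies measured arterial diameters, stenosis
geometry, per-outlet perfusion flows, total CoW inflow and MAP, each with a
modality-derived uniform uncertainty interval (segmentation: +/- 2 pixels;
PC-MRI: +/-16%; ultrasound: +/-35%; perfusion outflows: +/-16%; possibly
absent anterior communicating artery: 0.1-2.6 mm).  Each Monte Carlo
realization draws the uncertain inputs and flow targets, calibrates the
peripheral resistances preoperatively, virtually dilates the stenosis
(Rv = SR = Kt = 0, Dn = D_ICA) with the adjusted PRs held fixed, predicts
the postoperative state and records the percentage flow increase at the
CoW outlets.  The sample count grows in increments until the mean and
variance stabilize.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .network import VascularNetwork, extract_input_vector
from .solver import viscous_resistance
from .calibration import (FlowTargets, target_flows_from_measurements,
                          calibrate)

MODALITY_UNCERTAINTY = {"PC-MRI": 0.16, "ultrasound": 0.35, "exact": 0.0}
SPECT_UNCERTAINTY = 0.16
ACOA_INTERVAL = (0.1, 2.6)   # mm


class UQError(RuntimeError):
    pass


@dataclass
class StenosisGeometry:
    """Measured stenosis geometry: distal reference diameter Dn, stenosis
    ratio SR (so the throat is Ds = Dn*(1-SR)) and length Ls, all mm."""
    Dn: float
    SR: float
    Ls: float = 20.0

    def rv(self, delta_mm: float = 0.0) -> float:
        """Viscous resistance (mmHg.s/mL) of a parabolic throat profile
        after shifting every diameter by ``delta_mm``."""
        dn = self.Dn + delta_mm
        ds = max(self.Dn * (1.0 - self.SR) + delta_mm, 0.05)
        x = np.linspace(0.0, self.Ls, 201)
        d = ds + (dn - ds) * (2.0 * x / self.Ls - 1.0) ** 2
        return viscous_resistance(x, d)


@dataclass
class PatientRecord:
    """Synthetic analogue of the clinical inputs used for calibration."""
    diameters: dict                      # segment id -> measured mm
    pixel_size: float                    # mm per pixel
    stenosis_side: str                   # "left" / "right" / "both"
    stenosis: dict                       # side -> StenosisGeometry
    spect_flows: np.ndarray              # mL/min, CoW-outlet manifest order
    total_inflow: float                  # mL/min
    inflow_modality: str                 # "PC-MRI" | "ultrasound"
    map_mmhg: float
    age: float = 40.0
    lengths: dict = field(default_factory=dict)
    acoa_possibly_absent: bool = False
    kt_range: tuple = (1.0, 2.699)
    spect_uncertainty: float = SPECT_UNCERTAINTY

    def validate(self):
        if self.pixel_size < 0:
            raise ValueError("pixel_size must be >= 0")
        if self.stenosis_side not in ("left", "right", "both"):
            raise ValueError("stenosis_side must be left/right/both")
        if self.inflow_modality not in MODALITY_UNCERTAINTY:
            raise ValueError(f"unknown modality {self.inflow_modality!r}")

    @property
    def stenosed_sides(self):
        return ("left", "right") if self.stenosis_side == "both" \
            else (self.stenosis_side,)


@dataclass
class UncertainParam:
    name: str
    kind: str        # "slot" | "sten_delta" | "total_flow" | "spect_flow"
    index: int       # manifest slot index / side index / outlet position
    lower: float
    upper: float


@dataclass
class UncertaintyModel:
    """Baseline input vector plus the uniform intervals of every uncertain
    quantity; maps drawn parameter values to (input vector, flow targets)."""
    net: VascularNetwork
    record: PatientRecord
    x0: np.ndarray
    params: list

    @property
    def bounds(self) -> np.ndarray:
        return np.array([[p.lower, p.upper] for p in self.params])

    def realize(self, values: np.ndarray):
        """Build (x, FlowTargets) from one draw of the uncertain params."""
        rec = self.record
        x = self.x0.copy()
        spect = rec.spect_flows.astype(float).copy()
        total = rec.total_inflow
        deltas = {}
        for p, v in zip(self.params, values):
            if p.kind == "slot":
                x[p.index] = v
            elif p.kind == "sten_delta":
                deltas[p.index] = v
            elif p.kind == "total_flow":
                total = v
            elif p.kind == "spect_flow":
                spect[p.index] = v
        slots = self.net.input_manifest
        for si, side in enumerate(rec.stenosed_sides):
            delta = deltas.get(si, 0.0)
            geom = rec.stenosis[side]
            dn = np.clip(geom.Dn + delta, 2.9, 7.0)
            sr = np.clip(1.0 - max(geom.Dn * (1.0 - geom.SR) + delta, 0.05)
                         / (geom.Dn + delta), 0.0, 0.99)
            rv = np.clip(geom.rv(delta), 0.0, 500.0)
            for i, s in enumerate(slots):
                if s.side == side:
                    if s.kind == "sten_rv":
                        x[i] = rv
                    elif s.kind == "sten_dn":
                        x[i] = dn
                    elif s.kind == "sten_sr":
                        x[i] = sr
        targets = target_flows_from_measurements(spect, total, rec.map_mmhg)
        return x, targets

    def sample_case(self, rng: np.random.Generator):
        """One uniform draw of every uncertain parameter."""
        if self.params:
            b = self.bounds
            vals = rng.uniform(b[:, 0], b[:, 1])
        else:
            vals = np.empty(0)
        return self.realize(vals)


def build_uncertainty_model(record: PatientRecord,
                            net: VascularNetwork) -> UncertaintyModel:
    """Derive the uniform uncertainty intervals from a patient record.

    Diameter intervals are measured +/- 2 pixels intersected with the
    manifest bounds; the stenosis geometry carries a single shared diameter
    offset in [-2 px, +2 px] from which {Rv, SR, Dn} are recomputed; flow
    intervals follow the measurement modality; a possibly-absent anterior
    communicating artery spans 0.1-2.6 mm regardless of the measured value.
    """
    record.validate()
    x0 = extract_input_vector(net)
    slots = net.input_manifest
    params = []
    px2 = 2.0 * record.pixel_size
    acoa_ids = {s.id for s in net.segments if s.name == "Ant. comm."}
    for i, s in enumerate(slots):
        if s.kind == "diameter" and s.target in record.diameters:
            d = record.diameters[s.target]
            x0[i] = d
            if record.acoa_possibly_absent and s.target in acoa_ids:
                lo, hi = ACOA_INTERVAL
            else:
                lo = max(d - px2, s.lower)
                hi = min(d + px2, s.upper)
            if lo > hi:
                raise UQError(f"empty uncertainty interval for slot {s.name}")
            if hi > lo:
                params.append(UncertainParam(s.name, "slot", i, lo, hi))
        elif s.kind == "length" and s.target in record.lengths:
            x0[i] = record.lengths[s.target]
        elif s.kind == "age":
            x0[i] = record.age
        elif s.kind == "sten_kt" and s.side in record.stenosed_sides:
            lo, hi = record.kt_range
            x0[i] = 0.5 * (lo + hi)
            if hi > lo:
                params.append(UncertainParam(s.name, "slot", i, lo, hi))
        elif s.kind.startswith("sten_") and s.side not in record.stenosed_sides:
            x0[i] = 0.0
            if s.kind == "sten_dn":
                host_d = next((record.diameters.get(sl.target,
                                                    net.segment(sl.target).diameter)
                               for sl in slots if sl.kind == "diameter"
                               and sl.target == s.target), 4.0)
                x0[i] = host_d
    for si, side in enumerate(record.stenosed_sides):
        if px2 > 0:
            params.append(UncertainParam(f"stenosis geometry ({side})",
                                         "sten_delta", si, -px2, px2))
    u = MODALITY_UNCERTAINTY[record.inflow_modality]
    if u > 0:
        params.append(UncertainParam(f"total inflow ({record.inflow_modality})",
                                     "total_flow", 0,
                                     record.total_inflow * (1 - u),
                                     record.total_inflow * (1 + u)))
    us = record.spect_uncertainty
    for k, q in enumerate(record.spect_flows):
        if us > 0:
            params.append(UncertainParam(f"outlet flow {k}", "spect_flow", k,
                                         q * (1 - us), q * (1 + us)))
    model = UncertaintyModel(net, record, x0, params)
    # bake the measured (zero-offset) stenosis geometry into the baseline
    neutral = []
    for p in params:
        if p.kind == "slot":
            neutral.append(np.clip(x0[p.index], p.lower, p.upper))
        elif p.kind == "sten_delta":
            neutral.append(0.0)
        elif p.kind == "total_flow":
            neutral.append(record.total_inflow)
        else:
            neutral.append(record.spect_flows[p.index])
    model.x0, _ = model.realize(np.array(neutral))
    return model


def virtual_stenting(x: np.ndarray, net: VascularNetwork,
                     side: str) -> np.ndarray:
    """Complete dilation of the stenosis on ``side``: Rv = SR = Kt = 0 and
    Dn set to the (sampled) host-ICA diameter; all other slots unchanged."""
    x = np.asarray(x, float).copy()
    slots = net.input_manifest
    host = net.stenosis_hosts[side]
    d_ica = None
    for i, s in enumerate(slots):
        if s.kind == "diameter" and s.target == host:
            d_ica = x[i]
    if d_ica is None:
        d_ica = net.segment(host).diameter
    for i, s in enumerate(slots):
        if s.side == side and s.kind.startswith("sten_"):
            x[i] = d_ica if s.kind == "sten_dn" else 0.0
    return x


def delta_q(pre: np.ndarray, post: np.ndarray,
            net: VascularNetwork) -> np.ndarray:
    """Percentage increase of the cycle-averaged CoW outlet flows,
    (Q_post - Q_pre)/Q_pre * 100."""
    q_idx = [i for i, s in enumerate(net.output_manifest)
             if s.kind == "qbar" and s.target in net.cow_outlet_ids]
    pre_q = np.asarray(pre, float)[q_idx]
    post_q = np.asarray(post, float)[q_idx]
    if np.any(pre_q <= 0):
        raise ValueError("non-positive preoperative outlet flow")
    return (post_q - pre_q) / pre_q * 100.0


def _fd_mode(samples: np.ndarray) -> float:
    """Densest-bin center with Freedman-Diaconis bin width."""
    s = np.sort(samples)
    n = len(s)
    iqr = s[int(0.75 * (n - 1))] - s[int(0.25 * (n - 1))]
    if iqr <= 0:
        return float(np.median(s))
    width = 2.0 * iqr * n ** (-1.0 / 3.0)
    nbins = max(int(np.ceil((s[-1] - s[0]) / width)), 1)
    hist, edges = np.histogram(s, bins=min(nbins, 10_000))
    k = int(np.argmax(hist))
    return float(0.5 * (edges[k] + edges[k + 1]))


@dataclass
class UQResult:
    samples: np.ndarray            # (N_MC, n_outlets) percent
    outlet_names: list
    n_mc: int
    rejected: int
    mean: np.ndarray
    variance: np.ndarray
    mode: np.ndarray
    interval: np.ndarray           # (n_outlets, 2) min-max
    p_hyperperfusion: np.ndarray   # P(dQ > 100%) per outlet
    convergence_trace: list = field(default_factory=list)

    def summary(self) -> dict:
        return {name: {"mean": float(self.mean[i]),
                       "variance": float(self.variance[i]),
                       "mode": float(self.mode[i]),
                       "min": float(self.interval[i, 0]),
                       "max": float(self.interval[i, 1]),
                       "p_ch": float(self.p_hyperperfusion[i])}
                for i, name in enumerate(self.outlet_names)}


def uq_single_case(predictor, net, model: UncertaintyModel,
                   values: np.ndarray, **cal_kwargs):
    """One realization: calibrate preoperatively, virtually stent, predict
    postoperatively.  Returns the per-outlet percentage increases, or None
    if the preoperative calibration does not converge."""
    x, targets = model.realize(values)
    res = calibrate(predictor, net, x, targets, **cal_kwargs)
    if not res.converged:
        return None
    pre = res.outputs
    dq = None
    x_post = res.x
    for side in model.record.stenosed_sides:
        x_post = virtual_stenting(x_post, net, side)
    post = np.asarray(predictor(x_post), float)
    return delta_q(pre, post, net)


def run_uq(predictor, net: VascularNetwork, record: PatientRecord,
           seed: int, increment: int = 10_000, stat_tol: float = 0.001,
           max_samples: int = 100_000, **cal_kwargs) -> UQResult:
    """Grow the Monte Carlo sample in increments until the mean and the
    variance of the flow increase change by less than ``stat_tol``
    (relative) between increments."""
    model = build_uncertainty_model(record, net)
    rng = np.random.default_rng(seed)
    rows = []
    rejected = 0
    trace = []
    prev_mean = prev_var = None
    while True:
        target_n = len(rows) + increment
        while len(rows) < target_n:
            if self_reject_guard(rejected, len(rows)):
                raise UQError("calibration rejection rate above 95%")
            if model.params:
                b = model.bounds
                vals = rng.uniform(b[:, 0], b[:, 1])
            else:
                vals = np.empty(0)
            dq = uq_single_case(predictor, net, model, vals, **cal_kwargs)
            if dq is None:
                rejected += 1
                continue
            rows.append(dq)
        arr = np.array(rows)
        mean = arr.mean(axis=0)
        var = arr.var(axis=0)
        trace.append((len(rows), mean.copy(), var.copy()))
        if prev_mean is not None:
            dm = np.max(np.abs(mean - prev_mean)
                        / np.maximum(np.abs(prev_mean), 1.0))
            dv = np.max(np.abs(var - prev_var)
                        / np.maximum(np.abs(prev_var), 1.0))
            if (dm < stat_tol and dv < stat_tol) or len(rows) >= max_samples:
                break
        elif len(rows) >= max_samples or not model.params:
            break
        prev_mean, prev_var = mean, var
    if rejected > len(rows):
        warnings.warn(f"UQ rejection rate {rejected}/{rejected + len(rows)} "
                      "exceeds 50%", stacklevel=2)
    names = [net.segment(s.target).name
             for s in net.output_manifest
             if s.kind == "qbar" and s.target in net.cow_outlet_ids]
    return UQResult(
        samples=arr, outlet_names=names, n_mc=len(rows), rejected=rejected,
        mean=mean, variance=var,
        mode=np.array([_fd_mode(arr[:, j]) for j in range(arr.shape[1])]),
        interval=np.column_stack([arr.min(axis=0), arr.max(axis=0)]),
        p_hyperperfusion=(arr > 100.0).mean(axis=0),
        convergence_trace=trace)


def self_reject_guard(rejected: int, accepted: int) -> bool:
    return rejected > 40 and rejected > 19 * max(accepted, 1)
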