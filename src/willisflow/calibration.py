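"""Patient-specific adjustment of peripheral resistances.

Measured per-outlet flows (perfusion-derived) are first rescaled so they
sum to the measured total inflow of the circle of Willis while preserving
the flow distribution ratios; the CoW outlet PRs are then tuned by damped
multiplicative fixed-point updates, interleaved with a secant update of the
total-PR scaling factor against the measured mean arterial pressure, until
the predicted outlet flows and MAP match the targets.  The predictor is
any x -> y map honouring the network manifest (the 1D-0D simulator or a
trained surrogate), so both backends share this code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import VascularNetwork


@dataclass
class FlowTargets:
    """Per-outlet flow targets (mL/min) and the MAP target (mmHg)."""
    spect_flows: np.ndarray
    total_flow: float
    targets: np.ndarray
    map_target: float


def target_flows_from_measurements(spect_flows, total_inflow: float,
                                   map_mmhg: float) -> FlowTargets:
    """Rescale measured per-outlet flows to the measured total CoW inflow
    with constant distribution ratios:
    Q_i_target = Q_total * Q_i_SPECT / sum_j Q_j_SPECT."""
    spect = np.asarray(spect_flows, float)
    if np.any(spect <= 0) or total_inflow <= 0 or map_mmhg <= 0:
        raise ValueError("measured flows and MAP must be positive")
    targets = total_inflow * spect / spect.sum()
    return FlowTargets(spect, float(total_inflow), targets, float(map_mmhg))


@dataclass
class CalibrationResult:
    x: np.ndarray
    converged: bool
    iterations: int
    max_flow_residual: float      # max_i |Q_i/Q_i_target - 1|
    map_residual: float           # |MAP - MAP_target|, mmHg
    outputs: np.ndarray = field(default=None, repr=False)


def _calibration_indices(net: VascularNetwork):
    pr_idx = [i for i, s in enumerate(net.input_manifest) if s.kind == "pr_cow"]
    scale_idx = [i for i, s in enumerate(net.input_manifest)
                 if s.kind == "pr_scale"]
    q_idx = []
    for i_pr in pr_idx:
        sid = net.input_manifest[i_pr].target
        q_idx.append(next(i for i, o in enumerate(net.output_manifest)
                          if o.kind == "qbar" and o.target == sid))
    map_idx = next(i for i, o in enumerate(net.output_manifest)
                   if o.kind == "map")
    return pr_idx, scale_idx[0], q_idx, map_idx


def calibrate(predictor, net: VascularNetwork, x0: np.ndarray,
              targets: FlowTargets, tol_flow: float = 0.005,
              tol_map: float = 1.0, max_iter: int = 200,
              damping: float = 0.8, stall_patience: int = 25) -> CalibrationResult:
    """Adjust the CoW outlet PR slots and the total-PR scaling factor of
    ``x0`` until predicted outlet flows and MAP match ``targets``.

    PR updates are damped multiplicative, PR_i <- PR_i * (Q_i/Q_i_target)^damping
    (a higher-than-target flow means the load is too small), clamped to the
    manifest bounds; the scaling factor follows a secant iteration on
    MAP(scale) - MAP_target.  Non-convergence within ``max_iter`` returns
    ``converged=False`` rather than raising.
    """
    pr_idx, s_idx, q_idx, map_idx = _calibration_indices(net)
    if len(pr_idx) != len(targets.targets):
        raise ValueError(f"targets have {len(targets.targets)} outlets, "
                         f"manifest has {len(pr_idx)} PR slots")
    x = np.asarray(x0, float).copy()
    slots = net.input_manifest
    prev_s = None
    prev_g = None
    y = None
    best_score = np.inf
    stalled = 0
    it = 0
    for it in range(1, max_iter + 1):
        y = np.asarray(predictor(x), float)
        q = y[q_idx]
        map_pred = y[map_idx]
        flow_res = float(np.max(np.abs(q / targets.targets - 1.0)))
        map_res = float(abs(map_pred - targets.map_target))
        score = max(flow_res / tol_flow, map_res / tol_map)
        if score < 0.95 * best_score:
            best_score = score
            stalled = 0
        else:
            stalled += 1
            if stalled > stall_patience:
                break   # no longer improving; report non-convergence
        if flow_res <= tol_flow and map_res <= tol_map:
            in_bounds = all(
                slots[i].lower - 1e-9 <= x[i] <= slots[i].upper + 1e-9
                for i in pr_idx + [s_idx])
            return CalibrationResult(x, in_bounds, it, flow_res, map_res, y)
        if np.any(q <= 0):
            # reversed predicted outlet flow: fall back to a gentle halving
            ratio = np.where(q > 0, q / targets.targets, 0.5)
        else:
            ratio = q / targets.targets
        for k, i in enumerate(pr_idx):
            x[i] = float(np.clip(x[i] * ratio[k] ** damping,
                                 slots[i].lower, slots[i].upper))
        g = map_pred - targets.map_target
        s = x[s_idx]
        if prev_s is None or abs(g - prev_g) < 1e-12:
            s_new = s * (map_pred / targets.map_target) ** damping
        else:
            s_new = s - g * (s - prev_s) / (g - prev_g)
        prev_s, prev_g = s, g
        x[s_idx] = float(np.clip(s_new, slots[s_idx].lower,
                                 slots[s_idx].upper))
    q = y[q_idx]
    return CalibrationResult(
        x, False, max_iter,
        float(np.max(np.abs(q / targets.targets - 1.0))),
        float(abs(y[map_idx] - targets.map_target)), y)
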