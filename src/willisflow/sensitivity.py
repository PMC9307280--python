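"""Variance-based global sensitivity analysis (Sobol indices).

Saltelli's scheme with two quasi-random base matrices A and B and the D
radial matrices AB_i (column i of A replaced by B's) gives N*(D+2) model
evaluations for the first-order and total indices.  Estimators: the
Saltelli-2010 first-order estimator S_i = mean(f_B * (f_ABi - f_A)) / V and
the Jansen total estimator ST_i = mean((f_A - f_ABi)^2) / (2 V).  Percentile
bootstrap over evaluation blocks yields confidence intervals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc


class DegenerateOutputError(ValueError):
    """The model output has (near-)zero variance over the design."""


def saltelli_design(bounds: np.ndarray, N: int, seed: int = 0) -> np.ndarray:
    """Sample matrix of shape (N*(D+2), D) within ``bounds`` (D rows of
    [lower, upper]), ordered [A; B; AB_1; ...; AB_D].  Uses scrambled Sobol
    sequences for A and B; deterministic under ``seed``."""
    bounds = np.atleast_2d(np.asarray(bounds, float))
    D = bounds.shape[0]
    if D == 0:
        raise ValueError("at least one parameter is required")
    if N & (N - 1):
        warnings.warn(f"Saltelli base size N={N} is not a power of 2; "
                      "Sobol sequence balance is degraded", stacklevel=2)
    sob = qmc.Sobol(d=2 * D, scramble=True, rng=np.random.default_rng(seed))
    u = sob.random(N)
    a = u[:, :D]
    b = u[:, D:]
    lo, hi = bounds[:, 0], bounds[:, 1]
    A = lo + a * (hi - lo)
    B = lo + b * (hi - lo)
    blocks = [A, B]
    for i in range(D):
        ab = A.copy()
        ab[:, i] = B[:, i]
        blocks.append(ab)
    return np.vstack(blocks)


@dataclass
class SobolResult:
    first_order: np.ndarray        # S_n
    total: np.ndarray              # S_T,n
    first_ci: np.ndarray = None    # (D, 2) 95% bounds
    total_ci: np.ndarray = None
    N: int = 0
    D: int = 0
    names: list = field(default_factory=list)


def _indices_from_blocks(fA, fB, fAB):
    V = np.var(np.concatenate([fA, fB]), ddof=0)
    if V <= 0:
        raise DegenerateOutputError("zero output variance over the design")
    S = np.array([np.mean(fB * (fAB[i] - fA)) for i in range(len(fAB))]) / V
    ST = np.array([0.5 * np.mean((fA - fAB[i]) ** 2)
                   for i in range(len(fAB))]) / V
    return S, ST


def sobol_indices(y: np.ndarray, D: int, names=None) -> SobolResult:
    """First-order and total Sobol indices from evaluations ``y`` aligned
    with the :func:`saltelli_design` layout."""
    y = np.asarray(y, float)
    if y.ndim != 1 or y.size % (D + 2):
        raise ValueError("evaluations do not match an N*(D+2) design")
    N = y.size // (D + 2)
    fA = y[:N]
    fB = y[N:2 * N]
    fAB = [y[(2 + i) * N:(3 + i) * N] for i in range(D)]
    S, ST = _indices_from_blocks(fA, fB, fAB)
    return SobolResult(S, ST, N=N, D=D, names=list(names or []))


def bootstrap_ci(y: np.ndarray, D: int, B: int = 1000, level: float = 0.95,
                 seed: int = 0) -> SobolResult:
    """Indices plus percentile-bootstrap CIs resampling the N evaluation
    blocks (the same row draw is applied to A, B and every AB_i)."""
    if B < 100:
        raise ValueError("use at least 100 bootstrap resamples")
    y = np.asarray(y, float)
    N = y.size // (D + 2)
    fA = y[:N]
    fB = y[N:2 * N]
    fAB = np.array([y[(2 + i) * N:(3 + i) * N] for i in range(D)])
    S, ST = _indices_from_blocks(fA, fB, list(fAB))
    rng = np.random.default_rng(seed)
    bs = np.empty((B, D))
    bt = np.empty((B, D))
    for k in range(B):
        idx = rng.integers(0, N, size=N)
        try:
            s, t = _indices_from_blocks(fA[idx], fB[idx],
                                        list(fAB[:, idx]))
        except DegenerateOutputError:
            s = t = np.zeros(D)
        bs[k] = s
        bt[k] = t
    alpha = 0.5 * (1.0 - level)
    res = SobolResult(S, ST, N=N, D=D)
    res.first_ci = np.column_stack([np.quantile(bs, alpha, axis=0),
                                    np.quantile(bs, 1 - alpha, axis=0)])
    res.total_ci = np.column_stack([np.quantile(bt, alpha, axis=0),
                                    np.quantile(bt, 1 - alpha, axis=0)])
    return res


def ishigami(x: np.ndarray, a: float = 7.0, b: float = 0.1) -> np.ndarray:
    """Ishigami test function on [-pi, pi]^3 (closed-form Sobol indices)."""
    x = np.atleast_2d(x)
    return (np.sin(x[:, 0]) + a * np.sin(x[:, 1]) ** 2
            + b * x[:, 2] ** 4 * np.sin(x[:, 0]))


def ishigami_analytic(a: float = 7.0, b: float = 0.1) -> dict:
    """Analytic variance decomposition of the Ishigami function."""
    pi = math.pi
    v1 = 0.5 * (1.0 + b * pi ** 4 / 5.0) ** 2
    v2 = a ** 2 / 8.0
    v13 = b ** 2 * pi ** 8 * (1.0 / 18.0 - 1.0 / 50.0)
    V = v1 + v2 + v13
    return {"S1": v1 / V, "S2": v2 / V, "S3": 0.0,
            "ST1": (v1 + v13) / V, "ST2": v2 / V, "ST3": v13 / V, "V": V}


def run_sa(predictor, net, record, N: int, seed: int = 0,
           bootstrap: int = 1000, **cal_kwargs):
    """Sobol SA of the flow increase at the stenosis-side middle cerebral
    artery, propagated through the full UQ pipeline (sample -> calibrate ->
    stent -> percentage increase).  Non-converged calibrations are imputed
    with the nearest previously accepted evaluation (counted and reported).
    Returns (SobolResult, imputed count)."""
    from .uq import build_uncertainty_model, uq_single_case

    model = build_uncertainty_model(record, net)
    if not model.params:
        raise ValueError("record has no uncertain parameters")
    design = saltelli_design(model.bounds, N, seed=seed)
    side = model.record.stenosed_sides[0]
    host = net.stenosis_hosts[side]
    # stenosis-side MCA: same-side name prefix among CoW outlets
    prefix = net.segment(host).name.split(".")[0]
    q_ids = [s.target for s in net.output_manifest
             if s.kind == "qbar" and s.target in net.cow_outlet_ids]
    col = next((k for k, sid in enumerate(q_ids)
                if net.segment(sid).name.startswith(prefix)
                and "mid" in net.segment(sid).name), 0)
    y = np.empty(len(design))
    imputed = 0
    last = None
    backfill = []
    for r, vals in enumerate(design):
        dq = uq_single_case(predictor, net, model, vals, **cal_kwargs)
        if dq is None:
            imputed += 1
            if last is None:
                backfill.append(r)
                y[r] = np.nan
                continue
            y[r] = last
        else:
            y[r] = float(dq[col])
            last = y[r]
    for r in backfill:
        y[r] = last if last is not None else 0.0
    names = [p.name for p in model.params]
    res = bootstrap_ci(y, len(model.params), B=bootstrap, seed=seed)
    res.names = names
    return res, imputed
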