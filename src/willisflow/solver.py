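"""Closed-loop 1D-0D hemodynamics solver.

Integrates the compliant-tube (A, Q) system with the two-step Lax-Wendroff
scheme, couples segments at junctions by conservation of mass and total
pressure (Newton-Raphson), imposes the stenosis pressure-loss jump at
internal interfaces, advances the lumped 0D circulation with RK4 and drives
everything with a time-varying-elastance heart until a periodic state is
reached.  Cycle-averaged flow/pressure outputs are evaluated at the middle
grid node of each flagged artery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernel as K
from . import units as U
from .network import VascularNetwork, ArterySegment, StenosisSpec, apply_input_vector


class SolverError(RuntimeError):
    pass


class InstabilityError(SolverError):
    """Non-finite state, negative area, or a CFL violation."""


@dataclass
class SolverSettings:
    target_dx: float = 2.5            # mm
    CFL_number: float = 0.9
    max_cycles: int = 30
    periodicity_tol: float = 1.0e-3   # relative change of outputs per cycle
    cardiac_period: float = 1.0       # s
    blood_density: float = U.BLOOD_DENSITY
    blood_viscosity: float = U.BLOOD_VISCOSITY
    newton_tol: float = K.NEWTON_TOL
    speed_margin: float = 1.25        # safety factor on the CFL wave speed

    @property
    def K_R(self) -> float:
        """Friction resistance parameter 22*pi*mu/rho (m^2/s)."""
        return 22.0 * math.pi * self.blood_viscosity / self.blood_density

    def validate(self):
        if not (0 < self.CFL_number <= 1):
            raise ValueError("CFL_number must be in (0, 1]")
        if self.periodicity_tol <= 0:
            raise ValueError("periodicity_tol must be > 0")


# ------------------------------------------------------------------
# elementary constitutive relations (public oracles of the model)
# ------------------------------------------------------------------

def _beta(seg: ArterySegment) -> float:
    """Tube-law coefficient sqrt(pi)*Eh/((1-sigma^2)*A0), SI."""
    a0 = seg.A0 * 1e-6
    return math.sqrt(math.pi) * seg.Eh / ((1.0 - seg.poisson_ratio ** 2) * a0)


def tube_law_pressure(A: float, seg: ArterySegment) -> float:
    """Transmural pressure (Pa) at cross-sectional area ``A`` (m^2)."""
    if A <= 0:
        raise InstabilityError("non-positive area in tube law")
    a0 = seg.A0 * 1e-6
    p0 = U.mmhg_to_pa(seg.P0)
    return p0 + _beta(seg) * (math.sqrt(A) - math.sqrt(a0))


def tube_law_area(P: float, seg: ArterySegment) -> float:
    """Inverse tube law: area (m^2) at pressure ``P`` (Pa)."""
    a0 = seg.A0 * 1e-6
    p0 = U.mmhg_to_pa(seg.P0)
    root = math.sqrt(a0) + (P - p0) / _beta(seg)
    if root <= 0:
        raise InstabilityError("pressure below collapse in inverse tube law")
    return root ** 2


def wave_speed(A: float, seg: ArterySegment,
               rho: float = U.BLOOD_DENSITY) -> float:
    """Linearized pulse-wave speed c = sqrt(beta*sqrt(A)/(2 rho)) (m/s)."""
    return math.sqrt(_beta(seg) * math.sqrt(A) / (2.0 * rho))


def stenosis_pressure_loss(Q: float, dQdt: float, sten: StenosisSpec,
                           rho: float = U.BLOOD_DENSITY) -> float:
    """Pressure loss (Pa) across a stenosis at flow ``Q`` (m^3/s).

    Viscous + flow-separation + pulsatility terms; the separation term
    scales with {(1-SR)^-2 - 1}^2 Q|Q| and the pulsatility term with dQ/dt.
    """
    sten.validate()
    dn = sten.Dn * U.MM_M
    ls = sten.Ls * U.MM_M
    rv = sten.Rv * U.RES_SI
    sep = (1.0 / (1.0 - sten.SR) ** 2 - 1.0) ** 2
    k2 = sten.Kt * 8.0 * rho / (math.pi ** 2 * dn ** 4) * sep
    k3 = sten.Ku * 4.0 * rho * ls / (math.pi * dn ** 2)
    return rv * Q + k2 * Q * abs(Q) + k3 * dQdt


def viscous_resistance(x_mm: np.ndarray, d_mm: np.ndarray,
                       mu: float = U.BLOOD_VISCOSITY) -> float:
    """Poiseuille resistance of an axial diameter profile, mmHg.s/mL.

    Quadrature of 128*mu/(pi*D(x)^4) along the profile; equals
    128*mu*Ls/(pi*D^4) for a uniform lumen.
    """
    x = np.asarray(x_mm, dtype=float) * U.MM_M
    d = np.asarray(d_mm, dtype=float) * U.MM_M
    if np.any(d <= 0):
        raise ValueError("diameter profile must be strictly positive")
    if x[-1] <= x[0]:
        raise ValueError("profile must span a positive length")
    integrand = 128.0 * mu / (math.pi * d ** 4)
    return float(np.trapezoid(integrand, x)) / U.RES_SI


def cycle_average(t: np.ndarray, y: np.ndarray, Tc: float = 1.0) -> float:
    """Trapezoidal mean of a uniformly sampled signal over one period."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t[-1] - t[0] < Tc * (1.0 - 1e-9):
        raise ValueError("sampling window shorter than one period")
    return float(np.trapezoid(y, t)) / (t[-1] - t[0])


def solve_junction(w, sgn, beta, a0, ainit, rho=U.BLOOD_DENSITY,
                   p0=U.mmhg_to_pa(85.0)):
    """Newton solve of the junction coupling for given Riemann invariants.

    ``w[k]`` is the incoming invariant of end ``k`` (u+4c at a distal end,
    u-4c at a proximal end), ``sgn[k]`` is +1 for distal ends (flow feeds
    the junction) and -1 for proximal ends.  Returns (A, Q, P) arrays
    satisfying mass and total-pressure continuity to the Newton tolerance.
    """
    w = np.asarray(w, float)
    sgn = np.asarray(sgn, float)
    beta = np.asarray(beta, float)
    a0 = np.asarray(a0, float)
    a, u, ok = K._junction_newton(len(w), w, sgn, beta, a0,
                                  np.asarray(ainit, float).copy(), rho, p0)
    if not ok:
        raise SolverError("junction Newton iteration did not converge")
    p = p0 + beta * (np.sqrt(a) - np.sqrt(a0))
    return a, a * u, p


# ------------------------------------------------------------------
# network flattening
# ------------------------------------------------------------------

def _odd_nodes(length_mm: float, target_dx_mm: float) -> int:
    n = int(round(length_mm / target_dx_mm)) + 1
    n = max(n, 3)
    if n % 2 == 0:
        n += 1
    return n


@dataclass
class FlatNetwork:
    """SI arrays for the kernel plus bookkeeping back to the network."""
    net: VascularNetwork
    settings: SolverSettings
    seg_first: np.ndarray = None
    seg_n: np.ndarray = None
    seg_dx: np.ndarray = None
    seg_beta: np.ndarray = None
    seg_a0: np.ndarray = None
    A: np.ndarray = None
    Q: np.ndarray = None
    jn_ptr: np.ndarray = None
    jn_seg: np.ndarray = None
    jn_dist: np.ndarray = None
    st_u: np.ndarray = None
    st_d: np.ndarray = None
    st_rv: np.ndarray = None
    st_k2: np.ndarray = None
    st_k3: np.ndarray = None
    st_qprev: np.ndarray = None
    out_seg: np.ndarray = None
    out_r1: np.ndarray = None
    out_r2: np.ndarray = None
    out_c: np.ndarray = None
    out_blk: np.ndarray = None
    out_pc: np.ndarray = None
    blk_r: np.ndarray = None
    blk_l: np.ndarray = None
    blk_c: np.ndarray = None
    blk_p1: np.ndarray = None
    blk_q2: np.ndarray = None
    heart_state: np.ndarray = None
    hp: np.ndarray = None
    inlet_seg: int = 0
    # maps: network segment id -> flat segment index (or pair if split)
    flat_of: dict = field(default_factory=dict)
    mid_node: dict = field(default_factory=dict)
    outlet_ids: list = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]

    def node_index(self, sid: int, where: str = "mid") -> int:
        if where == "mid":
            return self.mid_node[sid]
        parts = self.flat_of[sid]
        if where == "prox":
            return int(self.seg_first[parts[0]])
        if where == "dist":
            f = parts[-1]
            return int(self.seg_first[f] + self.seg_n[f] - 1)
        raise ValueError(where)


def flatten(net: VascularNetwork, settings: SolverSettings) -> FlatNetwork:
    net.validate()
    settings.validate()
    rho = settings.blood_density
    fl = FlatNetwork(net=net, settings=settings)

    active_sten = {st.host_segment_id: st for st in net.stenoses
                   if not st.is_intact}

    firsts, ns, dxs, betas, a0s = [], [], [], [], []
    flat_of, mid_node = {}, {}
    pos = 0
    idx = 0
    st_rows = []
    for seg in net.segments:
        beta = _beta(seg)
        a0 = seg.A0 * 1e-6
        if seg.id in active_sten:
            # split at the midpoint; the pressure-loss jump sits between
            # the two halves, and the "middle node" is the upstream side
            # of the interface.
            half = seg.length / 2.0
            nh = (seg.n_nodes // 2 + 1) if seg.n_nodes else _odd_nodes(
                half, settings.target_dx)
            nh = max(nh, 3)
            parts = []
            for _ in range(2):
                firsts.append(pos)
                ns.append(nh)
                dxs.append(half * U.MM_M / (nh - 1))
                betas.append(beta)
                a0s.append(a0)
                parts.append(idx)
                pos += nh
                idx += 1
            flat_of[seg.id] = parts
            mid_node[seg.id] = firsts[parts[0]] + nh - 1
            st_rows.append((parts[0], parts[1], active_sten[seg.id]))
        else:
            n = seg.n_nodes if seg.n_nodes else _odd_nodes(
                seg.length, settings.target_dx)
            firsts.append(pos)
            ns.append(n)
            dxs.append(seg.length * U.MM_M / (n - 1))
            betas.append(beta)
            a0s.append(a0)
            flat_of[seg.id] = [idx]
            mid_node[seg.id] = pos + n // 2
            pos += n
            idx += 1

    fl.seg_first = np.array(firsts, dtype=np.int64)
    fl.seg_n = np.array(ns, dtype=np.int64)
    fl.seg_dx = np.array(dxs, dtype=float)
    fl.seg_beta = np.array(betas, dtype=float)
    fl.seg_a0 = np.array(a0s, dtype=float)
    fl.flat_of = flat_of
    fl.mid_node = mid_node

    nn = pos
    fl.A = np.empty(nn)
    fl.Q = np.zeros(nn)
    for s in range(len(firsts)):
        fl.A[firsts[s]:firsts[s] + ns[s]] = a0s[s]

    # junctions (flat indices: proximal end -> first part, distal -> last)
    ptr, jseg, jdist = [0], [], []
    for jn in net.junctions:
        for sid, end in jn:
            parts = flat_of[sid]
            if end == "d":
                jseg.append(parts[-1])
                jdist.append(1)
            else:
                jseg.append(parts[0])
                jdist.append(0)
        ptr.append(len(jseg))
    fl.jn_ptr = np.array(ptr, dtype=np.int64)
    fl.jn_seg = np.array(jseg, dtype=np.int64)
    fl.jn_dist = np.array(jdist, dtype=np.int64)

    su, sd, srv, sk2, sk3 = [], [], [], [], []
    for up, dn, st in st_rows:
        dn_m = st.Dn * U.MM_M
        ls_m = st.Ls * U.MM_M
        sep = (1.0 / (1.0 - st.SR) ** 2 - 1.0) ** 2
        su.append(up)
        sd.append(dn)
        srv.append(st.Rv * U.RES_SI)
        sk2.append(st.Kt * 8.0 * rho / (math.pi ** 2 * dn_m ** 4) * sep)
        sk3.append(st.Ku * 4.0 * rho * ls_m / (math.pi * dn_m ** 2))
    fl.st_u = np.array(su, dtype=np.int64)
    fl.st_d = np.array(sd, dtype=np.int64)
    fl.st_rv = np.array(srv, dtype=float)
    fl.st_k2 = np.array(sk2, dtype=float)
    fl.st_k3 = np.array(sk3, dtype=float)
    fl.st_qprev = np.zeros(len(su))

    blocks = {b.name: i for i, b in enumerate(net.body_blocks)}
    oseg, r1, r2, oc, oblk = [], [], [], [], []
    fl.outlet_ids = []
    for o in net.outlets:
        oseg.append(flat_of[o.segment_id][-1])
        r1.append(o.R_proximal * U.RES_SI)
        r2.append(o.R_distal * U.RES_SI)
        oc.append(o.compliance * U.CAP_SI)
        oblk.append(blocks[o.body_block])
        fl.outlet_ids.append(o.segment_id)
    fl.out_seg = np.array(oseg, dtype=np.int64)
    fl.out_r1 = np.array(r1, dtype=float)
    fl.out_r2 = np.array(r2, dtype=float)
    fl.out_c = np.array(oc, dtype=float)
    fl.out_blk = np.array(oblk, dtype=np.int64)
    fl.out_pc = np.full(len(oseg), U.mmhg_to_pa(85.0))

    fl.blk_r = np.array([b.R * U.RES_SI for b in net.body_blocks])
    fl.blk_l = np.array([b.L * U.IND_SI for b in net.body_blocks])
    fl.blk_c = np.array([b.C * U.CAP_SI for b in net.body_blocks])
    fl.blk_p1 = np.full(len(net.body_blocks), U.mmhg_to_pa(15.0))
    fl.blk_q2 = np.zeros(len(net.body_blocks))

    h = net.heart
    fl.hp = np.array([
        h.E_max_lv * U.MMHG_PA / U.ML_M3, h.E_min_lv * U.MMHG_PA / U.ML_M3,
        h.V0_lv * U.ML_M3,
        h.E_max_la * U.MMHG_PA / U.ML_M3, h.E_min_la * U.MMHG_PA / U.ML_M3,
        h.V0_la * U.ML_M3,
        h.Ts_lv, h.t_la, h.Ts_la,
        h.R_mv * U.RES_SI, h.R_av * U.RES_SI,
        h.cardiac_period,
    ])
    # initial chamber volumes near a 5 mmHg diastolic filling pressure
    v_la = h.V0_la + 5.0 / h.E_min_la
    v_lv = h.V0_lv + 5.0 / h.E_min_lv
    fl.heart_state = np.array([v_la * U.ML_M3, v_lv * U.ML_M3])
    fl.inlet_seg = flat_of[net.inlet_segment_id][0]
    return fl


# ------------------------------------------------------------------
# cycle integration
# ------------------------------------------------------------------

@dataclass
class CycleAverages:
    """Cycle-averaged outputs in the network's published layout
    (flows mL/min, pressures mmHg)."""
    names: list
    values: np.ndarray
    converged: bool
    cycles_run: int
    mean_q_node: np.ndarray      # mL/min per flat node
    mean_p_node: np.ndarray      # mmHg per flat node (static)
    mean_dyn_node: np.ndarray    # mmHg per flat node (dynamic, 0.5*rho*u^2)
    flat: FlatNetwork

    def as_dict(self) -> dict:
        return dict(zip(self.names, self.values.tolist()))

    def mean_flow(self, segment_id: int, where: str = "mid") -> float:
        return float(self.mean_q_node[self.flat.node_index(segment_id, where)])

    def mean_pressure(self, segment_id: int, where: str = "mid") -> float:
        return float(self.mean_p_node[self.flat.node_index(segment_id, where)])

    @property
    def outlet_flows(self) -> dict:
        return {sid: self.mean_flow(sid, "dist") for sid in self.flat.outlet_ids}

    @property
    def cardiac_output(self) -> float:
        """Mean inflow at the aortic root, mL/min."""
        return float(self.mean_q_node[int(
            self.flat.seg_first[self.flat.inlet_seg])])


def _kernel_args(fl: FlatNetwork, settings: SolverSettings):
    return (fl.A, fl.Q, fl.seg_first, fl.seg_n, fl.seg_dx, fl.seg_beta,
            fl.seg_a0, fl.jn_ptr, fl.jn_seg, fl.jn_dist,
            fl.st_u, fl.st_d, fl.st_rv, fl.st_k2, fl.st_k3, fl.st_qprev,
            fl.out_seg, fl.out_r1, fl.out_r2, fl.out_c, fl.out_blk, fl.out_pc,
            fl.blk_r, fl.blk_l, fl.blk_c, fl.blk_p1, fl.blk_q2,
            fl.heart_state, fl.hp, fl.inlet_seg,
            settings.blood_density, settings.K_R, U.mmhg_to_pa(85.0))


def _extract_outputs(net: VascularNetwork, fl: FlatNetwork,
                     mean_q: np.ndarray, mean_p: np.ndarray) -> np.ndarray:
    vals = np.empty(len(net.output_manifest))
    for i, slot in enumerate(net.output_manifest):
        node = fl.mid_node[slot.target]
        if slot.kind == "qbar":
            vals[i] = U.m3s_to_mlmin(mean_q[node])
        else:  # pbar / map
            vals[i] = U.pa_to_mmhg(mean_p[node])
    return vals


def run_to_periodic(net: VascularNetwork,
                    settings: SolverSettings | None = None,
                    record_segments: tuple = (),
                    record_every: int = 0) -> CycleAverages:
    """Integrate cardiac cycles until all cycle-averaged outputs change by
    less than ``periodicity_tol`` between consecutive cycles (or
    ``max_cycles`` is reached, with ``converged=False``).  Outputs are those
    of the final cycle."""
    settings = settings or SolverSettings()
    fl = flatten(net, settings)
    tc = settings.cardiac_period
    nn = fl.n_nodes
    sum_q = np.zeros(nn)
    sum_p = np.zeros(nn)
    sum_dyn = np.zeros(nn)

    rec_nodes = np.array([fl.mid_node[s] for s in record_segments],
                         dtype=np.int64)
    waveforms = []

    prev = None
    t = 0.0
    dxmin = float(fl.seg_dx.min())
    for cyc in range(settings.max_cycles):
        speed = K.max_wave_speed(fl.A, fl.Q, fl.seg_first, fl.seg_n,
                                 fl.seg_beta, settings.blood_density)
        dt = settings.CFL_number * dxmin / (speed * settings.speed_margin)
        n_steps = int(math.ceil(tc / dt))
        dt = tc / n_steps
        if record_every > 0:
            nrec = n_steps // record_every + 1
            rec_a = np.empty((nrec, len(rec_nodes)))
            rec_q = np.empty((nrec, len(rec_nodes)))
        else:
            rec_a = np.empty((0, max(len(rec_nodes), 1)))
            rec_q = np.empty((0, max(len(rec_nodes), 1)))
        code, done = K.run_steps(t, dt, n_steps, *_kernel_args(fl, settings),
                                 sum_q, sum_p, sum_dyn, rec_nodes,
                                 record_every, rec_a, rec_q)
        if code != K.OK:
            raise InstabilityError(
                f"solver instability in cycle {cyc + 1} after {done} steps "
                f"(t = {t + done * dt:.4f} s)")
        t += tc
        if record_every > 0:
            waveforms.append((dt * record_every, rec_a, rec_q))
        mean_q = sum_q / n_steps
        mean_p = sum_p / n_steps
        outs = _extract_outputs(net, fl, mean_q, mean_p)
        if prev is not None:
            rel = np.abs(outs - prev) / np.maximum(np.abs(prev), 1.0)
            if float(rel.max()) < settings.periodicity_tol:
                res = CycleAverages(
                    names=[s.name for s in net.output_manifest],
                    values=outs, converged=True, cycles_run=cyc + 1,
                    mean_q_node=U.m3s_to_mlmin(mean_q),
                    mean_p_node=U.pa_to_mmhg(mean_p),
                    mean_dyn_node=U.pa_to_mmhg(sum_dyn / n_steps), flat=fl)
                res.waveforms = waveforms
                return res
        prev = outs

    res = CycleAverages(names=[s.name for s in net.output_manifest],
                        values=prev, converged=False,
                        cycles_run=settings.max_cycles,
                        mean_q_node=U.m3s_to_mlmin(sum_q / n_steps),
                        mean_p_node=U.pa_to_mmhg(sum_p / n_steps),
                        mean_dyn_node=U.pa_to_mmhg(sum_dyn / n_steps),
                        flat=fl)
    res.waveforms = waveforms
    return res


def simulate_output_vector(x: np.ndarray, base_net: VascularNetwork,
                           settings: SolverSettings | None = None) -> np.ndarray:
    """Apply an input vector to the base network and return the
    cycle-averaged output vector (flows mL/min, pressures mmHg).

    Raises :class:`SolverError` if the periodic state is not reached.
    """
    net = apply_input_vector(base_net, x)
    res = run_to_periodic(net, settings)
    if not res.converged:
        raise SolverError("periodic state not reached within max_cycles")
    return res.values


class NetworkSimulation:
    """Step-by-step access to the coupled 1D-0D integration.

    ``run_to_periodic`` drives whole cardiac cycles on the same kernel;
    this wrapper advances one global time step at a time (interior nodes by
    Lax-Wendroff, junction/stenosis/outlet/inlet boundaries by their Newton
    solves, 0D states by RK4) for debugging and step-level tests.
    """

    def __init__(self, net: VascularNetwork,
                 settings: SolverSettings | None = None):
        self.settings = settings or SolverSettings()
        self.flat = flatten(net, self.settings)
        self.t = 0.0

    def max_dt(self) -> float:
        speed = K.max_wave_speed(self.flat.A, self.flat.Q,
                                 self.flat.seg_first, self.flat.seg_n,
                                 self.flat.seg_beta,
                                 self.settings.blood_density)
        return self.settings.CFL_number * float(self.flat.seg_dx.min()) / speed

    def advance(self, dt: float) -> None:
        """One global time step; raises on a CFL violation or instability
        before the divergence can propagate."""
        if dt > self.max_dt() * (1 + 1e-9):
            raise InstabilityError(
                f"dt = {dt:.3e} s violates the CFL limit {self.max_dt():.3e} s")
        fl = self.flat
        nn = fl.n_nodes
        Anew = np.empty(nn)
        Qnew = np.empty(nn)
        code = K.step(self.t, dt, *_kernel_args(fl, self.settings),
                      Anew, Qnew)
        if code != K.OK:
            raise InstabilityError(
                f"solver instability at t = {self.t:.5f} s (code {code})")
        self.t += dt


# ------------------------------------------------------------------
# single-tube simulator (pure Python; physics oracles and debugging)
# ------------------------------------------------------------------

class TubeSimulator:
    """Lax-Wendroff integration of one segment with simple boundary
    conditions: prescribed inflow, fixed-pressure reservoir, or
    non-reflecting ends.  Used to check the friction (Poiseuille) limit and
    the linearized pulse-wave speed against closed forms."""

    def __init__(self, seg: ArterySegment, n_nodes: int,
                 settings: SolverSettings | None = None,
                 inflow=None, outflow_pressure: float | None = None):
        self.seg = seg
        self.settings = settings or SolverSettings()
        self.n = n_nodes
        self.dx = seg.length * U.MM_M / (n_nodes - 1)
        self.beta = _beta(seg)
        self.a0 = seg.A0 * 1e-6
        self.p0 = U.mmhg_to_pa(seg.P0)
        self.rho = self.settings.blood_density
        self.A = np.full(n_nodes, self.a0)
        self.Q = np.zeros(n_nodes)
        self.inflow = inflow
        self.outflow_pressure = outflow_pressure
        self.t = 0.0

    def _c(self, A):
        return np.sqrt(self.beta * np.sqrt(A) / (2.0 * self.rho))

    def _p(self, A):
        return self.p0 + self.beta * (np.sqrt(A) - np.sqrt(self.a0))

    def max_dt(self):
        speed = float(np.max(np.abs(self.Q / self.A) + self._c(self.A)))
        return self.settings.CFL_number * self.dx / speed

    def step(self, dt: float):
        if dt > self.settings.CFL_number * self.dx / float(
                np.max(np.abs(self.Q / self.A) + self._c(self.A))) * (1 + 1e-9):
            raise InstabilityError("time step violates the CFL condition")
        A, Q = self.A, self.Q
        rho, kr = self.rho, self.settings.K_R
        cf = self.beta / (3.0 * rho)
        f2 = Q * Q / A + cf * A ** 1.5
        s2 = -kr * Q / A
        ah = 0.5 * (A[:-1] + A[1:]) - 0.5 * dt / self.dx * (Q[1:] - Q[:-1])
        qh = (0.5 * (Q[:-1] + Q[1:]) - 0.5 * dt / self.dx * (f2[1:] - f2[:-1])
              + 0.25 * dt * (s2[:-1] + s2[1:]))
        f2h = qh * qh / ah + cf * ah ** 1.5
        s2h = -kr * qh / ah
        An = A.copy()
        Qn = Q.copy()
        An[1:-1] = A[1:-1] - dt / self.dx * (qh[1:] - qh[:-1])
        Qn[1:-1] = (Q[1:-1] - dt / self.dx * (f2h[1:] - f2h[:-1])
                    + 0.5 * dt * (s2h[1:] + s2h[:-1]))

        c = self._c(A)
        u = Q / A
        # boundary invariants interpolated at the characteristic foot
        th = min(max((c[0] - u[0]) * dt / self.dx, 0.0), 1.0)
        w2 = ((1.0 - th) * (u[0] - 4.0 * c[0])
              + th * (u[1] - 4.0 * c[1]))
        if self.inflow is not None:
            q_in = self.inflow(self.t + dt) if callable(self.inflow) \
                else self.inflow
            a = A[0]
            for _ in range(60):
                cb = math.sqrt(self.beta * math.sqrt(a) / (2 * rho))
                ub = w2 + 4.0 * cb
                f = a * ub - q_in
                df = ub + cb
                da = -f / df
                a += da
                a = max(a, 0.05 * self.a0)
                if abs(da) < 1e-14 * a:
                    break
            An[0] = a
            Qn[0] = q_in
        else:  # non-reflecting: incoming invariant held at rest value
            w1 = 0.0 + 4.0 * self._c(np.array([self.a0]))[0]
            ub = 0.5 * (w1 + w2)
            cb = (w1 - w2) / 8.0
            a = (2.0 * rho * cb * cb / self.beta) ** 2
            An[0] = a
            Qn[0] = a * ub
        # distal boundary
        th = min(max((u[-1] + c[-1]) * dt / self.dx, 0.0), 1.0)
        w1 = ((1.0 - th) * (u[-1] + 4.0 * c[-1])
              + th * (u[-2] + 4.0 * c[-2]))
        if self.outflow_pressure is not None:
            root = math.sqrt(self.a0) + (self.outflow_pressure - self.p0) / self.beta
            a = root ** 2
            An[-1] = a
            Qn[-1] = a * (w1 - 4.0 * self._c(np.array([a]))[0])
        else:  # non-reflecting
            w2r = 0.0 - 4.0 * self._c(np.array([self.a0]))[0]
            ub = 0.5 * (w1 + w2r)
            cb = (w1 - w2r) / 8.0
            a = (2.0 * rho * cb * cb / self.beta) ** 2
            An[-1] = a
            Qn[-1] = a * ub
        if not np.all(np.isfinite(An)) or np.any(An <= 0):
            raise InstabilityError(f"non-finite state at t = {self.t:.5f} s")
        self.A, self.Q = An, Qn
        self.t += dt

    def run(self, duration: float):
        while True:
            dt = 0.5 * self.max_dt()
            if duration <= 0:
                return
            dt = min(dt, duration)
            self.step(dt)
            duration -= dt

    @property
    def pressure(self):
        return self._p(self.A)
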