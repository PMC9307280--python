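"""Numba kernels for the closed-loop 1D-0D time integration.

Everything here works on flat SI arrays produced by ``solver.flatten``:
artery segments are concatenated node ranges of (A, Q); junctions, stenosis
interfaces, Windkessel outlets and the heart inlet are boundary couplings
solved with Newton iterations on Riemann invariants (W = u +/- 4c for the
square-root tube law); the lumped 0D states advance with RK4.

The two-step Lax-Wendroff (Richtmyer) scheme integrates the interior nodes
of the (A, Q) system in conservative form with flux
F = (Q, Q^2/A + beta/(3 rho) A^{3/2}) and friction source -K_R Q/A.
"""

import numpy as np
from numba import njit

NEWTON_TOL = 1.0e-10
NEWTON_MAXIT = 50

OK = 0
ERR_NONFINITE = 1
ERR_NEWTON = 2


@njit(cache=True)
def _cwave(a, beta, rho):
    return np.sqrt(beta * np.sqrt(a) / (2.0 * rho))


@njit(cache=True)
def _pres(a, beta, a0, p0):
    return p0 + beta * (np.sqrt(a) - np.sqrt(a0))


@njit(cache=True)
def _w_foot(A, Q, first, n, dx, beta, rho, dt, distal):
    """Riemann invariant extrapolated to the characteristic foot."""
    if distal:
        i = first + n - 1
        u0 = Q[i] / A[i]
        c0 = _cwave(A[i], beta, rho)
        u1 = Q[i - 1] / A[i - 1]
        c1 = _cwave(A[i - 1], beta, rho)
        th = (u0 + c0) * dt / dx
        if th < 0.0:
            th = 0.0
        if th > 1.0:
            th = 1.0
        return (1.0 - th) * (u0 + 4.0 * c0) + th * (u1 + 4.0 * c1)
    else:
        i = first
        u0 = Q[i] / A[i]
        c0 = _cwave(A[i], beta, rho)
        u1 = Q[i + 1] / A[i + 1]
        c1 = _cwave(A[i + 1], beta, rho)
        th = (c0 - u0) * dt / dx
        if th < 0.0:
            th = 0.0
        if th > 1.0:
            th = 1.0
        return (1.0 - th) * (u0 - 4.0 * c0) + th * (u1 - 4.0 * c1)


@njit(cache=True)
def _lw_interior(A, Q, Anew, Qnew, first, n, dx, beta, a0, rho, kr, dt):
    """Richtmyer two-step Lax-Wendroff update of nodes 1..n-2."""
    cf = beta / (3.0 * rho)
    # half-step values at i+1/2 for i = 0..n-2 (stored locally)
    ah = np.empty(n - 1)
    qh = np.empty(n - 1)
    for k in range(n - 1):
        i = first + k
        f1l = Q[i]
        f1r = Q[i + 1]
        f2l = Q[i] * Q[i] / A[i] + cf * A[i] ** 1.5
        f2r = Q[i + 1] * Q[i + 1] / A[i + 1] + cf * A[i + 1] ** 1.5
        s2l = -kr * Q[i] / A[i]
        s2r = -kr * Q[i + 1] / A[i + 1]
        ah[k] = 0.5 * (A[i] + A[i + 1]) - 0.5 * dt / dx * (f1r - f1l)
        qh[k] = (0.5 * (Q[i] + Q[i + 1]) - 0.5 * dt / dx * (f2r - f2l)
                 + 0.25 * dt * (s2l + s2r))
    for k in range(1, n - 1):
        i = first + k
        f1l = qh[k - 1]
        f1r = qh[k]
        f2l = qh[k - 1] * qh[k - 1] / ah[k - 1] + cf * ah[k - 1] ** 1.5
        f2r = qh[k] * qh[k] / ah[k] + cf * ah[k] ** 1.5
        s2l = -kr * qh[k - 1] / ah[k - 1]
        s2r = -kr * qh[k] / ah[k]
        Anew[i] = A[i] - dt / dx * (f1r - f1l)
        Qnew[i] = Q[i] - dt / dx * (f2r - f2l) + 0.5 * dt * (s2l + s2r)


@njit(cache=True)
def _gauss_solve(J, f, x):
    """In-place Gaussian elimination with partial pivoting for the small
    dense junction systems (n <= 6); avoids LAPACK call overhead."""
    n = f.shape[0]
    for col in range(n):
        piv = col
        best = abs(J[col, col])
        for r in range(col + 1, n):
            if abs(J[r, col]) > best:
                best = abs(J[r, col])
                piv = r
        if piv != col:
            for cc in range(n):
                J[col, cc], J[piv, cc] = J[piv, cc], J[col, cc]
            f[col], f[piv] = f[piv], f[col]
        d = J[col, col]
        for r in range(col + 1, n):
            m = J[r, col] / d
            for cc in range(col, n):
                J[r, cc] -= m * J[col, cc]
            f[r] -= m * f[col]
    for r in range(n - 1, -1, -1):
        acc = f[r]
        for cc in range(r + 1, n):
            acc -= J[r, cc] * x[cc]
        x[r] = acc / J[r, r]


@njit(cache=True)
def _junction_newton(nend, w, sgn, beta, a0v, ainit, rho, p0):
    """Newton solve of mass + total-pressure coupling at one junction.

    Returns (a, u, converged flag).  ``sgn`` is +1 where the segment's
    distal end feeds the junction, -1 where its proximal end drains it.
    """
    a = ainit.copy()
    f = np.empty(nend)
    J = np.zeros((nend, nend))
    u = np.empty(nend)
    c = np.empty(nend)
    step_a = np.empty(nend)
    for _ in range(NEWTON_MAXIT):
        for k in range(nend):
            c[k] = _cwave(a[k], beta[k], rho)
            u[k] = w[k] - sgn[k] * 4.0 * c[k]
        r0 = 0.0
        for k in range(nend):
            r0 += sgn[k] * a[k] * u[k]
        f[0] = r0
        pt0 = _pres(a[0], beta[0], a0v[0], p0) + 0.5 * rho * u[0] * u[0]
        for i in range(1, nend):
            pti = _pres(a[i], beta[i], a0v[i], p0) + 0.5 * rho * u[i] * u[i]
            f[i] = pti - pt0
        # Jacobian
        for k in range(nend):
            J[0, k] = sgn[k] * u[k] - c[k]
        dpt0 = beta[0] / (2.0 * np.sqrt(a[0])) - rho * u[0] * sgn[0] * c[0] / a[0]
        for i in range(1, nend):
            for k in range(nend):
                J[i, k] = 0.0
            J[i, i] = (beta[i] / (2.0 * np.sqrt(a[i]))
                       - rho * u[i] * sgn[i] * c[i] / a[i])
            J[i, 0] = -dpt0
        for k in range(nend):
            f[k] = -f[k]
        _gauss_solve(J, f, step_a)
        step = step_a
        done = True
        for k in range(nend):
            a[k] += step[k]
            if a[k] < 0.05 * a0v[k]:
                a[k] = 0.05 * a0v[k]
            if abs(step[k]) > NEWTON_TOL * max(a[k], 1e-12):
                done = False
        if done:
            resid = abs(f[0])
            for i in range(1, nend):
                resid = max(resid, abs(f[i]))
            for k in range(nend):
                c[k] = _cwave(a[k], beta[k], rho)
                u[k] = w[k] - sgn[k] * 4.0 * c[k]
            return a, u, True
    return a, u, False


@njit(cache=True)
def _stenosis_newton(w0, w1, b0, b1, a00, a01, ainit0, ainit1,
                     rv, k2, k3, qprev, dt, rho, p0):
    """Two-end Newton at a stenosis interface: continuity of Q with a
    pressure jump R_v Q + k2 Q|Q| + k3 dQ/dt between total pressures."""
    a0 = ainit0
    a1 = ainit1
    for _ in range(NEWTON_MAXIT):
        c0 = _cwave(a0, b0, rho)
        c1 = _cwave(a1, b1, rho)
        u0 = w0 - 4.0 * c0
        u1 = w1 + 4.0 * c1
        q = a0 * u0
        dp = rv * q + k2 * q * abs(q) + k3 * (q - qprev) / dt
        f0 = a0 * u0 - a1 * u1
        f1 = (_pres(a0, b0, a00, p0) + 0.5 * rho * u0 * u0
              - _pres(a1, b1, a01, p0) - 0.5 * rho * u1 * u1 - dp)
        ddp_dq = rv + 2.0 * k2 * abs(q) + k3 / dt
        j00 = u0 - c0
        j01 = -(u1 + c1)
        j10 = (b0 / (2.0 * np.sqrt(a0)) - rho * u0 * c0 / a0
               - ddp_dq * (u0 - c0))
        j11 = -(b1 / (2.0 * np.sqrt(a1)) + rho * u1 * c1 / a1)
        det = j00 * j11 - j01 * j10
        da0 = (-f0 * j11 + f1 * j01) / det
        da1 = (-j00 * f1 + j10 * f0) / det
        a0 += da0
        a1 += da1
        if a0 < 0.05 * a00:
            a0 = 0.05 * a00
        if a1 < 0.05 * a01:
            a1 = 0.05 * a01
        if (abs(da0) <= NEWTON_TOL * max(a0, 1e-12)
                and abs(da1) <= NEWTON_TOL * max(a1, 1e-12)):
            return a0, a1, True
    return a0, a1, False


@njit(cache=True)
def _outlet_newton(w1, beta, a0v, ainit, r1, pc, rho, p0):
    """Terminal node coupled to the proximal Windkessel resistance."""
    a = ainit
    for _ in range(NEWTON_MAXIT):
        c = _cwave(a, beta, rho)
        u = w1 - 4.0 * c
        f = a * u - (_pres(a, beta, a0v, p0) - pc) / r1
        df = u - c - beta / (2.0 * np.sqrt(a) * r1)
        da = -f / df
        a += da
        if a < 0.05 * a0v:
            a = 0.05 * a0v
        if abs(da) <= NEWTON_TOL * max(a, 1e-12):
            return a, True
    return a, False


@njit(cache=True)
def _inlet_solve(w2, beta, a0v, ainit, p_lv, r_av, rho, p0):
    """Aortic-root node fed by the ventricle through the aortic valve."""
    a = ainit
    ok = False
    for _ in range(NEWTON_MAXIT):
        c = _cwave(a, beta, rho)
        u = w2 + 4.0 * c
        q_av = (p_lv - _pres(a, beta, a0v, p0)) / r_av
        f = a * u - q_av
        df = u + c + beta / (2.0 * np.sqrt(a) * r_av)
        da = -f / df
        a += da
        if a < 0.05 * a0v:
            a = 0.05 * a0v
        if abs(da) <= NEWTON_TOL * max(a, 1e-12):
            ok = True
            break
    q = a * (w2 + 4.0 * _cwave(a, beta, rho))
    if q >= 0.0 and ok:
        return a, q, True
    # valve closed: u = 0 exactly
    c = -w2 / 4.0
    if c <= 0.0:
        return a, 0.0, False
    a = (2.0 * rho * c * c / beta) ** 2
    return a, 0.0, True


@njit(cache=True)
def _elastance(t, tc, emax, emin, onset, dur):
    phi = (t - onset) % tc
    if phi < dur:
        e = 0.5 * (1.0 - np.cos(2.0 * np.pi * phi / dur))
    else:
        e = 0.0
    return emin + (emax - emin) * e


@njit(cache=True)
def _ode_rhs(t, pc, p1, q2, v_la, v_lv, q_term, q_av,
             out_r2, out_c, out_blk, blk_r, blk_l, blk_c, hp,
             dpc, dp1, dq2):
    """0D right-hand side; returns (dV_la, dV_lv) and fills the arrays."""
    no = pc.shape[0]
    nb = p1.shape[0]
    tc = hp[11]
    p_la = _elastance(t, tc, hp[3], hp[4], hp[7], hp[8]) * (v_la - hp[5])
    p_lv = _elastance(t, tc, hp[0], hp[1], 0.0, hp[6]) * (v_lv - hp[2])
    for b in range(nb):
        dp1[b] = 0.0
    for i in range(no):
        qo = (pc[i] - p1[out_blk[i]]) / out_r2[i]
        dpc[i] = (q_term[i] - qo) / out_c[i]
        dp1[out_blk[i]] += qo
    qven = 0.0
    for b in range(nb):
        dp1[b] = (dp1[b] - q2[b]) / blk_c[b]
        dq2[b] = (p1[b] - p_la - blk_r[b] * q2[b]) / blk_l[b]
        qven += q2[b]
    q_mv = (p_la - p_lv) / hp[9]
    if q_mv < 0.0:
        q_mv = 0.0
    # the aortic-valve outflow is the flow the 1D root actually accepted
    # (frozen over the step), keeping the 1D-0D volume exchange consistent
    return qven - q_mv, q_mv - q_av


@njit(cache=True)
def _rk4_0d(t0, dt, nsub, pc, p1, q2, heart_state, q_term, q_av,
            out_r2, out_c, out_blk, blk_r, blk_l, blk_c, hp):
    """``nsub`` classical RK4 substeps of length ``dt`` with frozen 1D
    couplings; scratch allocated once per call."""
    no = pc.shape[0]
    nb = p1.shape[0]
    k_pc = np.empty((4, no))
    k_p1 = np.empty((4, nb))
    k_q2 = np.empty((4, nb))
    k_la = np.empty(4)
    k_lv = np.empty(4)
    cpc = np.empty(no)
    cp1 = np.empty(nb)
    cq2 = np.empty(nb)
    coef = (0.0, 0.5, 0.5, 1.0)
    for isub in range(nsub):
        t = t0 + isub * dt
        for s in range(4):
            c = coef[s] * dt
            if s == 0:
                for i in range(no):
                    cpc[i] = pc[i]
                for b in range(nb):
                    cp1[b] = p1[b]
                    cq2[b] = q2[b]
                cla = heart_state[0]
                clv = heart_state[1]
            else:
                for i in range(no):
                    cpc[i] = pc[i] + c * k_pc[s - 1, i]
                for b in range(nb):
                    cp1[b] = p1[b] + c * k_p1[s - 1, b]
                    cq2[b] = q2[b] + c * k_q2[s - 1, b]
                cla = heart_state[0] + c * k_la[s - 1]
                clv = heart_state[1] + c * k_lv[s - 1]
            dla, dlv = _ode_rhs(t + c, cpc, cp1, cq2, cla, clv,
                                q_term, q_av, out_r2, out_c, out_blk,
                                blk_r, blk_l, blk_c, hp,
                                k_pc[s], k_p1[s], k_q2[s])
            k_la[s] = dla
            k_lv[s] = dlv
        w = dt / 6.0
        for i in range(no):
            pc[i] += w * (k_pc[0, i] + 2 * k_pc[1, i] + 2 * k_pc[2, i]
                          + k_pc[3, i])
        for b in range(nb):
            p1[b] += w * (k_p1[0, b] + 2 * k_p1[1, b] + 2 * k_p1[2, b]
                          + k_p1[3, b])
            q2[b] += w * (k_q2[0, b] + 2 * k_q2[1, b] + 2 * k_q2[2, b]
                          + k_q2[3, b])
        heart_state[0] += w * (k_la[0] + 2 * k_la[1] + 2 * k_la[2] + k_la[3])
        heart_state[1] += w * (k_lv[0] + 2 * k_lv[1] + 2 * k_lv[2] + k_lv[3])


@njit(cache=True)
def step(t, dt, A, Q, seg_first, seg_n, seg_dx, seg_beta, seg_a0,
         jn_ptr, jn_seg, jn_dist,
         st_u, st_d, st_rv, st_k2, st_k3, st_qprev,
         out_seg, out_r1, out_r2, out_c, out_blk, out_pc,
         blk_r, blk_l, blk_c, blk_p1, blk_q2,
         heart_state, hp, inlet_seg, rho, kr, p0, Anew, Qnew):
    """Advance the whole coupled system by one time step.  Returns an
    error code (0 = OK)."""
    nseg = seg_first.shape[0]
    for s in range(nseg):
        _lw_interior(A, Q, Anew, Qnew, seg_first[s], seg_n[s], seg_dx[s],
                     seg_beta[s], seg_a0[s], rho, kr, dt)

    # junctions
    njn = jn_ptr.shape[0] - 1
    for j in range(njn):
        lo = jn_ptr[j]
        hi = jn_ptr[j + 1]
        nend = hi - lo
        w = np.empty(nend)
        sgn = np.empty(nend)
        beta = np.empty(nend)
        a0v = np.empty(nend)
        ainit = np.empty(nend)
        nodes = np.empty(nend, dtype=np.int64)
        for k in range(nend):
            s = jn_seg[lo + k]
            distal = jn_dist[lo + k] == 1
            w[k] = _w_foot(A, Q, seg_first[s], seg_n[s], seg_dx[s],
                           seg_beta[s], rho, dt, distal)
            sgn[k] = 1.0 if distal else -1.0
            beta[k] = seg_beta[s]
            a0v[k] = seg_a0[s]
            node = seg_first[s] + seg_n[s] - 1 if distal else seg_first[s]
            nodes[k] = node
            ainit[k] = A[node]
        a, u, ok = _junction_newton(nend, w, sgn, beta, a0v, ainit, rho, p0)
        if not ok:
            return ERR_NEWTON
        for k in range(nend):
            Anew[nodes[k]] = a[k]
            Qnew[nodes[k]] = a[k] * u[k]

    # stenosis interfaces
    nst = st_u.shape[0]
    for j in range(nst):
        su = st_u[j]
        sd = st_d[j]
        iu = seg_first[su] + seg_n[su] - 1
        idn = seg_first[sd]
        w0 = _w_foot(A, Q, seg_first[su], seg_n[su], seg_dx[su],
                     seg_beta[su], rho, dt, True)
        w1 = _w_foot(A, Q, seg_first[sd], seg_n[sd], seg_dx[sd],
                     seg_beta[sd], rho, dt, False)
        a0r, a1r, ok = _stenosis_newton(
            w0, w1, seg_beta[su], seg_beta[sd], seg_a0[su], seg_a0[sd],
            A[iu], A[idn], st_rv[j], st_k2[j], st_k3[j], st_qprev[j],
            dt, rho, p0)
        if not ok:
            return ERR_NEWTON
        c0 = _cwave(a0r, seg_beta[su], rho)
        u0 = w0 - 4.0 * c0
        c1 = _cwave(a1r, seg_beta[sd], rho)
        u1 = w1 + 4.0 * c1
        Anew[iu] = a0r
        Qnew[iu] = a0r * u0
        Anew[idn] = a1r
        Qnew[idn] = a1r * u1
        st_qprev[j] = a0r * u0

    # Windkessel outlets
    no = out_seg.shape[0]
    q_term = np.empty(no)
    for j in range(no):
        s = out_seg[j]
        i = seg_first[s] + seg_n[s] - 1
        w1 = _w_foot(A, Q, seg_first[s], seg_n[s], seg_dx[s],
                     seg_beta[s], rho, dt, True)
        a, ok = _outlet_newton(w1, seg_beta[s], seg_a0[s], A[i],
                               out_r1[j], out_pc[j], rho, p0)
        if not ok:
            return ERR_NEWTON
        u = w1 - 4.0 * _cwave(a, seg_beta[s], rho)
        Anew[i] = a
        Qnew[i] = a * u
        q_term[j] = a * u

    # heart inlet
    s = inlet_seg
    i0 = seg_first[s]
    w2 = _w_foot(A, Q, seg_first[s], seg_n[s], seg_dx[s],
                 seg_beta[s], rho, dt, False)
    tc = hp[11]
    p_lv = _elastance(t, tc, hp[0], hp[1], 0.0, hp[6]) * (heart_state[1] - hp[2])
    a, q_in, ok = _inlet_solve(w2, seg_beta[s], seg_a0[s], A[i0],
                               p_lv, hp[10], rho, p0)
    if not ok:
        return ERR_NEWTON
    Anew[i0] = a
    Qnew[i0] = q_in

    # 0D advance with frozen boundary couplings; sub-stepped because the
    # open-valve chamber dynamics can be stiffer than the CFL time step
    nsub = int(dt / 2.0e-4) + 1
    _rk4_0d(t, dt / nsub, nsub, out_pc, blk_p1, blk_q2, heart_state,
            q_term, q_in, out_r2, out_c, out_blk, blk_r, blk_l, blk_c, hp)

    nn = A.shape[0]
    for i in range(nn):
        if not (np.isfinite(Anew[i]) and np.isfinite(Qnew[i])) or Anew[i] <= 0.0:
            return ERR_NONFINITE
        A[i] = Anew[i]
        Q[i] = Qnew[i]
    return OK


@njit(cache=True)
def run_steps(t0, dt, n_steps, A, Q, seg_first, seg_n, seg_dx, seg_beta,
              seg_a0, jn_ptr, jn_seg, jn_dist,
              st_u, st_d, st_rv, st_k2, st_k3, st_qprev,
              out_seg, out_r1, out_r2, out_c, out_blk, out_pc,
              blk_r, blk_l, blk_c, blk_p1, blk_q2,
              heart_state, hp, inlet_seg, rho, kr, p0,
              sum_q, sum_p, sum_dyn, rec_nodes, rec_every, rec_a, rec_q):
    """Run ``n_steps`` steps, accumulating per-node sums of Q, static
    pressure and dynamic pressure 0.5*rho*(Q/A)^2 (for cycle averages) and
    optionally recording waveforms at ``rec_nodes`` every ``rec_every``
    steps.  Returns (error code, steps completed)."""
    nn = A.shape[0]
    Anew = np.empty(nn)
    Qnew = np.empty(nn)
    nseg = seg_first.shape[0]
    for i in range(nn):
        sum_q[i] = 0.0
        sum_p[i] = 0.0
        sum_dyn[i] = 0.0
    irec = 0
    for it in range(n_steps):
        t = t0 + it * dt
        code = step(t, dt, A, Q, seg_first, seg_n, seg_dx, seg_beta, seg_a0,
                    jn_ptr, jn_seg, jn_dist,
                    st_u, st_d, st_rv, st_k2, st_k3, st_qprev,
                    out_seg, out_r1, out_r2, out_c, out_blk, out_pc,
                    blk_r, blk_l, blk_c, blk_p1, blk_q2,
                    heart_state, hp, inlet_seg, rho, kr, p0, Anew, Qnew)
        if code != OK:
            return code, it
        for i in range(nn):
            sum_q[i] += Q[i]
            u = Q[i] / A[i]
            sum_dyn[i] += 0.5 * rho * u * u
        for s in range(nseg):
            for k in range(seg_n[s]):
                i = seg_first[s] + k
                sum_p[i] += _pres(A[i], seg_beta[s], seg_a0[s], p0)
        if rec_every > 0 and it % rec_every == 0 and irec < rec_a.shape[0]:
            for k in range(rec_nodes.shape[0]):
                rec_a[irec, k] = A[rec_nodes[k]]
                rec_q[irec, k] = Q[rec_nodes[k]]
            irec += 1
    return OK, n_steps


@njit(cache=True)
def max_wave_speed(A, Q, seg_first, seg_n, seg_beta, rho):
    m = 0.0
    for s in range(seg_first.shape[0]):
        for k in range(seg_n[s]):
            i = seg_first[s] + k
            v = abs(Q[i] / A[i]) + _cwave(A[i], seg_beta[s], rho)
            if v > m:
                m = v
    return m
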