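"""Numba-compiled event loops for the spatial SSA and the hybrid method.

The hybrid replicate kernel advances a full trajectory: per step it draws the
next reaction time from the survival function P_R(t) (integrated propensities
along the mean diffusion trajectory), splits the domain into a Gaussian-flux
region and an SSA region per diffusive species, samples the correlated
Gaussian diffusion update, simulates low-copy diffusion and the chosen
reaction with the SSA, rounds to non-negative integers, and repeats.

Gaussian sampling detail: the per-edge flux fluctuation vector Xi (covariance
rho, the edge-space Lyapunov/integral form) enters the state update only
through (i) the net-flux combinations w = N Xi per compartment (N the signed
incidence map) and (ii) the individual fluxes of the few edges crossing the
region interface.  (w, Xi_interface) is itself a linear Ito system driven by
the same noise:

    dw/dt     = L w + N eta,        d xi_e/dt = r w_src(e) + eta_e,

so its covariance obeys a (K + n_interface)-dimensional Lyapunov ODE with the
lattice Laplacian L.  Sampling that reduced Gaussian is distribution-identical
to sampling the (2K-2)-dimensional rho submatrix and projecting, at a fraction
of the cost.  The equivalence against the explicit edge-space route is
exercised in the test suite.

All randomness uses numba's per-thread NumPy legacy generator; each replicate
seeds it once, making trajectories bit-reproducible.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# diagnostics slots for the hybrid kernel
DIAG_STEPS = 0
DIAG_REACTIONS = 1
DIAG_NOREACT = 2
DIAG_CLAMP_LOSS = 3
DIAG_ROUND_NET = 4
DIAG_SSA_FALLBACK = 5
DIAG_PSD_REPAIR = 6
N_DIAG = 7


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _ff(x, s):
    """Falling factorial x(x-1)...(x-s+1), clamped to 0 for x < s."""
    v = 1.0
    for m in range(s):
        f = x - m
        if f <= 0.0:
            return 0.0
        v *= f
    return v


@njit(cache=True, inline="always")
def _reaction_prop(X, k, r, stoich, pref):
    a = pref[k, r]
    if a == 0.0:
        return 0.0
    for i in range(stoich.shape[1]):
        s = stoich[r, i]
        if s > 0:
            a *= _ff(X[k, i], s)
            if a == 0.0:
                return 0.0
    return a


@njit(cache=True, inline="always")
def _comp_prop(X, k, stoich, pref, jumpw):
    tot = 0.0
    for r in range(pref.shape[1]):
        tot += _reaction_prop(X, k, r, stoich, pref)
    for i in range(jumpw.shape[1]):
        if jumpw[k, i] > 0.0:
            tot += jumpw[k, i] * X[k, i]
    return tot


# ---------------------------------------------------------------------------
# spatial SSA (direct method, per-compartment propensity groups)
# ---------------------------------------------------------------------------


@njit(cache=True)
def ssa_kernel(X, t_start, sample_times, stoich, net, pref, jump_rate, jumpw,
               nbr, nbr_cnt):
    """Exact direct-method SSA over all reaction and jump channels.

    ``X`` (K, S) float64 with integral values, modified in place.  Snapshots
    (state after the last event at or before each sample time) are returned
    as (nT, K, S).  Also returns the total clamped mass (mixed-Lambda
    reactions may overdraw a high-Lambda species; see model docs).
    """
    K, S = X.shape
    R = pref.shape[1]
    nT = sample_times.shape[0]
    out = np.empty((nT, K, S), np.float64)
    clamp_loss = 0.0

    comp_a = np.empty(K)
    for k in range(K):
        comp_a[k] = _comp_prop(X, k, stoich, pref, jumpw)
    a_tot = comp_a.sum()

    t = t_start
    si = 0
    ev = 0
    while si < nT:
        if a_tot <= 1e-300:
            while si < nT:
                out[si] = X
                si += 1
            break
        dt = -math.log(1.0 - np.random.random()) / a_tot
        t_next = t + dt
        while si < nT and sample_times[si] < t_next:
            out[si] = X
            si += 1
        if si >= nT:
            break
        t = t_next

        # select compartment, then channel within it
        u = np.random.random() * a_tot
        k = K - 1
        acc = 0.0
        for kk in range(K):
            acc += comp_a[kk]
            if u < acc:
                k = kk
                break
        u -= acc - comp_a[k]
        if u < 0.0:
            u = 0.0

        fired_jump_to = -1
        jump_sp = -1
        acc = 0.0
        chosen_r = -1
        for r in range(R):
            acc += _reaction_prop(X, k, r, stoich, pref)
            if u < acc:
                chosen_r = r
                break
        if chosen_r < 0:
            u -= acc
            for i in range(S):
                w = jumpw[k, i]
                if w > 0.0:
                    blk = w * X[k, i]
                    if u < blk:
                        per = jump_rate[i] * X[k, i]
                        j = int(u / per)
                        if j >= nbr_cnt[k]:
                            j = nbr_cnt[k] - 1
                        jump_sp = i
                        fired_jump_to = nbr[k, j]
                        break
                    u -= blk
            if jump_sp < 0:
                # numerical slack: re-draw next iteration
                continue

        if chosen_r >= 0:
            for i in range(S):
                X[k, i] += net[chosen_r, i]
                if X[k, i] < 0.0:
                    clamp_loss += -X[k, i]
                    X[k, i] = 0.0
            old = comp_a[k]
            comp_a[k] = _comp_prop(X, k, stoich, pref, jumpw)
            a_tot += comp_a[k] - old
        else:
            nb = fired_jump_to
            X[k, jump_sp] -= 1.0
            X[nb, jump_sp] += 1.0
            old = comp_a[k] + comp_a[nb]
            comp_a[k] = _comp_prop(X, k, stoich, pref, jumpw)
            comp_a[nb] = _comp_prop(X, nb, stoich, pref, jumpw)
            a_tot += comp_a[k] + comp_a[nb] - old

        ev += 1
        if ev % 1024 == 0:
            a_tot = comp_a.sum()
    return out, clamp_loss


@njit(cache=True)
def diffuse_ssa(x, dt, rj, esrc, etgt, counts, record_counts):
    """Diffusion-only SSA for one species on an explicit active-edge list.

    ``x`` (K,) float64 counts, modified in place; only compartments incident
    to the given edges can change, so the per-region total is conserved
    exactly.  When ``record_counts`` the number of firings per edge is
    accumulated into ``counts``.
    """
    nE = esrc.shape[0]
    if nE == 0 or dt <= 0.0:
        return
    t = 0.0
    while True:
        a_tot = 0.0
        for e in range(nE):
            a_tot += x[esrc[e]]
        a_tot *= rj
        if a_tot <= 1e-300:
            return
        t += -math.log(1.0 - np.random.random()) / a_tot
        if t > dt:
            return
        u = np.random.random() * a_tot / rj
        chosen = nE - 1
        acc = 0.0
        for e in range(nE):
            acc += x[esrc[e]]
            if u < acc:
                chosen = e
                break
        x[esrc[chosen]] -= 1.0
        x[etgt[chosen]] += 1.0
        if record_counts:
            counts[chosen] += 1.0


# ---------------------------------------------------------------------------
# hybrid method helpers
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _m_at(U, lam0, chat, rtau):
    """Mean concentration profile m(tau) = U exp(lam0 r tau) U' c0."""
    K = lam0.shape[0]
    w = np.empty(K)
    for i in range(K):
        w[i] = math.exp(lam0[i] * rtau) * chat[i]
    return np.dot(U, w)


@njit(cache=True)
def _fill_displaced(Xd, X, dspec, rr, lam, U, lam0, chats, tau):
    """Displaced counts along the mean diffusion trajectory at offset tau."""
    K = X.shape[0]
    for d in range(dspec.shape[0]):
        sp = dspec[d]
        m = _m_at(U, lam0, chats[d], rr[d] * tau)
        for k in range(K):
            v = lam[sp] * m[k]
            Xd[k, sp] = v if v > 0.0 else 0.0


@njit(cache=True)
def _mean_traj_nodes(U, lam0, chat, r, dt, nq):
    """m(tau_q) for the nq trapezoid nodes on [0, dt], as a (K, nq) matrix."""
    K = lam0.shape[0]
    W = np.empty((K, nq))
    hq = dt / (nq - 1)
    for i in range(K):
        f = math.exp(r * lam0[i] * hq)
        v = chat[i]
        W[i, 0] = v
        for q in range(1, nq):
            v *= f
            W[i, q] = v
    return np.dot(U, W)


@njit(cache=True)
def _total_prop(Xd, stoich, pref):
    tot = 0.0
    for k in range(pref.shape[0]):
        for r in range(pref.shape[1]):
            tot += _reaction_prop(Xd, k, r, stoich, pref)
    return tot


@njit(cache=True)
def _cum_prop(dt, nq, X, Xd, dspec, rr, lam, U, lam0, chats, stoich, pref):
    """Trapezoid integral of the total propensity along the mean trajectory.

    Returns (integral over [0, dt], integrand at dt).
    """
    nd = dspec.shape[0]
    K = X.shape[0]
    if dt <= 0.0:
        _fill_displaced(Xd, X, dspec, rr, lam, U, lam0, chats, 0.0)
        a0 = _total_prop(Xd, stoich, pref)
        return 0.0, a0
    hq = dt / (nq - 1)
    tot = 0.0
    a_end = 0.0
    Ms = np.empty((nd, K, nq))
    for d in range(nd):
        Ms[d] = _mean_traj_nodes(U, lam0, chats[d], rr[d], dt, nq)
    for q in range(nq):
        for d in range(nd):
            sp = dspec[d]
            for k in range(K):
                v = lam[sp] * Ms[d, k, q]
                Xd[k, sp] = v if v > 0.0 else 0.0
        a = _total_prop(Xd, stoich, pref)
        if q == 0 or q == nq - 1:
            tot += 0.5 * a
        else:
            tot += a
        if q == nq - 1:
            a_end = a
    return tot * hq, a_end


@njit(cache=True)
def _abar_matrix(dt, nq, X, Xd, dspec, rr, lam, U, lam0, chats, stoich, pref,
                 abar):
    """Integrated propensities abar[k, r] over [0, dt] (composite trapezoid)."""
    K, R = pref.shape
    nd = dspec.shape[0]
    abar[:, :] = 0.0
    if dt <= 0.0:
        return
    hq = dt / (nq - 1)
    Ms = np.empty((nd, K, nq))
    for d in range(nd):
        Ms[d] = _mean_traj_nodes(U, lam0, chats[d], rr[d], dt, nq)
    for q in range(nq):
        for d in range(nd):
            sp = dspec[d]
            for k in range(K):
                v = lam[sp] * Ms[d, k, q]
                Xd[k, sp] = v if v > 0.0 else 0.0
        w = 0.5 * hq if (q == 0 or q == nq - 1) else hq
        for k in range(K):
            for r in range(R):
                abar[k, r] += w * _reaction_prop(Xd, k, r, stoich, pref)


@njit(cache=True)
def _phi_edges(dt, rr_d, U, lam0, chat, src):
    """Cumulative mean flux phi_e(dt) = r * int_0^dt m_src(e) dtau per edge."""
    K = lam0.shape[0]
    g = np.empty(K)
    for i in range(K):
        z = rr_d * lam0[i]
        if abs(z) < 1e-13:
            g[i] = dt
        else:
            g[i] = (math.exp(z * dt) - 1.0) / z
        g[i] *= chat[i]
    J = np.dot(U, g)  # int_0^dt m(tau) dtau per compartment
    E = src.shape[0]
    phi = np.empty(E)
    for e in range(E):
        phi[e] = rr_d * J[src[e]]
    return phi


@njit(cache=True)
def _augmented_lyapunov(dt, rr_d, U, lam0, chat, nbr, nbr_cnt,
                        bsrc, btgt, lam0_min):
    """Covariance of (w, xi_interface) at dt via fixed-step RK4.

    w = N Xi is the per-compartment net flux fluctuation; the extra slots
    track the flux fluctuation of the listed interface edges.  Substep count
    follows the spectral radius of the diffusion generator, keeping the RK4
    error orders of magnitude below the statistical scales involved (the
    scheme is validated against the adaptively integrated edge-space
    covariance in the test suite).
    """
    K = lam0.shape[0]
    nb = bsrc.shape[0]
    dim = K + nb
    Sig = np.zeros((dim, dim))
    nsub = int(math.ceil(rr_d * abs(lam0_min) * dt / 0.4))
    if nsub < 2:
        nsub = 2
    hsub = dt / nsub

    P = np.empty((dim, dim))
    D1 = np.empty((dim, dim))
    D2 = np.empty((dim, dim))
    D3 = np.empty((dim, dim))
    Stmp = np.empty((dim, dim))

    m0 = _m_at(U, lam0, chat, 0.0)
    for s in range(nsub):
        t0 = s * hsub
        mh = _m_at(U, lam0, chat, rr_d * (t0 + 0.5 * hsub))
        m1 = _m_at(U, lam0, chat, rr_d * (t0 + hsub))
        _lyap_rhs(Sig, m0, rr_d, nbr, nbr_cnt, bsrc, btgt, P, D1)
        for i in range(dim):
            for j in range(dim):
                Stmp[i, j] = Sig[i, j] + 0.5 * hsub * D1[i, j]
        _lyap_rhs(Stmp, mh, rr_d, nbr, nbr_cnt, bsrc, btgt, P, D2)
        for i in range(dim):
            for j in range(dim):
                Stmp[i, j] = Sig[i, j] + 0.5 * hsub * D2[i, j]
                D1[i, j] += 2.0 * D2[i, j]
        _lyap_rhs(Stmp, mh, rr_d, nbr, nbr_cnt, bsrc, btgt, P, D3)
        for i in range(dim):
            for j in range(dim):
                Stmp[i, j] = Sig[i, j] + hsub * D3[i, j]
                D1[i, j] += 2.0 * D3[i, j]
        _lyap_rhs(Stmp, m1, rr_d, nbr, nbr_cnt, bsrc, btgt, P, D2)
        c = hsub / 6.0
        for i in range(dim):
            for j in range(dim):
                Sig[i, j] += c * (D1[i, j] + D2[i, j])
        m0 = m1
    # symmetrize against accumulated drift
    for i in range(dim):
        for j in range(i):
            v = 0.5 * (Sig[i, j] + Sig[j, i])
            Sig[i, j] = v
            Sig[j, i] = v
    return Sig


@njit(cache=True, inline="always")
def _lyap_rhs(Sig, m, rr_d, nbr, nbr_cnt, bsrc, btgt, P, out):
    """out = Atil Sig + (Atil Sig)' + Qtil(m) for the augmented system.

    Atil rows 0..K-1 are the lattice Laplacian, row K+b picks the source
    compartment of interface edge b; P is workspace.  Row operations are
    unit-stride so the compiler can vectorize them.
    """
    K = nbr.shape[0]
    nb = bsrc.shape[0]
    dim = K + nb
    # P = Atil @ Sig
    for c in range(K):
        deg = nbr_cnt[c]
        for j in range(dim):
            P[c, j] = -deg * Sig[c, j]
        for q in range(deg):
            d = nbr[c, q]
            for j in range(dim):
                P[c, j] += Sig[d, j]
        for j in range(dim):
            P[c, j] *= rr_d
    for b in range(nb):
        sb = bsrc[b]
        for j in range(dim):
            P[K + b, j] = rr_d * Sig[sb, j]
    for i in range(dim):
        for j in range(dim):
            out[i, j] = P[i, j] + P[j, i]
    # Qtil: compartment block
    for c in range(K):
        deg = nbr_cnt[c]
        mc = m[c] if m[c] > 0.0 else 0.0
        acc = deg * mc
        for q in range(deg):
            d = nbr[c, q]
            md = m[d] if m[d] > 0.0 else 0.0
            acc += md
            out[c, d] -= rr_d * (mc + md)
        out[c, c] += rr_d * acc
    # cross and interface blocks
    for b in range(nb):
        sb = bsrc[b]
        tb = btgt[b]
        msb = m[sb] if m[sb] > 0.0 else 0.0
        bb = rr_d * msb
        out[sb, K + b] -= bb
        out[K + b, sb] -= bb
        out[tb, K + b] += bb
        out[K + b, tb] += bb
        out[K + b, K + b] += bb


@njit(cache=True)
def _try_cholesky(A, L):
    """In-place lower Cholesky of A into L; False if not positive definite."""
    n = A.shape[0]
    for i in range(n):
        for j in range(i + 1):
            s = A[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                if s <= 0.0:
                    return False
                L[i, i] = math.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
    return True


@njit(cache=True)
def _sample_gaussian(Sig, repair_tol):
    """Draw N(0, Sig); Cholesky with a tiny diagonal jitter, eigendecomposition
    with PSD clipping as the fallback.

    Returns (draw, n_repaired) where n_repaired counts eigenvalues below
    -repair_tol * max_eig that had to be clipped.
    """
    dim = Sig.shape[0]
    z = np.empty(dim)
    for i in range(dim):
        z[i] = np.random.standard_normal()
    maxd = 0.0
    for i in range(dim):
        if Sig[i, i] > maxd:
            maxd = Sig[i, i]
    L = np.zeros((dim, dim))
    jitter = 1e-12 * maxd + 1e-300
    A = Sig.copy()
    for _ in range(2):
        for i in range(dim):
            A[i, i] = Sig[i, i] + jitter
        if _try_cholesky(A, L):
            v = np.empty(dim)
            for i in range(dim):
                s = 0.0
                for k in range(i + 1):
                    s += L[i, k] * z[k]
                v[i] = s
            return v, 0
        jitter *= 1e4
    evals, evecs = np.linalg.eigh(Sig)
    top = evals[dim - 1] if evals[dim - 1] > 0.0 else 0.0
    bad = 0
    w = np.empty(dim)
    for i in range(dim):
        ev = evals[i]
        if ev < -repair_tol * top - 1e-300:
            bad += 1
            ev = 0.0
        elif ev < 0.0:
            ev = 0.0
        w[i] = math.sqrt(ev) * z[i]
    return np.dot(evecs, w), bad


# ---------------------------------------------------------------------------
# hybrid replicate kernel
# ---------------------------------------------------------------------------


@njit(cache=True)
def hybrid_kernel(X, t_start, sample_times,
                  stoich, net, pref, lam,
                  src, tgt, U, lam0, xcol, Kx,
                  nbr, nbr_cnt,
                  dspec, rr, dmode,
                  TA, nq, root_tol, max_step, repair_tol,
                  kg_trace, dt_trace):
    """One hybrid-method trajectory; X (K, S) float64 modified in place.

    ``dmode`` per diffusive species: 0 monotone cut-off, 1 central-peak
    interval, 2 Gaussian everywhere, 3 SSA everywhere.  ``kg_trace``
    (cap, nd, 2) and ``dt_trace`` (cap,) record the first ``cap`` steps'
    Gaussian column ranges (0-based, inclusive; [1, 0] = empty) and step
    sizes.  Returns (snapshots, diagnostics).
    """
    K, S = X.shape
    R = pref.shape[1]
    nd = dspec.shape[0]
    E = src.shape[0]
    nT = sample_times.shape[0]
    out = np.empty((nT, K, S), np.float64)
    diag = np.zeros(N_DIAG)
    trace_cap = dt_trace.shape[0]

    Xd = np.empty((K, S))
    chats = np.empty((nd, K))
    abar = np.empty((K, R))
    Ut = U.T.copy()
    lam0_min = lam0[0]
    for i in range(K):
        if lam0[i] < lam0_min:
            lam0_min = lam0[i]

    # column aggregation buffers
    colL = np.empty(Kx)
    colR = np.empty(Kx)

    t = t_start
    si = 0
    while si < nT and sample_times[si] <= t + 1e-12:
        out[si] = X
        si += 1

    while si < nT:
        cap = sample_times[si]
        remaining = cap - t
        if remaining <= 1e-12 * (1.0 + abs(cap)):
            out[si] = X
            si += 1
            continue
        step_cap = remaining if remaining < max_step else max_step
        at_sample_cap = step_cap >= remaining * (1.0 - 1e-12)

        # mean-trajectory coefficients from the state at step start
        for d in range(nd):
            sp = dspec[d]
            c0 = np.ascontiguousarray(X[:, sp]) / lam[sp]
            chats[d] = np.dot(Ut, c0)
        for k in range(K):
            for i in range(S):
                Xd[k, i] = X[k, i]

        # --- steps 1-2: draw the next reaction time from P_R ---
        no_rx = True
        dt = step_cap
        if R > 0:
            r1 = 1.0 - np.random.random()
            target = -math.log(r1)
            if target > 0.0:
                # bracket from the constant-propensity guess target/a_tot(t0),
                # doubling until the cumulative integral reaches the target
                _, a0 = _cum_prop(0.0, nq, X, Xd, dspec, rr, lam, U, lam0,
                                  chats, stoich, pref)
                lo = 0.0
                Glo = 0.0
                hi = step_cap
                if a0 > 0.0:
                    h0 = target / a0
                    if h0 < step_cap:
                        hi = h0
                Ghi, _ = _cum_prop(hi, nq, X, Xd, dspec, rr, lam, U, lam0,
                                   chats, stoich, pref)
                while Ghi < target and hi < step_cap:
                    lo = hi
                    Glo = Ghi
                    hi = hi * 2.0
                    if hi > step_cap:
                        hi = step_cap
                    Ghi, _ = _cum_prop(hi, nq, X, Xd, dspec, rr, lam,
                                       U, lam0, chats, stoich, pref)
                if Ghi >= target:
                    # safeguarded Newton between brackets
                    no_rx = False
                    x_r = lo + (hi - lo) * ((target - Glo) / (Ghi - Glo)
                                            if Ghi > Glo else 0.5)
                    for _ in range(80):
                        if hi - lo <= root_tol * hi:
                            break
                        Gx, ax = _cum_prop(x_r, nq, X, Xd, dspec, rr, lam, U,
                                           lam0, chats, stoich, pref)
                        if Gx >= target:
                            hi = x_r
                            Ghi = Gx
                        else:
                            lo = x_r
                            Glo = Gx
                        if ax > 0.0:
                            xn = x_r + (target - Gx) / ax
                        else:
                            xn = 0.5 * (lo + hi)
                        if xn <= lo or xn >= hi:
                            xn = 0.5 * (lo + hi)
                        x_r = xn
                    dt = 0.5 * (lo + hi)
                    if dt <= 0.0:
                        dt = root_tol * step_cap

        # --- step 3: diffusion update per diffusive species ---
        for d in range(nd):
            sp = dspec[d]
            mode = dmode[d]
            if E == 0:
                break
            phi = _phi_edges(dt, rr[d], U, lam0, chats[d], src)
            # Gaussian column range [g1, g2] inclusive; empty if g1 > g2
            if mode == 3:
                g1, g2 = 1, 0
            elif mode == 2:
                g1, g2 = 0, Kx - 1
            else:
                for ix in range(Kx):
                    colL[ix] = 0.0
                    colR[ix] = 0.0
                for e in range(E):
                    cs = xcol[src[e]]
                    ct = xcol[tgt[e]]
                    if ct == cs - 1:
                        colL[cs] += lam[sp] * phi[e]
                    elif ct == cs + 1:
                        colR[cs] += lam[sp] * phi[e]
                if mode == 0:
                    g1 = 0
                    g0 = Kx
                    for ix in range(Kx):
                        failL = ix > 0 and colL[ix] <= TA
                        failR = ix < Kx - 1 and colR[ix] <= TA
                        if failL or failR:
                            g0 = ix
                            break
                    g2 = g0 - 1
                else:
                    # central peak: largest interval around the flux peak
                    peak = 0
                    best = -1.0
                    for ix in range(Kx):
                        v = colL[ix] if colL[ix] > colR[ix] else colR[ix]
                        if v > best:
                            best = v
                            peak = ix
                    okp = ((peak > 0 and colL[peak] > TA)
                           or (peak < Kx - 1 and colR[peak] > TA))
                    if not okp:
                        g1, g2 = 1, 0
                    else:
                        g1 = peak
                        while g1 > 0:
                            ix = g1 - 1
                            ok = ((ix > 0 and colL[ix] > TA)
                                  or (ix < Kx - 1 and colR[ix] > TA))
                            if ok:
                                g1 = ix
                            else:
                                break
                        g2 = peak
                        while g2 < Kx - 1:
                            ix = g2 + 1
                            ok = ((ix > 0 and colL[ix] > TA)
                                  or (ix < Kx - 1 and colR[ix] > TA))
                            if ok:
                                g2 = ix
                            else:
                                break
            if diag[DIAG_STEPS] < trace_cap:
                kg_trace[int(diag[DIAG_STEPS]), d, 0] = g1
                kg_trace[int(diag[DIAG_STEPS]), d, 1] = g2

            x = X[:, sp].copy()
            if g1 > g2:
                # SSA everywhere for this species
                diag[DIAG_SSA_FALLBACK] += 1.0
                cnt = np.empty(0)
                diffuse_ssa(x, dt, rr[d], src, tgt, cnt, False)
                X[:, sp] = x
                continue

            if mode != 2 and (g1 > 0 or g2 < Kx - 1):
                # simulate the SSA region (columns outside [g1, g2]);
                # interface columns act as reflective walls
                na = 0
                for e in range(E):
                    if not (g1 <= xcol[src[e]] <= g2) and \
                       not (g1 <= xcol[tgt[e]] <= g2):
                        na += 1
                esrc_a = np.empty(na, np.int64)
                etgt_a = np.empty(na, np.int64)
                j = 0
                for e in range(E):
                    if not (g1 <= xcol[src[e]] <= g2) and \
                       not (g1 <= xcol[tgt[e]] <= g2):
                        esrc_a[j] = src[e]
                        etgt_a[j] = tgt[e]
                        j += 1
                cnt = np.empty(0)
                diffuse_ssa(x, dt, rr[d], esrc_a, etgt_a, cnt, False)

            # interface edges: det = into the Gaussian region (mean applied),
            # bnd = out of the Gaussian region (sampled jointly)
            ndet = 0
            nbnd = 0
            for e in range(E):
                ing_s = g1 <= xcol[src[e]] <= g2
                ing_t = g1 <= xcol[tgt[e]] <= g2
                if ing_s and not ing_t:
                    nbnd += 1
                elif ing_t and not ing_s:
                    ndet += 1
            nb = ndet + nbnd
            bsrc = np.empty(nb, np.int64)
            btgt = np.empty(nb, np.int64)
            bphi = np.empty(nb)
            jd = 0
            jb = ndet
            for e in range(E):
                ing_s = g1 <= xcol[src[e]] <= g2
                ing_t = g1 <= xcol[tgt[e]] <= g2
                if ing_t and not ing_s:
                    bsrc[jd] = src[e]
                    btgt[jd] = tgt[e]
                    bphi[jd] = phi[e]
                    jd += 1
                elif ing_s and not ing_t:
                    bsrc[jb] = src[e]
                    btgt[jb] = tgt[e]
                    bphi[jb] = phi[e]
                    jb += 1

            Sig = _augmented_lyapunov(dt, rr[d], U, lam0, chats[d],
                                      nbr, nbr_cnt, bsrc, btgt, lam0_min)
            v, bad = _sample_gaussian(Sig, repair_tol)
            diag[DIAG_PSD_REPAIR] += bad

            # net mean flux per compartment (all edges)
            nphi = np.zeros(K)
            for e in range(E):
                nphi[src[e]] -= phi[e]
                nphi[tgt[e]] += phi[e]

            sqlam = math.sqrt(lam[sp])
            for c in range(K):
                if g1 <= xcol[c] <= g2:
                    noise = v[c]
                    for b in range(ndet):
                        if btgt[b] == c:
                            noise -= v[K + b]
                    x[c] += lam[sp] * nphi[c] + sqlam * noise
            for b in range(ndet):
                x[bsrc[b]] -= lam[sp] * bphi[b]
            for b in range(ndet, nb):
                x[btgt[b]] += lam[sp] * bphi[b] + sqlam * v[K + b]

            # round to nearest non-negative integers (SSA-region entries are
            # already integral, so this only affects the Gaussian update)
            for c in range(K):
                raw = x[c]
                if raw < 0.0:
                    diag[DIAG_CLAMP_LOSS] += -raw
                    x[c] = 0.0
                else:
                    rv = math.floor(raw + 0.5)
                    diag[DIAG_ROUND_NET] += rv - raw
                    x[c] = rv
            X[:, sp] = x

        # --- step 4: fire the selected reaction ---
        if not no_rx:
            _abar_matrix(dt, nq, X, Xd, dspec, rr, lam, U, lam0, chats,
                         stoich, pref, abar)
            tot = 0.0
            for k in range(K):
                for r in range(R):
                    tot += abar[k, r]
            if tot > 0.0:
                r2 = np.random.random()
                thresh = r2 * tot
                acc = 0.0
                q_sel = K - 1
                r_sel = R - 1
                done = False
                for k in range(K):
                    for r in range(R):
                        acc += abar[k, r]
                        if acc >= thresh:
                            q_sel = k
                            r_sel = r
                            done = True
                            break
                    if done:
                        break
                for i in range(S):
                    X[q_sel, i] += net[r_sel, i]
                    if X[q_sel, i] < 0.0:
                        diag[DIAG_CLAMP_LOSS] += -X[q_sel, i]
                        X[q_sel, i] = 0.0
                diag[DIAG_REACTIONS] += 1.0
        else:
            diag[DIAG_NOREACT] += 1.0

        if diag[DIAG_STEPS] < trace_cap:
            dt_trace[int(diag[DIAG_STEPS])] = dt
        diag[DIAG_STEPS] += 1.0

        # --- step 5: advance time, record samples ---
        if no_rx and at_sample_cap and dt >= step_cap * (1.0 - 1e-12):
            t = cap
        else:
            t = t + dt
        while si < nT and sample_times[si] <= t + 1e-9 * (1.0 + abs(t)):
            out[si] = X
            si += 1

    return out, diag
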