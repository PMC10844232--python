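"""Numba kernels: diabatic matrix evaluation and surface-hopping propagation.

Two diabatic models are compiled:

``MODEL_CHROMO`` (0)
    The 3-state (|P>, |I>, |B>) chromophore model over 4 reduced coordinates
    (phi_P, phi_I, theta_hoop, bla), parametrized by the packed vector of
    :data:`chromodyn.params.PARAM_FIELDS`.

``MODEL_LINEAR`` (1)
    A 1-D two-state linear-crossing model with constant diabatic coupling,
    ``H = [[a1*x, c], [c, a2*x]]`` with packed parameters ``[a1, a2, c]``.
    Used for validating the hopping algorithm against exact quantum dynamics.

All energies are in eV, lengths in Å, angles in rad, time in fs.  Masses
passed to the propagator must already be multiplied by ``AMU_TO_EV`` so that
kinetic energy is ``0.5 * m * v**2`` in eV.
"""

import numpy as np
from numba import njit

from .units import AMU_TO_EV, HBAR_EV_FS

MODEL_CHROMO = 0
MODEL_LINEAR = 1

HBAR = HBAR_EV_FS

# status codes returned by fssh_run
STATUS_MAX_TIME = 0
STATUS_S0_DONE = 1
STATUS_ENERGY_VIOLATION = 2


@njit(cache=True)
def model_dims(model):
    if model == MODEL_CHROMO:
        return 3, 4
    return 2, 1


@njit(cache=True)
def eval_model(model, p, q, H, dH):
    """Fill the diabatic matrix H (n,n) and its gradient dH (nc,n,n)."""
    if model == MODEL_CHROMO:
        phiP = q[0]
        phiI = q[1]
        th = q[2]
        r = q[3]
        sinP = np.sin(phiP)
        sinI = np.sin(phiI)
        cosP = np.cos(phiP)
        cosI = np.cos(phiI)
        # exact decoupling at 90° twists (cos(pi/2) rounds to ~6e-17)
        if abs(cosP) < 1e-14:
            cosP = 0.0
        if abs(cosI) < 1e-14:
            cosI = 0.0
        sP = sinP * sinP
        sI = sinI * sinI
        s2P = np.sin(2.0 * phiP)
        s2I = np.sin(2.0 * phiI)
        u4P = np.sin(4.0 * phiP)
        u4I = np.sin(4.0 * phiI)
        uP = s2P * s2P
        uI = s2I * s2I
        th2 = th * th
        s4I = sI * sI
        s8I = s4I * s4I
        sin7I = s4I * sI * sinI
        # one-sided Z/E twist asymmetry: ~0 on the Z side of the I-torsion,
        # destabilizes the E-side approach; exactly 0 at planar, 90° and 180°
        eps = 0.05
        root = np.sqrt(cosI * cosI + eps * eps)
        tau = 0.5 * p[27] * s8I * (root - cosI - eps)
        dtau_dI = 0.5 * p[27] * (
            8.0 * sin7I * cosI * (root - cosI - eps)
            + s8I * (1.0 - cosI / root) * sinI)
        conj = p[20] * uP + p[21] * uI + tau
        dconj_dP = 2.0 * p[20] * u4P
        dconj_dI = 2.0 * p[21] * u4I + dtau_dI

        eP = (p[0] + p[3] * sP + p[4] * sI
              + 0.5 * p[13] * (r - p[14]) ** 2
              + 0.5 * p[12] * th2 - p[10] * sI * th2 + conj - p[26])
        eI = (p[1] + p[5] * sP + p[6] * sI + 0.5 * p[9] * (1.0 - cosI)
              + 0.5 * p[13] * (r - p[15]) ** 2
              + 0.5 * p[12] * th2 - p[11] * sP * th2 + conj - p[26])
        eB = (p[2] + p[7] * sP + p[8] * sI
              + 0.5 * p[13] * (r - p[16]) ** 2
              + 0.5 * p[12] * th2 + conj - p[26])
        vPI = p[17] * cosP * cosI
        vPB = p[18] * cosP
        vIB = p[19] * cosI

        H[0, 0] = eP
        H[1, 1] = eI
        H[2, 2] = eB
        H[0, 1] = vPI
        H[1, 0] = vPI
        H[0, 2] = vPB
        H[2, 0] = vPB
        H[1, 2] = vIB
        H[2, 1] = vIB

        dH[:, :, :] = 0.0
        # d/dphi_P
        dH[0, 0, 0] = p[3] * s2P + dconj_dP
        dH[0, 1, 1] = p[5] * s2P - p[11] * s2P * th2 + dconj_dP
        dH[0, 2, 2] = p[7] * s2P + dconj_dP
        dH[0, 0, 1] = -p[17] * sinP * cosI
        dH[0, 1, 0] = dH[0, 0, 1]
        dH[0, 0, 2] = -p[18] * sinP
        dH[0, 2, 0] = dH[0, 0, 2]
        # d/dphi_I
        dH[1, 0, 0] = p[4] * s2I - p[10] * s2I * th2 + dconj_dI
        dH[1, 1, 1] = p[6] * s2I + 0.5 * p[9] * sinI + dconj_dI
        dH[1, 2, 2] = p[8] * s2I + dconj_dI
        dH[1, 0, 1] = -p[17] * cosP * sinI
        dH[1, 1, 0] = dH[1, 0, 1]
        dH[1, 1, 2] = -p[19] * sinI
        dH[1, 2, 1] = dH[1, 1, 2]
        # d/dtheta
        dH[2, 0, 0] = p[12] * th - 2.0 * p[10] * sI * th
        dH[2, 1, 1] = p[12] * th - 2.0 * p[11] * sP * th
        dH[2, 2, 2] = p[12] * th
        # d/dbla
        dH[3, 0, 0] = p[13] * (r - p[14])
        dH[3, 1, 1] = p[13] * (r - p[15])
        dH[3, 2, 2] = p[13] * (r - p[16])
    else:
        x = q[0]
        H[0, 0] = p[0] * x
        H[1, 1] = p[1] * x
        H[0, 1] = p[2]
        H[1, 0] = p[2]
        dH[:, :, :] = 0.0
        dH[0, 0, 0] = p[0]
        dH[0, 1, 1] = p[1]


@njit(cache=True)
def fix_phases(U):
    """Deterministic eigenvector sign: largest-magnitude component positive."""
    n = U.shape[1]
    for j in range(n):
        imax = 0
        vmax = abs(U[0, j])
        for i in range(1, n):
            if abs(U[i, j]) > vmax + 1e-14:
                vmax = abs(U[i, j])
                imax = i
        if U[imax, j] < 0.0:
            for i in range(n):
                U[i, j] = -U[i, j]


@njit(cache=True)
def align_phases(U, Uref):
    """Flip eigenvector signs to match a reference (continuity along a path)."""
    n = U.shape[1]
    for j in range(n):
        dot = 0.0
        for i in range(n):
            dot += U[i, j] * Uref[i, j]
        if dot < 0.0:
            for i in range(n):
                U[i, j] = -U[i, j]


@njit(cache=True)
def adiabatic(model, p, q):
    """Energies (ascending) and phase-fixed eigenvectors at q."""
    n, nc = model_dims(model)
    H = np.zeros((n, n))
    dH = np.zeros((nc, n, n))
    eval_model(model, p, q, H, dH)
    E, U = np.linalg.eigh(H)
    fix_phases(U)
    return E, U


@njit(cache=True)
def adiabatic_gradients(model, p, q):
    """Energies, eigenvectors and Hellmann-Feynman gradients (n, nc)."""
    n, nc = model_dims(model)
    H = np.zeros((n, n))
    dH = np.zeros((nc, n, n))
    eval_model(model, p, q, H, dH)
    E, U = np.linalg.eigh(H)
    fix_phases(U)
    grads = np.zeros((n, nc))
    for k in range(nc):
        for s in range(n):
            acc = 0.0
            for a in range(n):
                for b in range(n):
                    acc += U[a, s] * dH[k, a, b] * U[b, s]
            grads[s, k] = acc
    return E, U, grads


@njit(cache=True)
def nac_matrix(model, p, q, U, E):
    """Derivative couplings d[i,j,k] = <i|dH/dq_k|j> / (E_j - E_i)."""
    n, nc = model_dims(model)
    H = np.zeros((n, n))
    dH = np.zeros((nc, n, n))
    eval_model(model, p, q, H, dH)
    d = np.zeros((n, n, nc))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            de = E[j] - E[i]
            for k in range(nc):
                acc = 0.0
                for a in range(n):
                    for b in range(n):
                        acc += U[a, i] * dH[k, a, b] * U[b, j]
                d[i, j, k] = acc / de if abs(de) > 1e-12 else 0.0
    return d


@njit(cache=True)
def _electronic_step(c, E, sigma, h, nsub):
    """RK4 integration of the adiabatic TDSE with NAC terms over one step."""
    n = c.shape[0]
    dt = h / nsub
    for _ in range(nsub):
        k1 = np.zeros(n, dtype=np.complex128)
        k2 = np.zeros(n, dtype=np.complex128)
        k3 = np.zeros(n, dtype=np.complex128)
        k4 = np.zeros(n, dtype=np.complex128)
        for stage in range(4):
            if stage == 0:
                cc = c
            elif stage == 1:
                cc = c + 0.5 * dt * k1
            elif stage == 2:
                cc = c + 0.5 * dt * k2
            else:
                cc = c + dt * k3
            kk = np.zeros(n, dtype=np.complex128)
            for a in range(n):
                kk[a] = -1j * E[a] / HBAR * cc[a]
                for b in range(n):
                    kk[a] -= sigma[a, b] * cc[b]
            if stage == 0:
                k1 = kk
            elif stage == 1:
                k2 = kk
            elif stage == 2:
                k3 = kk
            else:
                k4 = kk
        c += dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    return c


@njit(cache=True)
def fssh_run(model, p, masses_ev, q0, mom0, state0, dt0, max_time,
             sigma_thresh, deco_C, s0_continue, seed, save_every,
             do_hops, max_frames, max_hops, etol):
    """Propagate one surface-hopping trajectory.

    Returns
    -------
    frames : (max_frames, 2+2*nc+n) array
        Saved frames: [t, active, q..., mom..., populations...].
    nframes : int
    hops : (max_hops, 4+2*nc) array
        Hop records: [t, from, to, gap, q..., mom...].
    nhops : int
    status : int
        One of the STATUS_* codes.
    drift : float
        Maximum absolute total-energy drift between hops, eV.
    """
    np.random.seed(seed)
    n, nc = model_dims(model)
    q = q0.copy()
    mom = mom0.copy()
    active = state0

    frames = np.zeros((max_frames, 2 + 2 * nc + n))
    hops = np.zeros((max_hops, 4 + 2 * nc))
    nframes = 0
    nhops = 0

    c = np.zeros(n, dtype=np.complex128)
    c[active] = 1.0 + 0.0j

    E, U, grads = adiabatic_gradients(model, p, q)
    Uprev = U.copy()
    d = nac_matrix(model, p, q, U, E)

    def_ke = 0.0
    for k in range(nc):
        def_ke += 0.5 * mom[k] * mom[k] / masses_ev[k]
    e_ref = def_ke + E[active]
    e_last_hop = e_ref
    drift = 0.0

    t = 0.0
    s0_time = 0.0
    status = STATUS_MAX_TIME
    istep = 0
    sigma_max = 0.0

    while t < max_time:
        # adaptive step: halve in strong-coupling regions
        h = dt0
        if sigma_max > sigma_thresh:
            h = 0.5 * dt0
        if t + h > max_time:
            h = max_time - t

        if istep % save_every == 0 and nframes < max_frames:
            frames[nframes, 0] = t
            frames[nframes, 1] = active
            for k in range(nc):
                frames[nframes, 2 + k] = q[k]
                frames[nframes, 2 + nc + k] = mom[k]
            for a in range(n):
                frames[nframes, 2 + 2 * nc + a] = abs(c[a]) ** 2
            nframes += 1

        # velocity Verlet on the active surface
        for k in range(nc):
            mom[k] -= 0.5 * h * grads[active, k]
        for k in range(nc):
            q[k] += h * mom[k] / masses_ev[k]
        E, U, grads = adiabatic_gradients(model, p, q)
        align_phases(U, Uprev)
        Uprev = U.copy()
        for k in range(nc):
            mom[k] -= 0.5 * h * grads[active, k]

        d = nac_matrix(model, p, q, U, E)
        vel = mom / masses_ev
        sigma = np.zeros((n, n))
        sigma_max = 0.0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                acc = 0.0
                for k in range(nc):
                    acc += d[i, j, k] * vel[k]
                sigma[i, j] = acc
                if abs(acc) > sigma_max:
                    sigma_max = abs(acc)

        # electronic amplitudes
        emax = 0.0
        for a in range(n):
            if abs(E[a]) > emax:
                emax = abs(E[a])
        nsub = 4 + int(h * (emax / HBAR + sigma_max) / 0.05)
        c = _electronic_step(c, E, sigma, h, nsub)

        # fewest-switches hop test
        if do_hops:
            pa = abs(c[active]) ** 2
            if pa > 1e-12:
                xi = np.random.random()
                cum = 0.0
                target = -1
                for b in range(n):
                    if b == active:
                        continue
                    flux = 2.0 * (sigma[active, b] * (c[b] * np.conj(c[active]))).real
                    prob = h * flux / pa
                    if prob > 0.0:
                        cum += prob
                        if xi < cum and target < 0:
                            target = b
                if target >= 0:
                    # momentum adjustment along the NAC direction
                    dvec = d[active, target]
                    a2 = 0.0
                    b1 = 0.0
                    for k in range(nc):
                        a2 += 0.5 * dvec[k] * dvec[k] / masses_ev[k]
                        b1 += mom[k] / masses_ev[k] * dvec[k]
                    de = E[target] - E[active]
                    disc = b1 * b1 - 4.0 * a2 * de
                    if a2 < 1e-14:
                        disc = -1.0
                    if disc >= 0.0:
                        sq = np.sqrt(disc)
                        g1 = (-b1 + sq) / (2.0 * a2)
                        g2 = (-b1 - sq) / (2.0 * a2)
                        gam = g1 if abs(g1) < abs(g2) else g2
                        for k in range(nc):
                            mom[k] += gam * dvec[k]
                        if nhops < max_hops:
                            hops[nhops, 0] = t + h
                            hops[nhops, 1] = active
                            hops[nhops, 2] = target
                            hops[nhops, 3] = abs(de)
                            for k in range(nc):
                                hops[nhops, 4 + k] = q[k]
                                hops[nhops, 4 + nc + k] = mom[k]
                            nhops += 1
                        active = target
                        grads_new = adiabatic_gradients(model, p, q)[2]
                        grads = grads_new
                        ke = 0.0
                        for k in range(nc):
                            ke += 0.5 * mom[k] * mom[k] / masses_ev[k]
                        e_last_hop = ke + E[active]
                    else:
                        # frustrated hop: reverse momentum along d
                        ud = 0.0
                        vd = 0.0
                        for k in range(nc):
                            ud += dvec[k] * dvec[k] / masses_ev[k]
                            vd += mom[k] / masses_ev[k] * dvec[k]
                        if ud > 1e-14:
                            beta = 2.0 * vd / ud
                            for k in range(nc):
                                mom[k] -= beta * dvec[k]

        # energy-based decoherence correction
        ke = 0.0
        for k in range(nc):
            ke += 0.5 * mom[k] * mom[k] / masses_ev[k]
        if deco_C > 0.0 and ke > 1e-10:
            norm_other = 0.0
            for b in range(n):
                if b == active:
                    continue
                de = abs(E[b] - E[active])
                if de > 1e-10:
                    tau = HBAR / de * (1.0 + deco_C / ke)
                    c[b] *= np.exp(-h / tau)
                norm_other += abs(c[b]) ** 2
            pa = abs(c[active]) ** 2
            if pa > 1e-14:
                c[active] *= np.sqrt(max(1.0 - norm_other, 0.0) / pa)

        dr = abs(ke + E[active] - e_last_hop)
        if dr > drift:
            drift = dr
        t += h
        istep += 1

        if drift > etol:
            status = STATUS_ENERGY_VIOLATION
            break

        if active == 0 and n > 1:
            s0_time += h
            if s0_time >= s0_continue:
                status = STATUS_S0_DONE
                break
        else:
            s0_time = 0.0

    # final frame
    if nframes < max_frames:
        frames[nframes, 0] = t
        frames[nframes, 1] = active
        for k in range(nc):
            frames[nframes, 2 + k] = q[k]
            frames[nframes, 2 + nc + k] = mom[k]
        for a in range(n):
            frames[nframes, 2 + 2 * nc + a] = abs(c[a]) ** 2
        nframes += 1

    return frames, nframes, hops, nhops, status, drift


@njit(cache=True)
def quench_descent(model, p, masses_ev, q0, step, max_steps, gtol):
    """Mass-weighted steepest descent on the ground state (MEP quench limit).

    Moves a fixed arc length ``step`` (in mass-weighted units of sqrt(eV)·fs)
    along the normalized downhill direction each iteration.
    """
    n, nc = model_dims(model)
    q = q0.copy()
    sqm = np.sqrt(masses_ev)
    for _ in range(max_steps):
        E, U, grads = adiabatic_gradients(model, p, q)
        gnorm = 0.0
        for k in range(nc):
            gw = grads[0, k] / sqm[k]
            gnorm += gw * gw
        gnorm = np.sqrt(gnorm)
        if gnorm < gtol:
            break
        for k in range(nc):
            q[k] -= step * (grads[0, k] / sqm[k]) / gnorm / sqm[k]
    return q
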