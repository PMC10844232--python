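"""Adiabatic model surfaces over reduced coordinates and their critical points.

Everything here works in the internal coordinate array ``[phi_P, phi_I,
theta, bla]`` (radians / Å).  Gradients are analytic (Hellmann–Feynman on
the diabatic matrix).  Mass-weighting uses the diagonal inertia tensor of
the parameter set; there is no kinetic coupling between reduced coordinates.

Coordinate bounds for optimizers: theta in [-90°, 90°], bla in
[-0.3, 0.3] Å; torsions unrestricted (wrapped on output).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import _kernels
from ._kernels import MODEL_CHROMO
from .geometry import ReducedGeometry
from .params import ChromophoreParams

__all__ = [
    "BranchingPlane",
    "PathResult",
    "potential",
    "derivative_coupling",
    "fragment_inertia",
    "ring_inertia_from_xyz",
    "locate_minimum",
    "locate_meci",
    "branching_plane",
    "neb_path",
    "seam_path",
]

THETA_MAX = np.pi / 2
BLA_MAX = 0.3

COLUMNS = ("phi_P", "phi_I", "theta_hoop", "bla")


def _bounds():
    return [(-2 * np.pi, 2 * np.pi), (-2 * np.pi, 2 * np.pi),
            (-THETA_MAX, THETA_MAX), (-BLA_MAX, BLA_MAX)]


def _as_q(q) -> np.ndarray:
    if isinstance(q, ReducedGeometry):
        return q.to_array()
    return np.asarray(q, dtype=float)


def potential(params: ChromophoreParams, state: int, q) -> tuple[float, np.ndarray]:
    """Adiabatic energy (eV) and analytic gradient of one state at ``q``.

    The gradient is in eV per internal unit (rad for angles, Å for BLA).
    """
    if state not in (0, 1, 2):
        raise ValueError(f"state index must be 0, 1 or 2, got {state}")
    qa = _as_q(q)
    E, U, grads = _kernels.adiabatic_gradients(MODEL_CHROMO, params.to_array(), qa)
    return float(E[state]), grads[state].copy()


def derivative_coupling(params: ChromophoreParams, q, i: int, j: int) -> np.ndarray:
    """First-derivative coupling vector d_ij = <i|dH/dq|j> / (E_j - E_i)."""
    if i == j:
        raise ValueError("derivative coupling requires i != j")
    qa = _as_q(q)
    p = params.to_array()
    E, U = _kernels.adiabatic(MODEL_CHROMO, p, qa)
    if abs(E[j] - E[i]) < 1e-8:
        raise ValueError(
            f"states {i},{j} degenerate (gap {abs(E[j]-E[i]):.2e} eV)")
    d = _kernels.nac_matrix(MODEL_CHROMO, p, qa, U, E)
    return d[i, j].copy()


def fragment_inertia(atom_masses, distances_to_axis) -> float:
    """Rigid-rotor moment of inertia I = sum(m_i d_i²), amu·Å²."""
    m = np.asarray(atom_masses, dtype=float)
    d = np.asarray(distances_to_axis, dtype=float)
    if m.size == 0 or d.size == 0:
        raise ValueError("empty atom list")
    if m.size != d.size:
        raise ValueError("mass/distance length mismatch")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    return float(np.sum(m * d * d))


_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998}


def ring_inertia_from_xyz(path, axis: tuple[int, int | None] = (0, 1)) -> float:
    """Moment of inertia of an XYZ fragment about the axis through two atoms.

    The axis runs through the two (0-based) atom indices in ``axis``; if the
    second index is None the axis runs through the first atom and the ring
    centroid (heavy atoms).  All atoms contribute m·d² with d the
    perpendicular distance to the axis.
    """
    symbols, coords = [], []
    with open(path) as fh:
        lines = fh.read().split("\n")
    nat = int(lines[0])
    for line in lines[2:2 + nat]:
        parts = line.split()
        symbols.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
    coords = np.array(coords)
    a = coords[axis[0]]
    if axis[1] is None:
        heavy = [i for i, s in enumerate(symbols) if s != "H"]
        b = coords[heavy].mean(axis=0)
    else:
        b = coords[axis[1]]
    u = (b - a) / np.linalg.norm(b - a)
    rel = coords - a
    dists = np.linalg.norm(rel - np.outer(rel @ u, u), axis=1)
    masses = [_MASSES[s] for s in symbols]
    return fragment_inertia(masses, dists)


def locate_minimum(params: ChromophoreParams, state: int, q0,
                   gtol: float = 1e-8, maxiter: int = 2000) -> ReducedGeometry:
    """Local minimum of one adiabatic surface from a starting geometry."""
    qa = _as_q(q0)

    def fun(x):
        e, g = potential(params, state, x)
        return e, g

    res = minimize(fun, qa, jac=True, method="L-BFGS-B", bounds=_bounds(),
                   options={"maxiter": maxiter, "ftol": 1e-14, "gtol": gtol})
    e, g = potential(params, state, res.x)
    if np.linalg.norm(g) > 1e-6:
        # polish with a short projected gradient descent
        x = res.x.copy()
        for _ in range(5000):
            e, g = potential(params, state, x)
            if np.linalg.norm(g) < 1e-7:
                break
            x -= 0.05 * g
            x[2] = np.clip(x[2], -THETA_MAX, THETA_MAX)
            x[3] = np.clip(x[3], -BLA_MAX, BLA_MAX)
        res.x = x
        e, g = potential(params, state, x)
        if np.linalg.norm(g) > 1e-5:
            raise RuntimeError(
                f"minimization did not converge (|g|={np.linalg.norm(g):.2e})")
    return ReducedGeometry.from_array(res.x)


def _gap_penalty(params, x, sigma, alpha):
    p = params.to_array()
    E, U, grads = _kernels.adiabatic_gradients(MODEL_CHROMO, p, x)
    gap = E[1] - E[0]
    mean = 0.5 * (E[0] + E[1])
    gmean = 0.5 * (grads[0] + grads[1])
    ggap = grads[1] - grads[0]
    pen = sigma * gap * gap / (gap + alpha)
    dpen = sigma * gap * (gap + 2 * alpha) / (gap + alpha) ** 2 * ggap
    return mean + pen, gmean + dpen, gap


def locate_meci(params: ChromophoreParams, q0, states=(0, 1),
                alpha: float = 0.02, gap_tol: float = 1e-4,
                max_cycles: int = 40) -> tuple[ReducedGeometry, float]:
    """Minimum-energy conical intersection by smooth gap-penalty minimization.

    Minimizes ``mean(E) + sigma·gap²/(gap+alpha)`` with sigma doubled each
    outer cycle until the S1-S0 gap falls below ``gap_tol`` (eV).  Returns
    the MECI geometry and its energy (mean of the two states, eV).
    """
    if tuple(states) != (0, 1):
        raise ValueError("only the S0/S1 seam is parametrized")
    x = _as_q(q0).copy()
    sigma = 3.5
    gap = np.inf
    for _ in range(max_cycles):
        res = minimize(lambda y: _gap_penalty(params, y, sigma, alpha)[:2],
                       x, jac=True, method="L-BFGS-B", bounds=_bounds(),
                       options={"maxiter": 500, "ftol": 1e-15, "gtol": 1e-10})
        x = res.x
        gap = _gap_penalty(params, x, sigma, alpha)[2]
        if gap < gap_tol:
            break
        sigma *= 2.0
    if gap >= gap_tol:
        raise RuntimeError(f"MECI search did not converge (gap {gap:.2e} eV)")
    if abs(x[2]) > THETA_MAX - 1e-9 or abs(x[3]) > BLA_MAX - 1e-9:
        raise RuntimeError("MECI search collapsed onto a coordinate bound")
    E, _ = _kernels.adiabatic(MODEL_CHROMO, params.to_array(), x)
    return ReducedGeometry.from_array(x), float(0.5 * (E[0] + E[1]))


@dataclass(frozen=True)
class BranchingPlane:
    """Orthonormalized branching-plane vectors at a conical intersection.

    ``g`` is the gradient-difference direction and ``h`` the derivative-
    coupling direction, both unit vectors in the internal coordinate space
    (rad, rad, rad, Å), mutually orthogonal, with +h pointing toward
    increasing phi_I (the E isomer).
    """

    g: np.ndarray
    h: np.ndarray

    def displace(self, q_meci, radius: float, angle_deg: float) -> np.ndarray:
        """q_meci + r·(cos(a)·g + sin(a)·h) in internal coordinates."""
        a = np.deg2rad(angle_deg)
        return _as_q(q_meci) + radius * (np.cos(a) * self.g + np.sin(a) * self.h)


def branching_plane(params: ChromophoreParams, q_meci) -> BranchingPlane:
    """First-order branching plane (g/h vectors) at a near-degenerate point.

    Uses the degenerate-subspace gradients; the two-state mixing angle is
    rotated so that g·h = 0, then both vectors are unit-normalized.
    """
    qa = _as_q(q_meci)
    p = params.to_array()
    E, U = _kernels.adiabatic(MODEL_CHROMO, p, qa)
    if E[1] - E[0] > 1e-3:
        raise ValueError(f"gap at q_meci is {E[1]-E[0]:.2e} eV (> 1e-3)")
    n, nc = 3, 4
    H = np.zeros((n, n))
    dH = np.zeros((nc, n, n))
    _kernels.eval_model(MODEL_CHROMO, p, qa, H, dH)
    v0, v1 = U[:, 0], U[:, 1]
    g = np.array([0.5 * (v1 @ dH[k] @ v1 - v0 @ dH[k] @ v0) for k in range(nc)])
    h = np.array([v0 @ dH[k] @ v1 for k in range(nc)])
    # rotate within the degenerate subspace to orthogonalize g and h
    num = 2.0 * (g @ h)
    den = (g @ g) - (h @ h)
    if abs(num) > 1e-14 or abs(den) > 1e-14:
        beta = 0.25 * np.arctan2(num, den)
        c2, s2 = np.cos(2 * beta), np.sin(2 * beta)
        g, h = c2 * g + s2 * h, -s2 * g + c2 * h
    ng, nh = np.linalg.norm(g), np.linalg.norm(h)
    if ng < 1e-10 or nh < 1e-10:
        raise ValueError("vanishing g or h vector norm")
    g, h = g / ng, h / nh
    # at a conical point the (g, h) pair is defined up to a rotation; label
    # the torsion-dominated direction as h (coupling gating is torsional)
    if abs(g[1]) > abs(h[1]):
        g, h = h, g
    if h[1] < 0:
        h = -h
    if g[np.argmax(np.abs(g))] < 0:
        g = -g
    return BranchingPlane(g=g, h=h)


@dataclass(frozen=True)
class PathResult:
    """A converged path: geometries, energies and the forward barrier (eV)."""

    images: list
    energies: np.ndarray
    barrier: float

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"phi_P": im.phi_P, "phi_I": im.phi_I,
             "theta_hoop": im.theta_hoop, "bla": im.bla, "energy_eV": e}
            for im, e in zip(self.images, self.energies)
        ]
        return pd.DataFrame(rows)


def _neb_optimize(energy_grad, x0, x1, n_images, masses, k_spring=1.0,
                  max_iter=1500, ftol=2e-4):
    """Nudged elastic band in mass-weighted coordinates (FIRE optimizer)."""
    sqm = np.sqrt(masses)
    a0, a1 = _as_q(x0) * 1.0, _as_q(x1) * 1.0
    path = np.array([a0 + (a1 - a0) * t for t in np.linspace(0, 1, n_images)])
    w = path * sqm  # mass-weighted images

    vel = np.zeros_like(w)
    dt = 0.08
    alpha = 0.1
    n_ok = 0
    for _ in range(max_iter):
        E = np.empty(n_images)
        G = np.empty_like(w)
        for i in range(n_images):
            e, g = energy_grad(w[i] / sqm)
            E[i] = e
            G[i] = g / sqm
        F = np.zeros_like(w)
        for i in range(1, n_images - 1):
            # improved tangent (upwind)
            tp = w[i + 1] - w[i]
            tm = w[i] - w[i - 1]
            if E[i + 1] > E[i] > E[i - 1]:
                tau = tp
            elif E[i + 1] < E[i] < E[i - 1]:
                tau = tm
            else:
                dmax = max(abs(E[i + 1] - E[i]), abs(E[i - 1] - E[i]))
                dmin = min(abs(E[i + 1] - E[i]), abs(E[i - 1] - E[i]))
                tau = tp * dmax + tm * dmin if E[i + 1] > E[i - 1] \
                    else tp * dmin + tm * dmax
            tau = tau / (np.linalg.norm(tau) + 1e-30)
            f_spring = k_spring * (np.linalg.norm(tp) - np.linalg.norm(tm))
            f_perp = -G[i] + (G[i] @ tau) * tau
            F[i] = f_perp + f_spring * tau
        fmax = np.abs(F).max() if n_images > 2 else 0.0
        if fmax < ftol:
            break
        # FIRE
        p = np.sum(F * vel)
        if p > 0:
            n_ok += 1
            if n_ok > 5:
                dt = min(dt * 1.1, 0.25)
                alpha *= 0.99
            vn = np.linalg.norm(vel)
            fn = np.linalg.norm(F) + 1e-30
            vel = (1 - alpha) * vel + alpha * vn * F / fn
        else:
            n_ok = 0
            dt *= 0.5
            alpha = 0.1
            vel[:] = 0.0
        vel += dt * F
        w += dt * vel
    E = np.array([energy_grad(w[i] / sqm)[0] for i in range(n_images)])
    return w / sqm, E


def neb_path(params: ChromophoreParams, state: int, qA, qB,
             n_images: int = 17, **kw) -> PathResult:
    """Minimum-energy path on one adiabatic surface between two anchors.

    The band is optimized in mass-weighted coordinates built from the
    parameter set's inertia tensor; the barrier is max(E) - E[start].
    """
    a, b = _as_q(qA), _as_q(qB)
    if np.allclose(a, b):
        raise ValueError("qA and qB must be distinct")

    def eg(x):
        return potential(params, state, x)

    path, E = _neb_optimize(eg, a, b, n_images, params.masses, **kw)
    images = [ReducedGeometry.from_array(x) for x in path]
    barrier = max(float(E.max() - E[0]), 0.0)
    return PathResult(images=images, energies=E, barrier=barrier)


def seam_path(params: ChromophoreParams, meci_a, meci_b,
              n_images: int = 15, sigma: float = 600.0, alpha: float = 0.02,
              gap_tol: float = 1e-3, **kw) -> PathResult:
    """Minimum-energy path constrained to the S1/S0 intersection seam.

    Optimizes a band on the penalized surface mean(E) + sigma·gap²/(gap+α)
    between two near-degenerate endpoints; reported energies are the mean
    of S0 and S1.  Every converged image must stay within ``gap_tol`` of
    degeneracy.
    """
    a, b = _as_q(meci_a), _as_q(meci_b)
    for x, tag in ((a, "meci_a"), (b, "meci_b")):
        E, _ = _kernels.adiabatic(MODEL_CHROMO, params.to_array(), x)
        if E[1] - E[0] > gap_tol:
            raise ValueError(f"{tag} is not near-degenerate "
                             f"(gap {E[1]-E[0]:.2e} eV)")
    if np.allclose(a, b):
        g = ReducedGeometry.from_array(a)
        E, _ = _kernels.adiabatic(MODEL_CHROMO, params.to_array(), a)
        return PathResult(images=[g], energies=np.array([0.5 * (E[0] + E[1])]),
                          barrier=0.0)

    def eg(x):
        f, g, _ = _gap_penalty(params, x, sigma, alpha)
        return f, g

    path, _ = _neb_optimize(eg, a, b, n_images, params.masses, **kw)
    energies = []
    for x in path:
        E, _ = _kernels.adiabatic(MODEL_CHROMO, params.to_array(), x)
        energies.append(0.5 * (E[0] + E[1]))
    energies = np.array(energies)
    images = [ReducedGeometry.from_array(x) for x in path]
    barrier = max(float(energies.max() - max(energies[0], energies[-1])), 0.0)
    return PathResult(images=images, energies=energies, barrier=barrier)
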