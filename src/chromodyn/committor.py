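"""Branching-plane cone sampling and photoisomerization committor analysis.

Configurations are sampled on polar grids in the branching plane of an
I-twisted intersection, q = q_MECI + r·(cos(a)·g + sin(a)·h), and the
photoproduct outcome of ground-state dynamics from each sample is computed
under three limiting schemes:

``mep``
    kinetic energy quenched after each infinitesimal step (steepest
    descent on S0 in mass-weighted coordinates) — the photoreactivity
    imprinted in the ground-state potential;
``zero_velocity``
    a single classical S0 trajectory started from rest;
``random_velocity``
    many S0 trajectories with isotropic random initial velocities whose
    magnitude corresponds to thermal equipartition over the four reduced
    modes — yielding a photoproduct probability p_E per sample.

The equicommittor is the p_E = 0.5 contour of the random-velocity map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from ._kernels import MODEL_CHROMO
from .geometry import ReducedGeometry
from .params import ChromophoreParams
from .surfaces import BranchingPlane
from .units import AMU_TO_EV, KB_EV

__all__ = [
    "ConeSample",
    "CommittorMap",
    "cone_sample",
    "committor",
    "committor_map",
    "equicommittor_map",
    "hop_velocity_distribution",
]

SCHEMES = ("mep", "zero_velocity", "random_velocity")


@dataclass(frozen=True)
class ConeSample:
    """One branching-plane displacement sample."""

    meci: str
    radius: float
    angle: float               # degrees; 90° is the pure +h direction
    geometry: ReducedGeometry

    def __post_init__(self):
        if self.radius < 0:
            raise ValueError("radius must be non-negative")


def cone_sample(meci_geom, plane: BranchingPlane, radii, angles,
                label: str = "MECI-I") -> list[ConeSample]:
    """Polar-grid samples q_meci + r·(cos(a)·g + sin(a)·h)."""
    if abs(plane.g @ plane.h) > 1e-9:
        raise ValueError("branching plane vectors must be orthogonal")
    out = []
    for r in radii:
        for a in angles:
            q = plane.displace(meci_geom, r, a)
            out.append(ConeSample(meci=label, radius=float(r), angle=float(a),
                                  geometry=ReducedGeometry.from_array(q)))
    return out


def _classify_phi(phi_i_rad: float) -> str:
    phi = (np.rad2deg(phi_i_rad) + 180.0) % 360.0 - 180.0
    if abs(phi) <= 55.0:
        return "Z"
    if abs(abs(phi) - 180.0) <= 55.0:
        return "E"
    return "unassigned"


def _ground_state_run(params, q0, mom0, t_max_fs, seed=0):
    masses_ev = params.masses * AMU_TO_EV
    frames, nframes, *_ = _kernels.fssh_run(
        MODEL_CHROMO, params.to_array(), masses_ev, np.asarray(q0, float),
        np.asarray(mom0, float), 0, 0.25, t_max_fs, 1e9, 0.0, 1e18, seed,
        1000000, False, 8, 0, 1e9)
    return frames[nframes - 1, 2:6]


def committor(params: ChromophoreParams, sample: ConeSample, scheme: str,
              n_velocities: int = 50, t_max_fs: float = 300.0,
              seed: int = 0, temperature_K: float = 300.0,
              descent_step: float = 0.05):
    """Photoproduct outcome (or probability) of one branching-plane sample.

    Returns a label ("Z", "E", "unassigned") for the deterministic schemes,
    or a dict with keys ``p_E``, ``n_E``, ``n_Z``, ``n_unassigned`` for the
    random-velocity scheme (unassigned endpoints are excluded from the
    p_E denominator and reported).
    """
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}")
    q0 = sample.geometry.to_array()
    masses_ev = params.masses * AMU_TO_EV
    if scheme == "mep":
        qf = _kernels.quench_descent(MODEL_CHROMO, params.to_array(),
                                     masses_ev, q0, descent_step,
                                     400000, 1e-5)
        return _classify_phi(qf[1])
    if scheme == "zero_velocity":
        qf = _ground_state_run(params, q0, np.zeros(4), t_max_fs, seed)
        return _classify_phi(qf[1])
    # random_velocity: isotropic direction in mass-weighted momentum space,
    # magnitude from equipartition (kT/2 per mode)
    rng = np.random.default_rng(seed)
    ke_total = 0.5 * KB_EV * temperature_K * 4
    counts = {"Z": 0, "E": 0, "unassigned": 0}
    for i in range(n_velocities):
        u = rng.standard_normal(4)
        u /= np.linalg.norm(u)
        # mass-weighted momentum p_x with |p_x|^2 / 2 = KE
        px = u * np.sqrt(2.0 * ke_total)
        mom = px * np.sqrt(masses_ev)
        qf = _ground_state_run(params, q0, mom, t_max_fs,
                               seed=int(rng.integers(0, 2**31 - 1)))
        counts[_classify_phi(qf[1])] += 1
    n_cl = counts["Z"] + counts["E"]
    return {
        "p_E": counts["E"] / n_cl if n_cl else np.nan,
        "n_E": counts["E"], "n_Z": counts["Z"],
        "n_unassigned": counts["unassigned"],
    }


@dataclass
class CommittorMap:
    """Committor outcomes on a polar branching-plane grid.

    ``values`` has shape (n_radii, n_angles): photoproduct probability
    p_E in [0, 1] for the random-velocity scheme, or 0/1/NaN encodings of
    the deterministic labels (E=1, Z=0, unassigned=NaN).
    """

    radii: np.ndarray
    angles: np.ndarray
    values: np.ndarray
    labels: list
    scheme: str
    n_velocities: int
    seed: int
    meci: str = "MECI-I"

    def to_dataframe(self):
        import pandas as pd
        rows = []
        for i, r in enumerate(self.radii):
            for j, a in enumerate(self.angles):
                rows.append({"r": r, "alpha": a, "p_E": self.values[i, j],
                             "label": self.labels[i][j], "scheme": self.scheme,
                             "n": self.n_velocities})
        return pd.DataFrame(rows)

    def plot_polar(self, ax=None):
        """Render the map as a polar scatter (angle = branching-plane angle,
        radius = displacement), colored by p_E, with the equicommittor line
        overlaid when it exists."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(subplot_kw={"projection": "polar"})
        rr, aa = np.meshgrid(self.radii, self.angles, indexing="ij")
        sc = ax.scatter(np.deg2rad(aa.ravel()), rr.ravel(),
                        c=self.values.ravel(), cmap="coolwarm", vmin=0,
                        vmax=1, s=60, edgecolors="k", linewidths=0.3)
        if self.scheme == "random_velocity":
            contour = equicommittor_map(self)
            if contour.size:
                ax.plot(np.deg2rad(contour[:, 1]), contour[:, 0], "k-",
                        lw=1.5)
        ax.set_title(f"{self.meci} ({self.scheme})")
        plt.colorbar(sc, ax=ax, label="p(E)")
        return ax

    def interp(self, r: float, a: float) -> float:
        """Bilinear interpolation of p_E on the polar grid."""
        ri = np.clip(np.searchsorted(self.radii, r) - 1, 0, len(self.radii) - 2)
        aj = np.clip(np.searchsorted(self.angles, a) - 1, 0, len(self.angles) - 2)
        r0, r1 = self.radii[ri], self.radii[ri + 1]
        a0, a1 = self.angles[aj], self.angles[aj + 1]
        tr = (r - r0) / (r1 - r0) if r1 > r0 else 0.0
        ta = (a - a0) / (a1 - a0) if a1 > a0 else 0.0
        v = self.values
        return float((1 - tr) * (1 - ta) * v[ri, aj] + tr * (1 - ta) * v[ri + 1, aj]
                     + (1 - tr) * ta * v[ri, aj + 1] + tr * ta * v[ri + 1, aj + 1])


DEFAULT_RADII = (0.05, 0.1, 0.2)
DEFAULT_ANGLES = tuple(np.arange(0.0, 360.0, 15.0))


def committor_map(params: ChromophoreParams, meci_geom, plane: BranchingPlane,
                  scheme: str, radii=DEFAULT_RADII, angles=DEFAULT_ANGLES,
                  n_velocities: int = 50, t_max_fs: float = 300.0,
                  seed: int = 0, label: str = "MECI-I") -> CommittorMap:
    """Evaluate the committor on a polar grid around one intersection."""
    radii = np.asarray(radii, float)
    angles = np.asarray(angles, float)
    values = np.full((radii.size, angles.size), np.nan)
    labels = [["" for _ in angles] for _ in radii]
    rng = np.random.default_rng(seed)
    for i, r in enumerate(radii):
        for j, a in enumerate(angles):
            s = ConeSample(meci=label, radius=float(r), angle=float(a),
                           geometry=ReducedGeometry.from_array(
                               plane.displace(meci_geom, r, a)))
            res = committor(params, s, scheme, n_velocities, t_max_fs,
                            seed=int(rng.integers(0, 2**31 - 1)))
            if scheme == "random_velocity":
                values[i, j] = res["p_E"]
                labels[i][j] = "p"
            else:
                labels[i][j] = res
                values[i, j] = {"E": 1.0, "Z": 0.0}.get(res, np.nan)
    return CommittorMap(radii=radii, angles=angles, values=values,
                        labels=labels, scheme=scheme,
                        n_velocities=n_velocities, seed=seed, meci=label)


def equicommittor_map(cmap: CommittorMap) -> np.ndarray:
    """The p_E = 0.5 level set of a random-velocity committor map.

    Returns an array of (r, angle) points where the bilinearly interpolated
    probability crosses 0.5, one point per crossing grid edge, sorted by
    angle; empty if the probability never crosses 0.5.
    """
    if cmap.scheme != "random_velocity":
        raise ValueError("equicommittor requires a random-velocity map")
    pts = []
    v = cmap.values - 0.5
    nr, na = v.shape
    for i in range(nr):
        for j in range(na - 1):
            a, b = v[i, j], v[i, j + 1]
            if np.isfinite(a) and np.isfinite(b) and a * b < 0:
                t = a / (a - b)
                pts.append((cmap.radii[i],
                            cmap.angles[j] + t * (cmap.angles[j + 1] - cmap.angles[j])))
    for j in range(na):
        for i in range(nr - 1):
            a, b = v[i, j], v[i + 1, j]
            if np.isfinite(a) and np.isfinite(b) and a * b < 0:
                t = a / (a - b)
                pts.append((cmap.radii[i] + t * (cmap.radii[i + 1] - cmap.radii[i]),
                            cmap.angles[j]))
    for i in range(nr):
        for j in range(na):
            if v[i, j] == 0.0:
                pts.append((cmap.radii[i], cmap.angles[j]))
    if not pts:
        return np.empty((0, 2))
    arr = np.array(pts)
    return arr[np.argsort(arr[:, 1])]


def hop_velocity_distribution(ensemble, plane: BranchingPlane,
                              min_twist_deg: float = 45.0,
                              params: ChromophoreParams | None = None) -> dict:
    """Signed hop velocities along +h, stratified by photoproduct.

    For every S1→S0 hop occurring in the I-twisted region (|phi_I| above
    ``min_twist_deg``), the nuclear velocity is projected onto the +h
    direction (deg/fs for the torsional component); hops on the negative-
    phi_I side are folded onto the positive side by flipping the sign, so
    both twist directions are combined.  Returns ``{label: array_of_v_h}``.
    """
    masses = params.masses if params is not None else _masses_of(ensemble)
    out: dict = {}
    found = False
    for traj in ensemble.trajectories:
        for hop in traj.hops:
            if hop.from_state != 1 or hop.to_state != 0:
                continue
            found = True
            q = hop.q.to_array()
            if abs(np.rad2deg(q[1])) < min_twist_deg:
                continue
            vel = np.asarray(hop.p, float) / masses
            v_h = float(vel @ plane.h)
            if q[1] < 0:
                v_h = -v_h
            label = traj.label or "unassigned"
            out.setdefault(label, []).append(np.rad2deg(v_h))
    if not found:
        return {}
    return {k: np.array(v) for k, v in out.items()}


def _masses_of(ensemble):
    from .calibration import builtin_params
    try:
        return builtin_params(ensemble.params_name).masses
    except KeyError:
        # synthetic/custom ensembles: unit masses
        return np.ones(4)
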