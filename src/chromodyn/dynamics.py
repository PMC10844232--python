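"""Surrogate nonadiabatic dynamics on the model surfaces.

Initial conditions are drawn from the thermal Wigner distribution of the
harmonic modes at the planar S0 minimum, filtered by a pump spectral
window, promoted to S1 and propagated with fewest-switches surface hopping
(velocity-Verlet nuclear integration, adaptive step halving in strong-
coupling regions, energy-based decoherence, momentum rescaling along the
derivative-coupling direction at hops).  After relaxing to S0 a trajectory
is continued for 150 fs before its photoproduct is classified from the
final I-torsion (±55° windows around the Z and E isomers).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from ._kernels import MODEL_CHROMO
from .geometry import ReducedGeometry
from .params import ChromophoreParams
from .surfaces import locate_minimum, potential
from .units import AMU_TO_EV, AU_TIME_FS, HBAR_EV_FS, KB_EV

__all__ = [
    "InitialCondition",
    "HopEvent",
    "Trajectory",
    "Ensemble",
    "PropagationSettings",
    "sample_wigner",
    "filter_excitation_window",
    "propagate",
    "classify_photoproduct",
    "run_ensemble",
]

# default strong-coupling threshold: 0.005 a.u. of (d·v), in 1/fs
SIGMA_THRESH_FS = 0.005 / AU_TIME_FS
# default decoherence constant: 0.1 hartree, in eV
DECOHERENCE_EV = 2.7211386


@dataclass
class InitialCondition:
    """Phase-space sample on S0, promoted to S1.

    ``p`` are momenta in amu-based units (mass × velocity, with torsional
    inertia in amu·Å² and rad/fs velocities).
    """

    q: ReducedGeometry
    p: np.ndarray
    vertical_gap: float
    weight: float = 1.0

    def __post_init__(self):
        if self.weight <= 0:
            raise ValueError("initial-condition weight must be > 0")


@dataclass(frozen=True)
class HopEvent:
    """A nonadiabatic transition record."""

    time: float               # fs
    q: ReducedGeometry
    p: np.ndarray             # amu-based momenta at the hop
    from_state: int
    to_state: int
    gap: float                # eV, >= 0
    transferred_weight: float
    v_h: float | None = None  # signed velocity along +h, deg/fs (set later)

    def __post_init__(self):
        if self.from_state == self.to_state:
            raise ValueError("hop must change the active state")
        if self.gap < 0:
            raise ValueError("hop gap must be non-negative")


@dataclass
class Trajectory:
    """A surface-hopping time series with its hop events and outcome."""

    times: np.ndarray          # fs
    qs: np.ndarray             # (n, 4) internal coordinates
    moms: np.ndarray           # (n, 4) amu-based momenta
    active: np.ndarray         # (n,) active adiabatic state
    populations: np.ndarray    # (n, 3) |c|^2
    hops: list
    status: int
    energy_drift: float        # eV, max drift between hops
    weight: float = 1.0
    seed: int = 0
    label: str | None = None   # photoproduct, filled by classify_photoproduct

    @property
    def valid(self) -> bool:
        return self.status != _kernels.STATUS_ENERGY_VIOLATION

    @property
    def reached_s0(self) -> bool:
        return bool(np.any(self.active == 0))

    def state_at(self, t: float) -> int:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return int(self.active[max(idx, 0)])


@dataclass
class Ensemble:
    """A weighted collection of trajectories from one parameter set."""

    trajectories: list
    params_name: str
    seed: int
    ics: list = field(default_factory=list)

    def __post_init__(self):
        w = sum(t.weight for t in self.trajectories)
        if self.trajectories and abs(w - 1.0) > 1e-8:
            for t in self.trajectories:
                t.weight /= w

    @property
    def weights(self) -> np.ndarray:
        return np.array([t.weight for t in self.trajectories])

    def summary(self) -> dict:
        labels = [t.label or classify_photoproduct(t) for t in self.trajectories]
        w = self.weights
        qy_e = float(sum(wi for wi, l in zip(w, labels) if l == "E"))
        trapped = float(sum(wi for wi, l in zip(w, labels) if l == "trapped"))
        p_first = 0.0
        for t, wi in zip(self.trajectories, w):
            first = _first_torsion_past(t, np.deg2rad(45.0))
            if first == "P":
                p_first += wi
        return {
            "quantum_yield_E": qy_e,
            "fraction_trapped": trapped,
            "fraction_initial_P_twist": float(p_first),
            "n_trajectories": len(self.trajectories),
        }


@dataclass(frozen=True)
class PropagationSettings:
    """Integration settings for the surface-hopping surrogate."""

    dt_fs: float = 0.25
    max_time_fs: float = 10000.0
    decoherence_eV: float = DECOHERENCE_EV
    sigma_thresh: float = SIGMA_THRESH_FS
    s0_continue_fs: float = 150.0
    save_every: int = 8
    energy_tol_eV: float = 0.01

    def validate(self):
        if self.dt_fs <= 0 or self.max_time_fs <= 0:
            raise ValueError("time step and horizon must be positive")


def _harmonic_modes(params: ChromophoreParams):
    """Frequencies (1/fs) and mass-weighted mode vectors of the S0 minimum."""
    qmin = locate_minimum(params, 0, [0.0, 0.0, 0.0, 0.0]).to_array()
    m_int = params.masses * AMU_TO_EV
    step = 1e-4
    K = np.zeros((4, 4))
    for k in range(4):
        qp, qm = qmin.copy(), qmin.copy()
        qp[k] += step
        qm[k] -= step
        _, gp = potential(params, 0, qp)
        _, gm = potential(params, 0, qm)
        K[k] = (gp - gm) / (2 * step)
    K = 0.5 * (K + K.T)
    Kw = K / np.sqrt(np.outer(m_int, m_int))
    lam, U = np.linalg.eigh(Kw)
    if np.any(lam <= 0):
        raise ValueError(
            "imaginary frequency at the S0 minimum; parameter set is not "
            f"harmonically stable (eigenvalues {lam})")
    return qmin, m_int, np.sqrt(lam), U


def sample_wigner(params: ChromophoreParams, n: int, temperature_K: float = 300.0,
                  seed: int | None = None) -> list[InitialCondition]:
    """Draw initial conditions from the thermal harmonic Wigner distribution.

    Positions and momenta of the four uncoupled reduced-coordinate normal
    modes are sampled from Gaussians with variances
    sigma_x² = (ħ/2ω)·coth(ħω/2kT) and sigma_p² = (ħω/2)·coth(ħω/2kT)
    (mass-weighted units); the vertical S1-S0 gap is attached to each sample.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    qmin, m_int, omega, U = _harmonic_modes(params)
    rng = np.random.default_rng(seed)
    if temperature_K > 0:
        x_arg = HBAR_EV_FS * omega / (2.0 * KB_EV * temperature_K)
        coth = 1.0 / np.tanh(x_arg)
    else:
        coth = np.ones_like(omega)
    sig_x = np.sqrt(HBAR_EV_FS / (2.0 * omega) * coth)
    sig_p = np.sqrt(HBAR_EV_FS * omega / 2.0 * coth)
    out = []
    p = params.to_array()
    for _ in range(n):
        x = rng.normal(0.0, sig_x)
        px = rng.normal(0.0, sig_p)
        dq = U @ x / np.sqrt(m_int)
        vel = U @ px / np.sqrt(m_int)
        q = qmin + dq
        E, _ = _kernels.adiabatic(MODEL_CHROMO, p, q)
        out.append(InitialCondition(
            q=ReducedGeometry.from_array(q),
            p=params.masses * vel,
            vertical_gap=float(E[1] - E[0]),
            weight=1.0 / n,
        ))
    return out


def filter_excitation_window(ics, center_eV: float = 2.48,
                             half_width_eV: float = 0.05,
                             shift_eV: float = 0.0) -> list[InitialCondition]:
    """Keep initial conditions whose shifted vertical gap lies in the window.

    ``shift_eV`` is the uniform spectral shift applied to computed gaps
    before comparing with the experimental pump window; weights of the
    surviving samples are renormalized to 1.
    """
    kept = [ic for ic in ics
            if abs(ic.vertical_gap + shift_eV - center_eV) <= half_width_eV]
    if not kept:
        warnings.warn("excitation window selected no initial conditions",
                      stacklevel=2)
        return []
    wtot = sum(ic.weight for ic in kept)
    return [InitialCondition(q=ic.q, p=ic.p, vertical_gap=ic.vertical_gap,
                             weight=ic.weight / wtot) for ic in kept]


def propagate(params: ChromophoreParams, ic: InitialCondition,
              settings: PropagationSettings | None = None,
              seed: int = 0) -> Trajectory:
    """Propagate one fewest-switches surface-hopping trajectory from S1."""
    settings = settings or PropagationSettings()
    settings.validate()
    p = params.to_array()
    masses_ev = params.masses * AMU_TO_EV
    q0 = ic.q.to_array()
    mom0 = np.asarray(ic.p, float) * AMU_TO_EV
    nsteps = int(settings.max_time_fs / settings.dt_fs) + 2
    max_frames = nsteps // settings.save_every + 4
    frames, nframes, hops, nhops, status, drift = _kernels.fssh_run(
        MODEL_CHROMO, p, masses_ev, q0, mom0, 1,
        settings.dt_fs, settings.max_time_fs, settings.sigma_thresh,
        settings.decoherence_eV, settings.s0_continue_fs, seed,
        settings.save_every, True, max_frames, 256, settings.energy_tol_eV)
    nc = 4
    fr = frames[:nframes]
    hop_events = []
    for i in range(nhops):
        row = hops[i]
        hop_events.append(HopEvent(
            time=row[0],
            q=ReducedGeometry.from_array(row[4:4 + nc]),
            p=row[4 + nc:4 + 2 * nc] / AMU_TO_EV,
            from_state=int(row[1]), to_state=int(row[2]), gap=row[3],
            transferred_weight=ic.weight,
        ))
    traj = Trajectory(
        times=fr[:, 0].copy(),
        qs=fr[:, 2:2 + nc].copy(),
        moms=fr[:, 2 + nc:2 + 2 * nc] / AMU_TO_EV,
        active=fr[:, 1].astype(int),
        populations=fr[:, 2 + 2 * nc:2 + 2 * nc + 3].copy(),
        hops=hop_events, status=int(status), energy_drift=float(drift),
        weight=ic.weight, seed=seed,
    )
    traj.label = classify_photoproduct(traj)
    return traj


def classify_photoproduct(traj: Trajectory) -> str:
    """Photoproduct label from the final I-torsion: Z, E, unassigned, trapped.

    Z if |phi_I| <= 55°, E if |phi_I - 180°| <= 55° (mod 360); trajectories
    that never reached the ground state are labeled "trapped".
    """
    if not traj.reached_s0:
        return "trapped"
    phi_i = np.rad2deg(traj.qs[-1, 1])
    phi_i = (phi_i + 180.0) % 360.0 - 180.0
    if abs(phi_i) <= 55.0:
        return "Z"
    if abs(abs(phi_i) - 180.0) <= 55.0:
        return "E"
    return "unassigned"


def _first_torsion_past(traj: Trajectory, threshold_rad: float) -> str | None:
    """Which bridge torsion first exceeds the threshold ("P", "I" or None)."""
    phi_p = np.abs(np.unwrap(traj.qs[:, 0]))
    phi_i = np.abs(np.unwrap(traj.qs[:, 1]))
    ip = np.argmax(phi_p > threshold_rad) if np.any(phi_p > threshold_rad) else -1
    ii = np.argmax(phi_i > threshold_rad) if np.any(phi_i > threshold_rad) else -1
    if ip < 0 and ii < 0:
        return None
    if ip < 0:
        return "I"
    if ii < 0:
        return "P"
    return "P" if ip < ii else "I"


def run_ensemble(params: ChromophoreParams, ics,
                 settings: PropagationSettings | None = None,
                 seed: int = 0) -> Ensemble:
    """Propagate an ensemble with per-trajectory seeds derived from ``seed``.

    Invalid trajectories (energy-conservation violations) are excluded with
    a warning; surviving weights are renormalized.
    """
    if not ics:
        raise ValueError("need at least one initial condition")
    settings = settings or PropagationSettings()
    rng = np.random.default_rng(seed)
    traj_seeds = rng.integers(0, 2**31 - 1, size=len(ics))
    trajectories = []
    for ic, s in zip(ics, traj_seeds):
        traj = propagate(params, ic, settings, seed=int(s))
        if not traj.valid:
            warnings.warn(
                f"trajectory seed {s} excluded: energy drift "
                f"{traj.energy_drift:.3e} eV", stacklevel=2)
            continue
        trajectories.append(traj)
    if not trajectories:
        raise RuntimeError("all trajectories were invalid")
    return Ensemble(trajectories=trajectories, params_name=params.name,
                    seed=seed, ics=list(ics))
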