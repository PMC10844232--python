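"""Excited-state decay analytics.

The S1 population of an ensemble is fitted to a delayed biexponential

    P(t) = 1                                           for t <= t0
    P(t) = a·exp(-(t-t0)/tau1) + (1-a)·exp(-(t-t0)/tau2)   for t > t0

with a sharp onset at the lag time t0 and tau1 <= tau2.  Errors are
estimated by bootstrap: resampling initial conditions for ensemble fits
(default 1500 cycles), or residual resampling for a single trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .diabatic import build_hamiltonian, effective_two_state
from .geometry import ReducedGeometry

__all__ = [
    "PopulationTrace",
    "DecayFit",
    "population_trace",
    "delayed_biexponential",
    "fit_delayed_biexponential",
    "bootstrap_errors",
    "ReducedDensity",
    "reduced_density",
    "absorption_spectrum",
]


@dataclass
class PopulationTrace:
    """S1 population on a uniform time grid (fs), values in [0, 1]."""

    times: np.ndarray
    s1_population: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.s1_population = np.asarray(self.s1_population, float)
        if self.times.shape != self.s1_population.shape:
            raise ValueError("time and population grids differ in length")
        if np.any(self.s1_population < -1e-9) or np.any(self.s1_population > 1 + 1e-9):
            raise ValueError("population values must lie in [0, 1]")


@dataclass
class DecayFit:
    """Delayed-biexponential fit parameters with bootstrap errors."""

    t0: float
    tau1: float
    tau2: float
    amplitude_a: float
    residual: float
    errors: dict = field(default_factory=dict)
    degenerate: bool = False
    n_boot: int = 0

    def params(self) -> tuple[float, float, float, float]:
        return self.t0, self.tau1, self.tau2, self.amplitude_a


def population_trace(ensemble, dt_fs: float = 10.0,
                     t_max: float | None = None) -> PopulationTrace:
    """Weighted fraction of trajectories with active state S1 vs time."""
    trajs = ensemble.trajectories
    if not trajs:
        raise ValueError("empty ensemble")
    if t_max is None:
        t_max = max(t.times[-1] for t in trajs)
    grid = np.arange(0.0, t_max + 0.5 * dt_fs, dt_fs)
    pop = np.zeros_like(grid)
    for traj in trajs:
        # state as a step function of time; persists after trajectory end
        idx = np.clip(np.searchsorted(traj.times, grid, side="right") - 1,
                      0, len(traj.times) - 1)
        pop += traj.weight * (traj.active[idx] >= 1)
    return PopulationTrace(times=grid, s1_population=pop)


def delayed_biexponential(t, t0, tau1, tau2, a):
    """Evaluate the delayed biexponential decay model."""
    t = np.asarray(t, float)
    out = np.ones_like(t)
    late = t > t0
    dt = t[late] - t0
    out[late] = a * np.exp(-dt / tau1) + (1.0 - a) * np.exp(-dt / tau2)
    return out


def _fit_once(times, y, x0, bounds):
    def resid(x):
        t0, lt1, lt2, za = x
        a = 1.0 / (1.0 + np.exp(-za))
        return delayed_biexponential(times, t0, np.exp(lt1), np.exp(lt2), a) - y

    return least_squares(resid, x0, bounds=bounds, method="trf",
                         ftol=1e-12, xtol=1e-12)


def fit_delayed_biexponential(trace: PopulationTrace, n_boot: int = 0,
                              seed: int | None = None,
                              t0_starts=None) -> DecayFit:
    """Least-squares fit of the delayed biexponential to a population trace.

    Multi-start over the lag time t0 (default 10 starts in [0, 500] fs);
    ties are broken by lowest residual, then lowest t0.  A fit collapsing
    to a single exponential (a -> 0 or 1, or tau1 ~ tau2) raises the
    ``degenerate`` flag.  If ``n_boot`` > 0, residual-resampling bootstrap
    standard errors are attached.
    """
    times, y = trace.times, trace.s1_population
    if t0_starts is None:
        t0_starts = np.linspace(0.0, 500.0, 10)
    tmax = times[-1]
    lo = np.array([0.0, np.log(1.0), np.log(1.0), -8.0])
    hi = np.array([max(tmax / 2.0, 1.0), np.log(1e7), np.log(1e7), 8.0])
    best = None
    for t0g in t0_starts:
        for lt1, lt2 in ((np.log(200.0), np.log(5000.0)),
                         (np.log(500.0), np.log(2e4))):
            x0 = np.clip(np.array([t0g, lt1, lt2, 1.0]), lo, hi)
            try:
                res = _fit_once(times, y, x0, (lo, hi))
            except Exception:
                continue
            key = (res.cost, res.x[0])
            if best is None or key < best[0]:
                best = (key, res)
    if best is None:
        raise RuntimeError("delayed-biexponential fit failed")
    res = best[1]
    fit = _to_fit(res)
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        model = delayed_biexponential(times, *fit.params())
        r = y - model
        samples = []
        for _ in range(n_boot):
            yb = model + rng.choice(r, size=r.size, replace=True)
            try:
                rb = _fit_once(times, yb, res.x, (lo, hi))
            except Exception:
                continue
            fb = _to_fit(rb)
            if not fb.degenerate:
                samples.append(fb.params())
        if samples:
            arr = np.array(samples)
            fit.errors = {k: float(np.std(arr[:, i], ddof=1)) if len(arr) > 1 else 0.0
                          for i, k in enumerate(("t0", "tau1", "tau2", "amplitude_a"))}
        fit.n_boot = n_boot
    return fit


def _to_fit(res) -> DecayFit:
    t0, lt1, lt2, za = res.x
    a = 1.0 / (1.0 + np.exp(-za))
    tau1, tau2 = np.exp(lt1), np.exp(lt2)
    if tau1 > tau2:
        tau1, tau2 = tau2, tau1
        a = 1.0 - a
    degenerate = bool(a < 0.02 or a > 0.98 or tau2 / tau1 < 1.25)
    return DecayFit(t0=float(t0), tau1=float(tau1), tau2=float(tau2),
                    amplitude_a=float(a),
                    residual=float(np.sqrt(2.0 * res.cost / res.fun.size)),
                    degenerate=degenerate)


def bootstrap_errors(ensemble, n_boot: int = 1500, seed: int | None = None,
                     dt_fs: float = 10.0) -> dict:
    """Bootstrap errors of the decay constants over initial conditions.

    Resamples trajectories (initial conditions) with replacement ``n_boot``
    times (default 1500 cycles), refits the delayed biexponential to each
    resampled population trace and reports per-parameter standard errors.
    Degenerate refits are dropped and counted.
    """
    trajs = ensemble.trajectories
    if len(trajs) < 5:
        raise ValueError("bootstrap needs at least 5 initial conditions")
    trace = population_trace(ensemble, dt_fs=dt_fs)
    point = fit_delayed_biexponential(trace)
    rng = np.random.default_rng(seed)
    n = len(trajs)
    t_max = max(t.times[-1] for t in trajs)
    grid = np.arange(0.0, t_max + 0.5 * dt_fs, dt_fs)
    # precompute per-trajectory S1 indicators on the grid
    states = np.empty((n, grid.size))
    w = np.array([t.weight for t in trajs])
    for i, traj in enumerate(trajs):
        idx = np.clip(np.searchsorted(traj.times, grid, side="right") - 1,
                      0, len(traj.times) - 1)
        states[i] = traj.active[idx] >= 1
    x_point = np.array([point.t0, np.log(point.tau1), np.log(point.tau2),
                        np.log(point.amplitude_a / (1 - point.amplitude_a + 1e-12))])
    lo = np.array([0.0, 0.0, 0.0, -8.0])
    hi = np.array([max(grid[-1] / 2.0, 1.0), np.log(1e7), np.log(1e7), 8.0])
    x_point = np.clip(x_point, lo, hi)
    samples, dropped = [], 0
    for _ in range(n_boot):
        pick = rng.integers(0, n, size=n)
        wb = w[pick]
        yb = wb @ states[pick] / wb.sum()
        try:
            res = _fit_once(grid, yb, x_point, (lo, hi))
            fb = _to_fit(res)
        except Exception:
            dropped += 1
            continue
        if fb.degenerate:
            dropped += 1
            continue
        samples.append(fb.params())
    out = {"n_boot": n_boot, "n_degenerate": dropped, "point": point}
    if samples:
        arr = np.array(samples)
        for i, k in enumerate(("t0", "tau1", "tau2", "amplitude_a")):
            out[k] = float(np.std(arr[:, i], ddof=1)) if len(arr) > 1 else 0.0
    return out


@dataclass
class ReducedDensity:
    """Monte-Carlo reduced S1 density along one torsion.

    ``density[i, j]`` is the density at time ``times[i]`` and angle
    ``angles[j]`` (degrees); each time slice integrates (over degrees) to
    the instantaneous S1 population, within Monte-Carlo error.
    """

    coordinate: str
    times: np.ndarray
    angles: np.ndarray
    density: np.ndarray

    def slice_integral(self, i: int) -> float:
        return float(np.trapezoid(self.density[i], self.angles))


def reduced_density(ensemble, coordinate: str, time_grid, angle_grid,
                    n_mc: int = 2000, seed: int | None = None,
                    kernel_sigma_deg: float = 8.0) -> ReducedDensity:
    """Monte-Carlo reduced S1 density along phi_I or phi_P.

    For each time, ``n_mc`` trajectories are drawn with replacement by
    weight; each draw on S1 deposits a Gaussian kernel (sigma 8°) at its
    current torsion angle, so the time-slice integral estimates the
    instantaneous S1 population.
    """
    if coordinate not in ("phi_I", "phi_P"):
        raise ValueError("coordinate must be 'phi_I' or 'phi_P'")
    col = 1 if coordinate == "phi_I" else 0
    trajs = ensemble.trajectories
    w = np.array([t.weight for t in trajs])
    w = w / w.sum()
    rng = np.random.default_rng(seed)
    times = np.asarray(time_grid, float)
    angles = np.asarray(angle_grid, float)
    dens = np.zeros((times.size, angles.size))
    norm = 1.0 / (kernel_sigma_deg * np.sqrt(2 * np.pi))
    for it, t in enumerate(times):
        picks = rng.choice(len(trajs), size=n_mc, p=w)
        for ip in picks:
            traj = trajs[ip]
            idx = min(max(np.searchsorted(traj.times, t, side="right") - 1, 0),
                      len(traj.times) - 1)
            if traj.active[idx] < 1:
                continue
            ang = np.rad2deg(traj.qs[idx, col])
            dens[it] += norm / n_mc * np.exp(
                -0.5 * ((angles - ang) / kernel_sigma_deg) ** 2)
    return ReducedDensity(coordinate=coordinate, times=times, angles=angles,
                          density=dens)


def absorption_spectrum(ics, fwhm_eV: float = 0.07, shift_eV: float = 0.16,
                        params=None, grid=None):
    """Gaussian-convolved absorption spectrum from vertical gaps.

    Each initial condition contributes a Gaussian centered at its vertical
    gap plus ``shift_eV`` with the given FWHM.  If ``params`` is supplied,
    sticks are weighted by the oscillator-strength surrogate
    (effective P/I coupling)²/gap; otherwise weights are uniform.

    Returns (energy grid, intensity).
    """
    gaps = np.array([ic.vertical_gap for ic in ics])
    weights = np.array([ic.weight for ic in ics])
    if params is not None:
        osc = []
        for ic in ics:
            H = build_hamiltonian(params, ic.q)
            _, v, _ = effective_two_state(H)
            osc.append(v**2 / max(ic.vertical_gap, 1e-6))
        weights = weights * np.array(osc)
    centers = gaps + shift_eV
    if grid is None:
        lo = centers.min() - 5 * max(fwhm_eV, 1e-3)
        hi = centers.max() + 5 * max(fwhm_eV, 1e-3)
        grid = np.linspace(lo, hi, 2001)
    grid = np.asarray(grid, float)
    if fwhm_eV <= 0:
        # stick spectrum: nearest-gridpoint histogram
        out = np.zeros_like(grid)
        for c, w in zip(centers, weights):
            out[np.argmin(np.abs(grid - c))] += w
        return grid, out
    sig = fwhm_eV / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    out = np.zeros_like(grid)
    for c, w in zip(centers, weights):
        out += w * np.exp(-0.5 * ((grid - c) / sig) ** 2)
    return grid, out
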