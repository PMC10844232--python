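"""Shared fixtures: parameter sets, critical points and reference ensembles.

Expensive objects (MECI searches, surface-hopping ensembles) are session-
scoped so the dynamics, committor and acceptance tests share them.
"""

import numpy as np
import pytest

from chromodyn import (InitialCondition, PropagationSettings, builtin_params,
                       filter_excitation_window, run_ensemble, sample_wigner)
from chromodyn.surfaces import branching_plane, locate_meci

DEG = np.pi / 180.0


def cubic_eigenvalues(A):
    """Independent 3x3 symmetric eigenvalue oracle: characteristic-polynomial
    roots via numpy.roots (no LAPACK eigensolver involved)."""
    A = np.asarray(A, float)
    c2 = -np.trace(A)
    c1 = (A[0, 0] * A[1, 1] + A[0, 0] * A[2, 2] + A[1, 1] * A[2, 2]
          - A[0, 1] ** 2 - A[0, 2] ** 2 - A[1, 2] ** 2)
    c0 = -np.linalg.det(A)
    roots = np.roots([1.0, c2, c1, c0])
    return np.sort(roots.real)


def windowed_ensemble(params, n_traj, seed, max_time_fs=3000.0):
    """Wigner sampling + pump-window filter + FSSH ensemble, the protocol
    used throughout for chromophore comparisons."""
    rng = np.random.default_rng(seed)
    kept = []
    for _ in range(40):
        ics = sample_wigner(params, 4 * n_traj, 300.0,
                            seed=int(rng.integers(0, 2**31 - 1)))
        kept += filter_excitation_window(ics, 2.48, 0.05,
                                         shift_eV=params.spectral_shift)
        if len(kept) >= n_traj:
            break
    kept = kept[:n_traj]
    w = sum(ic.weight for ic in kept)
    kept = [InitialCondition(q=ic.q, p=ic.p, vertical_gap=ic.vertical_gap,
                             weight=ic.weight / w) for ic in kept]
    settings = PropagationSettings(max_time_fs=max_time_fs)
    return run_ensemble(params, kept, settings, seed=seed)


@pytest.fixture(scope="session")
def hbdi():
    return builtin_params("HBDI")


@pytest.fixture(scope="session")
def tfhbdi():
    return builtin_params("TFHBDI")


@pytest.fixture(scope="session")
def mhbdi_in():
    return builtin_params("MHBDI_in_plane")


@pytest.fixture(scope="session")
def mhbdi_out():
    return builtin_params("MHBDI_out_of_plane")


@pytest.fixture(scope="session")
def hbdi_meci_i(hbdi):
    """HBDI I-twisted MECI geometry, energy and branching plane."""
    geom, energy = locate_meci(hbdi, [0.0, 90 * DEG, 25 * DEG, 0.0])
    plane = branching_plane(hbdi, geom.to_array())
    return geom, energy, plane


@pytest.fixture(scope="session")
def tf_meci_i(tfhbdi):
    geom, energy = locate_meci(tfhbdi, [0.0, 90 * DEG, 25 * DEG, 0.0])
    plane = branching_plane(tfhbdi, geom.to_array())
    return geom, energy, plane


@pytest.fixture(scope="session")
def tf_ensemble(tfhbdi):
    """500-trajectory TF ensemble under the pump-window protocol."""
    return windowed_ensemble(tfhbdi, 500, seed=11)


@pytest.fixture(scope="session")
def hbdi_ensemble(hbdi):
    """500-trajectory HBDI ensemble under the matched protocol."""
    return windowed_ensemble(hbdi, 500, seed=11)
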