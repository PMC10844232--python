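"""Model surfaces: gradients, couplings, critical points, paths."""

from pathlib import Path

import numpy as np
import pytest

from chromodyn import ReducedGeometry, potential
from chromodyn.calibration import seam_endpoints
from chromodyn.surfaces import (_neb_optimize, branching_plane,
                                derivative_coupling, fragment_inertia,
                                locate_meci, locate_minimum, neb_path,
                                ring_inertia_from_xyz, seam_path)

DEG = np.pi / 180.0
RINGS = Path(__file__).resolve().parents[1] / "src/chromodyn/data/rings"


def random_geometries(n, seed=0):
    rng = np.random.default_rng(seed)
    return [np.array([rng.uniform(-np.pi, np.pi), rng.uniform(-np.pi, np.pi),
                      rng.uniform(-1.3, 1.3), rng.uniform(-0.25, 0.25)])
            for _ in range(n)]


class TestPotential:
    def test_planar_minimum_is_stationary(self, hbdi):
        qmin = locate_minimum(hbdi, 0, [0.0, 0.0, 0.0, 0.0])
        e, g = potential(hbdi, 0, qmin)
        assert np.linalg.norm(g) < 1e-6
        assert e == pytest.approx(0.0, abs=1e-10)  # energy zero at S0 min

    def test_gradients_match_finite_differences(self, hbdi):
        h = 1e-5
        for q in random_geometries(1000, seed=2):
            for state in (0, 1, 2):
                e, g = potential(hbdi, state, q)
                for k in range(4):
                    qp, qm = q.copy(), q.copy()
                    qp[k] += h
                    qm[k] -= h
                    fd = (potential(hbdi, state, qp)[0]
                          - potential(hbdi, state, qm)[0]) / (2 * h)
                    scale = max(abs(fd), 1.0)
                    assert abs(fd - g[k]) / scale < 1e-6

    def test_tf_s1_monotone_uphill_along_p_torsion(self, tfhbdi):
        qmin = locate_minimum(tfhbdi, 0, [0.0, 0.0, 0.0, 0.0]).to_array()
        energies = []
        for phi in np.linspace(0, 90 * DEG, 46):
            q = qmin.copy()
            q[0] = phi
            energies.append(potential(tfhbdi, 1, q)[0])
        assert np.all(np.diff(energies) > -1e-9)

    def test_invalid_state_index(self, hbdi):
        with pytest.raises(ValueError):
            potential(hbdi, 3, [0.0, 0.0, 0.0, 0.0])


class TestDerivativeCoupling:
    def test_antisymmetric(self, hbdi):
        for q in random_geometries(50, seed=4):
            d01 = derivative_coupling(hbdi, q, 0, 1)
            d10 = derivative_coupling(hbdi, q, 1, 0)
            np.testing.assert_allclose(d01, -d10, atol=1e-12)

    def test_doubly_twisted_torsional_components_vanish(self, hbdi):
        """At phi_P = phi_I = 90° the P-I coupling derivative vanishes in
        every coordinate (each gating factor retains the other's cosine),
        while the fragment-bridge couplings keep finite torsional
        components."""
        q = np.array([90 * DEG, 90 * DEG, 0.2, 0.05])
        d01 = derivative_coupling(hbdi, q, 0, 1)
        # S0/S1 are the decoupled |I>, |P> states here: all components zero
        np.testing.assert_allclose(d01[:2], 0.0, atol=1e-12)
        np.testing.assert_allclose(d01[2:], 0.0, atol=1e-12)
        d_bridge = derivative_coupling(hbdi, q, 0, 2)
        assert np.abs(d_bridge[:2]).max() > 1e-3

    def test_inverse_gap_scaling(self):
        """Halving the gap at fixed numerator doubles the coupling norm.

        On the 1-D linear-crossing model at the crossing point the numerator
        <0|dH/dx|1> = (a1-a2)/2 is independent of the constant coupling c,
        while the gap is 2c."""
        from chromodyn import _kernels
        q = np.array([0.0])
        d_full, d_half = [], []
        for c in (0.2, 0.1):
            p = np.array([0.5, -0.5, c])
            E, U = _kernels.adiabatic(_kernels.MODEL_LINEAR, p, q)
            d = _kernels.nac_matrix(_kernels.MODEL_LINEAR, p, q, U, E)
            (d_full if c == 0.2 else d_half).append(abs(d[0, 1, 0]))
        assert d_half[0] == pytest.approx(2.0 * d_full[0], rel=1e-10)

    def test_matches_eigenvector_differentiation_oracle(self, hbdi):
        """d_ij equals the phase-tracked numerical derivative of the
        eigenvectors, <i(q)| d/dq |j(q)>."""
        from chromodyn import _kernels
        p = hbdi.to_array()
        h = 1e-6
        for q in random_geometries(40, seed=9):
            E, U = _kernels.adiabatic(0, p, q)
            if E[1] - E[0] < 0.05 or E[2] - E[1] < 0.05:
                continue
            d01 = derivative_coupling(hbdi, q, 0, 1)
            for k in range(4):
                qp, qm = q.copy(), q.copy()
                qp[k] += h
                qm[k] -= h
                _, Up = _kernels.adiabatic(0, p, qp)
                _, Um = _kernels.adiabatic(0, p, qm)
                _kernels.align_phases(Up, U)
                _kernels.align_phases(Um, U)
                dj = (Up[:, 1] - Um[:, 1]) / (2 * h)
                assert U[:, 0] @ dj == pytest.approx(d01[k], abs=1e-5)

    def test_degenerate_states_rejected(self):
        from chromodyn import ChromophoreParams
        p = ChromophoreParams(v_PI0=0.0, v_PB0=0.0, v_IB0=0.0,
                              r_P=0.0, r_I=0.0, b_P=0.0, b_I=0.0)
        with pytest.raises(ValueError, match="degenerate"):
            derivative_coupling(p, [0.0, 0.0, 0.0, 0.0], 0, 1)

    def test_same_state_rejected(self, hbdi):
        with pytest.raises(ValueError):
            derivative_coupling(hbdi, [0, 0, 0, 0], 1, 1)


class TestFragmentInertia:
    def test_rigid_rotor_sum(self):
        assert fragment_inertia([1.0, 1.0], [1.0, 1.0]) == 2.0

    def test_substituted_rings_are_heavier(self):
        i_h = ring_inertia_from_xyz(RINGS / "p_ring_hbdi.xyz", axis=(0, 3))
        i_f = ring_inertia_from_xyz(RINGS / "p_ring_tfhbdi.xyz", axis=(0, 3))
        i_m = ring_inertia_from_xyz(RINGS / "p_ring_mhbdi.xyz", axis=(0, 3))
        assert i_f > i_h
        assert i_m > i_h

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fragment_inertia([], [])


class TestLocateMinimum:
    def test_twisted_s1_minimum_near_90(self, hbdi):
        g = locate_minimum(hbdi, 1, [0.0, 80 * DEG, 0.0, hbdi.r_P])
        assert g.phi_I == pytest.approx(90.0, abs=5.0)

    def test_idempotent_at_minimum(self, hbdi):
        g1 = locate_minimum(hbdi, 0, [0.0, 0.0, 0.0, 0.0])
        g2 = locate_minimum(hbdi, 0, g1)
        np.testing.assert_allclose(g1.to_array(), g2.to_array(), atol=1e-6)


class TestLocateMeci:
    def test_converges_to_tight_degeneracy(self, hbdi_meci_i, hbdi):
        geom, energy, _ = hbdi_meci_i
        q = geom.to_array()
        e0, g0 = potential(hbdi, 0, q)
        e1, g1 = potential(hbdi, 1, q)
        assert e1 - e0 < 1e-4

    def test_tf_meci_i_close_to_twisted_minimum(self, tfhbdi, tf_meci_i):
        _, e_meci, _ = tf_meci_i
        s1i = locate_minimum(tfhbdi, 1, [0.0, 85 * DEG, 0.0, tfhbdi.r_P])
        e_min = potential(tfhbdi, 1, s1i.to_array())[0]
        assert abs(e_meci - e_min) < 0.1

    def test_tf_meci_p_far_above_fc(self, tfhbdi):
        qmin = locate_minimum(tfhbdi, 0, [0.0, 0.0, 0.0, 0.0]).to_array()
        fc = potential(tfhbdi, 1, qmin)[0]
        _, e_meci_p = locate_meci(tfhbdi, [90 * DEG, 0.0, 25 * DEG, 0.0])
        assert e_meci_p - fc > 0.5

    def test_seam_projected_gradient_small(self, hbdi, hbdi_meci_i):
        """The mean-energy gradient at a converged MECI vanishes in the
        seam directions (complement of the branching plane)."""
        geom, _, plane = hbdi_meci_i
        q = geom.to_array()
        g0 = potential(hbdi, 0, q)[1]
        g1 = potential(hbdi, 1, q)[1]
        gmean = 0.5 * (g0 + g1)
        proj = (gmean - (gmean @ plane.g) * plane.g
                - (gmean @ plane.h) * plane.h)
        assert np.linalg.norm(proj) < 1e-3


class TestBranchingPlane:
    def test_orthonormal(self, hbdi_meci_i):
        _, _, plane = hbdi_meci_i
        assert np.linalg.norm(plane.g) == pytest.approx(1.0, abs=1e-12)
        assert np.linalg.norm(plane.h) == pytest.approx(1.0, abs=1e-12)
        assert plane.g @ plane.h == pytest.approx(0.0, abs=1e-10)

    def test_h_is_torsional_toward_e_isomer(self, hbdi_meci_i):
        _, _, plane = hbdi_meci_i
        assert abs(plane.h[1]) > 0.9
        assert plane.h[1] > 0  # +h points toward increasing phi_I

    def test_g_dominated_by_bla(self, hbdi_meci_i):
        _, _, plane = hbdi_meci_i
        assert np.argmax(np.abs(plane.g)) == 3

    def test_requires_near_degeneracy(self, hbdi):
        with pytest.raises(ValueError):
            branching_plane(hbdi, np.zeros(4))


def quartic_double_well(x):
    """1-D double well V = (x^2-1)^2 with saddle V(0) = 1."""
    q = np.atleast_1d(x)
    v = (q[0] ** 2 - 1.0) ** 2
    g = np.array([4.0 * q[0] * (q[0] ** 2 - 1.0)])
    return v, g


class TestNebPath:
    def test_double_well_barrier_matches_closed_form(self):
        path, E = _neb_optimize(quartic_double_well, np.array([-1.0]),
                                np.array([1.0]), 21, np.array([1.0]))
        assert E.max() - E[0] == pytest.approx(1.0, abs=1e-4)

    def test_monotone_downhill_barrier_zero(self):
        def slope(x):
            return float(x[0]), np.array([1.0])
        path, E = _neb_optimize(slope, np.array([1.0]), np.array([-1.0]),
                                11, np.array([1.0]))
        assert max(E.max() - E[0], 0.0) == 0.0

    def test_mhbdi_in_plane_i_torsion_barrier(self, mhbdi_in):
        qmin = locate_minimum(mhbdi_in, 0, [0.0, 0.0, 0.0, 0.0]).to_array()
        s1i = locate_minimum(mhbdi_in, 1, [0.0, 85 * DEG, 0.0, mhbdi_in.r_P])
        res = neb_path(mhbdi_in, 1, qmin, s1i.to_array(), n_images=15)
        assert res.barrier == pytest.approx(0.05, abs=0.02)

    def test_barrier_stable_under_image_doubling(self, mhbdi_in):
        qmin = locate_minimum(mhbdi_in, 0, [0.0, 0.0, 0.0, 0.0]).to_array()
        s1i = locate_minimum(mhbdi_in, 1, [0.0, 85 * DEG, 0.0, mhbdi_in.r_P])
        b1 = neb_path(mhbdi_in, 1, qmin, s1i.to_array(), n_images=15).barrier
        b2 = neb_path(mhbdi_in, 1, qmin, s1i.to_array(), n_images=29).barrier
        assert abs(b1 - b2) < 5e-3

    def test_identical_anchors_rejected(self, hbdi):
        with pytest.raises(ValueError):
            neb_path(hbdi, 1, np.zeros(4), np.zeros(4))


class TestSeamPath:
    def test_identical_endpoints_single_point(self, hbdi_meci_i, hbdi):
        geom, _, _ = hbdi_meci_i
        res = seam_path(hbdi, geom.to_array(), geom.to_array())
        assert len(res.images) == 1
        assert res.barrier == 0.0

    def test_hbdi_seam_barrier(self, hbdi, hbdi_meci_i):
        geom, _, _ = hbdi_meci_i
        qa = geom.to_array()
        qb = qa.copy()
        qb[2] = -qb[2]
        res = seam_path(hbdi, qa, qb, n_images=15)
        assert res.barrier == pytest.approx(0.10, abs=0.05)
        # every image stays near-degenerate
        for im in res.images:
            q = im.to_array()
            gap = potential(hbdi, 1, q)[0] - potential(hbdi, 0, q)[0]
            assert gap < 2e-3

    def test_tf_seam_has_interior_minimum(self, tfhbdi):
        qa, qb = seam_endpoints(tfhbdi)
        res = seam_path(tfhbdi, qa, qb, n_images=15)
        interior = res.energies[1:-1].min()
        assert interior < min(res.energies[0], res.energies[-1]) - 0.05
        assert res.barrier == pytest.approx(0.0, abs=1e-6)

    def test_non_degenerate_endpoint_rejected(self, hbdi):
        with pytest.raises(ValueError):
            seam_path(hbdi, np.zeros(4), np.array([0.0, np.pi / 2, 0.4, 0.0]))
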