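"""Cone sampling, committor schemes, equicommittor, hop velocities."""

import numpy as np
import pytest

from chromodyn import (ReducedGeometry, committor, committor_map, cone_sample,
                       equicommittor_map, hop_velocity_distribution)
from chromodyn.committor import CommittorMap, ConeSample

DEG = np.pi / 180.0


class TestConeSample:
    def test_zero_radius_is_meci(self, hbdi_meci_i):
        geom, _, plane = hbdi_meci_i
        s = cone_sample(geom.to_array(), plane, [0.0], [0.0])[0]
        np.testing.assert_allclose(s.geometry.to_array(), geom.to_array(),
                                   atol=1e-12)

    def test_displacement_lies_in_branching_plane(self, hbdi_meci_i):
        geom, _, plane = hbdi_meci_i
        samples = cone_sample(geom.to_array(), plane, [0.05, 0.2],
                              np.arange(0, 360, 40))
        for s in samples:
            d = s.geometry.to_array() - geom.to_array()
            residual = (d - (d @ plane.g) * plane.g
                        - (d @ plane.h) * plane.h)
            assert np.linalg.norm(residual) < 1e-10

    def test_90_degrees_is_pure_positive_h(self, hbdi_meci_i):
        geom, _, plane = hbdi_meci_i
        s = cone_sample(geom.to_array(), plane, [0.1], [90.0])[0]
        d = s.geometry.to_array() - geom.to_array()
        np.testing.assert_allclose(d, 0.1 * plane.h, atol=1e-12)
        assert d[1] > 0  # increasing phi_I

    def test_negative_radius_rejected(self, hbdi_meci_i):
        geom, _, plane = hbdi_meci_i
        with pytest.raises(ValueError):
            ConeSample(meci="x", radius=-0.1, angle=0.0,
                       geometry=ReducedGeometry())


def _sample_at(geometry):
    return ConeSample(meci="test", radius=0.0, angle=0.0, geometry=geometry)


class TestCommittor:
    def test_far_wells_are_absorbing(self, hbdi):
        z_point = _sample_at(ReducedGeometry(phi_I=10.0))
        e_point = _sample_at(ReducedGeometry(phi_I=170.0))
        for scheme in ("mep", "zero_velocity"):
            assert committor(hbdi, z_point, scheme) == "Z"
            assert committor(hbdi, e_point, scheme) == "E"
        rz = committor(hbdi, z_point, "random_velocity", n_velocities=10,
                       seed=1)
        re = committor(hbdi, e_point, "random_velocity", n_velocities=10,
                       seed=1)
        assert rz["p_E"] == 0.0
        assert re["p_E"] == 1.0

    def test_random_velocity_reproducible(self, hbdi, hbdi_meci_i):
        geom, _, plane = hbdi_meci_i
        s = cone_sample(geom.to_array(), plane, [0.1], [90.0])[0]
        r1 = committor(hbdi, s, "random_velocity", n_velocities=20, seed=9)
        r2 = committor(hbdi, s, "random_velocity", n_velocities=20, seed=9)
        assert r1 == r2

    def test_mep_outcome_invariant_to_step_size(self, hbdi, hbdi_meci_i):
        geom, _, plane = hbdi_meci_i
        for angle in (45.0, 135.0, 270.0):
            s = cone_sample(geom.to_array(), plane, [0.1], [angle])[0]
            o1 = committor(hbdi, s, "mep", descent_step=0.05)
            o2 = committor(hbdi, s, "mep", descent_step=0.02)
            assert o1 == o2

    def test_unknown_scheme_rejected(self, hbdi, hbdi_meci_i):
        geom, _, plane = hbdi_meci_i
        s = cone_sample(geom.to_array(), plane, [0.1], [0.0])[0]
        with pytest.raises(ValueError):
            committor(hbdi, s, "diffusion")


class TestEquicommittor:
    def _logistic_map(self, width_deg=5.0):
        radii = np.array([0.05, 0.1, 0.2])
        angles = np.arange(0.0, 181.0, 7.5)
        p = 1.0 / (1.0 + np.exp(-(angles - 90.0) / width_deg))
        values = np.tile(p, (radii.size, 1))
        return CommittorMap(radii=radii, angles=angles, values=values,
                            labels=[["p"] * angles.size] * radii.size,
                            scheme="random_velocity", n_velocities=50, seed=0)

    def test_logistic_field_contour_at_90(self):
        cmap = self._logistic_map()
        contour = equicommittor_map(cmap)
        assert len(contour) > 0
        np.testing.assert_allclose(contour[:, 1], 90.0, atol=1.0)

    def test_contour_points_interpolate_to_half(self):
        cmap = self._logistic_map()
        for r, a in equicommittor_map(cmap):
            assert abs(cmap.interp(r, a) - 0.5) < 1e-6

    def test_uniform_field_has_empty_contour(self):
        cmap = self._logistic_map()
        cmap.values[:] = 1.0
        assert equicommittor_map(cmap).size == 0

    def test_requires_random_velocity_scheme(self):
        cmap = self._logistic_map()
        cmap.scheme = "mep"
        with pytest.raises(ValueError):
            equicommittor_map(cmap)


class TestHopVelocityDistribution:
    def test_positive_torsional_velocity_projects_positive(self, hbdi,
                                                           hbdi_meci_i):
        from chromodyn.dynamics import HopEvent, Trajectory, Ensemble
        geom, _, plane = hbdi_meci_i
        p = np.zeros(4)
        p[1] = hbdi.inertia_I * 0.5  # +phi_I angular momentum
        hop = HopEvent(time=100.0, q=ReducedGeometry(phi_I=91.0), p=p,
                       from_state=1, to_state=0, gap=0.01,
                       transferred_weight=1.0)
        traj = Trajectory(times=np.array([0.0, 250.0]), qs=np.zeros((2, 4)),
                          moms=np.zeros((2, 4)), active=np.array([1, 0]),
                          populations=np.zeros((2, 3)), hops=[hop], status=1,
                          energy_drift=0.0, label="E")
        ens = Ensemble(trajectories=[traj], params_name="HBDI", seed=0)
        out = hop_velocity_distribution(ens, plane, params=hbdi)
        assert out["E"][0] > 0

    def test_mirrored_hops_fold_to_symmetric_distribution(self, hbdi,
                                                          hbdi_meci_i):
        """Hops at ±phi_I with mirrored velocities are folded onto one
        side; a mirror-symmetric pair gives mean exactly zero."""
        from chromodyn.dynamics import HopEvent, Trajectory, Ensemble
        _, _, plane = hbdi_meci_i
        trajs = []
        for sign in (+1, -1):
            p = np.zeros(4)
            p[1] = sign * hbdi.inertia_I * 0.3
            hop = HopEvent(time=50.0, q=ReducedGeometry(phi_I=sign * 92.0),
                           p=p, from_state=1, to_state=0, gap=0.02,
                           transferred_weight=0.5)
            trajs.append(Trajectory(
                times=np.array([0.0, 200.0]), qs=np.zeros((2, 4)),
                moms=np.zeros((2, 4)), active=np.array([1, 0]),
                populations=np.zeros((2, 3)), hops=[hop], status=1,
                energy_drift=0.0, label="Z", weight=0.5))
        ens = Ensemble(trajectories=trajs, params_name="HBDI", seed=0)
        out = hop_velocity_distribution(ens, plane, params=hbdi)
        assert np.mean(out["Z"]) == pytest.approx(out["Z"][0], abs=1e-12)
        assert out["Z"][0] == pytest.approx(out["Z"][1])

    def test_tf_distribution_displaced_toward_positive(self, tfhbdi,
                                                       tf_ensemble,
                                                       tf_meci_i):
        """TF hop velocities along +h are predominantly positive (ballistic
        approach toward the E isomer), and the isomerizing subset almost
        exclusively so."""
        _, _, plane = tf_meci_i
        out = hop_velocity_distribution(tf_ensemble, plane, params=tfhbdi)
        all_vh = np.concatenate([v for v in out.values()])
        assert len(all_vh) > 100
        assert np.median(all_vh) > 0
        assert (all_vh > 0).mean() > 0.6
        assert (out["E"] > 0).mean() > 0.9

    def test_no_hops_gives_empty(self, hbdi, hbdi_meci_i):
        from chromodyn import synth_ensemble
        _, _, plane = hbdi_meci_i
        ens = synth_ensemble(lambda rng, n: np.full(n, 1.0), {"trapped": 1.0},
                             5, seed=0)
        assert hop_velocity_distribution(ens, plane, params=hbdi) == {}


def test_polar_plot_renders(tmp_path):
    import matplotlib
    matplotlib.use("Agg")
    radii = np.array([0.05, 0.1])
    angles = np.arange(0.0, 360.0, 45.0)
    cmap = CommittorMap(radii=radii, angles=angles,
                        values=np.random.default_rng(0).random((2, 8)),
                        labels=[["p"] * 8] * 2, scheme="random_velocity",
                        n_velocities=10, seed=0)
    ax = cmap.plot_polar()
    ax.figure.savefig(tmp_path / "map.png")
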