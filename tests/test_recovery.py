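"""Closed-form mirror-symmetric recovery: oracles, round trips, invariants."""

import math

import numpy as np
import pytest

from conftest import ray_mirror_oracle
from mirrorshape.geometry import (Camera, project_perspective,
                                  similarity_procrustes_distance)
from mirrorshape.recovery import (CorrespondenceError, ImageCorrespondenceSet,
                                  SingularConfigurationError, back_project,
                                  canonical_plane_parameters,
                                  estimate_vanishing_point, midpoint_image,
                                  polar_about_vanishing_point, recover_depths,
                                  recover_shape, reproject, vanishing_line)
from mirrorshape.stimuli import random_symmetric_pairs


class TestVanishingPoint:
    def test_lines_through_known_point(self):
        v = np.array([3.0, 0.0])
        angles = [0.3, 1.1, 2.0]
        p = np.array([v + 1.0 * np.array([np.cos(a), np.sin(a)]) for a in angles])
        q = np.array([v + 2.5 * np.array([np.cos(a), np.sin(a)]) for a in angles])
        est = estimate_vanishing_point(p, q)
        assert not est.orthographic
        np.testing.assert_allclose(est.point, v, atol=1e-10)
        assert est.residual < 1e-12

    def test_parallel_chords_flag_orthographic(self):
        p = np.array([[0.0, 0.0], [0.0, 1.0], [0.5, 2.0]])
        q = p + np.array([1.0, 0.0])
        est = estimate_vanishing_point(p, q)
        assert est.orthographic
        np.testing.assert_allclose(np.abs(est.direction), [1.0, 0.0], atol=1e-12)

    def test_noisy_lines_recover_point_with_noise_scale_residual(self, rng):
        v = np.array([3.0, 0.0])
        angles = rng.uniform(0.2, 2.9, 20)
        sigma = 1e-3
        p = np.array([v + 1.0 * np.array([np.cos(a), np.sin(a)]) for a in angles])
        q = np.array([v + 2.0 * np.array([np.cos(a), np.sin(a)]) for a in angles])
        est = estimate_vanishing_point(p + rng.normal(0, sigma, p.shape),
                                       q + rng.normal(0, sigma, q.shape))
        assert abs(est.point[0] - 3.0) < 0.1
        assert est.residual == pytest.approx(sigma, rel=2.0)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError, match="2 pairs"):
            estimate_vanishing_point([[0, 0]], [[1, 1]])


class TestVanishingLine:
    @pytest.mark.parametrize("z_F,x_v,expected", [
        (3.0, 3.0, -3.0),     # x_v = z_F gives x_h = -z_F
        (2.0, -4.0, 1.0),     # -z_F²/x_v = -4/-4
        (1.0, 1e12, -1e-12),  # far vanishing point: line at the principal point
    ])
    def test_algebra(self, z_F, x_v, expected):
        assert vanishing_line(x_v, Camera(z_F)) == pytest.approx(expected)

    def test_frontoparallel_plane_is_singular(self):
        with pytest.raises(SingularConfigurationError):
            vanishing_line(0.0, Camera(1.0))


class TestMidpointImage:
    def test_equal_radii_reduce_to_the_common_point(self):
        m = midpoint_image([2.0], [2.0], [0.5], 3.0)
        np.testing.assert_allclose(m, [[3.0 + 2.0 * np.cos(0.5), 2.0 * np.sin(0.5)]])

    def test_vanishing_radius_pulls_midpoint_to_v(self):
        m = midpoint_image([1.0], [1e-12], [1.0], 3.0)
        np.testing.assert_allclose(m, [[3.0, 0.0]], atol=1e-11)

    def test_harmonic_never_exceeds_arithmetic_mean(self, rng):
        """The projected 3D midpoint lies nearer the vanishing point than the
        image midpoint of the pair (AM-HM inequality)."""
        r1 = rng.uniform(0.1, 5.0, 200)
        r2 = rng.uniform(0.1, 5.0, 200)
        alpha = rng.uniform(0, 2 * np.pi, 200)
        m = midpoint_image(r1, r2, alpha, 0.0)
        h = np.linalg.norm(m, axis=1)
        assert np.all(h <= 0.5 * (r1 + r2) + 1e-12)

    def test_degenerate_pair_rejected(self):
        with pytest.raises(ValueError):
            midpoint_image([0.0], [0.0], [0.0], 1.0)

    def test_matches_projection_of_true_3d_midpoint(self, symmetric_scene, rng):
        """Midpoint-consistency oracle: the harmonic-mean construction equals
        the perspective image of (P+Q)/2 on random configurations."""
        worst = 0.0
        for _ in range(200):
            sc = symmetric_scene(n_pairs=5, z_F=float(rng.choice([2.0, 10.0, 100.0])))
            canon_p = sc["corr"].p @ _rot2(-sc["theta"]).T
            canon_q = sc["corr"].q @ _rot2(-sc["theta"]).T
            canon = ImageCorrespondenceSet(canon_p, canon_q, sc["camera"])
            r_phi, r_psi, alpha, swapped = polar_about_vanishing_point(canon, sc["x_v"])
            m = midpoint_image(r_phi, r_psi, alpha, sc["x_v"])
            m_world = m @ _rot2(sc["theta"]).T
            m_true = project_perspective(0.5 * (sc["P"] + sc["Q"]), sc["camera"])
            worst = max(worst, np.abs(m_world - m_true).max())
        assert worst < 1e-10


def _rot2(theta):
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s], [s, c]])


class TestRecoverDepths:
    def test_matches_ray_intersection_oracle(self, symmetric_scene, rng):
        """Dual-route validation: the closed-form depths agree with the
        independent ray/mirror-constraint linear solve."""
        for _ in range(50):
            sc = symmetric_scene(n_pairs=6, z_F=float(rng.choice([2.0, 10.0])))
            P_or, Q_or = ray_mirror_oracle(sc["corr"].p, sc["corr"].q,
                                           sc["camera"], sc["plane"])
            shape = recover_shape(sc["corr"], d_c=sc["d_c"])
            assert np.abs(shape.P - P_or).max() < 1e-8
            assert np.abs(shape.Q - Q_or).max() < 1e-8

    def test_swapping_radii_swaps_outputs(self):
        cam = Camera(2.0)
        z1, z2 = recover_depths([1.0], [2.0], [0.4], 3.0, cam, 1.0)
        z2s, z1s = recover_depths([2.0], [1.0], [0.4], 3.0, cam, 1.0)
        assert z1 == pytest.approx(z1s)
        assert z2 == pytest.approx(z2s)

    def test_equal_radii_give_equal_depths(self):
        z1, z2 = recover_depths([1.5], [1.5], [0.2], 3.0, Camera(2.0), 1.0)
        assert z1 == pytest.approx(z2)

    def test_midpoint_on_vanishing_line_rejected(self):
        cam = Camera(1.0)
        x_v = 1.0  # x_h = -1; choose radii placing the midpoint exactly there
        # harmonic radius h with alpha = pi: x_m = x_v - h = -1  =>  h = 2
        with pytest.raises(SingularConfigurationError):
            recover_depths([2.0], [2.0], [np.pi], x_v, cam, 1.0)


class TestBackProject:
    def test_principal_ray(self):
        np.testing.assert_allclose(back_project([(0, 0)], -3.7, Camera(2.0)),
                                   [(0, 0, -3.7)])

    def test_inverts_projection_example(self):
        np.testing.assert_allclose(back_project([(0.5, 0)], -1.0, Camera(1.0)),
                                   [(1.0, 0.0, -1.0)])

    def test_projection_round_trip(self, rng):
        cam = Camera(2.0)
        img = rng.uniform(-1, 1, (50, 2))
        z = rng.uniform(-5, -0.5, 50)
        back = back_project(img, z, cam)
        np.testing.assert_allclose(project_perspective(back, cam), img, atol=1e-12)

    def test_depth_at_center_rejected(self):
        with pytest.raises(SingularConfigurationError):
            back_project([(0.1, 0.2)], 2.0, Camera(2.0))


class TestRecoverShape:
    def test_roundtrip_with_true_parameters(self, symmetric_scene, rng):
        for z_F in (2.0, 10.0, 100.0):
            sc = symmetric_scene(n_pairs=8, z_F=z_F)
            shape = recover_shape(sc["corr"], d_c=sc["d_c"])
            assert np.abs(shape.P - sc["P"]).max() < 1e-8
            assert np.abs(shape.Q - sc["Q"]).max() < 1e-8

    def test_recovered_shape_is_symmetric_and_planar(self, symmetric_scene):
        sc = symmetric_scene(n_pairs=8)
        shape = recover_shape(sc["corr"])  # default d_c
        # midpoints on the symmetry plane
        assert np.sqrt(np.mean(shape.plane.signed_distance(shape.midpoints) ** 2)) < 1e-9
        # reflecting one half about the plane gives the other
        from mirrorshape.geometry import mirror_reflect
        assert np.abs(mirror_reflect(shape.P, shape.plane) - shape.Q).max() < 1e-8

    def test_reprojection_reproduces_input(self, symmetric_scene):
        sc = symmetric_scene(n_pairs=8)
        shape = recover_shape(sc["corr"])
        re = reproject(shape)
        assert np.abs(re.p - sc["corr"].p).max() < 1e-9
        assert np.abs(re.q - sc["corr"].q).max() < 1e-9

    def test_d_c_family_is_a_similarity_family(self, symmetric_scene):
        """The free parameter d_c changes size and distance, not shape."""
        sc = symmetric_scene(n_pairs=8)
        shapes = [recover_shape(sc["corr"], d_c=dc) for dc in (0.5, 1.0, 2.0)]
        for a in shapes:
            for b in shapes:
                assert similarity_procrustes_distance(a.points, b.points) < 1e-6

    def test_asymmetric_input_refused(self, rng):
        cam = Camera(2.0)
        p = rng.uniform(-1, 1, (8, 2))
        q = rng.uniform(-1, 1, (8, 2))
        with pytest.raises(CorrespondenceError):
            recover_shape(ImageCorrespondenceSet(p, q, cam))

    def test_forced_recovery_proceeds_on_bad_input(self, rng):
        cam = Camera(2.0)
        p = rng.uniform(-1, 1, (8, 2)) + np.array([2.0, 0.0])
        q = rng.uniform(-1, 1, (8, 2)) + np.array([4.0, 0.0])
        shape = recover_shape(ImageCorrespondenceSet(p, q, cam), force=True)
        assert shape.P.shape == (8, 3)

    def test_orthographic_convergence(self):
        """A fixed orthographic image, read as a perspective image with
        growing z_F, recovers shapes converging to an orthographic-family
        member: successive recoveries agree ever better."""
        local = np.random.default_rng(7)
        P, Q, plane = random_symmetric_pairs(8, local)
        cam_far = Camera(1e5)  # effectively orthographic viewing
        p_img = project_perspective(P, cam_far)
        q_img = project_perspective(Q, cam_far)
        prev = None
        dists = []
        for z_F in (1e2, 1e3, 1e4):
            corr = ImageCorrespondenceSet(p_img, q_img, Camera(z_F))
            shape = recover_shape(corr, force=True, parallel_tol=1e-14)
            if prev is not None:
                dists.append(similarity_procrustes_distance(prev, shape.points))
            prev = shape.points
        # successive members approach each other at roughly O(1/z_F)
        assert dists[1] < 0.5 * dists[0]
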