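"""Synthetic scene generator: projection, carrier tangency, silhouette conic,
rendering and batch generation."""

import numpy as np
import pytest
from scipy.optimize import minimize

from ovometry.errors import (
    BehindCameraError,
    FramingError,
    GeometryError,
    ParameterError,
)
from ovometry.projective import PlanePoint, cross_ratio
from ovometry.simulate import (
    CameraModel,
    CarrierGroove,
    EggEllipsoid,
    conic_extreme_points,
    default_scene,
    generate_batch,
    project,
    project_direction,
    render_scene,
    resting_height,
    silhouette_conic,
)


def frontal_camera(depth_axis=True):
    """Identity-pose camera at the origin looking along +z."""
    return CameraModel(
        fx=800, fy=800, cx=320, cy=240, rotation=np.eye(3), translation=np.zeros(3)
    )


class TestProjection:
    def test_optical_axis_hits_principal_point(self):
        cam = frontal_camera()
        assert np.allclose(project(cam, (0, 0, 500)).xy, [320, 240])

    def test_pinhole_similar_triangles(self):
        cam = frontal_camera()
        p = project(cam, (10.0, 0, 200.0))
        assert p.x - 320 == pytest.approx(800 * 10.0 / 200.0)

    def test_behind_camera_flagged(self):
        with pytest.raises(BehindCameraError):
            project(frontal_camera(), (0, 0, -10))

    def test_cross_ratio_preserved(self, rng):
        cam = CameraModel.look_at((-60, -400, 150), (0, 0, 20))
        for _ in range(50):
            base = rng.uniform(-30, 30, 3)
            w = rng.normal(size=3)
            w /= np.linalg.norm(w)
            params = np.sort(rng.uniform(-25, 25, 4))
            if np.min(np.diff(params)) < 0.5:
                continue
            world = [base + t * w for t in params]
            t1, t2, t3, t4 = params
            cr_world = ((t1 - t3) * (t2 - t4)) / ((t2 - t3) * (t1 - t4))
            imgs = [project(cam, X) for X in world]
            assert cross_ratio(*imgs) == pytest.approx(cr_world, rel=1e-9)

    def test_rotation_must_be_orthonormal(self):
        with pytest.raises(ParameterError):
            CameraModel(fx=800, fy=800, cx=320, cy=240,
                        rotation=np.eye(3) * 1.001, translation=np.zeros(3))


class TestRestingHeight:
    def test_flat_floor_limit(self):
        assert resting_height(21.0, np.pi / 2) == pytest.approx(21.0)

    def test_thirty_degree_groove(self):
        assert resting_height(21.0, np.pi / 6) == pytest.approx(42.0)

    def test_tangency_distance_to_walls(self, rng):
        for _ in range(50):
            b = rng.uniform(5, 30)
            a = rng.uniform(0.15, np.pi / 2 - 0.01)
            h = resting_height(b, a)
            for n in CarrierGroove(half_angle=a).wall_normals():
                assert abs(n @ np.array([0, 0, h])) == pytest.approx(b, abs=1e-9)

    def test_matches_brute_force_tangency_search(self, rng):
        """Minimize center height subject to both wall distances >= b_e."""
        for _ in range(20):
            b = rng.uniform(5, 30)
            a = rng.uniform(0.15, np.pi / 2 - 0.01)
            n1, n2 = CarrierGroove(half_angle=a).wall_normals()

            def neg_feasible(h):
                c = np.array([0, 0, float(np.atleast_1d(h)[0])])
                return max(b - n1 @ c, b - n2 @ c, 0.0) * 1e3 + h

            res = minimize(neg_feasible, x0=[3 * b], method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-10})
            assert resting_height(b, a) == pytest.approx(float(res.x[0]), abs=1e-6)

    def test_invalid_half_angle(self):
        with pytest.raises(ParameterError):
            resting_height(10.0, 0.0)
        with pytest.raises(ParameterError):
            resting_height(10.0, 2.0)


class TestSilhouetteConic:
    def test_axially_viewed_spheroid_silhouette_is_circle(self):
        cam = frontal_camera()
        egg = EggEllipsoid(semi_major=30, semi_minor=20,
                           center=np.array([0.0, 0, 300.0]),
                           axis_direction=np.array([0.0, 0, 1.0]))
        C = silhouette_conic(egg, cam)
        # centered at the principal point, isotropic
        ex = conic_extreme_points(C, (1, 0))
        ey = conic_extreme_points(C, (0, 1))
        assert np.allclose(0.5 * (ex.p1.xy + ex.p2.xy), [320, 240], atol=1e-6)
        assert ex.pixel_length == pytest.approx(ey.pixel_length, rel=1e-9)

    def test_camera_inside_rejected(self):
        egg = EggEllipsoid(semi_major=30, semi_minor=20,
                           center=np.array([0.0, 0, 5.0]))
        with pytest.raises(GeometryError):
            silhouette_conic(egg, frontal_camera())

    def test_sampled_surface_points_inside(self, scene, rng):
        C = scene.truth.conic
        pts = scene.egg.surface_points(10_000, rng)
        vals = []
        for p in pts:
            x = project(scene.camera, p).to_array()
            x = x / x[2]
            vals.append(float(x @ C @ x))
        assert max(vals) <= 1e-6

    def test_silhouette_chord_bias_positive_and_shrinking(self):
        """The silhouette's extremal chord overestimates the projected axis;
        the relative bias decreases with camera distance."""
        rel_bias = []
        for k in (1.0, 2.0, 4.0):
            cam = CameraModel.look_at(
                (-45 * k, -395 * k, 100 * k), (0, 0, 30), fx=800 * k, fy=800 * k
            )
            egg = EggEllipsoid(semi_major=27, semi_minor=21,
                               center=np.array([0.0, 0, 30.0]))
            C = silhouette_conic(egg, cam)
            pa = project(cam, egg.center + 27 * egg.axis_direction)
            pb = project(cam, egg.center - 27 * egg.axis_direction)
            d = pb.xy - pa.xy
            proj_len = np.linalg.norm(d)
            chord = conic_extreme_points(C, d / proj_len).pixel_length
            assert chord >= proj_len - 1e-9
            rel_bias.append(chord / proj_len - 1.0)
        assert rel_bias == sorted(rel_bias, reverse=True)

    def test_affine_limit_recovers_axis_lengths(self):
        egg = EggEllipsoid(semi_major=27, semi_minor=21,
                           center=np.array([0.0, 0, 30.0]))
        k = 64.0
        cam = CameraModel.look_at(
            (0, -395 * k, 30), (0, 0, 30), fx=800 * k, fy=800 * k
        )
        C = silhouette_conic(egg, cam)
        scale = 800 * k / (395 * k)  # px per mm at the egg
        chord = conic_extreme_points(C, (1, 0)).pixel_length
        assert chord / scale == pytest.approx(54.0, rel=1e-4)


class TestConicExtremes:
    def test_unit_circle(self):
        C = np.diag([1.0, 1.0, -1.0])
        ep = conic_extreme_points(C, (1, 0))
        assert np.allclose(ep.p1.xy, [-1, 0], atol=1e-12)
        assert np.allclose(ep.p2.xy, [1, 0], atol=1e-12)

    def test_axis_aligned_ellipse_vertical(self):
        C = np.diag([1.0 / 9.0, 1.0 / 4.0, -1.0])
        ep = conic_extreme_points(C, (0, 1))
        assert np.allclose(ep.p1.xy, [0, -2], atol=1e-12)
        assert np.allclose(ep.p2.xy, [0, 2], atol=1e-12)

    def test_matches_dense_boundary_sampling(self, rng):
        for _ in range(20):
            a, b = rng.uniform(2, 10, 2)
            phi = rng.uniform(0, np.pi)
            cx, cy = rng.uniform(-5, 5, 2)
            d = rng.normal(size=2)
            d /= np.linalg.norm(d)
            R = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
            ts = np.linspace(0, 2 * np.pi, 200_000, endpoint=False)
            bound = (R @ np.vstack([a * np.cos(ts), b * np.sin(ts)])).T + (cx, cy)
            smax = bound[np.argmax(bound @ d)]
            # conic matrix of the same ellipse
            A2 = R @ np.diag([1 / a**2, 1 / b**2]) @ R.T
            C = np.zeros((3, 3))
            C[:2, :2] = A2
            C[:2, 2] = -A2 @ (cx, cy)
            C[2, :2] = -A2 @ (cx, cy)
            C[2, 2] = (cx, cy) @ A2 @ (cx, cy) - 1.0
            ep = conic_extreme_points(C, d)
            # the support *value* agrees to 1e-6 (position agreement is only
            # as fine as the boundary sampling step)
            assert float(ep.p2.xy @ d) == pytest.approx(float(smax @ d), abs=1e-6)
            assert np.linalg.norm(ep.p2.xy - smax) < 1e-2

    def test_degenerate_conic_rejected(self):
        with pytest.raises(GeometryError):
            conic_extreme_points(np.zeros((3, 3)), (1, 0))


class TestRenderScene:
    def test_mask_classes_partition(self, rendered):
        labels = rendered.label_mask.labels
        assert set(np.unique(labels)) <= {0, 1, 2}
        assert (labels == 1).sum() > 0 and (labels == 2).sum() > 0

    def test_truth_endpoints_reproject_exactly(self, scene):
        t = scene.truth
        A = scene.egg.center + scene.egg.semi_major * scene.egg.axis_direction
        assert np.allclose(project(scene.camera, A).xy, t.major_endpoints.p1.xy)

    def test_framing_error_when_egg_outside(self):
        sc = default_scene()
        sc.camera = CameraModel.look_at((-45, -395, 100), (1000.0, 0, 40))
        sc.truth = None
        with pytest.raises(FramingError):
            render_scene(sc)


class TestGenerateBatch:
    def test_deterministic_given_seed(self):
        b1 = generate_batch(5, noise_px=0.5, seed=9)
        b2 = generate_batch(5, noise_px=0.5, seed=9)
        for s1, s2 in zip(b1, b2):
            assert s1.true_major_mm == s2.true_major_mm
            assert np.allclose(s1.scene_major.egg_a.xy, s2.scene_major.egg_a.xy)

    def test_zero_spread_gives_identical_axes(self):
        b = generate_batch(10, size_distribution=(54.0, 0.0, 42.0, 0.0), seed=0)
        assert {s.true_major_mm for s in b} == {54.0}
        assert {s.true_minor_mm for s in b} == {42.0}

    def test_sample_mean_matches_distribution(self):
        b = generate_batch(1000, seed=2)
        majors = np.array([s.true_major_mm for s in b])
        se = 1.85 / np.sqrt(len(b))
        assert abs(majors.mean() - 54.25) <= 3 * se

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ParameterError):
            generate_batch(3, size_distribution=(40.0, 1.0, 42.0, 1.0))
        with pytest.raises(ParameterError):
            generate_batch(0)

    def test_scene_json_serializes(self, scene):
        import json

        d = json.loads(scene.to_json())
        assert d["egg"]["semi_major"] == pytest.approx(54.25 / 2)
        assert "truth" in d
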