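"""Cross-ratio length transfer and interplanar-distance recovery."""

import numpy as np
import pytest

from ovometry.errors import (
    DegenerateInputError,
    GeometryError,
    InconsistentConfigurationError,
    ParameterError,
)
from ovometry.measure import (
    MeasurementScene,
    interplanar_Z,
    interplanar_Zc,
    interplanar_Zcr,
    measure_axis,
    measure_axis_detail,
    measure_egg,
    transfer_projection_point,
)
from ovometry.projective import PlaneLine, PlanePoint, join
from ovometry.simulate import (
    CameraModel,
    default_scene,
    measurement_scenes_from_truth,
    project,
    project_direction,
    random_coplanar_measurement,
)

from conftest import random_interplanar_case

IDEAL_LINE = PlaneLine(0.0, 0.0, 1.0)


def pt(x, y):
    return PlanePoint.from_xy(x, y)


def affine_scene(R=40.0):
    """Fronto-parallel limit: vanishing line ideal, everything affine."""
    return MeasurementScene(
        egg_a=pt(0, 0), egg_b=pt(0, 100),
        ref_c=pt(40, 60), ref_d=pt(40, 100),
        vline=IDEAL_LINE, ref_length_R=R,
    )


class TestTransferProjection:
    def test_affine_parallel_transport(self):
        e, f, g = transfer_projection_point(affine_scene())
        assert e.is_ideal and g.is_ideal
        assert np.allclose(f.xy, [0.0, 60.0], atol=1e-9)

    def test_exact_simulator_projection_of_F(self, rng):
        """f must coincide with the projection of the world point F = B + (C-D)."""
        cam = CameraModel.look_at((-60, -400, 120), (0, 0, 30))
        A, B = np.array([30.0, 0, 40]), np.array([-25.0, 0, 38])
        D = np.array([55.0, 0, 10])
        C = D + (A - B) * 0.6  # CD parallel to AB in the plane y=0
        vline = join(project_direction(cam, (1, 0, 0)), project_direction(cam, (0, 0, 1)))
        scene = MeasurementScene(
            egg_a=project(cam, A), egg_b=project(cam, B),
            ref_c=project(cam, C), ref_d=project(cam, D),
            vline=vline, ref_length_R=float(np.linalg.norm(C - D)),
        )
        _, f, _ = transfer_projection_point(scene)
        F = B + (C - D)
        assert np.allclose(f.xy, project(cam, F).xy, atol=1e-6)

    def test_degenerate_bd_on_vline(self):
        b, d = pt(0, 100), pt(40, 100)
        scene = MeasurementScene(
            egg_a=pt(0, 0), egg_b=b, ref_c=pt(40, 60), ref_d=d,
            vline=join(b, d), ref_length_R=40.0,
        )
        with pytest.raises(GeometryError):
            transfer_projection_point(scene)


class TestMeasureAxis:
    def test_affine_ratio(self):
        assert measure_axis(affine_scene(R=40.0)) == pytest.approx(100.0)

    def test_projective_exactness_on_random_scenes(self, rng):
        for _ in range(60):
            scene, L = random_coplanar_measurement(rng)
            assert measure_axis(scene) == pytest.approx(L, rel=1e-9)

    def test_scale_equivariance_in_R(self, rng):
        scene, _ = random_coplanar_measurement(rng)
        z1 = measure_axis(scene)
        scaled = MeasurementScene(
            egg_a=scene.egg_a, egg_b=scene.egg_b,
            ref_c=scene.ref_c, ref_d=scene.ref_d,
            vline=scene.vline, ref_length_R=3.0 * scene.ref_length_R,
        )
        assert measure_axis(scaled) == pytest.approx(3.0 * z1, rel=1e-12)

    def test_affine_consistency_as_camera_recedes(self):
        """Receding camera with focal scaled: the measurement approaches the
        simple pixel-length ratio times R."""
        A, B = np.array([27.0, 0, 30]), np.array([-27.0, 0, 30])
        D, C = np.array([45.0, 0, 5]), np.array([85.0, 0, 5])
        gaps = []
        for k in (1.0, 16.0, 256.0):
            cam = CameraModel.look_at(
                (-45 * 1, -395 * k, 100 * 1), (0, 0, 30), fx=800 * k, fy=800 * k
            )
            pa, pb, pc, pd = (project(cam, X) for X in (A, B, C, D))
            vline = join(
                project_direction(cam, (1, 0, 0)), project_direction(cam, (0, 0, 1))
            )
            scene = MeasurementScene(
                egg_a=pa, egg_b=pb, ref_c=pc, ref_d=pd,
                vline=vline, ref_length_R=40.0,
            )
            naive = 40.0 * np.linalg.norm(pb.xy - pa.xy) / np.linalg.norm(
                pd.xy - pc.xy
            )
            gaps.append(abs(measure_axis(scene) - naive))
        assert gaps == sorted(gaps, reverse=True)
        assert gaps[-1] < 1e-3

    def test_audit_points_recorded(self):
        det = measure_axis_detail(affine_scene())
        assert det.e.is_ideal and det.g.is_ideal
        assert det.length_mm == pytest.approx(100.0)


class TestMeasureEgg:
    def test_exact_inputs_recover_both_axes(self, scene):
        s_major, s_minor = measurement_scenes_from_truth(scene, use_silhouette=False)
        m = measure_egg(s_major, s_minor)
        assert m.major_mm == pytest.approx(scene.truth.true_major_mm, rel=1e-6)
        assert m.minor_mm == pytest.approx(scene.truth.true_minor_mm, rel=1e-6)

    def test_missing_minor_scene_named(self, scene):
        s_major, _ = measurement_scenes_from_truth(scene)
        with pytest.raises(DegenerateInputError, match="minor"):
            measure_egg(s_major, None)

    def test_noisy_batch_error_scale(self):
        """0.5 px endpoint noise: median |error| <= 1 mm (major), 2 mm (minor)."""
        from ovometry.simulate import generate_batch

        batch = generate_batch(60, noise_px=0.5, seed=11)
        errM, errm = [], []
        for s in batch:
            m = measure_egg(s.scene_major, s.scene_minor)
            errM.append(abs(m.major_mm - s.true_major_mm))
            errm.append(abs(m.minor_mm - s.true_minor_mm))
        assert np.median(errM) <= 1.0
        assert np.median(errm) <= 2.0


class TestInterplanar:
    def test_chain_matches_camera_oracle(self, rng):
        for _ in range(40):
            case = random_interplanar_case(rng)
            zcr = interplanar_Zcr(*case["r"][:2], case["r"][2], case["r"][3], case["Zr"])
            assert zcr == pytest.approx(case["Zcr"], rel=1e-6)
            zc = interplanar_Zc(zcr, *case["s"][:2], case["s"][3], case["s"][2])
            assert zc == pytest.approx(case["Zc"], rel=1e-6)
            z = interplanar_Z(*case["x"][:2], case["x"][3], case["x"][2], zc)
            assert z == pytest.approx(case["Z"], rel=1e-6)

    def test_Zcr_linear_in_Zr(self, rng):
        case = random_interplanar_case(rng)
        r1, r2, v, cr = case["r"]
        z1 = interplanar_Zcr(r1, r2, v, cr, case["Zr"])
        z2 = interplanar_Zcr(r1, r2, v, cr, 0.5 * case["Zr"])
        assert z2 == pytest.approx(0.5 * z1, rel=1e-12)

    def test_Zcr_affine_limit_with_ideal_v(self):
        # v ideal: the bracket's v-distances cancel; pure affine ratio
        r1, r2 = pt(0, 100), pt(0, 40)
        cr = pt(0, 160)  # camera-plane trace
        v = PlanePoint.from_direction(0, 1)
        # bracket = d(r2,cr)/d(r1,cr) = 120/60 = 2 -> Zcr = Zr/(1-2) < 0
        with pytest.raises(InconsistentConfigurationError):
            interplanar_Zcr(r1, r2, v, cr, 30.0)
        # consistent ordering: cr on the far side
        cr2 = pt(0, -20)
        zcr = interplanar_Zcr(r1, r2, v, cr2, 30.0)
        assert zcr == pytest.approx(30.0 / (1 - 60.0 / 120.0))

    def test_Zc_equals_Zcr_for_coincident_planes(self):
        p = pt(10, 10)
        assert interplanar_Zc(200.0, p, pt(10.0, 10.0), pt(0, 50), pt(0, -90)) == (
            pytest.approx(200.0)
        )

    def test_Z_zero_for_coincident_image_points(self):
        assert interplanar_Z(pt(3, 4), pt(3, 4), pt(0, 50), pt(0, -90), 300.0) == 0.0

    def test_Z_unbounded_configuration_rejected(self):
        # x' at the vanishing point: the second plane recedes to infinity
        v = pt(0, -90)
        with pytest.raises(InconsistentConfigurationError):
            interplanar_Z(pt(0, 10), pt(0.0, -90.0), pt(0, 50), v, 300.0)

    def test_swapped_planes_same_magnitude(self, rng):
        case = random_interplanar_case(rng)
        x, xp, v, c = case["x"]
        z1 = interplanar_Z(x, xp, c, v, case["Zc"])
        z2 = interplanar_Z(xp, x, c, v, case["Zc"] - case["Z"])
        assert z2 == pytest.approx(z1, rel=1e-9)

    def test_parameter_validation(self):
        with pytest.raises(ParameterError):
            interplanar_Zcr(pt(0, 0), pt(1, 0), pt(2, 0), pt(3, 0), -1.0)
        with pytest.raises(ParameterError):
            interplanar_Z(pt(0, 0), pt(1, 0), pt(2, 0), pt(3, 0), 0.0)


class TestSceneValidation:
    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ParameterError):
            MeasurementScene(
                egg_a=pt(0, 0), egg_b=pt(0, 1), ref_c=pt(1, 0), ref_d=pt(1, 1),
                vline=IDEAL_LINE, ref_length_R=0.0,
            )

    def test_coincident_egg_endpoints_rejected(self):
        with pytest.raises(DegenerateInputError):
            MeasurementScene(
                egg_a=pt(0, 0), egg_b=pt(0, 0), ref_c=pt(1, 0), ref_d=pt(1, 1),
                vline=IDEAL_LINE, ref_length_R=1.0,
            )
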