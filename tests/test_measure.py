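import numpy as np
import pytest
import trimesh as tm

from asdmetry.core import CartesianVolume, SeptumPlane
from asdmetry.measure import (
    DefectRim,
    defect_metrics,
    extract_rim,
    marching_cubes,
    point_distance,
)
from asdmetry.phantom import (
    LABEL_BLOOD,
    AcquisitionConfig,
    PhantomSpec,
    generate_phantom,
    septum_plane_of,
    true_defect_metrics,
)
from asdmetry.pipeline import measure_phantom


def _ball_mask(n=48, radius_vox=20, spacing=0.5):
    ax = np.arange(n) - (n - 1) / 2
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    ball = np.sqrt(X**2 + Y**2 + Z**2) < radius_vox
    return CartesianVolume(ball.astype(np.uint8), (spacing,) * 3)


class TestMarchingCubes:
    def test_sphere_surface_area_within_3_percent(self):
        # radius 10 mm at 0.5 mm spacing -> 4 pi 100 mm^2
        mesh = marching_cubes(_ball_mask(n=48, radius_vox=20, spacing=0.5))
        area = tm.Trimesh(mesh.vertices, mesh.faces, process=False).area
        assert area == pytest.approx(4 * np.pi * 100.0, rel=0.03)

    def test_sphere_is_watertight_genus_zero(self):
        mesh = marching_cubes(_ball_mask())
        t = tm.Trimesh(mesh.vertices, mesh.faces, process=False)
        assert t.is_watertight
        assert t.euler_number == 2

    def test_single_voxel_yields_small_closed_surface(self):
        data = np.zeros((5, 5, 5), dtype=np.uint8)
        data[2, 2, 2] = 1
        mesh = marching_cubes(CartesianVolume(data, (1, 1, 1)))
        t = tm.Trimesh(mesh.vertices, mesh.faces, process=False)
        assert t.is_watertight
        assert 0 < t.area < 6.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            marching_cubes(CartesianVolume(np.zeros((4, 4, 4), dtype=np.uint8), (1, 1, 1)))

    def test_vertices_in_physical_mm(self):
        mesh = marching_cubes(_ball_mask(n=48, radius_vox=20, spacing=0.5))
        radii = np.linalg.norm(mesh.vertices, axis=1)
        assert radii.mean() == pytest.approx(10.0, abs=0.5)


class TestExtractRim:
    def test_circular_defect_rim_close_to_true_circle(self):
        spec = PhantomSpec(defect_long=10.0, defect_short=10.0)
        _, labels = generate_phantom(spec)
        mask = CartesianVolume((labels.data == LABEL_BLOOD).astype(np.uint8), labels.spacing)
        rim = extract_rim(mask, septum_plane_of(spec), face="left_atrial")
        assert rim is not None
        assert len(rim.points) >= 16
        centre = rim.plane_point
        radii = np.linalg.norm(rim.points - centre, axis=1)
        assert np.all(np.abs(radii - 5.0) <= spec.spacing)  # within 1 voxel

    def test_intact_septum_reports_no_defect(self):
        spec = PhantomSpec(defect_long=0.0, defect_short=0.0)
        _, labels = generate_phantom(spec)
        mask = CartesianVolume((labels.data == LABEL_BLOOD).astype(np.uint8), labels.spacing)
        assert extract_rim(mask, septum_plane_of(spec), face="left_atrial") is None

    def test_rim_is_planar_within_one_voxel(self, study_spec, study_phantom):
        _, labels = study_phantom
        mask = CartesianVolume((labels.data == LABEL_BLOOD).astype(np.uint8), labels.spacing)
        rim = extract_rim(mask, septum_plane_of(study_spec), face="right_atrial")
        assert rim.max_plane_distance <= study_spec.spacing


class TestDefectMetrics:
    @staticmethod
    def _rim_from_polygon(radii_fn, n=200):
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        pts = np.stack([radii_fn(t)[0], radii_fn(t)[1], np.zeros(n)], axis=1)
        return DefectRim(
            points=pts, plane_point=np.zeros(3), plane_normal=np.array([0, 0, 1.0]),
            face="left_atrial",
        )

    def test_circle_closed_form(self):
        rim = self._rim_from_polygon(lambda t: (5 * np.cos(t), 5 * np.sin(t)))
        m = defect_metrics(rim)
        assert m.long_diameter == pytest.approx(10.0, abs=0.01)
        assert m.short_diameter == pytest.approx(10.0, abs=0.01)
        assert m.area == pytest.approx(np.pi * 25.0, rel=0.01)

    def test_ellipse_closed_form(self):
        rim = self._rim_from_polygon(lambda t: (6 * np.cos(t), 3 * np.sin(t)))
        m = defect_metrics(rim)
        assert m.long_diameter == pytest.approx(12.0, abs=0.05)
        assert m.short_diameter == pytest.approx(6.0, abs=0.05)
        assert m.area == pytest.approx(np.pi * 6 * 3, rel=0.01)

    def test_short_never_exceeds_long_and_area_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            r = 3 + rng.random(60) * 4
            t = np.linspace(0, 2 * np.pi, 60, endpoint=False)
            pts = np.stack([r * np.cos(t), r * np.sin(t), np.zeros(60)], axis=1)
            m = defect_metrics(
                DefectRim(pts, np.zeros(3), np.array([0, 0, 1.0]), "left_atrial")
            )
            assert m.short_diameter <= m.long_diameter + 1e-9
            assert m.area <= np.pi * (m.long_diameter / 2) ** 2 + 1e-9

    def test_degenerate_rim_rejected(self):
        with pytest.raises(ValueError):
            DefectRim(np.zeros((2, 3)), np.zeros(3), np.array([0, 0, 1.0]), "left_atrial")
        collinear = np.stack([np.arange(5.0), np.zeros(5), np.zeros(5)], axis=1)
        with pytest.raises(ValueError):
            defect_metrics(
                DefectRim(collinear, np.zeros(3), np.array([0, 0, 1.0]), "left_atrial")
            )


class TestPointDistance:
    def test_identical_points_zero(self):
        assert point_distance((1, 2, 3), (1, 2, 3)) == 0.0

    def test_pythagorean_triple(self):
        assert point_distance((0, 0, 0), (3, 4, 0)) == pytest.approx(5.0)

    def test_half_millimetre_spacing_handled_in_mm(self):
        vol = CartesianVolume(np.zeros((11, 11, 11)), (0.5, 0.5, 0.5))
        p = vol.index_to_world(np.array([5, 5, 5]))
        q = vol.index_to_world(np.array([6, 5, 5]))
        assert point_distance(p, q) == pytest.approx(0.5)


class TestMetricInvariants:
    def test_metrics_invariant_under_septum_rotation(self):
        # same defect measured with the septum at 0 and 30 degrees tilt
        results = []
        for normal in [(0.0, 0.0, 1.0), (0.0, np.sin(np.radians(30)), np.cos(np.radians(30)))]:
            spec = PhantomSpec(defect_long=10.0, defect_short=7.0, septum_normal=normal)
            _, labels = generate_phantom(spec)
            mask = CartesianVolume(
                (labels.data == LABEL_BLOOD).astype(np.uint8), labels.spacing
            )
            rim = extract_rim(mask, septum_plane_of(spec), face="left_atrial")
            results.append(defect_metrics(rim))
        a, b = results
        assert abs(a.long_diameter - b.long_diameter) <= 2 * 0.5
        assert abs(a.short_diameter - b.short_diameter) <= 2 * 0.5

    @pytest.mark.parametrize(
        "defect_long,defect_short,angle,seed",
        [(6.0, 4.0, 10.0, 0), (12.0, 8.0, 140.0, 3)],
    )
    def test_full_pipeline_recovery_within_tolerance(
        self, defect_long, defect_short, angle, seed
    ):
        # end-to-end: acquisition with default speckle at 0.5 mm spacing;
        # diameters within 10%, area within 15% of ground truth
        spec = PhantomSpec(
            defect_long=defect_long, defect_short=defect_short, defect_angle=angle
        )
        acq = AcquisitionConfig(slice_width=120, slice_depth=64, seed=seed)
        result = measure_phantom(spec, acq)
        true = true_defect_metrics(spec)
        for face in ("left_atrial", "right_atrial"):
            rec = result.recovered[face]
            assert abs(rec["long_diameter"] - true["long_diameter"]) <= 0.10 * true["long_diameter"]
            assert abs(rec["short_diameter"] - true["short_diameter"]) <= 0.10 * true["short_diameter"]
            assert abs(rec["area"] - true["area"]) <= 0.15 * true["area"]
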