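import numpy as np
import pytest
from dataclasses import replace

from fragaria3d.cloud_io import ColouredCloud
from fragaria3d.geometry import DegenerateGeometryError
from fragaria3d.synthgen import SceneSpec, generate_scene
from fragaria3d.traits import (
    CalibrationStandard,
    calibrate_scale,
    count_achenes,
    measure_calyx,
    measure_colour,
    measure_dimensions,
    measure_volume,
    process_batch,
    process_sample,
)


def grid_cloud(lx, ly, lz, n=10):
    ax = np.linspace(0, lx, 2 * n + 1)
    ay = np.linspace(0, ly, n + 1)
    az = np.linspace(0, lz, n + 1)
    g = np.meshgrid(ax, ay, az, indexing="ij")
    pts = np.column_stack([a.ravel() for a in g])
    return ColouredCloud(pts, np.full((len(pts), 3), 0.5))


class TestCalibration:
    def test_identity_scale(self):
        holder = grid_cloud(38.0, 19.0, 19.0)
        assert calibrate_scale(holder) == pytest.approx(1.0, rel=1e-9)

    @pytest.mark.parametrize("extent", [0.36, 0.78, 1.73])
    def test_reported_image_space_extents(self, extent):
        holder = grid_cloud(extent, extent / 2, extent / 2)
        assert calibrate_scale(holder) == pytest.approx(38.0 / extent, rel=1e-9)

    def test_custom_standard(self):
        holder = grid_cloud(2.0, 1.0, 1.0)
        std = CalibrationStandard(true_holder_height=50.0)
        assert calibrate_scale(holder, std) == pytest.approx(25.0, rel=1e-9)

    def test_degenerate_holder_rejected(self):
        flat = ColouredCloud(
            np.c_[np.random.default_rng(0).uniform(size=(30, 2)), np.zeros(30)],
            np.full((30, 3), 0.5),
        )
        with pytest.raises(DegenerateGeometryError):
            calibrate_scale(flat)


class TestDimensions:
    def test_generator_scene_within_3pc(self):
        spec = SceneSpec(
            seed=5, fruit_height_mm=25, fruit_length_mm=30, fruit_width_mm=28,
            noise_sd_mm=0.0, colour_noise_sd=0.0,
        )
        cloud, truth = generate_scene(spec)
        body = cloud.subset(truth.labels == "body")
        holder = cloud.subset(truth.labels == "holder")
        scale = calibrate_scale(holder)
        h, l, w = measure_dimensions(body, holder, scale)
        assert h == pytest.approx(25.0, rel=0.03)
        assert l == pytest.approx(30.0, rel=0.03)
        assert w == pytest.approx(28.0, rel=0.03)
        assert l >= w

    def test_body_duplicating_holder_gives_zero_height(self):
        holder = grid_cloud(38.0, 19.0, 19.0)
        h, _, _ = measure_dimensions(holder, holder, scale=1.0)
        assert h == 0.0

    @pytest.mark.parametrize("s", [0.36, 1.73])
    def test_scale_invariance(self, s, small_spec):
        base, t0 = generate_scene(small_spec)
        scaled, _ = generate_scene(
            replace(small_spec, global_scale=small_spec.global_scale * s)
        )
        def dims(cloud, truth):
            body = cloud.subset(truth.labels == "body")
            holder = cloud.subset(truth.labels == "holder")
            sc = calibrate_scale(holder)
            return measure_dimensions(body, holder, sc)
        np.testing.assert_allclose(dims(base, t0), dims(scaled, t0), rtol=0.01)


class TestVolume:
    def test_spherical_fruit(self, rng):
        pts = rng.normal(size=(5000, 3))
        pts = 20.0 * pts / np.linalg.norm(pts, axis=1, keepdims=True)
        cloud = ColouredCloud(pts, np.full((5000, 3), 0.5))
        vol = measure_volume(cloud, scale=1.0)
        assert vol == pytest.approx(4 * np.pi * 20**3 / 3 / 1000, rel=0.05)

    def test_cubic_scale_dependence(self, rng):
        pts = rng.normal(size=(2000, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        cloud = ColouredCloud(pts, np.full((2000, 3), 0.5))
        v1 = measure_volume(cloud, scale=1.0, method="convex_hull")
        v2 = measure_volume(cloud, scale=2.0, method="convex_hull")
        assert v2 == pytest.approx(8 * v1, rel=1e-12)

    def test_generator_volume_within_7pc(self, small_spec):
        cloud, truth = generate_scene(small_spec)
        body = cloud.subset(truth.labels == "body")
        vol = measure_volume(body, scale=truth.scale_mm_per_unit)
        assert vol == pytest.approx(truth.volume_ml, rel=0.07)


class TestCalyxAndAchenes:
    def test_two_point_calyx(self):
        calyx = ColouredCloud([[0, 0, 0], [1, 0, 0]], np.full((2, 3), 0.5))
        assert measure_calyx(calyx, scale=38.0) == pytest.approx(38.0)

    def test_singleton_calyx_rejected(self):
        calyx = ColouredCloud([[0, 0, 0]], [[0.5, 0.5, 0.5]])
        with pytest.raises(DegenerateGeometryError):
            measure_calyx(calyx, scale=1.0)

    def test_generator_calyx_within_3pc(self, small_spec):
        cloud, truth = generate_scene(small_spec)
        calyx = cloud.subset(truth.labels == "calyx")
        got = measure_calyx(calyx, scale=truth.scale_mm_per_unit)
        assert got == pytest.approx(truth.calyx_size_mm, rel=0.03)

    def test_generator_achene_count_exact(self, small_spec):
        cloud, truth = generate_scene(small_spec)
        cand = cloud.subset(truth.labels == "achene")
        n = count_achenes(cand, scale=truth.scale_mm_per_unit)
        assert n == truth.achene_count

    def test_empty_candidates(self):
        empty = ColouredCloud(np.empty((0, 3)), np.empty((0, 3)))
        assert count_achenes(empty, scale=1.0) == 0

    def test_merged_spots_count_as_one(self, rng):
        """Two spots closer than the tolerance merge: the known failure
        mode of distance clustering on dense achene packings."""
        a = rng.normal(scale=0.1, size=(8, 3))
        b = a + [1.0, 0, 0]          # 1.0 mm apart < 1.5 mm tolerance
        cand = ColouredCloud(np.vstack([a, b]), np.full((16, 3), 0.5))
        assert count_achenes(cand, scale=1.0, tolerance_mm=1.5) == 1


class TestColour:
    def test_constant_hue(self):
        from test_segmentation import cloud_from_hues

        assert measure_colour(cloud_from_hues([10.0] * 20)) == pytest.approx(10.0)

    def test_wraparound_symmetry(self):
        from test_segmentation import cloud_from_hues

        got = measure_colour(cloud_from_hues([350.0] * 50 + [10.0] * 50))
        assert got == pytest.approx(0.0, abs=1e-9) or got == pytest.approx(
            360.0, abs=1e-9
        )

    def test_generator_hue_recovered(self, small_spec):
        cloud, truth = generate_scene(replace(small_spec, colour_noise_sd=4.0))
        body = cloud.subset(truth.labels == "body")
        diff = (measure_colour(body) - truth.mean_hue_deg + 180) % 360 - 180
        assert abs(diff) < 2.0


class TestPipeline:
    def test_full_record_on_generator_scene(self, clean_scene):
        cloud, truth = clean_scene
        rec = process_sample(cloud, "s")
        assert rec.status == "ok"
        for f in ("height_mm", "length_mm", "width_mm", "volume_ml",
                  "calyx_size_mm", "achene_count", "mean_hue_deg",
                  "scale_mm_per_unit"):
            assert getattr(rec, f) is not None

    def test_missing_calyx_flagged_not_fatal(self, small_spec):
        cloud, _ = generate_scene(replace(small_spec, n_calyx_points=0))
        rec = process_sample(cloud, "nocalyx")
        assert rec.calyx_size_mm is None
        assert "calyx" in rec.status
        assert rec.height_mm is not None and rec.volume_ml is not None

    def test_unsegmentable_scene_fails_cleanly(self):
        grey = ColouredCloud(np.random.default_rng(0).uniform(size=(50, 3)),
                             np.full((50, 3), 0.5))
        rec = process_sample(grey, "grey")
        assert rec.status.startswith("failed")
        assert rec.height_mm is None

    def test_batch_preserves_input_order(self, tmp_path, small_spec):
        from fragaria3d.cloud_io import write_cloud

        cloud, _ = generate_scene(small_spec)
        names = ["b.ply", "a.ply", "c.ply"]
        paths = []
        for n in names:
            paths.append(write_cloud(cloud, tmp_path / n))
        df = process_batch(paths)
        assert list(df["sample_id"]) == ["b", "a", "c"]
        assert (df["status"] == "ok").all()
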