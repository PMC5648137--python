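import numpy as np
import pytest

from wims import morphology as M
from wims.detect import Adhesion
from wims.synthdata import scenario_library, simulate_movie


def disk_mask(shape, cx, cy, r):
    ys, xs = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (xs - cx) ** 2 + (ys - cy) ** 2 <= r * r


def disk_frame(shape=(256, 256), cx=128, cy=128, r=80, level=100.0):
    return np.where(disk_mask(shape, cx, cy, r), level, 0.0) + 5.0


class TestExtractBoundary:
    def test_empty_frame_yields_no_contour(self):
        contour, mask, _ = M.extract_boundary(np.zeros((64, 64)), scales=[10, 14, 18])
        assert contour is None
        assert not mask.any()

    def test_disk_radius_within_band_minimum(self):
        frame = disk_frame()
        scales = list(range(20, 101, 4))
        contour, mask, _ = M.extract_boundary(frame, scales=scales)
        r = np.hypot(contour.vertices[:, 0] - 128, contour.vertices[:, 1] - 128)
        assert abs(r.mean() - 80) <= 20  # bounded by the smallest band scale
        assert np.abs(r - 80).max() <= 20

    def test_threshold_monotonicity(self):
        frame = disk_frame(shape=(128, 128), cx=64, cy=64, r=40)
        scales = list(range(10, 41, 4))
        areas = []
        for frac in (0.3, 0.5, 0.7):
            _, mask, _ = M.extract_boundary(frame, scales=scales, threshold_rule=frac)
            areas.append(mask.sum())
        assert areas[0] >= areas[1] >= areas[2]


class TestRegionDecomposition:
    def test_identical_masks_have_no_change(self):
        m = disk_mask((64, 64), 32, 32, 20)
        dec = M.decompose_regions(m, m)
        assert not dec.protruded_mask.any()
        assert not dec.retracted_mask.any()

    def test_translated_disk_has_equal_crescents(self):
        m0 = disk_mask((64, 64), 30, 32, 15)
        m1 = disk_mask((64, 64), 34, 32, 15)
        dec = M.decompose_regions(m0, m1)
        assert dec.protruded_mask.sum() == dec.retracted_mask.sum()

    def test_set_identities_exact_on_random_masks(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            m0 = rng.random((32, 32)) > 0.5
            m1 = rng.random((32, 32)) > 0.5
            dec = M.decompose_regions(m0, m1)
            assert not (dec.protruded_mask & dec.retracted_mask).any()
            assert not (dec.protruded_mask & dec.stable_mask).any()
            np.testing.assert_array_equal(dec.stable_mask | dec.protruded_mask, m1)
            np.testing.assert_array_equal(dec.stable_mask | dec.retracted_mask, m0)

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            M.decompose_regions(np.zeros((4, 4), bool), np.zeros((5, 5), bool))


class TestFrontMetrics:
    def test_growing_disk_velocity_and_areas(self, scenarios):
        cfg = scenarios["growing_disk"]
        series, _ = simulate_movie(cfg)
        masks = []
        for t in range(series.n_frames):
            _, m, _ = M.extract_boundary(series.frame(t), scales=range(10, 41, 4))
            masks.append(m)
        decs = [M.decompose_regions(masks[i], masks[i + 1], i, i + 1)
                for i in range(len(masks) - 1)]
        fm = M.front_metrics(decs, series.pixel_size, series.frame_interval)
        # the disk grows one pixel per 5 s frame: 0.105 * 12 = 1.26 um/min
        assert fm["front_velocity_um_per_min"] == pytest.approx(1.26, rel=0.10)
        swept = fm["table"]["swept_area_um2"].to_numpy()
        assert np.all(np.diff(swept) > 0)

    def test_full_circle_front_arc_length(self):
        m0 = disk_mask((160, 160), 80, 80, 40)
        m1 = disk_mask((160, 160), 80, 80, 42)
        dec = M.decompose_regions(m0, m1)
        fm = M.front_metrics([dec], pixel_size=1.0, frame_interval=1.0)
        arc = fm["table"]["arc_length_um"].iloc[0]
        # binary-mask contours carry a small staircase excess
        assert arc == pytest.approx(2 * np.pi * 42, rel=0.08)

    def test_annulus_swept_area(self):
        m0 = disk_mask((160, 160), 80, 80, 40)
        m1 = disk_mask((160, 160), 80, 80, 48)
        dec = M.decompose_regions(m0, m1)
        fm = M.front_metrics([dec], pixel_size=1.0, frame_interval=1.0)
        area = fm["table"]["swept_area_um2"].iloc[0]
        assert area == pytest.approx(np.pi * (48**2 - 40**2), rel=0.02)


def straight_contour(y=50.0):
    xs = np.linspace(0, 99, 100)
    v = np.column_stack([xs, np.full_like(xs, y)])
    v = np.vstack([v, [[99, y + 100]], [[0, y + 100]], v[:1]])
    return M.BoundaryContour(v)


class TestAdhesionBoundaryGeometry:
    def test_perpendicular_adhesion(self):
        contour = straight_contour()
        ad = Adhesion(x=50, y=30, a=5, xi=0.5, theta=90.0, coefficient=1.0)
        geo = M.adhesion_boundary_geometry(ad, contour, pixel_size=1.0)
        assert geo["tangent_angle_deg"] == pytest.approx(90.0, abs=1.0)
        assert geo["distance_px"] == pytest.approx(20.0, abs=0.5)

    def test_parallel_adhesion(self):
        contour = straight_contour()
        ad = Adhesion(x=50, y=30, a=5, xi=0.5, theta=0.0, coefficient=1.0)
        geo = M.adhesion_boundary_geometry(ad, contour, pixel_size=1.0)
        assert geo["tangent_angle_deg"] == pytest.approx(0.0, abs=1.0)

    def test_radial_adhesion_on_circle(self):
        phi = np.linspace(0, 2 * np.pi, 720)
        v = np.column_stack([150 + 100 * np.cos(phi), 150 + 100 * np.sin(phi)])
        contour = M.BoundaryContour(v)
        # adhesion at radius 80 along +x, oriented radially (theta = 0)
        ad = Adhesion(x=230, y=150, a=5, xi=0.5, theta=0.0, coefficient=1.0)
        geo = M.adhesion_boundary_geometry(ad, contour, pixel_size=0.105)
        assert geo["distance_um"] == pytest.approx(20 * 0.105, rel=0.03)
        assert geo["tangent_angle_deg"] == pytest.approx(90.0, abs=2.0)


class TestAssignRegion:
    @pytest.fixture
    def decomposition(self):
        # cell translates right: protruded crescent on the right edge,
        # retracted crescent on the left
        m0 = disk_mask((220, 220), 100, 110, 60)
        m1 = disk_mask((220, 220), 120, 110, 60)
        return M.decompose_regions(m0, m1)

    def test_far_adhesion_is_central(self, decomposition):
        ad = Adhesion(x=110, y=110, a=5, xi=1.0, theta=0.0, coefficient=1.0)
        assert M.assign_region(ad, decomposition) == "central"

    def test_adhesion_near_protruding_front(self, decomposition):
        ad = Adhesion(x=172, y=110, a=5, xi=1.0, theta=0.0, coefficient=1.0)
        assert M.assign_region(ad, decomposition) == "protruding"

    def test_adhesion_near_retracting_front(self, decomposition):
        ad = Adhesion(x=48, y=110, a=5, xi=1.0, theta=0.0, coefficient=1.0)
        assert M.assign_region(ad, decomposition) == "retracting"

    def test_equidistant_is_intersecting(self):
        m0 = disk_mask((100, 100), 50, 50, 30)
        xs = np.mgrid[0:100, 0:100][1]
        m1 = (disk_mask((100, 100), 50, 50, 36) & (xs >= 50)) | (
            disk_mask((100, 100), 50, 50, 24) & (xs < 50)
        ) | (m0 & (xs >= 50))
        dec = M.decompose_regions(m0, m1)
        ad = Adhesion(x=50, y=22, a=4, xi=1.0, theta=0.0, coefficient=1.0)
        label = M.assign_region(ad, dec, tie_tolerance_px=6.0)
        assert label == "intersecting"
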