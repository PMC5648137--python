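import numpy as np
import pytest

from wims import cwt
from wims.wavelets import stretched


@pytest.fixture
def rng():
    return np.random.default_rng(0)


class TestImageSeries:
    def test_shape_normalisation(self, rng):
        s = cwt.ImageSeries(rng.uniform(0, 1, (3, 8, 8)))
        assert s.data.shape == (3, 1, 8, 8)
        assert s.n_frames == 3
        assert s.frame_shape == (8, 8)

    def test_rejects_negative_intensities(self, rng):
        with pytest.raises(ValueError):
            cwt.ImageSeries(rng.uniform(-1, 0, (2, 4, 4)))

    def test_channel_lookup_by_name(self, rng):
        s = cwt.ImageSeries(rng.uniform(0, 1, (2, 2, 4, 4)), channels=("red", "green"))
        np.testing.assert_array_equal(s.frame(0, "green"), s.data[0, 1])


class TestMeshOperations:
    def test_refine_replicates_blocks(self):
        frame = np.array([[1.0, 2.0], [3.0, 4.0]])
        fine = cwt.refine_mesh(frame, 4)
        assert fine.shape == (8, 8)
        # each original pixel becomes a constant 4x4 block
        for i in range(2):
            for j in range(2):
                block = fine[4 * i : 4 * i + 4, 4 * j : 4 * j + 4]
                assert np.all(block == frame[i, j])

    def test_refine_factor_one_is_identity(self, rng):
        frame = rng.uniform(0, 1, (5, 7))
        np.testing.assert_array_equal(cwt.refine_mesh(frame, 1), frame)

    def test_refine_preserves_mean(self, rng):
        frame = rng.uniform(0, 1, (16, 16))
        assert cwt.refine_mesh(frame, 4).mean() == pytest.approx(frame.mean())

    def test_refine_rejects_bad_factor(self):
        with pytest.raises(ValueError):
            cwt.refine_mesh(np.ones((4, 4)), 0)

    def test_coarsen_block_means_and_zero_border(self):
        frame = np.full((4, 4), 8.0)
        coarse, mesh = cwt.coarsen_and_pad(frame, a_max=4.0)
        pad = int(np.ceil(4.0 * 4.0 / 2))
        inner = coarse[pad:-pad, pad:-pad]
        assert inner.shape == (2, 2)
        assert np.all(inner == 8.0)
        border = coarse.copy()
        border[pad:-pad, pad:-pad] = 0.0
        assert np.all(border == 0.0)

    def test_coarse_coordinate_map(self):
        # a single bright pixel must produce a coefficient maximum at its
        # original position after the coarse round trip
        frame = np.zeros((64, 64))
        frame[30, 20] = 100.0
        field = cwt.forward_transform(frame, "mexican_hat", scales=[20.0])
        native = field.plane_native(0)[0, 0]
        iy, ix = np.unravel_index(np.argmax(native), native.shape)
        assert abs(iy - 30) <= 1 and abs(ix - 20) <= 1


class TestForwardTransform:
    def test_uniform_image_vanishes_in_interior(self):
        frame = np.full((64, 64), 7.0)
        field = cwt.forward_transform(frame, "mexican_hat", scales=[4.0, 6.0])
        for n, a in enumerate(field.scales):
            m = int(np.ceil(4.0 * a)) + 1
            interior = field.planes[n][0, 0, m:-m, m:-m]
            assert np.abs(interior).max() <= 1e-6 * 7.0 * a

    def test_single_pixel_closed_form(self):
        frame = np.zeros((64, 64))
        frame[30, 20] = 5.0
        a, xi, theta = 5.0, 1.5, 40.0
        field = cwt.forward_transform(
            frame, "stretched", scales=[a], xis=[xi], thetas=[theta]
        )
        t = field.planes[0][0, 0]
        ys, xs = np.mgrid[0:64, 0:64]
        expected = (5.0 / a) * stretched(20 - xs, 30 - ys, a, xi, theta)
        assert np.abs(t - expected).max() <= 5e-3 * np.abs(expected).max()
        iy, ix = np.unravel_index(np.argmax(np.abs(t)), t.shape)
        assert (iy, ix) == (30, 20)

    def test_linearity(self, rng):
        i1 = rng.uniform(0, 1, (48, 48))
        i2 = rng.uniform(0, 1, (48, 48))
        kw = dict(family="stretched", scales=[5.0], xis=[1.5], thetas=[25.0])
        t1 = cwt.forward_transform(i1, **kw).planes[0]
        t2 = cwt.forward_transform(i2, **kw).planes[0]
        t12 = cwt.forward_transform(i1 + i2, **kw).planes[0]
        assert np.abs(t12 - (t1 + t2)).max() <= 1e-10 * np.abs(t12).max()

    @pytest.mark.parametrize("a,xi,theta", [(5.0, 0.5, 120.0), (6.0, 1.5, 30.0), (8.0, 1.0, 0.0)])
    def test_truncated_box_matches_brute_force(self, rng, a, xi, theta):
        frame = rng.uniform(0, 1, (64, 64))
        ref = cwt.forward_transform_reference(frame, "stretched", a, xi, theta)
        field = cwt.forward_transform(
            frame, "stretched", scales=[a], xis=[xi], thetas=[theta]
        )
        diff = np.abs(field.planes[0][0, 0] - ref).max()
        assert diff <= 0.01 * np.abs(ref).max()

    def test_shift_equivariance(self, rng):
        frame = rng.uniform(0, 1, (64, 64))
        shifted = np.roll(frame, (3, 2), axis=(0, 1))
        a = 5.0
        t0 = cwt.forward_transform(frame, "mexican_hat", scales=[a]).planes[0][0, 0]
        t1 = cwt.forward_transform(shifted, "mexican_hat", scales=[a]).planes[0][0, 0]
        m = int(np.ceil(4.0 * a)) + 4
        np.testing.assert_allclose(
            t1[m + 3 : -m, m + 2 : -m],
            t0[m : -m - 3, m : -m - 2],
            atol=1e-8 * np.abs(t0).max(),
        )

    def test_stretched_unit_xi_equals_mexican_hat(self, rng):
        frame = rng.uniform(0, 1, (48, 48))
        tm = cwt.forward_transform(frame, "mexican_hat", scales=[6.0]).planes[0][0, 0]
        ts = cwt.forward_transform(
            frame, "stretched", scales=[6.0], xis=[1.0], thetas=[77.0]
        ).planes[0][0, 0]
        assert np.abs(ts - tm).max() <= 1e-10 * np.abs(tm).max()

    def test_rejects_empty_or_oversized_scales(self):
        with pytest.raises(ValueError):
            cwt.forward_transform(np.ones((32, 32)), scales=[])
        with pytest.raises(ValueError):
            cwt.forward_transform(np.ones((32, 32)), scales=[500.0])


class TestTransformStack:
    def test_matches_forward_transform(self, rng):
        frame = rng.uniform(0, 1, (48, 48))
        thetas = [0.0, 30.0, 60.0]
        field = cwt.forward_transform(
            frame, "stretched", scales=[5.0, 18.0], xis=[1.5], thetas=thetas
        )
        stack = cwt.transform_stack(frame, [5.0, 18.0], [1.5], thetas, dtype=np.float64)
        np.testing.assert_allclose(stack, field.values_native(dtype=np.float64), atol=1e-8)

    def test_independent_of_chunking(self, rng):
        frame = rng.uniform(0, 1, (40, 40))
        thetas = np.arange(12) * 15.0
        s1 = cwt.transform_stack(
            frame, [5.0], [1.5], thetas, cwt.MeshConfig(theta_chunk=3), dtype=np.float64
        )
        s2 = cwt.transform_stack(
            frame, [5.0], [1.5], thetas, cwt.MeshConfig(theta_chunk=45), dtype=np.float64
        )
        np.testing.assert_array_equal(s1, s2)

    def test_rotating_image_permutes_theta_axis(self, rng):
        frame = np.zeros((49, 49))
        ys, xs = np.mgrid[0:49, 0:49]
        frame += 100 * stretched(xs - 24, ys - 24, 5.0, 0.4, 20.0)
        rot = np.rot90(frame)  # +90 deg in the image convention
        thetas = np.arange(18) * 10.0
        s0 = cwt.transform_stack(frame, [5.0], [0.5], thetas, dtype=np.float64)
        s1 = cwt.transform_stack(rot, [5.0], [0.5], thetas, dtype=np.float64)
        prof0 = s0[0, 0, :, 24, 24]
        prof1 = s1[0, 0, :, 24, 24]
        shift = (np.argmax(prof1) - np.argmax(prof0)) % 18
        assert shift == 9  # 90 degrees = 9 grid steps of 10 deg


class TestInverseTransform:
    def test_zero_coefficients_give_zero_image(self):
        frame = np.zeros((48, 48))
        field = cwt.forward_transform(frame, "mexican_hat", scales=[4.0, 8.0])
        rec = cwt.inverse_transform(field)
        assert np.abs(rec).max() == 0.0

    def test_band_restriction_validation(self, rng):
        frame = rng.uniform(0, 1, (48, 48))
        field = cwt.forward_transform(frame, "mexican_hat", scales=[4.0, 8.0])
        with pytest.raises(ValueError):
            cwt.inverse_transform(field, band=(100.0, 200.0))

    def test_round_trip_over_broad_band(self):
        # image built from in-band features reconstructs to < 5% L2 error
        n = 128
        xs = np.arange(n)
        gx, gy = np.meshgrid(xs, xs, indexing="xy")
        img = np.zeros((n, n))
        for (cx, cy, a0) in [(50, 60, 8.0), (84, 70, 12.0), (64, 40, 6.0)]:
            img += stretched(gx - cx, gy - cy, a0, 1.0, 0.0)
        rec = cwt.band_reconstruction(img, np.arange(2.0, 65.0, 1.0))
        err = np.linalg.norm(rec - img) / np.linalg.norm(img)
        assert err < 0.05

    def test_band_filter_attenuates_fine_structure(self):
        n = 96
        xs = np.arange(n)
        gx, gy = np.meshgrid(xs, xs, indexing="xy")
        blob = stretched(gx - 48, gy - 48, 16.0, 1.0, 0.0)
        sine = 0.5 * np.sin(2 * np.pi * gx / 6.0) * np.exp(
            -((gx - 48) ** 2 + (gy - 48) ** 2) / (2 * 20.0**2)
        )
        img = 10.0 + blob + sine

        def sine_amplitude(image):
            w = np.exp(-((gx - 48) ** 2 + (gy - 48) ** 2) / (2 * 20.0**2))
            basis = np.sin(2 * np.pi * gx / 6.0) * w
            return abs((image * basis).sum() / (basis * basis).sum())

        full = cwt.band_reconstruction(img, np.arange(2.0, 41.0, 1.0))
        coarse = cwt.band_reconstruction(img, np.arange(12.0, 41.0, 1.0))
        assert sine_amplitude(coarse) < sine_amplitude(full) / 10.0


class TestPersistence:
    def test_hdf5_round_trip(self, rng, tmp_path):
        frame = rng.uniform(0, 1, (40, 40))
        field = cwt.forward_transform(
            frame, "stretched", scales=[4.0, 18.0], xis=[1.5], thetas=[0.0, 90.0]
        )
        path = tmp_path / "coeffs.h5"
        field.save_hdf5(path)
        loaded = cwt.CoefficientField.load_hdf5(path)
        assert loaded.family == "stretched"
        np.testing.assert_array_equal(loaded.scales, field.scales)
        for p1, p2 in zip(loaded.planes, field.planes):
            np.testing.assert_array_equal(p1, p2)
        assert loaded.meshes[1].step == field.meshes[1].step
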