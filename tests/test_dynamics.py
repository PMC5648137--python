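import numpy as np
import pytest

from wims import dynamics as dyn
from wims.detect import Adhesion
from wims.morphology import BoundaryContour
from wims.synthdata import (
    ClusterSpec,
    boundary_polyline,
    scenario_library,
    simulate_movie,
    simulate_profile,
)


def square_contour(half=40.0, center=(48.0, 48.0)):
    cx, cy = center
    v = np.array(
        [
            [cx - half, cy - half], [cx + half, cy - half],
            [cx + half, cy + half], [cx - half, cy + half],
            [cx - half, cy - half],
        ]
    )
    return BoundaryContour(v)


class TestExtractProfile:
    def test_gaussian_ridge_sampled_accurately(self):
        # a ridge varying only along x must reproduce its 1-D Gaussian
        from wims.cwt import ImageSeries

        ys, xs = np.mgrid[0:96, 0:96].astype(float)
        ridge = 10.0 + 100.0 * np.exp(-((xs - 60) ** 2) / (2 * 9.0))
        series = ImageSeries(ridge[None])
        ad = Adhesion(x=48, y=48, a=8, xi=0.5, theta=0.0, coefficient=1.0, frame=0)
        prof = dyn.extract_profile(series, ad, square_contour(), window=0)
        sample_x = 48.0 + prof.positions * prof.direction[0]
        expected = 10.0 + 100.0 * np.exp(-((sample_x - 60) ** 2) / (2 * 9.0))
        np.testing.assert_allclose(prof.intensities[0], expected, rtol=0.01, atol=0.5)

    def test_positions_identical_across_frames(self, scenarios):
        cfg = scenarios["category_B"]
        series, _ = simulate_movie(cfg)
        ad = Adhesion(x=70, y=48, a=8, xi=0.5, theta=0.0, coefficient=1.0, frame=20)
        contour = BoundaryContour(boundary_polyline(cfg, 20))
        contours = [BoundaryContour(boundary_polyline(cfg, t)) for t in range(cfg.n_frames)]
        prof = dyn.extract_profile(series, ad, contour, contours_per_frame=contours)
        assert prof.intensities.shape[0] == len(prof.frames)
        # one fixed coordinate array serves every frame by construction
        assert prof.positions.flags.writeable in (True, False)
        assert np.isfinite(prof.boundary_position).sum() >= 35

    def test_window_clamped_at_series_start(self):
        from wims.cwt import ImageSeries

        series = ImageSeries(np.full((31, 96, 96), 5.0))
        ad = Adhesion(x=48, y=48, a=8, xi=0.5, theta=0.0, coefficient=1.0, frame=10)
        prof = dyn.extract_profile(series, ad, square_contour(), window=20)
        assert prof.frames[0] == 0 and prof.frames[-1] == 30

    def test_axis_missing_contour_raises(self):
        from wims.cwt import ImageSeries

        series = ImageSeries(np.full((1, 96, 96), 5.0))
        far = square_contour(half=5.0, center=(10.0, 10.0))
        ad = Adhesion(x=60, y=60, a=8, xi=0.5, theta=90.0, coefficient=1.0, frame=0)
        with pytest.raises(ValueError):
            dyn.extract_profile(series, ad, far)


class TestMixtureFit:
    def test_recovers_generated_two_gaussian_parameters(self):
        # the canonical two-peak profile: baseline 10, amplitudes 50/30,
        # widths 2/2, centers 10/18 on a 0..28 grid
        x = np.arange(29, dtype=float)
        y = (
            10.0
            + 50.0 * np.exp(-((x - 10) ** 2) / 8.0)
            + 30.0 * np.exp(-((x - 18) ** 2) / 8.0)
        )
        fit = dyn.fit_two_gaussians(x, y)
        assert fit.fitted and fit.n_peaks_effective == 2
        assert fit.beta1 == pytest.approx(10.0, abs=0.1)
        assert fit.beta2 == pytest.approx(18.0, abs=0.1)

    def test_single_gaussian_collapses_to_one_peak(self):
        x = np.arange(41, dtype=float)
        y = 5.0 + 80.0 * np.exp(-((x - 20) ** 2) / (2 * 16.0))
        fit = dyn.fit_two_gaussians(x, y)
        assert fit.fitted
        assert fit.n_peaks_effective == 1
        assert len(fit.peaks()) == 1

    def test_mirror_symmetric_profile_gives_symmetric_centers(self):
        x = np.arange(41, dtype=float)
        y = (
            4.0
            + 60.0 * np.exp(-((x - 14) ** 2) / 8.0)
            + 60.0 * np.exp(-((x - 26) ** 2) / 8.0)
        )
        fit = dyn.fit_two_gaussians(x, y)
        assert (fit.beta1 + fit.beta2) / 2 == pytest.approx(20.0, abs=0.1)

    def test_too_few_samples_returns_marker(self):
        x = np.arange(20, dtype=float)
        # a sub-resolution spike leaves too few samples above the cutoff
        y = 5.0 + 50.0 * np.exp(-((x - 10) ** 2) / (2 * 0.25))
        fit = dyn.fit_two_gaussians(x, y)
        assert not fit.fitted


class TestTrajectories:
    @staticmethod
    def fits_from_tracks(tracks, n_frames=30, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        fits = []
        for t in range(n_frames):
            betas = [b0 + v * t + rng.normal(0, noise) for b0, v in tracks]
            if len(betas) == 1:
                fits.append(
                    dyn.MixtureFit(5, 100, 0, 2, 2, betas[0], betas[0], 0.0, 1, frame=t)
                )
            else:
                fits.append(
                    dyn.MixtureFit(5, 100, 90, 2, 2, betas[0], betas[1], 0.0, 2, frame=t)
                )
        return fits

    def test_two_constant_velocity_clusters(self):
        fits = self.fits_from_tracks([(-10.0, 0.3), (10.0, -0.2)])
        trajs = dyn.build_trajectories(fits)
        long = [t for t in trajs if len(t.frames) >= 25]
        assert len(long) == 2
        assert not any(any(t.stray) for t in long)

    def test_single_frame_flip_is_flagged_stray(self):
        fits = self.fits_from_tracks([(-10.0, 0.2), (10.0, -0.2)])
        # one isolated frame where the fit collapsed to a single peak
        fits[12] = dyn.MixtureFit(5, 190, 0, 2, 2, -7.6, -7.6, 0.0, 1, frame=12)
        trajs = dyn.build_trajectories(fits)
        flagged = [t for t in trajs if any(s and f == 12 for f, s in zip(t.frames, t.stray))]
        assert flagged

    def test_appearance_frame_is_first_retained(self):
        fits = self.fits_from_tracks([(0.0, 0.1)], n_frames=12)
        trajs = dyn.build_trajectories(fits)
        assert trajs[0].appearance_frame == 0

    def test_intensity_series_formula(self):
        t = dyn.ClusterTrajectory(0, frames=[0], betas=[0.0], amplitudes=[50.0],
                                  widths=[2.0], stray=[False])
        assert t.intensity[0] == pytest.approx(50.0 * 2.0 * np.sqrt(2 * np.pi))


class TestVelocity:
    def test_known_slope_arithmetic(self):
        # 0.25 px/frame toward the boundary side = -0.315 um/min away
        t = dyn.ClusterTrajectory(
            0,
            frames=list(range(10)),
            betas=[0.25 * k for k in range(10)],
            amplitudes=[1.0] * 10, widths=[2.0] * 10, stray=[False] * 10,
        )
        v = dyn.estimate_velocity(t, pixel_size=0.105, frame_interval=5.0)
        assert v["velocity"] == pytest.approx(-0.315, rel=1e-6)

    def test_stationary_cluster_ci_contains_zero(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            betas = rng.normal(0.0, 0.2, 20)
            t = dyn.ClusterTrajectory(
                0, frames=list(range(20)), betas=list(betas),
                amplitudes=[1.0] * 20, widths=[2.0] * 20, stray=[False] * 20,
            )
            lo, hi = dyn.estimate_velocity(t)["ci"]
            hits += lo <= 0.0 <= hi
        assert hits >= 90  # 95% CI: a handful of misses are expected

    def test_velocity_estimator_is_unbiased(self):
        # constant-velocity cluster re-fit from noisy rendered profiles
        x = np.arange(-20.0, 21.0)
        errors = []
        for seed in range(60):
            prof, truth = simulate_profile(
                x, 21, a0=10.0,
                clusters=[ClusterSpec(s0=8.0, v_away=0.5, amplitude=100.0)],
                noise=None if seed is None else None, seed=seed,
            )
            rng = np.random.default_rng(seed)
            prof = prof + rng.normal(0, 8.0, prof.shape)
            fits = [dyn.fit_two_gaussians(x, prof[t], frame=t) for t in range(21)]
            trajs = dyn.build_trajectories(fits)
            best = max(trajs, key=lambda t: len(t.retained()[0]))
            v = dyn.estimate_velocity(best)["velocity"]
            errors.append(v - 0.5)
        assert abs(np.mean(errors)) < 0.05 * 0.5

    def test_too_short_trajectory_is_undefined(self):
        t = dyn.ClusterTrajectory(0, frames=[0, 1], betas=[0, 1],
                                  amplitudes=[1, 1], widths=[1, 1], stray=[False] * 2)
        assert np.isnan(dyn.estimate_velocity(t)["velocity"])

    def test_piecewise_fit_detects_direction_switch(self):
        frames = list(range(30))
        betas = [-0.3 * k if k < 15 else -4.5 + 0.3 * (k - 15) for k in frames]
        t = dyn.ClusterTrajectory(0, frames=frames, betas=betas,
                                  amplitudes=[1.0] * 30, widths=[2.0] * 30,
                                  stray=[False] * 30)
        pw = dyn.piecewise_velocity(t)
        assert pw is not None
        assert pw["v_before"] > 0 > pw["v_after"]
        assert abs(pw["break_frame"] - 15) <= 2


class TestClassification:
    @pytest.mark.parametrize("category", list("ABCDEFGHIJ"))
    def test_all_ten_categories_recovered(self, scenarios, category):
        cfg = scenarios[f"category_{category}"]
        series, _ = simulate_movie(cfg)
        ad = Adhesion(x=70, y=48, a=8, xi=0.5, theta=0.0, coefficient=100.0, frame=20)
        contour = BoundaryContour(boundary_polyline(cfg, 20))
        prof = dyn.extract_profile(series, ad, contour, window=20)
        fits = [
            dyn.fit_two_gaussians(prof.positions, prof.intensities[k], frame=int(t))
            for k, t in enumerate(prof.frames)
        ]
        trajs = dyn.build_trajectories(fits)
        result = dyn.classify_dynamics(trajs)
        assert result["category"] == category


class TestRegionalHistograms:
    def test_single_speed_lands_in_one_positive_bin(self):
        records = [{"region": "central", "velocity": 0.33, "category": "B"}] * 12
        out = dyn.regional_velocity_histograms(records)
        counts, edges = out["histograms"]["central"]
        occupied = np.nonzero(counts)[0]
        assert len(occupied) == 1
        assert edges[occupied[0]] == pytest.approx(0.3, abs=1e-9)
        assert counts.sum() == 12

    def test_bin_totals_conserved_and_fractions_recovered(self):
        rng = np.random.default_rng(0)
        records = []
        for i in range(200):
            away = rng.random() < 0.7
            v = abs(rng.normal(0.4, 0.1)) * (1 if away else -1)
            records.append({"region": "protruding", "velocity": v, "category": "B"})
        out = dyn.regional_velocity_histograms(records)
        counts, edges = out["histograms"]["protruding"]
        assert counts.sum() == 200
        centers = 0.5 * (edges[:-1] + edges[1:])
        frac_away = counts[centers > 0].sum() / 200
        assert frac_away == pytest.approx(0.7, abs=3 * np.sqrt(0.7 * 0.3 / 200))
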