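"""Intra-adhesion sub-population dynamics from fixed cross-section profiles.

Each detected adhesion defines a fixed 1-D axis through its center along
its orientation, reaching the cell boundary on one side and an equal
length on the other.  Intensity profiles are sampled along this axis for
a window of frames around the reference frame (default +/- 20) and each
frame's profile is fitted with a constrained mixture of two Gaussians on
a flat baseline:

    phi(x) = A0 + A1' exp(-(x - b1)^2 / (2 a1^2)) + A2' exp(-(x - b2)^2 / (2 a2^2))

with ``A0`` the profile minimum, both amplitudes constrained
non-negative, and only samples above the mean of the profile's extremes
entering the fit.  Peak centers linked across frames become cluster
trajectories; their least-squares velocities, collisions and direction
switches map onto a ten-category taxonomy of internal dynamics.

Sign convention: velocities are positive when a cluster moves *away*
from the cell boundary (stated in all outputs; the profile coordinate
itself increases toward the boundary).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, optimize, stats

from .cwt import ImageSeries
from .detect import Adhesion
from .morphology import BoundaryContour

__all__ = [
    "ProfileSeries",
    "MixtureFit",
    "ClusterTrajectory",
    "extract_profile",
    "fit_two_gaussians",
    "build_trajectories",
    "estimate_velocity",
    "piecewise_velocity",
    "classify_dynamics",
    "regional_velocity_histograms",
    "CATEGORY_DESCRIPTIONS",
]

CATEGORY_DESCRIPTIONS = {
    "A": "two peaks colliding with one another",
    "B": "one peak translating away from the cell boundary",
    "C": "two peaks translating away from the cell boundary",
    "D": "three peaks translating away from the cell boundary",
    "E": "a stationary peak and a peak translating away",
    "F": "a stationary peak and a peak translating toward the boundary",
    "G": "one stationary peak",
    "H": "two stationary peaks",
    "I": "collision after which the inbound peak switches direction and both move away",
    "J": "a stationary peak with two peaks translating away",
    "other": "unclassified pattern",
}


@dataclass
class ProfileSeries:
    """Intensity profiles along a fixed adhesion axis over a frame window.

    ``positions`` is the signed axis coordinate in pixels, identical for
    every frame, increasing toward the cell boundary (the boundary
    intersects the axis at ``positions ~ +L`` in the reference frame).
    ``boundary_position[t]`` is the axis coordinate of the frame-t
    boundary crossing (NaN when the contour no longer crosses the axis).
    """

    positions: np.ndarray
    intensities: np.ndarray  # (n_frames, n_positions)
    frames: np.ndarray
    boundary_position: np.ndarray
    origin: tuple[float, float]
    direction: tuple[float, float]  # unit vector toward the boundary
    adhesion_id: int = -1
    clipped: bool = False  # True when the far side exits the frame


def _axis_contour_crossings(
    origin: np.ndarray, direction: np.ndarray, contour: BoundaryContour
) -> np.ndarray:
    """Signed axis coordinates where a contour crosses the adhesion axis."""
    v = contour.vertices
    a, b = v[:-1], v[1:]
    n = np.array([-direction[1], direction[0]])  # normal to the axis
    fa = (a - origin) @ n
    fb = (b - origin) @ n
    cross = (fa * fb) <= 0
    out = []
    for i in np.nonzero(cross)[0]:
        denom = fa[i] - fb[i]
        if denom == 0:
            continue
        t = fa[i] / denom
        pt = a[i] + t * (b[i] - a[i])
        out.append(float((pt - origin) @ direction))
    return np.array(sorted(out))


def extract_profile(
    series: ImageSeries,
    adhesion: Adhesion,
    contour: BoundaryContour,
    contours_per_frame: Sequence[BoundaryContour | None] | None = None,
    window: int = 20,
    channel=0,
    step: float = 1.0,
) -> ProfileSeries:
    """Sample fixed-axis intensity profiles around an adhesion.

    The axis runs through the adhesion center along its orientation; the
    boundary side is the nearest crossing of the reference-frame
    contour.  Samples are taken at ``step``-pixel spacing with bilinear
    interpolation from ``-L`` to ``+L`` where ``+L`` is the boundary
    crossing; if the far side leaves the frame the profile is clipped
    and flagged.  The window covers ``adhesion.frame +/- window``,
    clamped to the series.
    """
    origin = np.array([adhesion.x, adhesion.y], dtype=float)
    th = np.deg2rad(adhesion.theta)
    direction = np.array([np.cos(th), -np.sin(th)])
    crossings = _axis_contour_crossings(origin, direction, contour)
    if crossings.size == 0:
        raise ValueError(
            f"adhesion {adhesion.id}: axis along theta={adhesion.theta:.1f} deg "
            "does not intersect the reference contour"
        )
    s_b = crossings[np.argmin(np.abs(crossings))]
    if s_b < 0:
        direction = -direction
        s_b = -s_b
    length = float(s_b)
    positions = np.arange(-np.floor(length / step), np.floor(length / step) + 1) * step

    h, w = series.frame_shape
    pts = origin[None, :] + positions[:, None] * direction[None, :]
    in_frame = (
        (pts[:, 0] >= 0) & (pts[:, 0] <= w - 1) & (pts[:, 1] >= 0) & (pts[:, 1] <= h - 1)
    )
    clipped = not bool(in_frame.all())
    if clipped:
        keep = np.nonzero(in_frame)[0]
        positions = positions[keep[0] : keep[-1] + 1]
        pts = pts[keep[0] : keep[-1] + 1]

    t0 = max(0, adhesion.frame - window)
    t1 = min(series.n_frames - 1, adhesion.frame + window)
    frames = np.arange(t0, t1 + 1)
    coords = [pts[:, 1], pts[:, 0]]  # (row, col)
    intensities = np.empty((len(frames), len(positions)))
    for k, t in enumerate(frames):
        intensities[k] = ndimage.map_coordinates(
            series.frame(t, channel), coords, order=1, mode="nearest"
        )
    boundary_position = np.full(len(frames), np.nan)
    for k, t in enumerate(frames):
        c = None
        if contours_per_frame is not None and t < len(contours_per_frame):
            c = contours_per_frame[t]
        elif t == adhesion.frame:
            c = contour
        if c is None:
            continue
        cr = _axis_contour_crossings(origin, direction, c)
        if cr.size:
            boundary_position[k] = cr[np.argmin(np.abs(cr - length))]
    return ProfileSeries(
        positions=positions,
        intensities=intensities,
        frames=frames,
        boundary_position=boundary_position,
        origin=(float(origin[0]), float(origin[1])),
        direction=(float(direction[0]), float(direction[1])),
        adhesion_id=adhesion.id,
        clipped=clipped,
    )


@dataclass
class MixtureFit:
    """Result of one constrained two-Gaussian profile fit."""

    A0: float
    amp1: float
    amp2: float
    alpha1: float
    alpha2: float
    beta1: float
    beta2: float
    residual: float
    n_peaks_effective: int
    fitted: bool = True
    frame: int = 0

    def peaks(self) -> list[tuple[float, float, float]]:
        """Effective peaks as (beta, amplitude, width), sorted by beta."""
        if not self.fitted:
            return []
        out = [(self.beta1, self.amp1, self.alpha1), (self.beta2, self.amp2, self.alpha2)]
        if self.n_peaks_effective == 1:
            out = [max(out, key=lambda p: p[1])]
        return sorted(out)


def _gauss1(params, x, a0):
    a1, s1, b1 = params
    return a0 + a1 * np.exp(-((x - b1) ** 2) / (2 * s1 * s1))


def _mixture_model(params, x, a0):
    a1, a2, s1, s2, b1, b2 = params
    return (
        a0
        + a1 * np.exp(-((x - b1) ** 2) / (2 * s1 * s1))
        + a2 * np.exp(-((x - b2) ** 2) / (2 * s2 * s2))
    )


def fit_two_gaussians(
    positions: np.ndarray,
    profile: np.ndarray,
    frame: int = 0,
    min_samples: int = 8,
    collapse_fraction: float = 0.05,
) -> MixtureFit:
    """Constrained two-Gaussian mixture fit of one profile.

    Only samples above the mean of the profile's extremes enter the
    least-squares problem; both amplitudes are bounded below by zero.
    When one fitted amplitude is below ``collapse_fraction`` of the
    other, or below three times the fit's RMS residual (a noise bump,
    not a population), the profile is effectively single-peaked.  Profiles with too
    few samples above the cutoff return an unfitted marker rather than
    raising.
    """
    x = np.asarray(positions, dtype=float)
    y = np.asarray(profile, dtype=float)
    a0 = float(y.min())
    cutoff = 0.5 * (y.max() + y.min())
    mask = y > cutoff
    if mask.sum() < min_samples or y.max() <= y.min():
        return MixtureFit(a0, 0, 0, 1, 1, 0, 0, np.nan, 0, fitted=False, frame=frame)
    xm, ym = x[mask], y[mask]

    # initial peak guesses from the smoothed profile: raw noisy samples
    # routinely hand the optimiser a spurious start
    sm = ndimage.gaussian_filter1d(y, 2.0, mode="nearest")
    sm_masked = np.where(mask, sm, -np.inf)
    b1 = float(x[int(np.argmax(sm_masked))])
    far = np.where(np.abs(x - b1) >= 4.0, sm_masked, -np.inf)
    b2 = float(x[int(np.argmax(far))]) if np.isfinite(far).any() else b1
    amp0 = float(ym.max() - a0)
    span = max(xm.max() - xm.min(), 4.0)
    blo, bhi = xm.min() - 1.0, xm.max() + 1.0
    p0 = [amp0, 0.7 * amp0, 2.5, 2.5, b1, b2]
    lo = [0.0, 0.0, 0.5, 0.5, blo, blo]
    hi = [np.inf, np.inf, span, span, bhi, bhi]
    res = optimize.least_squares(
        lambda p: _mixture_model(p, xm, a0) - ym, p0, bounds=(lo, hi), method="trf"
    )
    a1, a2, s1, s2, c1, c2 = res.x
    if abs(c1 - c2) < 2.5 and min(a1, a2) > 0:
        # unresolved pair: the two Gaussians model a single population
        tot = a1 + a2
        c1 = c2 = (a1 * c1 + a2 * c2) / tot
        s1 = s2 = (a1 * s1 + a2 * s2) / tot
        a1, a2 = tot, 0.0
    big, small = max(a1, a2), min(a1, a2)
    n_eff = 1 if (big <= 0 or small < collapse_fraction * big) else 2
    if n_eff == 2 and len(ym) > 7:
        # A noisy single peak is readily over-split into two overlapping
        # Gaussians: keep two only if they beat one by a nested F-test.
        # The comparison is evaluated on the *full* profile -- the
        # evidence for two populations (the valley, the flanks) lies
        # mostly below the fitting cutoff.
        res1 = optimize.least_squares(
            lambda p: _gauss1(p, xm, a0) - ym,
            [amp0, 2.5, b1],
            bounds=([0.0, 0.5, blo], [np.inf, span, bhi]),
        )
        rss1 = float(((_gauss1(res1.x, x, a0) - y) ** 2).sum())
        rss2 = float(((_mixture_model(res.x, x, a0) - y) ** 2).sum())
        dof2 = len(y) - 6
        if dof2 >= 1 and rss2 > 0:
            f_stat = ((rss1 - rss2) / 3.0) / (rss2 / dof2)
            if f_stat < stats.f.ppf(0.99, 3, dof2):
                n_eff = 1
                a1, s1, c1 = res1.x
                a2 = 0.0
                s2, c2 = s1, c1
    if c1 > c2:  # deterministic order by center
        a1, a2, s1, s2, c1, c2 = a2, a1, s2, s1, c2, c1
    return MixtureFit(
        A0=a0, amp1=float(a1), amp2=float(a2), alpha1=float(s1), alpha2=float(s2),
        beta1=float(c1), beta2=float(c2), residual=float(2 * res.cost),
        n_peaks_effective=n_eff, fitted=True, frame=frame,
    )


@dataclass
class ClusterTrajectory:
    """One sub-population tracked across the profile window."""

    cluster_id: int
    frames: list[int] = field(default_factory=list)
    betas: list[float] = field(default_factory=list)
    amplitudes: list[float] = field(default_factory=list)
    widths: list[float] = field(default_factory=list)
    stray: list[bool] = field(default_factory=list)

    @property
    def intensity(self) -> np.ndarray:
        """Area under the Gaussian peak per retained sample: A' * alpha * sqrt(2 pi)."""
        a = np.asarray(self.amplitudes)
        w = np.asarray(self.widths)
        return a * w * np.sqrt(2 * np.pi)

    def retained(self) -> tuple[np.ndarray, np.ndarray]:
        keep = ~np.asarray(self.stray, dtype=bool)
        return np.asarray(self.frames)[keep], np.asarray(self.betas)[keep]

    @property
    def appearance_frame(self) -> int:
        f, _ = self.retained()
        return int(f[0]) if len(f) else int(self.frames[0])

    @property
    def disappearance_frame(self) -> int:
        f, _ = self.retained()
        return int(f[-1]) if len(f) else int(self.frames[-1])


def _stray_frames(n_eff: dict[int, int]) -> set[int]:
    """Frames whose effective peak count differs from both neighbours."""
    frames = sorted(n_eff)
    stray = set()
    for i, t in enumerate(frames):
        prev_n = n_eff[frames[i - 1]] if i > 0 else None
        next_n = n_eff[frames[i + 1]] if i < len(frames) - 1 else None
        if prev_n is not None and next_n is not None:
            if n_eff[t] != prev_n and n_eff[t] != next_n and prev_n == next_n:
                stray.add(t)
    return stray


def build_trajectories(
    fits: Sequence[MixtureFit],
    max_jump: float = 1.5,
    max_gap: int = 4,
    stitch_gap: int = 8,
    stitch_jump: float = 3.0,
) -> list[ClusterTrajectory]:
    """Associate fitted peaks across frames into cluster trajectories.

    Nearest-center matching with a maximum per-frame jump (the default
    1.5 px/frame comfortably covers the ~1 um/min speeds of real
    sub-populations plus fit jitter); frames whose effective peak count
    flips against both neighbours are flagged stray and excluded from
    velocity estimation (they still appear in the trajectory for
    inspection).  A trajectory survives up to ``max_gap`` consecutive
    frames without a match.  A final stitching pass joins temporally
    disjoint fragments of the same cluster (gap up to ``stitch_gap``
    frames,end positions within ``stitch_jump`` px).
    """
    fits = [f for f in fits if f.fitted]
    fits.sort(key=lambda f: f.frame)
    n_eff = {f.frame: f.n_peaks_effective for f in fits}
    stray = _stray_frames(n_eff)

    trajectories: list[ClusterTrajectory] = []
    active: list[ClusterTrajectory] = []
    for f in fits:
        peaks = f.peaks()
        is_stray = f.frame in stray
        # greedy nearest association, each trajectory and peak used once
        pairs = []
        for ti, traj in enumerate(active):
            # anchor on the last non-stray entry: stray frames are noise
            # and must not mediate hand-offs between distinct clusters
            anchor = len(traj.frames) - 1
            while anchor > 0 and traj.stray[anchor]:
                anchor -= 1
            gap = f.frame - traj.frames[anchor]
            if gap > max_gap + 1:
                continue
            # gate against the extrapolated position rather than scaling
            # the jump allowance with the gap: over several skipped
            # frames a cluster continues its recent motion, it does not
            # teleport onto a different peak
            predicted = traj.betas[anchor] + _tail_slope(traj) * gap
            allowed = max_jump * (1.0 + 0.5 * (gap - 1))
            for pi, (beta, amp, width) in enumerate(peaks):
                d = abs(beta - predicted)
                if d <= allowed:
                    pairs.append((d, ti, pi))
        pairs.sort()
        used_t, used_p = set(), set()
        for d, ti, pi in pairs:
            if ti in used_t or pi in used_p:
                continue
            used_t.add(ti)
            used_p.add(pi)
            beta, amp, width = peaks[pi]
            traj = active[ti]
            traj.frames.append(f.frame)
            traj.betas.append(beta)
            traj.amplitudes.append(amp)
            traj.widths.append(width)
            traj.stray.append(is_stray)
        for pi, (beta, amp, width) in enumerate(peaks):
            if pi in used_p:
                continue
            traj = ClusterTrajectory(cluster_id=len(trajectories))
            traj.frames.append(f.frame)
            traj.betas.append(beta)
            traj.amplitudes.append(amp)
            traj.widths.append(width)
            traj.stray.append(is_stray)
            trajectories.append(traj)
            active.append(traj)
        active = [t for t in active if f.frame - t.frames[-1] <= max_gap]
    return _stitch(trajectories, stitch_gap, stitch_jump)


def _tail_slope(traj: ClusterTrajectory, n: int = 6) -> float:
    """Recent drift of a trajectory, px/frame, for extrapolation.

    Needs at least four points (a two-point "slope" is noise) and is
    clipped to +/- 1 px/frame, the physical speed range of the clusters.
    """
    f = np.asarray(traj.frames[-n:], dtype=float)
    b = np.asarray(traj.betas[-n:], dtype=float)
    if len(f) < 4 or f[-1] == f[0]:
        return 0.0
    return float(np.clip(np.polyfit(f, b, 1)[0], -1.0, 1.0))


def _stitch(trajectories, stitch_gap: int, stitch_jump: float):
    """Join temporally disjoint fragments of one moving cluster.

    A fragment continues another when it starts shortly after the other
    ends, near the position the other's recent motion extrapolates to.
    """
    trajectories = sorted(trajectories, key=lambda t: t.frames[0])

    def endpoints(t):
        f, b = t.retained()
        if len(f):
            return int(f[0]), int(f[-1]), float(b[0]), float(b[-1])
        return t.frames[0], t.frames[-1], t.betas[0], t.betas[-1]

    def zipper(ta, tb) -> bool:
        # one peak alternately claimed by two trajectories: spans overlap,
        # per-frame membership is disjoint, positions coincide
        fa, ba = ta.retained()
        fb, bb = tb.retained()
        if len(fa) < 3 or len(fb) < 3:
            return False
        if min(fa[-1], fb[-1]) - max(fa[0], fb[0]) < 3:
            return False
        if len(np.intersect1d(fa, fb)) > 1:
            return False
        interp = np.interp(fb, fa, ba)
        return float(np.median(np.abs(bb - interp))) <= stitch_jump

    merged = True
    while merged:
        merged = False
        for i, ta in enumerate(trajectories):
            _, a_end, _, a_beta = endpoints(ta)
            for tb in trajectories[i + 1 :]:
                if zipper(ta, tb):
                    order = np.argsort(np.concatenate([ta.frames, tb.frames]))
                    for attr in ("frames", "betas", "amplitudes", "widths", "stray"):
                        combined = getattr(ta, attr) + getattr(tb, attr)
                        setattr(ta, attr, [combined[k] for k in order])
                    trajectories.remove(tb)
                    merged = True
                    break
                b_start, _, b_beta, _ = endpoints(tb)
                gap = b_start - a_end
                predicted = a_beta + _tail_slope(ta) * max(gap, 0)
                # a stray tail/head may overlap by a frame or two
                if -2 <= gap <= stitch_gap and abs(b_beta - predicted) <= stitch_jump:
                    keep = [k for k, f in enumerate(ta.frames) if f <= a_end]
                    add = [k for k, f in enumerate(tb.frames) if f > a_end]
                    ta.frames = [ta.frames[k] for k in keep] + [tb.frames[k] for k in add]
                    ta.betas = [ta.betas[k] for k in keep] + [tb.betas[k] for k in add]
                    ta.amplitudes = [ta.amplitudes[k] for k in keep] + [
                        tb.amplitudes[k] for k in add
                    ]
                    ta.widths = [ta.widths[k] for k in keep] + [tb.widths[k] for k in add]
                    ta.stray = [ta.stray[k] for k in keep] + [tb.stray[k] for k in add]
                    trajectories.remove(tb)
                    merged = True
                    break
            if merged:
                break
    for k, t in enumerate(trajectories):
        t.cluster_id = k
    return trajectories


def estimate_velocity(
    trajectory: ClusterTrajectory,
    pixel_size: float = 0.105,
    frame_interval: float = 5.0,
) -> dict:
    """Least-squares cluster velocity in um/min with a 95% CI.

    Positive velocities move *away* from the cell boundary (profile
    coordinates increase toward it, so the regression slope is negated).
    Returns NaNs when fewer than 4 retained samples exist.
    """
    f, b = trajectory.retained()
    if len(f) < 4:
        return {"velocity": np.nan, "ci": (np.nan, np.nan), "n": int(len(f))}
    t = f * frame_interval
    fit = stats.linregress(t, b * pixel_size)
    v = -fit.slope * 60.0
    half = stats.t.ppf(0.975, len(f) - 2) * fit.stderr * 60.0
    return {"velocity": float(v), "ci": (float(v - half), float(v + half)), "n": int(len(f))}


def boundary_velocity(
    profile: ProfileSeries, pixel_size: float = 0.105, frame_interval: float = 5.0
) -> dict:
    """Velocity of the boundary crossing along the axis, same estimator/sign."""
    ok = np.isfinite(profile.boundary_position)
    if ok.sum() < 4:
        return {"velocity": np.nan, "ci": (np.nan, np.nan), "n": int(ok.sum())}
    t = profile.frames[ok] * frame_interval
    fit = stats.linregress(t, profile.boundary_position[ok] * pixel_size)
    v = -fit.slope * 60.0
    half = stats.t.ppf(0.975, ok.sum() - 2) * fit.stderr * 60.0
    return {"velocity": float(v), "ci": (float(v - half), float(v + half)), "n": int(ok.sum())}


def piecewise_velocity(
    trajectory: ClusterTrajectory,
    pixel_size: float = 0.105,
    frame_interval: float = 5.0,
    min_segment: int = 3,
) -> dict | None:
    """Two-segment velocity fit with the RSS-optimal breakpoint.

    Returns segment velocities (away-positive) and the break frame when
    a breakpoint with opposite-sign slopes exists, else None.
    """
    f, b = trajectory.retained()
    if len(f) < 2 * min_segment:
        return None
    t = f * frame_interval
    y = b * pixel_size
    best = None
    for k in range(min_segment, len(f) - min_segment + 1):
        r1 = stats.linregress(t[:k], y[:k])
        r2 = stats.linregress(t[k:], y[k:])
        rss = float(
            ((y[:k] - (r1.intercept + r1.slope * t[:k])) ** 2).sum()
            + ((y[k:] - (r2.intercept + r2.slope * t[k:])) ** 2).sum()
        )
        if best is None or rss < best[0]:
            best = (rss, k, -r1.slope * 60.0, -r2.slope * 60.0)
    _, k, v1, v2 = best
    if np.sign(v1) == np.sign(v2):
        return None
    return {"v_before": float(v1), "v_after": float(v2), "break_frame": int(f[k])}


def _collision(
    t1: ClusterTrajectory,
    t2: ClusterTrajectory,
    collision_distance: float,
) -> int | None:
    """First frame where two approaching clusters come within the collision distance."""
    f1, b1 = t1.retained()
    f2, b2 = t2.retained()
    common, i1, i2 = np.intersect1d(f1, f2, return_indices=True)
    if len(common) < 3:
        return None
    sep = np.abs(b1[i1] - b2[i2])
    below = np.nonzero(sep <= collision_distance)[0]
    for k in below:
        if k >= 1 and sep[k] < sep[:k].max() - 1e-9:  # approaching beforehand
            return int(common[k])
    return None


def _merge_collision(
    trajectories: Sequence[ClusterTrajectory],
    collision_distance: float = 2.0,
    all_trajectories: Sequence[ClusterTrajectory] | None = None,
    last_frame: int | None = None,
) -> int | None:
    """Collision detected as a merge or absorption event.

    Two peaks wider than their closing distance stop being separable
    well before their centers meet: the mixture collapses to one peak.
    Either both incoming trajectories end together and a single
    successor starts between their last positions (merge), or one
    trajectory ends near the other, which continues (absorption).  In
    both cases the pair must have been approaching (their separation
    shrank over their common frames).  Returns the collision frame.
    """
    for i, ta in enumerate(trajectories):
        fa, ba = ta.retained()
        if len(fa) < 3:
            continue
        for tb in trajectories[i + 1 :]:
            fb, bb = tb.retained()
            if len(fb) < 3:
                continue
            common, i1, i2 = np.intersect1d(fa, fb, return_indices=True)
            if len(common) < 3:
                continue
            sep = np.abs(ba[i1] - bb[i2])
            if not sep[-1] < 0.85 * sep.max():
                continue
            widths = np.concatenate([ta.widths, tb.widths])
            # two Gaussians blend into one fittable hump when their centers
            # come within a few widths of each other
            resolvable = max(collision_distance, 4.0 * float(np.mean(widths)))
            end_a, end_b = fa[-1], fb[-1]
            if abs(end_a - end_b) <= 2:
                # merge: both end together, one successor in between
                end = max(end_a, end_b)
                lo = min(ba[-1], bb[-1]) - 3.0
                hi = max(ba[-1], bb[-1]) + 3.0
                for tc in (all_trajectories if all_trajectories is not None else trajectories):
                    if tc is ta or tc is tb:
                        continue
                    fc, bc = tc.retained()
                    if len(fc) >= 2 and 0 <= fc[0] - end <= 5 and lo <= bc[0] <= hi:
                        return int(end)
                # no visible successor (the merged hump may fall below the
                # fitting cutoff): a strong simultaneous approach ending
                # mid-window still marks a merge
                if (
                    (last_frame is None or end <= last_frame - 3)
                    and sep[-1] < 0.7 * sep.max()
                    and sep[-1] <= resolvable
                ):
                    return int(end)
            # absorption: the earlier-ending trajectory vanishes close to
            # the surviving one while they were approaching
            first, f_first, b_first = (ta, fa, ba) if end_a <= end_b else (tb, fb, bb)
            other, f_other, b_other = (tb, fb, bb) if end_a <= end_b else (ta, fa, ba)
            end = f_first[-1]
            # absorption demands a genuine collapse of the separation, not
            # merely a drift toward the survivor
            if (
                f_other[-1] >= end + 3
                and sep[-1] <= resolvable
                and sep[-1] < 0.6 * sep.max()
            ):
                return int(end)
    return None


def classify_dynamics(
    trajectories: Sequence[ClusterTrajectory],
    pixel_size: float = 0.105,
    frame_interval: float = 5.0,
    v_stationary: float = 0.05,
    collision_distance: float = 2.0,
    min_lifetime: int = 8,
) -> dict:
    """Map an adhesion's cluster trajectories onto the ten-category taxonomy.

    Categories: (A) two colliding peaks; (B-D) one/two/three peaks
    translating away from the boundary; (E) stationary + away;
    (F) stationary + toward; (G-H) one/two stationary; (I) collision
    followed by a direction switch, both away; (J) stationary + two
    away.  ``v_stationary`` (um/min) separates stationary from
    translating; a collision requires the inter-peak separation to drop
    below ``collision_distance`` (px) while approaching.
    """
    trajs = [t for t in trajectories if len(t.retained()[0]) >= min_lifetime]
    # collisions and merges may involve short-lived pieces (e.g. the
    # unresolved successor of a merge), so event detection looks at a
    # broader set than the pattern lookup
    trajs_all = [t for t in trajectories if len(t.retained()[0]) >= 4]
    velocities = [estimate_velocity(t, pixel_size, frame_interval)["velocity"] for t in trajs]

    def status(v: float) -> str:
        if not np.isfinite(v):
            return "unknown"
        if abs(v) < v_stationary:
            return "stationary"
        return "away" if v > 0 else "toward"

    statuses = [status(v) for v in velocities]
    pattern = "+".join(sorted(statuses))
    result = {
        "n_clusters": len(trajs),
        "velocities": velocities,
        "statuses": statuses,
        "pattern": pattern,
    }

    # collisions: either two resolved peaks pass within the collision
    # distance while approaching, or two approaching peaks merge (the
    # mixture stops resolving them and a single successor takes over)
    col = None
    for i in range(len(trajs_all)):
        for j in range(i + 1, len(trajs_all)):
            c = _collision(trajs_all[i], trajs_all[j], collision_distance)
            if c is not None and (col is None or c < col):
                col = c
    if col is None:
        last_frame = max(
            (t.frames[-1] for t in trajectories if t.frames), default=None
        )
        col = _merge_collision(
            trajs_all, collision_distance,
            all_trajectories=list(trajectories), last_frame=last_frame,
        )
    if col is not None:
        result["collision_frame"] = col
        # a peak heading toward the boundary before the collision?
        vel_all = [
            estimate_velocity(t, pixel_size, frame_interval)["velocity"] for t in trajs_all
        ]
        pre_toward = any(
            np.isfinite(v) and v < -v_stationary
            for t, v in zip(trajs_all, vel_all)
            if t.retained()[0][0] <= col
        )
        switched = any(
            (pw := piecewise_velocity(t, pixel_size, frame_interval)) is not None
            and pw["v_before"] < 0 < pw["v_after"]
            and abs(pw["break_frame"] - col) <= 6
            for t in trajs_all
        )
        # movement of everything still present after the collision has
        # settled (a few frames' margin past the event itself)
        post = []
        for t in trajs_all:
            f, b = t.retained()
            sel = f >= col + 5
            # short fragments carry no reliable direction information
            if sel.sum() >= 6:
                fit = stats.linregress(f[sel] * frame_interval, b[sel] * pixel_size)
                post.append(-fit.slope * 60.0)
        all_away_after = (
            len(post) > 0
            and all(v > -v_stationary for v in post)
            and any(v > v_stationary for v in post)
        )
        if (switched or pre_toward) and all_away_after:
            result["category"] = "I"
        else:
            result["category"] = "A"
        return result

    lookup = {
        ("away",): "B",
        ("away", "away"): "C",
        ("away", "away", "away"): "D",
        ("away", "stationary"): "E",
        ("stationary", "toward"): "F",
        ("stationary",): "G",
        ("stationary", "stationary"): "H",
        ("away", "away", "stationary"): "J",
    }
    result["category"] = lookup.get(tuple(sorted(statuses)), "other")
    return result


def regional_velocity_histograms(
    records,
    bin_width: float = 0.1,
):
    """Signed velocity histograms per cell region, away-positive.

    ``records`` is an iterable of dicts with keys ``region``,
    ``velocity`` (um/min, positive away from the boundary) and
    optionally ``category``.  Returns per-region ``(counts, edges)``
    histograms with ``bin_width`` um/min bins plus a per-category
    mean +/- 95% CI table.
    """
    import pandas as pd

    table = pd.DataFrame(list(records))
    if table.empty:
        return {"histograms": {}, "category_table": table}
    v = table["velocity"].to_numpy(dtype=float)
    vmax = np.nanmax(np.abs(v)) if np.isfinite(v).any() else bin_width
    n_bins = int(np.ceil(vmax / bin_width)) + 1
    edges = np.arange(-n_bins, n_bins + 1) * bin_width
    hists = {}
    for region, sub in table.groupby("region"):
        counts, _ = np.histogram(sub["velocity"].dropna(), bins=edges)
        hists[region] = (counts, edges)
    cat_rows = []
    if "category" in table.columns:
        for cat, sub in table.groupby("category"):
            vals = sub["velocity"].dropna().to_numpy()
            if len(vals) == 0:
                continue
            mean = float(vals.mean())
            if len(vals) > 1:
                half = float(
                    stats.t.ppf(0.975, len(vals) - 1) * vals.std(ddof=1) / np.sqrt(len(vals))
                )
            else:
                half = np.nan
            cat_rows.append(
                {"category": cat, "mean_velocity": mean, "ci95_half_width": half, "n": len(vals)}
            )
    import pandas as pd

    return {"histograms": hists, "category_table": pd.DataFrame(cat_rows)}
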