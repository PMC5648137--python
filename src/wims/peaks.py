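"""Consensus peak detection for 1-D bundle profiles and pole-velocity analysis.

Protein populations at the ends ("poles") of actomyosin bundles appear
as peaks in 1-D intensity profiles sampled along the bundle axis.  Three
independent detectors are run on each profile and only peaks found by
all three (within a matching tolerance) are kept, which suppresses
noise-induced false positives:

1. prominence ordering of smoothed local extrema, with Gaussian (or
   two-Gaussian) fits between flanking minima;
2. local extrema of the second derivative of the smoothed profile,
   fitted with 1-D Mexican-hat shapes whose double integral recovers the
   original peak analytically;
3. least-squares fits of the long-tailed Lorentzian-pair wavelet.

"Size" is unified across the methods as the integrated intensity above
baseline of the fitted shape, so the three detectors are directly
comparable.  The two-channel pole analysis tracks the outermost
consensus peak on each side of a bundle in both channels and reports
per-pole velocities (positive toward the bundle center) and the
same-side velocity difference between the channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, optimize, stats

from .cwt import ImageSeries
from .detect import Adhesion, ellipse_axes
from .wavelets import lorentzian_pair

__all__ = [
    "Peak",
    "PeakSet",
    "PoleTrack",
    "peaks_by_prominence",
    "peaks_by_second_derivative",
    "peaks_by_lorentzian_wavelet",
    "consensus",
    "pole_analysis",
]

# integral of the Lorentzian pair's positive lobe (|u| < sqrt(2)), amp = 1
_LORENTZ_LOBE = float((2 / np.pi) * (np.arctan(np.sqrt(2)) - np.arctan(np.sqrt(2) / 2)))


@dataclass(frozen=True)
class Peak:
    center: float  # pixels along the profile
    size: float  # integrated intensity above baseline
    width: float  # pixels
    method: int


@dataclass
class PeakSet:
    peaks: list[Peak] = field(default_factory=list)
    profile_id: str = ""

    def centers(self) -> np.ndarray:
        return np.array([p.center for p in self.peaks])

    def __len__(self) -> int:
        return len(self.peaks)


def _smooth(y: np.ndarray, sigma: float) -> np.ndarray:
    return ndimage.gaussian_filter1d(np.asarray(y, dtype=float), sigma, mode="nearest")


def _noise_sigma(y: np.ndarray) -> float:
    """Robust per-sample noise level from first differences (MAD-based)."""
    d = np.diff(np.asarray(y, dtype=float))
    if len(d) == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))


def _extrema(y: np.ndarray):
    """Indices of interior local maxima and minima (plateau-safe)."""
    from scipy.signal import argrelextrema

    maxima = argrelextrema(y, np.greater_equal, order=1)[0]
    maxima = np.array([i for i in maxima if 0 < i < len(y) - 1 and (y[i] > y[i - 1] or y[i] > y[i + 1])], dtype=int)
    minima = argrelextrema(y, np.less_equal, order=1)[0]
    return maxima, minima


def _gauss(x, amp, center, sigma, base):
    return base + amp * np.exp(-((x - center) ** 2) / (2 * sigma * sigma))


def peaks_by_prominence(
    profile: np.ndarray,
    smoothing: float = 1.5,
    min_prominence_fraction: float = 0.05,
    min_snr: float = 4.0,
    profile_id: str = "",
) -> PeakSet:
    """Method 1: smoothed local extrema ordered by prominence.

    Prominence is the larger of the drops to the two flanking minima
    (profile ends count as minima).  Each minima-bounded interval is
    fitted with a Gaussian above the interval baseline; size is the
    fitted area ``A * sigma * sqrt(2 pi)``.  Peaks whose amplitude is
    below ``min_snr`` times the profile's robust noise level are noise
    bumps, not populations, and are dropped.
    """
    y = np.asarray(profile, dtype=float)
    if len(y) < 8:
        raise ValueError("profile too short")
    noise = _noise_sigma(y)
    s = _smooth(y, smoothing)
    rng = s.max() - s.min()
    if rng <= 0:
        return PeakSet([], profile_id)
    maxima, minima = _extrema(s)
    if len(maxima) == 0:
        return PeakSet([], profile_id)
    bounds = np.unique(np.concatenate([[0], minima, [len(y) - 1]]))
    peaks = []
    x = np.arange(len(y), dtype=float)
    for m in maxima:
        left = bounds[bounds < m]
        right = bounds[bounds > m]
        if len(left) == 0 or len(right) == 0:
            continue
        lo, hi = int(left.max()), int(right.min())
        prom = max(s[m] - s[lo], s[m] - s[hi])
        if prom < min_prominence_fraction * rng:
            continue
        xm, ym = x[lo : hi + 1], y[lo : hi + 1]
        base = float(ym.min())
        amp0 = max(float(y[m] - base), 1e-6)
        try:
            popt = optimize.least_squares(
                lambda p: _gauss(xm, p[0], p[1], p[2], base) - ym,
                [amp0, float(m), max(1.0, (hi - lo) / 4.0)],
                bounds=([0, lo - 1, 0.3], [np.inf, hi + 1, max(2.0, float(hi - lo))]),
            ).x
        except Exception:
            continue
        amp, center, sigma = popt
        if amp <= 0 or amp < min_snr * noise:
            continue
        peaks.append(
            Peak(center=float(center), size=float(amp * sigma * np.sqrt(2 * np.pi)),
                 width=float(sigma), method=1)
        )
    peaks.sort(key=lambda p: -p.size)
    return PeakSet(peaks, profile_id)


def _ricker1d(x, amp, center, s):
    u = (x - center) / s
    return amp * (1 - u * u) * np.exp(-u * u / 2)


def peaks_by_second_derivative(
    profile: np.ndarray, smoothing: float = 1.5, min_snr: float = 4.0,
    profile_id: str = "",
) -> PeakSet:
    """Method 2: Mexican hats fitted to the second derivative.

    A Gaussian peak ``A exp(-(x-c)^2/2s^2)`` has second derivative
    ``-(A/s^2) ricker((x-c)/s)``; fitting ``B * ricker`` to the negated
    second difference and integrating twice analytically recovers the
    peak: height ``B s^2``, area ``B s^3 sqrt(2 pi)``.
    """
    y = np.asarray(profile, dtype=float)
    if len(y) < 8:
        raise ValueError("profile too short")
    noise = _noise_sigma(y)
    s = _smooth(y, smoothing)
    d2 = np.gradient(np.gradient(s))
    neg = d2 < -0.02 * max(np.abs(d2).max(), 1e-12)
    peaks = []
    x = np.arange(len(y), dtype=float)
    i = 0
    while i < len(y):
        if not neg[i]:
            i += 1
            continue
        j = i
        while j < len(y) and neg[j]:
            j += 1
        run = slice(max(0, 2 * i - j), min(len(y), 2 * j - i))  # run plus one width margin
        c0 = float(x[i:j][np.argmin(d2[i:j])])
        s0 = max((j - i) / 2.0, 0.8)
        b0 = float(-d2[i:j].min())
        try:
            popt = optimize.least_squares(
                lambda p: _ricker1d(x[run], p[0], p[1], p[2]) - (-d2[run]),
                [b0, c0, s0],
                bounds=([0, x[run][0], 0.3], [np.inf, x[run][-1], len(y)]),
            ).x
        except Exception:
            i = j
            continue
        amp, center, width = popt
        # recovered peak height is B * s^2; test it against the noise floor
        if amp > 0 and amp * width**2 >= min_snr * noise:
            peaks.append(
                Peak(center=float(center), size=float(amp * width**3 * np.sqrt(2 * np.pi)),
                     width=float(width), method=2)
            )
        i = j
    peaks.sort(key=lambda p: -p.size)
    return PeakSet(peaks, profile_id)


def peaks_by_lorentzian_wavelet(
    profile: np.ndarray, smoothing: float = 1.5, min_snr: float = 4.0,
    profile_id: str = "",
) -> PeakSet:
    """Method 3: least-squares Lorentzian-pair template fits.

    Candidate locations come from smoothed maxima; at each, a scaled
    Lorentzian pair (free amplitude, center, width) is fitted over the
    minima-bounded interval.  Size is the fitted positive-lobe area
    (``0.2164 * amplitude``, independent of the width).
    """
    y = np.asarray(profile, dtype=float)
    if len(y) < 8:
        raise ValueError("profile too short")
    noise = _noise_sigma(y)
    s = _smooth(y, smoothing)
    rng = s.max() - s.min()
    if rng <= 0:
        return PeakSet([], profile_id)
    maxima, minima = _extrema(s)
    bounds = np.unique(np.concatenate([[0], minima, [len(y) - 1]]))
    peaks = []
    x = np.arange(len(y), dtype=float)
    for m in maxima:
        left = bounds[bounds < m]
        right = bounds[bounds > m]
        if len(left) == 0 or len(right) == 0:
            continue
        lo, hi = int(left.max()), int(right.min())
        if max(s[m] - s[lo], s[m] - s[hi]) < 0.05 * rng:
            continue
        base0 = float(y[lo : hi + 1].min())
        g0 = max(1.0, (hi - lo) / 6.0)
        amp0 = max(float(y[m] - base0), 1e-6) * 2 * np.pi * g0
        xm, ym = x[lo : hi + 1], y[lo : hi + 1]

        def resid(p, xm=xm, ym=ym):
            # free baseline: the template's negative lobes would otherwise
            # be soaked up by the interval minimum
            return p[3] + p[0] * lorentzian_pair(xm, p[1], p[2]) - ym

        try:
            popt = optimize.least_squares(
                resid, [amp0, float(m), g0, base0],
                bounds=(
                    [0, lo - 1, 0.2, -np.inf],
                    [np.inf, hi + 1, 4.0 * max(1, hi - lo), np.inf],
                ),
            ).x
        except Exception:
            continue
        amp, center, gamma, _base = popt
        # template peak height is amp / (2 pi gamma)
        if amp <= 0 or amp / (2 * np.pi * gamma) < min_snr * noise:
            continue
        peaks.append(
            Peak(center=float(center), size=float(amp * _LORENTZ_LOBE),
                 width=float(gamma), method=3)
        )
    peaks.sort(key=lambda p: -p.size)
    return PeakSet(peaks, profile_id)


def consensus(
    sets: Sequence[PeakSet], match_tolerance: float = 2.0
) -> PeakSet:
    """Keep peaks reported by all three methods within the tolerance.

    A method-1 peak is retained iff each other set has a peak within
    ``match_tolerance`` pixels of its center; retained center/size are
    the method-1 values (others available as alternates in the returned
    peak order).  Permutation-invariant in the inputs: the reference set
    is the one with method id 1, falling back to the first.
    """
    if len(sets) != 3:
        raise ValueError("consensus expects exactly three peak sets")
    ref = next((s for s in sets if s.peaks and s.peaks[0].method == 1), sets[0])
    others = [s for s in sets if s is not ref]
    kept = []
    for p in ref.peaks:
        ok = True
        for s in others:
            if len(s) == 0 or np.abs(s.centers() - p.center).min() > match_tolerance:
                ok = False
                break
        if ok:
            kept.append(p)
    return PeakSet(kept, ref.profile_id)


def detect_consensus_peaks(
    profile: np.ndarray, smoothing: float = 1.5, match_tolerance: float = 2.0,
    profile_id: str = "",
) -> PeakSet:
    """Run all three detectors and return their consensus."""
    s1 = peaks_by_prominence(profile, smoothing, profile_id=profile_id)
    s2 = peaks_by_second_derivative(profile, smoothing, profile_id=profile_id)
    s3 = peaks_by_lorentzian_wavelet(profile, smoothing, profile_id=profile_id)
    return consensus([s1, s2, s3], match_tolerance)


@dataclass
class PoleTrack:
    """One pole population of a bundle in one channel."""

    bundle_id: int
    pole_side: str  # left | right
    channel: str
    frames: list[int] = field(default_factory=list)
    positions: list[float] = field(default_factory=list)  # signed px along axis
    velocity: float = np.nan  # um/min, positive toward the bundle center
    ci: tuple[float, float] = (np.nan, np.nan)
    partner: "PoleTrack | None" = None

    @property
    def delta_v(self) -> float:
        """v_vinculin - v_myosin for a linked same-side pair."""
        if self.partner is None:
            return np.nan
        if self.channel == self.partner.channel:
            return np.nan
        v_v = self.velocity if self.channel != "myosin" else self.partner.velocity
        v_m = self.partner.velocity if self.channel != "myosin" else self.velocity
        return float(v_v - v_m)


def _fit_pole_velocity(
    track: PoleTrack, pixel_size: float, frame_interval: float
) -> None:
    if len(track.frames) < 4:
        return
    t = np.asarray(track.frames, dtype=float) * frame_interval
    p = np.asarray(track.positions) * pixel_size
    fit = stats.linregress(t, p)
    sign = 1.0 if track.pole_side == "left" else -1.0  # toward center = +s for left pole
    v = sign * fit.slope * 60.0
    half = stats.t.ppf(0.975, len(t) - 2) * fit.stderr * 60.0
    track.velocity = float(v)
    track.ci = (float(v - half), float(v + half))


def pole_analysis(
    series: ImageSeries,
    bundle: Adhesion,
    channels: tuple = ("myosin", "vinculin"),
    smoothing: float = 1.5,
    match_tolerance: float = 2.0,
    length_factor: float = 1.5,
    bin_width: float = 0.03,
    gate_px: float = 3.0,
) -> dict:
    """Two-channel pole tracking along a detected bundle axis.

    Per frame and channel, the profile along the bundle's major axis is
    consensus-peak detected; the outermost peaks on each side of the
    bundle midpoint are the poles.  Pole positions are tracked over all
    frames (skipping, with a flag, frames where fewer than two consensus
    peaks exist) and fitted with straight lines; velocities are positive
    toward the bundle center.  Same-side poles of the two channels are
    linked, giving ``delta_v = v_vinculin - v_myosin`` per pair.
    Histograms use ``bin_width`` um/min bins.
    """
    # the bundle's long axis: along r_par for xi <= 1, along r_perp
    # (theta + 90 deg) for xi > 1
    axis_deg = bundle.theta if bundle.xi <= 1.0 else (bundle.theta + 90.0) % 180.0
    th = np.deg2rad(axis_deg)
    direction = np.array([np.cos(th), -np.sin(th)])
    semi = max(ellipse_axes(bundle.a, bundle.xi, "scaled"))
    half_len = length_factor * semi
    positions = np.arange(-np.floor(half_len), np.floor(half_len) + 1, 1.0)
    origin = np.array([bundle.x, bundle.y])
    pts = origin[None, :] + positions[:, None] * direction[None, :]
    h, w = series.frame_shape
    inb = (pts[:, 0] >= 0) & (pts[:, 0] <= w - 1) & (pts[:, 1] >= 0) & (pts[:, 1] <= h - 1)
    positions, pts = positions[inb], pts[inb]
    coords = [pts[:, 1], pts[:, 0]]

    tracks = {
        (ch, side): PoleTrack(bundle.id, side, ch)
        for ch in channels
        for side in ("left", "right")
    }
    skipped = {ch: [] for ch in channels}

    def centroid(prof: np.ndarray, idx_center: float, width: float) -> float:
        """Center of mass of the local, baseline-subtracted peak."""
        half = max(int(round(1.5 * width)), 3)
        i0 = max(0, int(round(idx_center)) - half)
        i1 = min(len(prof), int(round(idx_center)) + half + 1)
        seg = prof[i0:i1]
        wgt = np.clip(seg - seg.min(), 0, None)
        if wgt.sum() <= 0:
            return float(idx_center)
        return float((np.arange(i0, i1) * wgt).sum() / wgt.sum())

    for t in range(series.n_frames):
        for ci, ch in enumerate(channels):
            prof = ndimage.map_coordinates(
                series.frame(t, ci), coords, order=1, mode="nearest"
            )
            ps = detect_consensus_peaks(prof, smoothing, match_tolerance, f"{ch}:{t}")
            if len(ps) < 2:
                skipped[ch].append(t)
                continue
            # the poles: outermost substantial consensus peak on each side;
            # once established, a pole is followed by proximity (poles
            # drift far less than a pixel per frame), which rides out
            # frames where the consensus list is incomplete or noisy
            largest = max(p.size for p in ps.peaks)
            strong = [p for p in ps.peaks if p.size >= 0.25 * largest]
            got_both = True
            chosen = {}
            for side, sign in (("left", -1.0), ("right", 1.0)):
                track = tracks[(ch, side)]
                cands = [p for p in strong if sign * (positions[0] + p.center) > 0]
                if track.positions:
                    last = track.positions[-1]
                    gated = [
                        p for p in cands
                        if abs(positions[0] + p.center - last) <= gate_px
                    ]
                    chosen[side] = (
                        min(gated, key=lambda p: abs(positions[0] + p.center - last))
                        if gated
                        else None
                    )
                elif cands:
                    chosen[side] = (
                        min(cands, key=lambda p: p.center)
                        if side == "left"
                        else max(cands, key=lambda p: p.center)
                    )
                else:
                    chosen[side] = None
                got_both &= chosen[side] is not None
            if not got_both:
                skipped[ch].append(t)
                continue
            for side in ("left", "right"):
                pk = chosen[side]
                pos = positions[0] + centroid(prof, pk.center, pk.width)
                tracks[(ch, side)].frames.append(t)
                tracks[(ch, side)].positions.append(pos)

    for tr in tracks.values():
        _fit_pole_velocity(tr, series.pixel_size, series.frame_interval)
    # link same-side poles across channels
    if len(channels) == 2:
        for side in ("left", "right"):
            a = tracks[(channels[0], side)]
            b = tracks[(channels[1], side)]
            a.partner, b.partner = b, a

    velocities = {ch: [tracks[(ch, s)].velocity for s in ("left", "right")] for ch in channels}
    all_v = np.array([v for vs in velocities.values() for v in vs if np.isfinite(v)])
    deltas = []
    if len(channels) == 2:
        for side in ("left", "right"):
            d = tracks[(channels[1], side)].delta_v
            if np.isfinite(d):
                deltas.append(d)

    def hist(vals):
        vals = np.asarray(vals, dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            return np.array([]), np.array([0.0, bin_width])
        vmax = max(np.abs(vals).max(), bin_width)
        n = int(np.ceil(vmax / bin_width)) + 1
        edges = np.arange(-n, n + 1) * bin_width
        counts, _ = np.histogram(vals, bins=edges)
        return counts, edges

    return {
        "tracks": list(tracks.values()),
        "velocities": velocities,
        "combined_velocities": all_v,
        "delta_v": np.array(deltas),
        "histograms": {
            **{ch: hist(velocities[ch]) for ch in channels},
            "combined": hist(all_v),
            "delta_v": hist(deltas),
        },
        "skipped_frames": skipped,
    }
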