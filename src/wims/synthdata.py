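"""Ground-truthed synthetic fluorescence movies and profiles.

No imaging data ships with this package; every analysis stage is
exercised against scenes rendered here, with exact truth tables.  A
scene contains:

* a cell: a smooth blob (disk plus low-order radial modes) whose
  boundary advances at prescribed normal velocities per angular sector
  (defaults in the 0.3-2 um/min range typical of protruding fronts);
* adhesions: oriented anisotropic Gaussian blobs (lengths of a few to
  ~20 px, widths of ~0.5-3 px).  The photometric model is deliberately a
  Gaussian, not a wavelet shape, so detection is always tested under
  model mismatch, as with real data;
* optional intra-adhesion clusters: 1-D Gaussians moving along the
  adhesion axis (0.04-1.1 um/min range), with optional scripted
  direction switches;
* optional two-channel actomyosin bundles with pole populations in both
  channels converging at scripted speeds;
* camera noise: Poisson shot noise followed by Gaussian read noise.

Axis conventions match the analysis code: orientation angles are
degrees from the +x axis with direction vector ``(cos phi, -sin phi)``;
cluster positions are signed along-axis coordinates, positive toward
the cell boundary; scripted cluster velocities are positive *away* from
the boundary.  A fixed seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .cwt import ImageSeries

__all__ = [
    "CellSpec",
    "AdhesionSpec",
    "ClusterSpec",
    "BundleSpec",
    "NoiseSpec",
    "noise_for_snr",
    "effective_peak",
    "SceneConfig",
    "simulate_movie",
    "simulate_profile",
    "scenario_library",
    "elongation_axis",
]


def um_per_min_to_px_per_frame(v: float, pixel_size: float, frame_interval: float) -> float:
    return v / pixel_size * frame_interval / 60.0


@dataclass
class CellSpec:
    """A smooth cell mask with sector-wise front velocities.

    Radius at polar angle ``phi`` (radians) and frame ``t`` is
    ``r0 + sum_k amp_k cos(k phi + phase_k) + v(phi) * t`` where
    ``v(phi)`` is the normal velocity (um/min) of the sector containing
    ``phi``.  Sectors are ``(start_deg, end_deg, v_um_min)`` triples.
    """

    center: tuple[float, float] = (64.0, 64.0)
    radius: float = 40.0
    mode_amps: tuple[float, ...] = ()
    mode_phases: tuple[float, ...] = ()
    sectors: tuple[tuple[float, float, float], ...] = ()
    edge_width: float = 1.5
    body_intensity: float = 20.0

    def radius_at(self, phi: np.ndarray, t: int, pixel_size: float, frame_interval: float):
        r = np.full_like(np.asarray(phi, dtype=float), self.radius)
        for k, (amp, ph) in enumerate(zip(self.mode_amps, self.mode_phases), start=2):
            r = r + amp * np.cos(k * phi + ph)
        deg = np.rad2deg(phi) % 360.0
        for (a0, a1, v) in self.sectors:
            vpx = um_per_min_to_px_per_frame(v, pixel_size, frame_interval)
            if a0 <= a1:
                sel = (deg >= a0) & (deg < a1)
            else:
                sel = (deg >= a0) | (deg < a1)
            r = r + np.where(sel, vpx * t, 0.0)
        return r


@dataclass
class AdhesionSpec:
    """An oriented anisotropic Gaussian blob.

    ``phi`` is the elongation-axis angle in degrees (direction
    ``(cos phi, -sin phi)``); ``sigma_par``/``sigma_perp`` are the
    standard deviations along/across that axis in pixels.  ``vx, vy``
    give an optional drift in px/frame; the blob exists on frames
    ``birth <= t < death``.
    """

    x: float
    y: float
    sigma_par: float = 3.0
    sigma_perp: float = 1.0
    phi: float = 0.0
    amplitude: float = 100.0
    birth: int = 0
    death: int | None = None
    vx: float = 0.0
    vy: float = 0.0
    id: int = -1

    def center_at(self, t: int) -> tuple[float, float]:
        return self.x + self.vx * t, self.y + self.vy * t


@dataclass
class ClusterSpec:
    """A 1-D sub-population moving along its adhesion's axis.

    ``s0`` is the signed along-axis position (px, positive toward the
    boundary) at the cluster's ``birth`` frame; ``v_away`` the velocity
    in um/min, positive away from the boundary.  An optional switch
    changes the velocity to ``v_after`` from ``switch_frame`` on.
    Amplitude may drift at ``amp_rate`` intensity units per second.  The
    cluster exists on frames ``birth <= t < death``.
    """

    s0: float
    v_away: float
    amplitude: float = 100.0
    width: float = 3.5
    amp_rate: float = 0.0
    switch_frame: int | None = None
    v_after: float | None = None
    birth: int = 0
    death: int | None = None

    def alive(self, t: int) -> bool:
        return self.birth <= t and (self.death is None or t < self.death)

    def position_at(self, t: int, pixel_size: float, frame_interval: float) -> float:
        # away-positive velocity decreases the toward-boundary coordinate s
        v1 = -um_per_min_to_px_per_frame(self.v_away, pixel_size, frame_interval)
        dt = t - self.birth
        if self.switch_frame is None or t <= self.switch_frame:
            return self.s0 + v1 * dt
        v2 = -um_per_min_to_px_per_frame(self.v_after, pixel_size, frame_interval)
        dt1 = self.switch_frame - self.birth
        return self.s0 + v1 * dt1 + v2 * (t - self.switch_frame)

    def velocity_at(self, t: int) -> float:
        if self.switch_frame is not None and t > self.switch_frame:
            return float(self.v_after)
        return float(self.v_away)

    def amplitude_at(self, t: int, frame_interval: float) -> float:
        return max(self.amplitude + self.amp_rate * (t - self.birth) * frame_interval, 0.0)


@dataclass
class BundleSpec:
    """A two-channel actomyosin bundle with converging pole populations.

    Poles sit at signed axis offsets ``+/- pole_offset`` shrinking at
    ``v_myosin`` / ``v_vinculin`` (um/min, positive toward the bundle
    center) in the respective channels.
    """

    x: float
    y: float
    phi: float = 0.0
    pole_offset: float = 15.0
    v_myosin: float = 0.02
    v_vinculin: float = 0.02
    amplitude: float = 120.0
    pole_width: float = 2.0
    body_amplitude: float = 25.0
    body_width: float = 1.2
    id: int = 0

    def pole_position(self, t: int, channel: str, pixel_size: float, frame_interval: float):
        v = self.v_myosin if channel == "myosin" else self.v_vinculin
        vpx = um_per_min_to_px_per_frame(v, pixel_size, frame_interval)
        return max(self.pole_offset - vpx * t, 1.0)


@dataclass
class NoiseSpec:
    """Poisson(gain * I)/gain shot noise followed by Gaussian read noise."""

    gaussian_sigma: float = 10.0
    poisson_gain: float = 5.0


def effective_peak(
    amplitude: float, sigma_par: float, sigma_perp: float, psf_sigma: float = 1.0
) -> float:
    """Peak intensity of a Gaussian blob after diffraction blur."""
    f1 = sigma_par / np.sqrt(sigma_par**2 + psf_sigma**2)
    f2 = sigma_perp / np.sqrt(sigma_perp**2 + psf_sigma**2)
    return amplitude * f1 * f2


def noise_for_snr(
    amplitude: float, background: float, snr: float, poisson_gain: float = 5.0
) -> NoiseSpec:
    """Noise parameters giving the stated peak SNR under the camera model.

    SNR is defined as signal amplitude over the *total* rms noise at the
    brightest pixel: shot-noise variance ``(background + amplitude) /
    gain`` plus read-noise variance.  The read noise absorbs whatever
    the shot noise does not account for (zero if shot noise alone
    already exceeds the requested level).
    """
    total_var = (amplitude / snr) ** 2
    shot_var = (background + amplitude) / poisson_gain
    read_var = max(total_var - shot_var, 0.0)
    return NoiseSpec(gaussian_sigma=float(np.sqrt(read_var)), poisson_gain=poisson_gain)


@dataclass
class SceneConfig:
    shape: tuple[int, int] = (128, 128)
    pixel_size: float = 0.105
    frame_interval: float = 5.0
    n_frames: int = 41
    background: float = 10.0
    cell: CellSpec | None = None
    adhesions: list[AdhesionSpec] = field(default_factory=list)
    clusters: dict[int, list[ClusterSpec]] = field(default_factory=dict)
    bundles: list[BundleSpec] = field(default_factory=list)
    noise: NoiseSpec | None = None
    psf_sigma: float = 1.0
    seed: int = 0
    name: str = "scene"

    def __post_init__(self) -> None:
        for i, ad in enumerate(self.adhesions):
            if ad.id < 0:
                ad.id = i
        if self.cell is not None:
            self._check_adhesions_inside()

    def _check_adhesions_inside(self) -> None:
        cx, cy = self.cell.center
        for ad in self.adhesions:
            r = np.hypot(ad.x - cx, ad.y - cy)
            r0 = self.cell.radius_at(
                np.arctan2(ad.y - cy, ad.x - cx), 0, self.pixel_size, self.frame_interval
            )
            if r > float(r0):
                raise ValueError(f"adhesion {ad.id} lies outside the initial cell mask")


def elongation_axis(a: float | None = None, xi: float | None = None, theta: float | None = None, adhesion=None) -> float:
    """Elongation-axis angle (deg, [0,180)) of a detected adhesion.

    The stretched wavelet extends along r_perp when ``xi > 1`` (axis at
    ``theta + 90``) and along r_par when ``xi < 1`` (axis at ``theta``);
    an isotropic detection has no axis (returns NaN).
    """
    if adhesion is not None:
        a, xi, theta = adhesion.a, adhesion.xi, adhesion.theta
    if xi == 1.0:
        return float("nan")
    return float(theta % 180.0) if xi < 1.0 else float((theta + 90.0) % 180.0)


def cell_mask(cfg: SceneConfig, t: int) -> np.ndarray:
    """Exact boolean cell mask at frame ``t``."""
    h, w = cfg.shape
    ys, xs = np.mgrid[0:h, 0:w]
    cx, cy = cfg.cell.center
    dx, dy = xs - cx, ys - cy
    r = np.hypot(dx, dy)
    phi = np.arctan2(dy, dx)
    return r <= cfg.cell.radius_at(phi, t, cfg.pixel_size, cfg.frame_interval)


def boundary_polyline(cfg: SceneConfig, t: int, n: int = 720) -> np.ndarray:
    """Exact boundary polyline (closed, (x, y) columns) at frame ``t``."""
    phi = np.linspace(0, 2 * np.pi, n, endpoint=False)
    r = cfg.cell.radius_at(phi, t, cfg.pixel_size, cfg.frame_interval)
    cx, cy = cfg.cell.center
    pts = np.column_stack([cx + r * np.cos(phi), cy + r * np.sin(phi)])
    return np.vstack([pts, pts[:1]])


def _outward_direction(cfg: SceneConfig, ad: AdhesionSpec) -> np.ndarray:
    """Unit vector along the adhesion axis pointing toward the boundary."""
    u = np.array([np.cos(np.deg2rad(ad.phi)), -np.sin(np.deg2rad(ad.phi))])
    if cfg.cell is not None:
        cx, cy = cfg.cell.center
        if u @ np.array([ad.x - cx, ad.y - cy]) < 0:
            u = -u
    return u


def render_frame(cfg: SceneConfig, t: int, rng: np.random.Generator | None = None) -> np.ndarray:
    """Render one frame (or one (C, H, W) array when bundles exist)."""
    h, w = cfg.shape
    ys, xs = np.mgrid[0:h, 0:w].astype(float)
    n_channels = 2 if cfg.bundles else 1
    img = np.full((n_channels, h, w), float(cfg.background))

    if cfg.cell is not None:
        cx, cy = cfg.cell.center
        dx, dy = xs - cx, ys - cy
        r = np.hypot(dx, dy)
        phi = np.arctan2(dy, dx)
        rt = cfg.cell.radius_at(phi, t, cfg.pixel_size, cfg.frame_interval)
        soft = np.clip((rt - r) / cfg.cell.edge_width + 0.5, 0.0, 1.0)
        img[0] += cfg.cell.body_intensity * soft

    for ad in cfg.adhesions:
        death = ad.death if ad.death is not None else cfg.n_frames
        if not (ad.birth <= t < death):
            continue
        axc, ayc = ad.center_at(t)
        u = _outward_direction(cfg, ad)
        dxy = np.stack([xs - axc, ys - ayc])
        s = u[0] * dxy[0] + u[1] * dxy[1]
        d_perp = -u[1] * dxy[0] + u[0] * dxy[1]
        perp = np.exp(-(d_perp**2) / (2 * ad.sigma_perp**2))
        clusters = cfg.clusters.get(ad.id)
        if clusters:
            along = np.zeros_like(s)
            for cl in clusters:
                if not cl.alive(t):
                    continue
                sc = cl.position_at(t, cfg.pixel_size, cfg.frame_interval)
                amp = cl.amplitude_at(t, cfg.frame_interval)
                along = along + amp * np.exp(-((s - sc) ** 2) / (2 * cl.width**2))
            img[0] += along * perp
        else:
            img[0] += ad.amplitude * np.exp(-(s**2) / (2 * ad.sigma_par**2)) * perp

    for b in cfg.bundles:
        u = np.array([np.cos(np.deg2rad(b.phi)), -np.sin(np.deg2rad(b.phi))])
        dxy = np.stack([xs - b.x, ys - b.y])
        s = u[0] * dxy[0] + u[1] * dxy[1]
        d_perp = -u[1] * dxy[0] + u[0] * dxy[1]
        perp = np.exp(-(d_perp**2) / (2 * b.pole_width**2))
        body_perp = np.exp(-(d_perp**2) / (2 * b.body_width**2))
        for ci, ch in enumerate(("myosin", "vinculin")):
            p = b.pole_position(t, ch, cfg.pixel_size, cfg.frame_interval)
            poles = np.exp(-((s - p) ** 2) / (2 * b.pole_width**2)) + np.exp(
                -((s + p) ** 2) / (2 * b.pole_width**2)
            )
            body = np.exp(-(s**2) / (2 * (b.pole_offset * 1.2) ** 2))
            img[ci] += b.amplitude * poles * perp + b.body_amplitude * body * body_perp

    if cfg.psf_sigma > 0:  # diffraction blur before the camera
        from scipy.ndimage import gaussian_filter

        img = gaussian_filter(img, (0, cfg.psf_sigma, cfg.psf_sigma))
    if cfg.noise is not None and rng is not None:
        if cfg.noise.poisson_gain > 0:
            img = rng.poisson(np.maximum(img, 0) * cfg.noise.poisson_gain) / cfg.noise.poisson_gain
        if cfg.noise.gaussian_sigma > 0:
            img = img + rng.normal(0.0, cfg.noise.gaussian_sigma, img.shape)
    return np.maximum(img, 0.0)


def simulate_movie(cfg: SceneConfig) -> tuple[ImageSeries, dict]:
    """Render a scene and return the series plus exact truth tables.

    Truth tables (pandas DataFrames): ``adhesions`` (per frame and id:
    center, axis angle, sigmas, amplitude), ``clusters`` (per frame:
    signed axis position, current away-positive velocity, amplitude),
    ``boundary`` (per frame polyline vertices), ``bundles`` (per frame
    and channel: pole positions and scripted velocities).
    """
    rng = np.random.default_rng(cfg.seed)
    frames = np.stack([render_frame(cfg, t, rng) for t in range(cfg.n_frames)])
    channels = ("myosin", "vinculin") if cfg.bundles else ("ch0",)
    series = ImageSeries(frames, cfg.pixel_size, cfg.frame_interval, channels)

    adh_rows, cluster_rows, boundary_rows, bundle_rows = [], [], [], []
    for t in range(cfg.n_frames):
        for ad in cfg.adhesions:
            death = ad.death if ad.death is not None else cfg.n_frames
            if not (ad.birth <= t < death):
                continue
            x, y = ad.center_at(t)
            adh_rows.append(
                {"frame": t, "id": ad.id, "x": x, "y": y, "phi": ad.phi % 180.0,
                 "sigma_par": ad.sigma_par, "sigma_perp": ad.sigma_perp,
                 "amplitude": ad.amplitude}
            )
            for k, cl in enumerate(cfg.clusters.get(ad.id, [])):
                if not cl.alive(t):
                    continue
                cluster_rows.append(
                    {"frame": t, "adhesion_id": ad.id, "cluster_id": k,
                     "s_px": cl.position_at(t, cfg.pixel_size, cfg.frame_interval),
                     "v_away_um_min": cl.velocity_at(t),
                     "amplitude": cl.amplitude_at(t, cfg.frame_interval)}
                )
        if cfg.cell is not None:
            poly = boundary_polyline(cfg, t, n=360)
            boundary_rows.append({"frame": t, "x": poly[:, 0], "y": poly[:, 1]})
        for b in cfg.bundles:
            for ch in ("myosin", "vinculin"):
                v = b.v_myosin if ch == "myosin" else b.v_vinculin
                bundle_rows.append(
                    {"frame": t, "bundle_id": b.id, "channel": ch,
                     "pole_offset_px": b.pole_position(t, ch, cfg.pixel_size, cfg.frame_interval),
                     "v_toward_center_um_min": v}
                )
    truth = {
        "adhesions": pd.DataFrame(adh_rows),
        "clusters": pd.DataFrame(cluster_rows),
        "boundary": pd.DataFrame(boundary_rows),
        "bundles": pd.DataFrame(bundle_rows),
        "config": cfg,
    }
    return series, truth


def simulate_profile(
    positions: np.ndarray,
    n_frames: int,
    a0: float,
    clusters: Sequence[ClusterSpec],
    pixel_size: float = 0.105,
    frame_interval: float = 5.0,
    noise: NoiseSpec | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Forward-generate a two-Gaussian-style space-time profile plus truth."""
    rng = np.random.default_rng(seed)
    x = np.asarray(positions, dtype=float)
    out = np.empty((n_frames, len(x)))
    rows = []
    for t in range(n_frames):
        y = np.full_like(x, float(a0))
        for k, cl in enumerate(clusters):
            if not cl.alive(t):
                continue
            sc = cl.position_at(t, pixel_size, frame_interval)
            amp = cl.amplitude_at(t, frame_interval)
            y = y + amp * np.exp(-((x - sc) ** 2) / (2 * cl.width**2))
            rows.append(
                {"frame": t, "cluster_id": k, "beta_px": sc, "amplitude": amp,
                 "width": cl.width, "v_away_um_min": cl.velocity_at(t)}
            )
        if noise is not None:
            if noise.poisson_gain > 0:
                y = rng.poisson(np.maximum(y, 0) * noise.poisson_gain) / noise.poisson_gain
            if noise.gaussian_sigma > 0:
                y = y + rng.normal(0, noise.gaussian_sigma, y.shape)
        out[t] = y
    return out, pd.DataFrame(rows)


def _category_clusters(category: str) -> list[ClusterSpec]:
    """Scripted cluster sets realizing each of the ten taxonomy categories.

    Positions stay within the profile reach of the standard category
    scene (boundary ~18 px from the adhesion center); concurrent peaks
    are kept >= ~7 px apart so the two-Gaussian fits resolve them, and
    "three peak" patterns unfold as successions (at most two peaks
    coexist, matching the mixture window).  Colliding pairs stop at the
    meeting point; the switch case resumes away from the boundary.
    """
    v = 0.45  # um/min, a typical intra-adhesion speed
    table = {
        # approach from both sides, meet mid-window and stall; narrow
        # enough that the approach stays resolvable for many frames
        "A": [
            ClusterSpec(s0=10.0, v_away=0.6, width=2.5, switch_frame=21, v_after=0.0),
            ClusterSpec(s0=-10.0, v_away=-0.6, width=2.5, switch_frame=21, v_after=0.0),
        ],
        "B": [ClusterSpec(s0=10.0, v_away=v)],
        "C": [ClusterSpec(s0=2.0, v_away=0.5), ClusterSpec(s0=13.0, v_away=v)],
        # three peaks translating away, appearing in succession; each new
        # peak nucleates near the boundary, well away from its dying
        # predecessor, so tracks never bridge across the hand-over
        "D": [
            ClusterSpec(s0=12.0, v_away=0.55, birth=0, death=15),
            ClusterSpec(s0=12.0, v_away=0.55, birth=16, death=29),
            ClusterSpec(s0=12.0, v_away=0.55, birth=30, death=41),
        ],
        "E": [ClusterSpec(s0=10.0, v_away=0.0), ClusterSpec(s0=-3.0, v_away=v)],
        "F": [ClusterSpec(s0=-12.0, v_away=0.0), ClusterSpec(s0=-1.0, v_away=-v)],
        "G": [ClusterSpec(s0=2.0, v_away=0.0)],
        "H": [ClusterSpec(s0=6.0, v_away=0.0), ClusterSpec(s0=-6.0, v_away=0.0)],
        # inbound peak collides at ~frame 15 and switches to move away;
        # narrower clusters keep the approach resolvable until they meet
        "I": [
            ClusterSpec(s0=13.0, v_away=0.8, width=2.5),
            ClusterSpec(s0=-12.0, v_away=-0.8, width=2.5, switch_frame=20, v_after=0.3),
        ],
        # one stationary peak with two peaks translating away in succession
        "J": [
            ClusterSpec(s0=-10.0, v_away=0.0),
            ClusterSpec(s0=12.0, v_away=0.55, birth=0, death=19),
            ClusterSpec(s0=12.0, v_away=0.55, birth=20, death=41),
        ],
    }
    return table[category]


def scenario_library(seed: int = 0, snr: float = 10.0) -> dict[str, SceneConfig]:
    """Named, fully scripted scenes covering every analysis stage.

    One scene per internal-dynamics category A-J, a wild-type-like
    bundle (pole speeds ~0.02 um/min), a mutant-like bundle (~0.1
    um/min with the vinculin pole twice as fast as myosin), and a
    whole-cell protrusion/retraction scene.  ``snr`` sets the adhesion
    amplitude to read-noise ratio.
    """
    amp = 100.0
    noise = noise_for_snr(effective_peak(amp, 8.0, 1.5), 15.0, snr)
    lib: dict[str, SceneConfig] = {}

    for cat in "ABCDEFGHIJ":
        clusters = _category_clusters(cat)
        cell = CellSpec(center=(48.0, 48.0), radius=40.0, body_intensity=15.0)
        ad = AdhesionSpec(x=70.0, y=48.0, sigma_par=8.0, sigma_perp=1.5, phi=0.0,
                          amplitude=amp, id=0)
        lib[f"category_{cat}"] = SceneConfig(
            shape=(96, 96), n_frames=41, cell=cell, adhesions=[ad],
            clusters={0: clusters},
            noise=noise, seed=seed, name=f"category_{cat}",
        )

    for name, vm, vv in (("bundle_wildtype", 0.02, 0.02), ("bundle_mutant", 0.065, 0.13)):
        b = BundleSpec(x=48.0, y=48.0, phi=25.0, pole_offset=16.0,
                       v_myosin=vm, v_vinculin=vv, amplitude=150.0)
        lib[name] = SceneConfig(
            shape=(96, 96), n_frames=61, cell=None, bundles=[b],
            noise=noise_for_snr(effective_peak(150.0, 2.0, 2.0), 10.0, snr),
            seed=seed, name=name,
        )

    cell = CellSpec(
        center=(64.0, 64.0), radius=30.0, mode_amps=(2.0,), mode_phases=(0.4,),
        sectors=((300.0, 60.0, 1.8), (120.0, 200.0, 0.9)), body_intensity=20.0,
    )
    rng = np.random.default_rng(seed)
    adhesions = []
    for i in range(8):
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(8.0, 22.0)
        adhesions.append(
            AdhesionSpec(
                x=64.0 + rad * np.cos(ang), y=64.0 + rad * np.sin(ang),
                sigma_par=rng.uniform(2.5, 5.0), sigma_perp=rng.uniform(0.8, 1.5),
                phi=float(np.rad2deg(-ang) % 180.0),  # roughly radial
                amplitude=amp, id=i,
            )
        )
    lib["protrusion"] = SceneConfig(
        shape=(128, 128), n_frames=21, cell=cell, adhesions=adhesions,
        noise=noise, seed=seed, name="protrusion",
    )

    lib["growing_disk"] = SceneConfig(
        shape=(160, 160), n_frames=11,
        cell=CellSpec(center=(80.0, 80.0), radius=40.0,
                      sectors=((0.0, 360.0, 1.26),),  # exactly 1 px / 5 s frame
                      body_intensity=60.0),
        noise=None, seed=seed, name="growing_disk",
    )
    return lib


def detection_scene(
    n_adhesions: int = 20,
    shape: tuple[int, int] = (176, 176),
    snr: float = 10.0,
    seed: int = 0,
    drift: float = 0.0,
    n_frames: int = 1,
) -> SceneConfig:
    """A frame of well-separated oriented adhesions for detection/tracking tests.

    Adhesion lengths span the realistic 4-20 px range (sigma_par 1.5-5),
    widths 0.5-1.5 px sigma; placement enforces a center spacing
    compatible with non-overlapping footprints.  ``drift`` adds a random
    per-adhesion velocity (px/frame) for tracking scenarios.
    """
    rng = np.random.default_rng(seed)
    amp = 100.0
    h, w = shape
    margin = 18.0
    centers: list[tuple[float, float]] = []
    adhesions: list[AdhesionSpec] = []
    attempts = 0
    while len(adhesions) < n_adhesions and attempts < 20000:
        attempts += 1
        x = rng.uniform(margin, w - margin)
        y = rng.uniform(margin, h - margin)
        if any(np.hypot(x - cx, y - cy) < 24.0 for cx, cy in centers):
            continue
        sp = rng.uniform(2.5, 5.0)
        adhesions.append(
            AdhesionSpec(
                x=x, y=y, sigma_par=sp, sigma_perp=rng.uniform(0.6, 1.1),
                phi=rng.uniform(0.0, 180.0), amplitude=amp * rng.uniform(0.7, 1.0),
                vx=rng.uniform(-drift, drift), vy=rng.uniform(-drift, drift),
                id=len(adhesions),
            )
        )
        centers.append((x, y))
    if len(adhesions) < n_adhesions:
        raise RuntimeError("could not place the requested number of adhesions")
    eff = float(np.median([
        effective_peak(ad.amplitude, ad.sigma_par, ad.sigma_perp) for ad in adhesions
    ]))
    return SceneConfig(
        shape=shape, n_frames=n_frames, cell=None, adhesions=adhesions,
        noise=noise_for_snr(eff, 10.0, snr),
        seed=seed, name="detection",
    )
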