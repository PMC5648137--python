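"""TIFF input, run configuration and the end-to-end analysis pipeline.

The pipeline runs transform → adhesion detection → boundary extraction →
region decomposition → frame linking → intra-adhesion dynamics (and
two-channel pole analysis when a second channel is present), writing CSV
tables and a JSON summary.  Every output is deterministic given the
configuration and seed; each table carries the configuration hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import detect, dynamics, morphology, track
from .cwt import ImageSeries, MeshConfig
from .synthdata import elongation_axis

logger = logging.getLogger("wims")

__all__ = ["RunConfig", "read_series", "write_series", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    """All knobs of the end-to-end pipeline with their standard defaults.

    Defaults follow the method's stated values where it states them: the
    10% retention threshold for wavelet maxima, the a = 20..200 step 4
    boundary band, the 10-degree linking tolerance, the +/- 20 frame
    dynamics window, 0.105 um/pixel and 5 s/frame calibration.
    """

    pixel_size: float = 0.105  # um per pixel
    frame_interval: float = 5.0  # seconds
    scales: tuple = tuple(range(4, 21))
    xis: tuple = (0.5, 1.0, 1.5)
    n_thetas: int = 180
    threshold_fraction: float = 0.10
    boundary_scales: tuple = tuple(range(20, 201, 4))
    boundary_threshold: str | float = "otsu"
    link_max_angle: float = 10.0
    ellipse_convention: str = "scaled"
    dynamics_window: int = 20
    v_stationary: float = 0.05  # um/min
    collision_distance: float = 2.0  # px
    consensus_tolerance: float = 2.0  # px
    refine_below: float = 4.0
    coarsen_above: float = 16.0
    truncation: float = 4.0
    seed: int = 0
    channels: tuple = ("ch0",)

    def mesh_config(self) -> MeshConfig:
        return MeshConfig(
            refine_below=self.refine_below,
            coarsen_above=self.coarsen_above,
            truncation=self.truncation,
        )

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path) -> RunConfig:
    """Read a RunConfig from TOML (preferred) or YAML."""
    path = Path(path)
    if path.suffix in (".yml", ".yaml"):
        import yaml

        data = yaml.safe_load(path.read_text())
    else:
        import tomllib

        data = tomllib.loads(path.read_text())
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("scales", "xis", "boundary_scales", "channels"):
        if key in data:
            data[key] = tuple(data[key])
    return RunConfig(**data)


def read_series(
    paths,
    pixel_size: float = 0.105,
    frame_interval: float = 5.0,
    channels: tuple | None = None,
) -> ImageSeries:
    """Read one TIFF stack (T, H, W) or several aligned single-channel stacks.

    Calibration comes from the arguments (configuration overrides any
    file metadata; a notice is logged when both are present).
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    stacks = []
    for p in paths:
        with tifffile.TiffFile(str(p)) as tf:
            arr = tf.asarray()
            if tf.pages[0].tags.get("XResolution") is not None:
                logger.info(
                    "%s carries resolution metadata; using configured "
                    "pixel size %.4f um instead", p, pixel_size,
                )
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise ValueError(f"{p}: expected a (T, H, W) stack, got shape {arr.shape}")
        stacks.append(arr.astype(float))
    shapes = {s.shape for s in stacks}
    if len({s[1:] for s in shapes}) > 1 or len({s[0] for s in shapes}) > 1:
        raise ValueError(
            "channel stacks disagree in shape: "
            + ", ".join(f"{p}: {s.shape}" for p, s in zip(paths, stacks))
        )
    data = np.stack(stacks, axis=1)  # (T, C, H, W)
    if channels is None:
        channels = tuple(f"ch{i}" for i in range(data.shape[1]))
    return ImageSeries(data, pixel_size, frame_interval, channels)


def write_series(path, series: ImageSeries) -> None:
    data = series.data
    if data.shape[1] == 1:
        data = data[:, 0]
    tifffile.imwrite(str(path), data.astype(np.float32), photometric="minisblack")


def _adhesion_table(per_frame, pixel_size: float, cfg_hash: str) -> pd.DataFrame:
    rows = []
    for ads in per_frame:
        for ad in ads:
            rows.append(
                {
                    "frame": ad.frame, "id": ad.id, "x": ad.x, "y": ad.y,
                    "a_px": ad.a, "a_um": ad.a * pixel_size, "xi": ad.xi,
                    "theta_deg": ad.theta,
                    "axis_deg": elongation_axis(adhesion=ad),
                    "coefficient": ad.coefficient, "config": cfg_hash,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(
    series: ImageSeries,
    config: RunConfig | None = None,
    out_dir=None,
) -> dict:
    """Run the full analysis on a calibrated series.

    Returns a result bundle of DataFrames and objects; when ``out_dir``
    is given, CSV/JSON artifacts are written there.  Stages log their
    progress; a failure aborts with the stage name after persisting what
    completed.
    """
    cfg = config or RunConfig()
    cfg_hash = cfg.hash()
    mesh = cfg.mesh_config()
    out = {"config": cfg, "config_hash": cfg_hash}
    stage = "detect"
    try:
        per_frame = []
        for t in range(series.n_frames):
            ads = detect.detect_adhesions(
                series.frame(t), scales=cfg.scales, xis=cfg.xis,
                thetas=cfg.n_thetas, threshold_fraction=cfg.threshold_fraction,
                mesh_config=mesh, frame=t, convention=cfg.ellipse_convention,
            )
            per_frame.append(ads)
            logger.info("frame %d: %d adhesions", t, len(ads))
        out["adhesions"] = _adhesion_table(per_frame, series.pixel_size, cfg_hash)

        stage = "boundary"
        contours, masks = [], []
        for t in range(series.n_frames):
            c, m, _ = morphology.extract_boundary(
                series.frame(t), scales=cfg.boundary_scales,
                threshold_rule=cfg.boundary_threshold, mesh_config=mesh,
                frame_index=t,
            )
            contours.append(c)
            masks.append(m)

        stage = "regions"
        decomps = [
            morphology.decompose_regions(masks[i], masks[i + 1], i, i + 1)
            for i in range(len(masks) - 1)
        ]
        front = {
            label: morphology.front_metrics(
                decomps, series.pixel_size, series.frame_interval, label
            )
            for label in ("protruding", "retracting")
        }
        out["front_metrics"] = front

        stage = "track"
        tracks, counts = track.build_tracks(
            per_frame, max_angle=cfg.link_max_angle, convention=cfg.ellipse_convention
        )
        out["tracks"] = tracks
        out["adhesion_counts"] = pd.DataFrame(
            {"frame": np.arange(series.n_frames), "n_adhesions": counts,
             "config": cfg_hash}
        )

        stage = "dynamics"
        mid = series.n_frames // 2
        mid_dec = decomps[min(mid, len(decomps) - 1)] if decomps else None
        records = []
        for ad in per_frame[mid] if per_frame else []:
            try:
                prof = dynamics.extract_profile(
                    series, ad, contours[mid], contours_per_frame=contours,
                    window=cfg.dynamics_window,
                )
            except ValueError:
                continue
            fits = [
                dynamics.fit_two_gaussians(prof.positions, prof.intensities[k], frame=int(t))
                for k, t in enumerate(prof.frames)
            ]
            trajs = dynamics.build_trajectories(fits)
            cls = dynamics.classify_dynamics(
                trajs, series.pixel_size, series.frame_interval,
                cfg.v_stationary, cfg.collision_distance,
            )
            region = (
                morphology.assign_region(ad, mid_dec, series.pixel_size)
                if mid_dec is not None
                else "central"
            )
            for v in cls["velocities"]:
                records.append(
                    {"adhesion_id": ad.id, "region": region,
                     "category": cls["category"], "velocity": v,
                     "config": cfg_hash}
                )
        out["dynamics"] = pd.DataFrame(records)
        if records:
            out["velocity_histograms"] = dynamics.regional_velocity_histograms(records)

        if series.data.shape[1] >= 2:
            stage = "poles"
            from .peaks import pole_analysis

            bundles = per_frame[0][:1] if per_frame and per_frame[0] else []
            out["poles"] = [
                pole_analysis(series, b, match_tolerance=cfg.consensus_tolerance)
                for b in bundles
            ]
        else:
            logger.info("single-channel input: pole analysis skipped")
    except Exception as err:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {err}") from err

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        out["adhesions"].to_csv(out_dir / "adhesions.csv", index=False)
        out["adhesion_counts"].to_csv(out_dir / "adhesion_counts.csv", index=False)
        if isinstance(out.get("dynamics"), pd.DataFrame):
            out["dynamics"].to_csv(out_dir / "dynamics.csv", index=False)
        for label in ("protruding", "retracting"):
            front[label]["table"].to_csv(out_dir / f"front_{label}.csv", index=False)
        summary = {
            "config_hash": cfg_hash,
            "n_frames": int(series.n_frames),
            "n_tracks": len(out.get("tracks", [])),
            "adhesion_counts": [int(c) for c in counts],
            "front_velocity_um_per_min": {
                label: front[label]["front_velocity_um_per_min"] for label in front
            },
        }
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    return out
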