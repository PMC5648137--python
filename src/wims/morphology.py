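"""Cell-boundary extraction and protrusion/retraction kinematics.

The cell outline lives at coarse scales: a band-limited reconstruction
from large-scale Mexican-hat coefficients (default band a = 20..200,
step 4) smooths away adhesions and noise, and thresholding it (Otsu by
default) yields the cell mask.  The boundary is recovered as a
sub-pixel marching-squares contour at the threshold level; its accuracy
is bounded by the smallest scale in the band.

Between two frames the plane decomposes into protruded (entered),
retracted (vacated) and stable (occupied in both) regions, and the
contour splits into protruding/retracting/stable front segments.  Front
kinematics (arc length, swept area, normal advance velocity) and
adhesion-to-boundary geometry (distance, angle to the local tangent)
are computed from these pieces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu

from .cwt import MeshConfig, band_reconstruction
from .detect import Adhesion

__all__ = [
    "BoundaryContour",
    "FrontSegment",
    "RegionDecomposition",
    "extract_boundary",
    "mask_boundary_contour",
    "decompose_regions",
    "front_metrics",
    "adhesion_boundary_geometry",
    "assign_region",
]

DEFAULT_BOUNDARY_SCALES = tuple(range(20, 201, 4))


@dataclass
class BoundaryContour:
    """A closed, sub-pixel cell outline in original pixel coordinates.

    ``vertices`` has shape ``(n, 2)`` with columns ``(x, y)``; the first
    and last vertex coincide.
    """

    vertices: np.ndarray
    frame: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if len(v) and not np.allclose(v[0], v[-1]):
            v = np.vstack([v, v[0]])
        self.vertices = v

    @property
    def enclosed_area(self) -> float:
        """Shoelace area in pixels^2 (absolute value)."""
        v = self.vertices
        if len(v) < 4:
            return 0.0
        x, y = v[:, 0], v[:, 1]
        return float(abs(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1])) / 2.0)

    @property
    def arc_length(self) -> float:
        """Perimeter in pixels."""
        d = np.diff(self.vertices, axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())


@dataclass
class FrontSegment:
    """A labeled piece of a cell contour."""

    label: str  # protruding | retracting | stable
    vertices: np.ndarray  # (n, 2) as (x, y)

    @property
    def arc_length(self) -> float:
        if len(self.vertices) < 2:
            return 0.0
        d = np.diff(self.vertices, axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())


@dataclass
class RegionDecomposition:
    """Protruded / retracted / stable decomposition between two frames."""

    protruded_mask: np.ndarray
    retracted_mask: np.ndarray
    stable_mask: np.ndarray
    front_segments: list[FrontSegment]
    t0: int = 0
    t1: int = 1
    contour_t0: BoundaryContour | None = None
    contour_t1: BoundaryContour | None = None


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask)
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def _contour_xy(rc: np.ndarray) -> np.ndarray:
    """find_contours (row, col) vertices -> (x, y) columns."""
    return rc[:, ::-1].copy()


def extract_boundary(
    frame: np.ndarray,
    scales: Sequence[float] = DEFAULT_BOUNDARY_SCALES,
    threshold_rule: str | float = "otsu",
    mesh_config: MeshConfig | None = None,
    frame_index: int = 0,
) -> tuple[BoundaryContour | None, np.ndarray, np.ndarray]:
    """Extract the cell boundary from a coarse-scale reconstruction.

    ``threshold_rule`` is ``"otsu"`` or a fraction of the reconstruction
    maximum.  Returns ``(contour, mask, reconstruction)``; the contour is
    the sub-pixel outline of the largest foreground component, or None
    (with an all-false mask) when there is no foreground.
    """
    frame = np.asarray(frame, dtype=float)
    recon = band_reconstruction(frame, scales, "mexican_hat", mesh_config)
    lo, hi = float(recon.min()), float(recon.max())
    if hi <= lo:
        return None, np.zeros(frame.shape, dtype=bool), recon
    if threshold_rule == "otsu":
        thr = float(threshold_otsu(recon))
    else:
        thr = lo + float(threshold_rule) * (hi - lo)
    mask = _largest_component(recon >= thr)
    if not mask.any():
        return None, mask, recon
    # sub-pixel contour at the threshold level, restricted to the kept component
    contours = measure.find_contours(recon, thr)
    best, best_score = None, -1.0
    for rc in contours:
        mid = rc[len(rc) // 2]
        iy, ix = int(round(mid[0])), int(round(mid[1]))
        iy = np.clip(iy, 0, mask.shape[0] - 1)
        ix = np.clip(ix, 0, mask.shape[1] - 1)
        region = mask[
            max(0, iy - 1) : iy + 2, max(0, ix - 1) : ix + 2
        ]
        if not region.any():
            continue
        c = BoundaryContour(_contour_xy(rc), frame=frame_index)
        if c.enclosed_area > best_score:
            best, best_score = c, c.enclosed_area
    if best is None:  # fall back to the mask outline
        best = mask_boundary_contour(mask, frame_index)
    return best, mask, recon


def mask_boundary_contour(mask: np.ndarray, frame_index: int = 0) -> BoundaryContour | None:
    """Sub-pixel outline of a binary mask (marching squares at 0.5)."""
    if not mask.any():
        return None
    mask = _largest_component(mask)
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        return None
    best = max(
        (BoundaryContour(_contour_xy(rc), frame=frame_index) for rc in contours),
        key=lambda c: c.enclosed_area,
    )
    return best


def _label_contour(
    contour: BoundaryContour, change_mask: np.ndarray, label: str, other: str = "stable"
) -> list[FrontSegment]:
    """Split a contour into runs adjacent / not adjacent to changed pixels."""
    if contour is None or len(contour.vertices) < 2:
        return []
    grown = ndimage.binary_dilation(change_mask, iterations=2)
    v = contour.vertices
    iy = np.clip(np.round(v[:, 1]).astype(int), 0, change_mask.shape[0] - 1)
    ix = np.clip(np.round(v[:, 0]).astype(int), 0, change_mask.shape[1] - 1)
    near = grown[iy, ix]
    segments: list[FrontSegment] = []
    start = 0
    for i in range(1, len(v) + 1):
        if i == len(v) or near[i] != near[start]:
            seg_label = label if near[start] else other
            segments.append(FrontSegment(seg_label, v[start:i].copy()))
            start = i
            if i == len(v):
                break
    return segments


def decompose_regions(
    mask_t0: np.ndarray,
    mask_t1: np.ndarray,
    t0: int = 0,
    t1: int = 1,
) -> RegionDecomposition:
    """Split two cell masks into protruded, retracted and stable regions.

    Set identities hold exactly: ``stable | protruded == mask_t1`` and
    ``stable | retracted == mask_t0``; the three masks are pairwise
    disjoint.  Contour pieces of the later frame adjacent to protruded
    pixels are labeled protruding; pieces of the earlier frame adjacent
    to retracted pixels are labeled retracting.
    """
    m0 = np.asarray(mask_t0, dtype=bool)
    m1 = np.asarray(mask_t1, dtype=bool)
    if m0.shape != m1.shape:
        raise ValueError("masks must have the same shape")
    protruded = m1 & ~m0
    retracted = m0 & ~m1
    stable = m0 & m1
    c0 = mask_boundary_contour(m0, frame_index=t0)
    c1 = mask_boundary_contour(m1, frame_index=t1)
    segments = _label_contour(c1, protruded, "protruding")
    segments += [
        s for s in _label_contour(c0, retracted, "retracting") if s.label == "retracting"
    ]
    return RegionDecomposition(
        protruded_mask=protruded,
        retracted_mask=retracted,
        stable_mask=stable,
        front_segments=segments,
        t0=t0,
        t1=t1,
        contour_t0=c0,
        contour_t1=c1,
    )


def _polyline_min_distance(point: np.ndarray, vertices: np.ndarray) -> tuple[float, int]:
    """Min distance from a point to a polyline; returns (distance, nearest vertex index)."""
    v = vertices
    if len(v) == 1:
        return float(np.hypot(*(point - v[0]))), 0
    a, b = v[:-1], v[1:]
    ab = b - a
    ap = point[None, :] - a
    denom = (ab * ab).sum(axis=1)
    t = np.zeros(len(a))
    np.divide((ap * ab).sum(axis=1), denom, out=t, where=denom > 0)
    t = np.clip(t, 0.0, 1.0)
    proj = a + t[:, None] * ab
    d = np.hypot(*(point[None, :] - proj).T)
    i = int(np.argmin(d))
    vi = i if np.hypot(*(point - v[i])) <= np.hypot(*(point - v[i + 1])) else i + 1
    return float(d[i]), vi


def front_metrics(
    decompositions: Sequence[RegionDecomposition],
    pixel_size: float = 0.105,
    frame_interval: float = 5.0,
    label: str = "protruding",
):
    """Front kinematics time series for one region label.

    For each frame pair: total arc length (um) of fronts with ``label``,
    the newly swept area (um^2, cumulative in the output) and the mean
    normal advance of the front (nearest-point distance between the
    consecutive contours, averaged along the labeled front).  The front
    velocity (um/min) is the least-squares slope of cumulative advance
    versus time, with its standard error.
    """
    import pandas as pd
    from scipy import stats

    rows = []
    cum_area = 0.0
    cum_disp = 0.0
    for dec in decompositions:
        segs = [s for s in dec.front_segments if s.label == label]
        arc = sum(s.arc_length for s in segs) * pixel_size
        change = dec.protruded_mask if label == "protruding" else dec.retracted_mask
        cum_area += float(change.sum()) * pixel_size**2
        ref = dec.contour_t0 if label == "protruding" else dec.contour_t1
        disp = 0.0
        if ref is not None and segs:
            pts = np.vstack([s.vertices for s in segs])
            if len(pts) > 200:  # subsample long fronts for speed
                pts = pts[:: max(1, len(pts) // 200)]
            dists = [_polyline_min_distance(p, ref.vertices)[0] for p in pts]
            disp = float(np.mean(dists))
        cum_disp += disp
        rows.append(
            {
                "t0": dec.t0,
                "t1": dec.t1,
                "time_s": dec.t1 * frame_interval,
                "arc_length_um": arc,
                "swept_area_um2": cum_area,
                "front_advance_um": disp * pixel_size,
                "cum_advance_um": cum_disp * pixel_size,
            }
        )
    table = pd.DataFrame(rows)
    velocity = np.nan
    stderr = np.nan
    if len(table) >= 2:
        fit = stats.linregress(table["time_s"], table["cum_advance_um"])
        velocity = fit.slope * 60.0  # um/s -> um/min
        stderr = fit.stderr * 60.0 if fit.stderr is not None else np.nan
    return {"table": table, "front_velocity_um_per_min": velocity, "velocity_stderr": stderr}


def adhesion_boundary_geometry(
    adhesion: Adhesion,
    contour: BoundaryContour,
    pixel_size: float = 0.105,
    tangent_window: int = 5,
) -> dict:
    """Distance (um) and angle (deg, folded to [0, 90]) to the nearest boundary.

    The local tangent is a least-squares line through the contour
    vertices within ``tangent_window`` of the nearest point; the
    adhesion's orientation is axial, so the angle between it and the
    tangent is folded into [0, 90].
    """
    if contour is None or len(contour.vertices) < 2:
        raise ValueError("contour is empty")
    p = np.array([adhesion.x, adhesion.y], dtype=float)
    dist, vi = _polyline_min_distance(p, contour.vertices)
    v = contour.vertices[:-1] if len(contour.vertices) > 2 else contour.vertices
    n = len(v)
    idx = (np.arange(vi - tangent_window, vi + tangent_window + 1)) % n
    pts = v[idx]
    centered = pts - pts.mean(axis=0)
    # principal direction of the local vertex cloud = tangent
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    tangent = vt[0]
    tangent_angle = np.rad2deg(np.arctan2(-tangent[1], tangent[0])) % 180.0
    diff = abs(adhesion.theta - tangent_angle) % 180.0
    angle = min(diff, 180.0 - diff)
    angle = min(angle, 180.0 - angle) if angle > 90.0 else angle
    return {
        "distance_um": dist * pixel_size,
        "distance_px": dist,
        "tangent_angle_deg": float(angle),
        "nearest_vertex": int(vi),
    }


def assign_region(
    adhesion: Adhesion,
    decomposition: RegionDecomposition,
    pixel_size: float = 0.105,
    centrality_distance_um: float = 4.0,
    tie_tolerance_px: float = 2.0,
) -> str:
    """Classify an adhesion as protruding / retracting / central / intersecting.

    Central means at least ``centrality_distance_um`` from the cell
    boundary; otherwise the label of the nearest labeled front segment
    wins, with near-equidistant protruding and retracting fronts
    (within ``tie_tolerance_px``) classed as intersecting.
    """
    p = np.array([adhesion.x, adhesion.y], dtype=float)
    d_all = np.inf
    for c in (decomposition.contour_t1, decomposition.contour_t0):
        if c is not None and len(c.vertices) >= 2:
            d_all = min(d_all, _polyline_min_distance(p, c.vertices)[0])
    if d_all * pixel_size >= centrality_distance_um:
        return "central"
    d = {"protruding": np.inf, "retracting": np.inf}
    for seg in decomposition.front_segments:
        if seg.label in d and len(seg.vertices):
            d[seg.label] = min(d[seg.label], _polyline_min_distance(p, seg.vertices)[0])
    dp, dr = d["protruding"], d["retracting"]
    if not np.isfinite(dp) and not np.isfinite(dr):
        return "central"
    if abs(dp - dr) <= tie_tolerance_px:
        return "intersecting"
    return "protruding" if dp < dr else "retracting"
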