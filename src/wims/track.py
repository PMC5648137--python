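"""Frame-to-frame linking of detected adhesions into tracks.

Adhesions in consecutive frames are the same object when the later one
falls inside the elliptical search region of the earlier one (the
earlier adhesion's own footprint ellipse) and their orientations agree
axially to within 10 degrees.  Brighter adhesions claim candidates
first, each candidate is claimed at most once, and a track ends the
first frame it goes unmatched (no gap closing by default; a one-frame
gap tolerance is available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .detect import Adhesion, _conic_matrix, ellipse_axes

__all__ = ["AdhesionTrack", "axial_difference", "link_frames", "build_tracks"]


def axial_difference(theta1: float, theta2: float) -> float:
    """Smallest angle between two axial orientations (degrees, in [0, 90]).

    Orientations are lines, not vectors: 178 deg and 2 deg differ by 4.
    """
    d = abs(theta1 - theta2) % 180.0
    return min(d, 180.0 - d)


@dataclass
class AdhesionTrack:
    """A frame-linked adhesion lifetime."""

    track_id: int
    adhesions: list[Adhesion] = field(default_factory=list)

    @property
    def first_frame(self) -> int:
        return self.adhesions[0].frame

    @property
    def last_frame(self) -> int:
        return self.adhesions[-1].frame

    @property
    def lifetime_frames(self) -> int:
        return self.last_frame - self.first_frame + 1

    def translational_velocity(
        self, pixel_size: float = 0.105, frame_interval: float = 5.0
    ) -> tuple[float, float]:
        """Linear-fit drift of the center, as (vx, vy) in um/min."""
        if len(self.adhesions) < 2:
            return 0.0, 0.0
        t = np.array([a.frame for a in self.adhesions], dtype=float)
        x = np.array([a.x for a in self.adhesions])
        y = np.array([a.y for a in self.adhesions])
        scale = pixel_size * 60.0 / frame_interval
        vx = np.polyfit(t, x, 1)[0] * scale
        vy = np.polyfit(t, y, 1)[0] * scale
        return float(vx), float(vy)

    def speed(self, pixel_size: float = 0.105, frame_interval: float = 5.0) -> float:
        vx, vy = self.translational_velocity(pixel_size, frame_interval)
        return float(np.hypot(vx, vy))


def _inside_ellipse(source: Adhesion, candidate: Adhesion, convention: str) -> bool:
    p, q = ellipse_axes(source.a, source.xi, convention)
    a = _conic_matrix(source.x, source.y, p, q, source.theta)
    v = np.array([candidate.x, candidate.y, 1.0])
    return float(v @ a @ v) <= 0.0


def link_frames(
    adhesions_t: Sequence[Adhesion],
    adhesions_t1: Sequence[Adhesion],
    max_angle: float = 10.0,
    convention: str = "scaled",
) -> dict[int, int]:
    """Match adhesions of frame t to frame t+1.

    Iterates frame-t adhesions in descending coefficient order; each
    claims the highest-coefficient unclaimed frame-t+1 adhesion lying
    inside its own footprint ellipse with axial orientation difference
    at most ``max_angle`` degrees.  Ties between equal-coefficient
    candidates go to the nearest center, then the lower index.  Returns
    ``{index_in_t: index_in_t1}``; matching is injective.
    """
    order = sorted(
        range(len(adhesions_t)),
        key=lambda i: (-adhesions_t[i].coefficient, adhesions_t[i].y, adhesions_t[i].x),
    )
    claimed: set[int] = set()
    matches: dict[int, int] = {}
    for i in order:
        src = adhesions_t[i]
        best = None
        for j, cand in enumerate(adhesions_t1):
            if j in claimed:
                continue
            if axial_difference(src.theta, cand.theta) > max_angle:
                continue
            if not _inside_ellipse(src, cand, convention):
                continue
            dist = np.hypot(cand.x - src.x, cand.y - src.y)
            key = (-cand.coefficient, dist, j)
            if best is None or key < best[0]:
                best = (key, j)
        if best is not None:
            matches[i] = best[1]
            claimed.add(best[1])
    return matches


def build_tracks(
    frames: Sequence[Sequence[Adhesion]],
    max_angle: float = 10.0,
    convention: str = "scaled",
    gap_tolerance: int = 0,
) -> tuple[list[AdhesionTrack], list[int]]:
    """Link per-frame adhesion lists into tracks.

    Returns ``(tracks, count_series)`` where ``count_series[t]`` is the
    number of adhesions detected in frame ``t`` (totals are preserved:
    every detection belongs to exactly one track).  ``gap_tolerance=1``
    allows a track to survive one unmatched frame by re-linking against
    the frame after it.
    """
    tracks: list[AdhesionTrack] = []
    # open[k] = (track index, frames since last match)
    open_tracks: list[tuple[int, int]] = []
    count_series = [len(f) for f in frames]
    for t, current in enumerate(frames):
        assigned = [False] * len(current)
        if t > 0 and open_tracks:
            heads = [tracks[k].adhesions[-1] for k, _ in open_tracks]
            matches = link_frames(heads, current, max_angle, convention)
            next_open: list[tuple[int, int]] = []
            for idx, (k, age) in enumerate(open_tracks):
                if idx in matches:
                    j = matches[idx]
                    tracks[k].adhesions.append(current[j])
                    assigned[j] = True
                    next_open.append((k, 0))
                elif age < gap_tolerance:
                    next_open.append((k, age + 1))
            open_tracks = next_open
        else:
            open_tracks = []
        for j, ad in enumerate(current):
            if not assigned[j]:
                tracks.append(AdhesionTrack(track_id=len(tracks), adhesions=[ad]))
                open_tracks.append((len(tracks) - 1, 0))
    return tracks, count_series
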