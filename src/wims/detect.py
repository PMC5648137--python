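"""Focal adhesion detection from stretched-wavelet coefficient grids.

An adhesion is an elongated, oriented intensity blob.  Candidates are the
strict local maxima of the stretched-wavelet coefficients over position,
orientation (wrapped mod 180 deg) and, when present, the (scale, axis
ratio) grid; maxima below a fraction (default 10%) of the strongest
maximum are discarded.  The surviving candidates are swept in descending
coefficient order and greedily accepted if their oriented-ellipse
footprint does not intersect any previously accepted footprint, so the
brightest structures claim their territory first.

The isotropic grid member ``xi = 1`` responds identically at every
orientation; its orientation axis is collapsed before maxima finding so
circular blobs are detected once rather than once per angle, and a
candidate at ``xi = 1`` must beat its anisotropic grid neighbours at
*every* orientation (they are all grid-adjacent to the degenerate
orientation coordinate).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .cwt import CoefficientField, MeshConfig, transform_stack
from .wavelets import stretched

__all__ = [
    "Adhesion",
    "find_local_maxima",
    "find_stack_maxima",
    "place_adhesions",
    "detect_adhesions",
    "reconstruct_from_maxima",
    "size_histogram",
    "ellipse_axes",
    "ellipses_disjoint",
]


@dataclass(frozen=True)
class Adhesion:
    """A detected oriented adhesion: an ellipse in original pixel coordinates."""

    x: float
    y: float
    a: float
    xi: float
    theta: float  # degrees in [0, 180)
    coefficient: float
    frame: int = 0
    id: int = -1

    def __post_init__(self) -> None:
        if self.coefficient <= 0:
            raise ValueError("adhesion coefficient must be positive")
        object.__setattr__(self, "theta", float(self.theta) % 180.0)

    @property
    def center(self) -> tuple[float, float]:
        return (self.x, self.y)


def ellipse_axes(a: float, xi: float, convention: str = "scaled") -> tuple[float, float]:
    """Footprint semi-axes (along r_par, along r_perp) of an adhesion.

    The default ``scaled`` convention uses semi-axes ``(a, a * xi)``,
    which scales the exclusion region with the detected size.  The
    ``literal`` convention uses axes of length ``a`` and ``xi`` directly
    (semi-axes ``a/2`` and ``xi/2``).
    """
    if convention == "scaled":
        return float(a), float(a * xi)
    if convention == "literal":
        return float(a) / 2.0, float(xi) / 2.0
    raise ValueError(f"unknown ellipse convention {convention!r}")


def _conic_matrix(cx: float, cy: float, p: float, q: float, theta_deg: float) -> np.ndarray:
    """3x3 conic of an ellipse, normalized so interior points give X^T A X < 0.

    Semi-axis ``p`` lies along the orientation direction
    ``(cos theta, -sin theta)`` (the wavelet's r_par axis), ``q`` along
    the perpendicular.
    """
    th = np.deg2rad(theta_deg)
    u = np.array([np.cos(th), -np.sin(th)])
    v = np.array([np.sin(th), np.cos(th)])
    m = np.outer(u, u) / (p * p) + np.outer(v, v) / (q * q)
    c = np.array([cx, cy])
    mc = m @ c
    out = np.empty((3, 3))
    out[:2, :2] = m
    out[:2, 2] = -mc
    out[2, :2] = -mc
    out[2, 2] = c @ mc - 1.0
    return out


def ellipses_disjoint(e1: tuple, e2: tuple, tol: float = 1e-9) -> bool:
    """Exact algebraic disjointness test for two ellipses.

    Each ellipse is ``(cx, cy, semi_par, semi_perp, theta_deg)``.  Uses
    the characteristic cubic ``f(lam) = det(lam * A + B)`` of the conic
    pencil: the ellipses are separated iff the cubic has two distinct
    positive real roots (external tangency gives a positive double root
    and counts as disjoint interiors here).  Resolution-independent, in
    contrast to raster tests.
    """
    a1 = _conic_matrix(*e1)
    a2 = _conic_matrix(*e2)
    # cubic coefficients via exact interpolation at 4 points
    lam = np.array([-1.0, 0.0, 1.0, 2.0])
    vals = np.array([np.linalg.det(l * a1 + a2) for l in lam])
    coeffs = np.linalg.solve(np.vander(lam, 4), vals)
    roots = np.roots(coeffs)
    scale = max(abs(roots).max(), 1.0)
    real = roots[np.abs(roots.imag) <= tol * scale].real
    pos = np.sort(real[real > tol])
    if len(pos) >= 2:
        # two distinct positive roots => separated; a double positive root
        # (external tangency) also leaves the interiors disjoint
        return True
    return False


def _as_stack(coeffs: CoefficientField) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    stack = coeffs.values_native(dtype=np.float32)
    return stack, coeffs.scales, coeffs.xis, coeffs.thetas


def find_local_maxima(coeffs, threshold_fraction: float = 0.10):
    """Strict local maxima of a coefficient field over (a, xi, theta, b).

    ``coeffs`` is a :class:`~wims.cwt.CoefficientField` or a tuple
    ``(stack, scales, xis, thetas)`` with ``stack`` of shape
    ``(n_a, n_xi, n_theta, H, W)`` at native resolution.  Returns
    candidates as ``(a, xi, theta, x, y, T)`` records sorted by
    descending coefficient, keeping only positive maxima at least
    ``threshold_fraction`` of the strongest one.
    """
    if isinstance(coeffs, CoefficientField):
        stack, scales, xis, thetas = _as_stack(coeffs)
    else:
        stack, scales, xis, thetas = coeffs
        stack = np.asarray(stack)
    if stack.size == 0:
        raise ValueError("empty coefficient field")
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold_fraction must be in (0, 1]")
    return find_stack_maxima(stack, scales, xis, thetas, threshold_fraction)


def _slab_filter(plane3: np.ndarray, exclude_center: bool) -> np.ndarray:
    """3-box maximum over (theta, y, x) of one scale/xi slab.

    Theta wraps (orientations are periodic mod 180 deg); outside the
    frame there is no neighbour (-inf padding).  With
    ``exclude_center`` the slab's own center voxel is left out, which
    turns ``plane > filter`` into a strict local-maximum test.
    """
    p = plane3
    look_theta = p.shape[0] > 1
    if look_theta:
        p = np.concatenate([p[-1:], p, p[:1]], axis=0)
    p = np.pad(p, ((0, 0), (1, 1), (1, 1)), constant_values=-np.inf)
    fp = np.ones((3 if look_theta else 1, 3, 3), dtype=bool)
    if exclude_center:
        fp[fp.shape[0] // 2, 1, 1] = False
    out = ndimage.maximum_filter(p, footprint=fp, mode="constant", cval=-np.inf)
    sl_t = slice(1, -1) if look_theta else slice(None)
    return out[sl_t, 1:-1, 1:-1]


class _Slab:
    """Coefficients of all xi planes at one scale, with cached box maxima."""

    def __init__(self, planes: list[np.ndarray]):
        self.planes = planes
        self.incl = [_slab_filter(p, exclude_center=False) for p in planes]
        # max over all orientations, for comparison against degenerate planes
        self.incl_any_theta = [m.max(axis=0, keepdims=True) for m in self.incl]


def refine_orientation(
    frame_image: np.ndarray,
    adhesions: Sequence[Adhesion],
    scales: Sequence[float] = (6.0, 8.0, 10.0, 12.0),
    xi: float = 0.2,
    n_theta: int = 180,
    window_deg: float = 25.0,
    smooth_deg: float = 3.0,
    truncation: float = 3.5,
) -> list[Adhesion]:
    """Refine detected orientations with a fan of strongly elongated wavelets.

    The grid argmax over theta is noisy: at the small scales where
    adhesions register best, the orientation response is a shallow lobe
    on a large isotropic baseline, so single-sample argmax jitters by
    several degrees at realistic noise levels.  This estimator evaluates
    a thin wavelet (axis ratio ``xi`` well below 1) over a full 1-degree
    fan at several scales, subtracts the lobe baseline, and takes the
    doubled-angle circular mean of the response within a window around
    the lobe maximum, summing the weighted mean vectors across scales.
    That averages the noise over the whole lobe instead of trusting one
    grid sample.  Detected ``theta`` values are updated in place of the
    grid angles, preserving each detection's (a, xi) and the axis
    convention (elongation along r_par for xi < 1, along r_perp for
    xi > 1); isotropic detections are left untouched.
    """
    frame_image = np.asarray(frame_image, dtype=float)
    h, w = frame_image.shape
    thetas = np.arange(n_theta) * (180.0 / n_theta)
    step = 180.0 / n_theta
    halfwin = int(round(window_deg / step))

    # kernel fans, one per refinement scale
    fans = []
    for a in scales:
        radius = int(np.ceil(truncation * a))
        c = np.arange(-radius, radius + 1, dtype=float)
        gx, gy = np.meshgrid(c, c, indexing="xy")
        kerns = np.empty((n_theta, (2 * radius + 1) ** 2))
        for i, th in enumerate(thetas):
            k = stretched(gx, gy, a, xi, th)
            kerns[i] = (k - k.mean()).ravel()
        fans.append((radius, kerns))

    out = []
    for ad in adhesions:
        if ad.xi == 1.0:
            out.append(ad)
            continue
        z = 0.0 + 0.0j
        for (radius, kerns), a in zip(fans, scales):
            iy, ix = int(round(ad.y)), int(round(ad.x))
            y0, y1 = iy - radius, iy + radius + 1
            x0, x1 = ix - radius, ix + radius + 1
            if y0 < 0 or x0 < 0 or y1 > h or x1 > w:
                continue  # refinement fan would leave the frame
            prof = kerns @ frame_image[y0:y1, x0:x1].ravel() / a
            sm = ndimage.gaussian_filter1d(prof, smooth_deg / step, mode="wrap")
            ti = int(sm.argmax())
            idx = (np.arange(ti - halfwin, ti + halfwin + 1)) % n_theta
            wgt = np.clip(sm[idx] - sm[idx].min(), 0, None) ** 2
            z += (wgt * np.exp(1j * np.deg2rad(2.0 * thetas[idx]))).sum()
        if z == 0:
            out.append(ad)
            continue
        axis = float(np.rad2deg(np.angle(z)) / 2.0 % 180.0)
        theta = axis if ad.xi < 1.0 else (axis - 90.0) % 180.0
        out.append(replace(ad, theta=theta))
    return out


def _maxima_from_slabs(
    slabs,
    scales: np.ndarray,
    xis: np.ndarray,
    thetas: np.ndarray,
    threshold_fraction: float,
    border_margin_scale: float,
) -> list[tuple[float, float, float, float, float, float]]:
    """Strict local maxima over (a, xi, theta, b) from a per-scale slab stream.

    Only three consecutive scale slabs are held at once, so memory stays
    bounded for large orientation fans.  ``slabs`` yields, per scale, a
    list of ``(n_theta_or_1, H, W)`` planes (isotropic planes arrive with
    their degenerate orientation axis already collapsed to length 1).
    """
    n_xi = len(xis)
    degenerate = [xis[i] == 1.0 and len(thetas) > 1 for i in range(n_xi)]
    candidates: list[tuple[float, float, float, float, float, float]] = []

    def process(ai: int, prev: _Slab | None, cur: _Slab, nxt: _Slab | None):
        a = float(scales[ai])
        for i in range(n_xi):
            plane = cur.planes[i]
            h, w = plane.shape[-2:]
            strict = plane > _slab_filter(plane, exclude_center=True)
            for nb in (prev, nxt):  # same-xi scale neighbours, inclusive box
                if nb is not None:
                    strict &= plane > nb.incl[i]
            for j in (i - 1, i + 1):  # adjacent xi planes, all three scales
                if j < 0 or j >= n_xi:
                    continue
                for nb in (prev, cur, nxt):
                    if nb is None:
                        continue
                    if degenerate[i] and not degenerate[j]:
                        other = nb.incl_any_theta[j]
                    else:
                        other = nb.incl[j]  # broadcasts when j is degenerate
                    strict &= plane > other
            strict &= plane > 0
            xi = float(xis[i])
            margin = border_margin_scale * a * max(1.0, xi)
            for ti, yy, xx in zip(*np.nonzero(strict)):
                if (
                    yy < margin or xx < margin
                    or yy > h - 1 - margin or xx > w - 1 - margin
                ):
                    continue
                theta = 0.0 if degenerate[i] else float(thetas[ti])
                candidates.append(
                    (a, xi, theta, float(xx), float(yy), float(plane[ti, yy, xx]))
                )

    prev: _Slab | None = None
    cur: _Slab | None = None
    ai = 0
    for planes in slabs:
        nxt = _Slab(planes)
        if cur is not None:
            process(ai, prev, cur, nxt)
            ai += 1
            prev = cur
        cur = nxt
    if cur is not None:
        process(ai, prev, cur, None)
    if candidates:
        threshold = threshold_fraction * max(c[5] for c in candidates)
        candidates = [c for c in candidates if c[5] >= threshold]
    # descending coefficient; ties broken by lower y, then lower x
    candidates.sort(key=lambda c: (-c[5], c[4], c[3]))
    return candidates


def _collapse_iso(block: np.ndarray, xis, thetas) -> list[np.ndarray]:
    """Per-xi planes of one scale, isotropic orientation axis collapsed."""
    planes = []
    for i in range(len(xis)):
        if xis[i] == 1.0 and len(thetas) > 1:
            planes.append(np.ascontiguousarray(block[i, :1]))
        else:
            planes.append(np.ascontiguousarray(block[i]))
    return planes


def find_stack_maxima(
    stack: np.ndarray,
    scales: Sequence[float],
    xis: Sequence[float],
    thetas: Sequence[float],
    threshold_fraction: float = 0.10,
    border_margin_scale: float = 1.0,
) -> list[tuple[float, float, float, float, float, float]]:
    """Core maxima finder on a native-resolution coefficient stack.

    Candidates closer to a frame edge than ``border_margin_scale`` times
    their footprint extent (``a * max(1, xi)``) are discarded: those
    coefficients are contaminated by the image border.  The retention
    threshold is ``threshold_fraction`` of the strongest surviving
    maximum.
    """
    scales = np.asarray(scales, dtype=float)
    xis = np.asarray(xis, dtype=float)
    thetas = np.asarray(thetas, dtype=float)
    slabs = (_collapse_iso(stack[n], xis, thetas) for n in range(len(scales)))
    return _maxima_from_slabs(
        slabs, scales, xis, thetas, threshold_fraction, border_margin_scale
    )


def place_adhesions(
    candidates: Sequence[tuple],
    frame: int = 0,
    convention: str = "scaled",
    frame_shape: tuple[int, int] | None = None,
) -> list[Adhesion]:
    """Greedily place non-overlapping adhesions from sorted candidates.

    ``candidates`` are ``(a, xi, theta, x, y, T)`` in descending-``T``
    order (re-sorted defensively with the deterministic tie-break).  A
    candidate is accepted iff its footprint ellipse is disjoint from all
    previously accepted ones; centers must lie inside the frame when
    ``frame_shape`` is given.
    """
    ordered = sorted(candidates, key=lambda c: (-c[5], c[4], c[3]))
    accepted: list[Adhesion] = []
    footprints: list[tuple] = []
    for a, xi, theta, x, y, t in ordered:
        if t <= 0:
            continue
        if frame_shape is not None:
            hh, ww = frame_shape
            if not (0 <= y <= hh - 1 and 0 <= x <= ww - 1):
                continue
        p, q = ellipse_axes(a, xi, convention)
        ell = (x, y, p, q, theta)
        radius = max(p, q)
        ok = True
        for other in footprints:
            # cheap bounding-circle accept before the exact test
            d = np.hypot(other[0] - x, other[1] - y)
            if d > radius + max(other[2], other[3]):
                continue
            if not ellipses_disjoint(ell, other):
                ok = False
                break
        if ok:
            footprints.append(ell)
            accepted.append(
                Adhesion(
                    x=x, y=y, a=a, xi=xi, theta=theta,
                    coefficient=t, frame=frame, id=len(accepted),
                )
            )
    return accepted


def detect_adhesions(
    frame_image: np.ndarray,
    scales: Sequence[float] = tuple(range(4, 21)),
    xis: Sequence[float] = (0.5, 1.0, 1.5),
    thetas: Sequence[float] | int = 360,
    threshold_fraction: float = 0.10,
    mesh_config: MeshConfig | None = None,
    frame: int = 0,
    convention: str = "scaled",
    background: str | float | None = "median",
    refine: bool = True,
) -> list[Adhesion]:
    """Detect adhesions in one frame over a full (a, xi, theta) grid.

    ``thetas`` may be an integer number of orientations spanning
    [0, 180).  The default grids mirror the two modes used in practice:
    a fixed ``(a=10, xi=1.5)`` fan for quick maps, or the variable-size
    grid ``a = 4..20``, ``xi in {1/2, 1, 3/2}`` used for size surveys
    (pass those explicitly).

    ``background`` (default: the frame median) is subtracted before
    transforming.  Because the sampled kernels are zero-sum this leaves
    interior coefficients untouched; it only removes the spurious
    response of the camera background against the zero beyond the frame
    edge, which would otherwise dominate large-scale coefficients near
    corners.
    """
    if isinstance(thetas, int):
        thetas = np.arange(thetas) * (180.0 / thetas)
    frame_image = np.asarray(frame_image, dtype=float)
    if background == "median":
        frame_image = frame_image - np.median(frame_image)
    elif background is not None:
        frame_image = frame_image - float(background)
    scales = np.asarray([float(a) for a in scales])
    xis = np.asarray([float(x) for x in xis])
    thetas = np.asarray([float(t) for t in thetas])

    def slabs():
        # one scale at a time keeps memory bounded for large theta fans
        for a in scales:
            block = transform_stack(frame_image, [a], xis, thetas, mesh_config)[0]
            yield _collapse_iso(block, xis, thetas)

    cands = _maxima_from_slabs(
        slabs(), scales, xis, thetas, threshold_fraction, border_margin_scale=1.0
    )
    placed = place_adhesions(
        cands, frame=frame, convention=convention, frame_shape=frame_image.shape
    )
    if refine:
        placed = refine_orientation(frame_image, placed)
    return placed


def reconstruct_from_maxima(
    adhesions: Sequence[Adhesion],
    shape: tuple[int, int],
    da: float = 1.0,
    db: float = 1.0,
    truncation: float = 4.0,
) -> np.ndarray:
    """Sparse image reconstruction from placed wavelet maxima.

    ``I_R(r) = sum_l da*db * a^-4 * T_l * psi_(xi,theta_l)((r - b_l)/a)``,
    each term truncated at its kernel box.  Linear in the adhesion list.
    """
    h, w = shape
    out = np.zeros((h, w))
    for ad in adhesions:
        radius = int(np.ceil(truncation * ad.a * max(1.0, ad.xi)))
        y0, y1 = max(0, int(ad.y) - radius), min(h, int(ad.y) + radius + 1)
        x0, x1 = max(0, int(ad.x) - radius), min(w, int(ad.x) + radius + 1)
        ys, xs = np.mgrid[y0:y1, x0:x1]
        psi = stretched(xs - ad.x, ys - ad.y, ad.a, ad.xi, ad.theta)
        out[y0:y1, x0:x1] += (da * db / ad.a**4) * ad.coefficient * psi
    return out


def size_histogram(
    adhesions: Sequence[Adhesion],
    pixel_size: float = 0.105,
    bin_width: float | None = None,
    a_range: tuple[float, float] | None = None,
):
    """Histogram of adhesion length scales in micrometres.

    Default bin width is one pixel (``pixel_size`` um).  Returns
    ``(counts, bin_edges_um)``; counts sum to the number of adhesions.
    """
    if bin_width is None:
        bin_width = pixel_size
    sizes = np.array([ad.a * pixel_size for ad in adhesions], dtype=float)
    if a_range is not None:
        lo, hi = a_range[0] * pixel_size, a_range[1] * pixel_size
    elif len(sizes):
        lo, hi = sizes.min(), sizes.max()
    else:
        lo, hi = 0.0, bin_width
    first = np.floor(lo / bin_width)
    last = np.ceil(hi / bin_width + 1e-9)
    edges = np.arange(first, last + 1) * bin_width
    if len(edges) < 2:
        edges = np.array([first * bin_width, (first + 1) * bin_width])
    counts, edges = np.histogram(sizes, bins=edges)
    return counts, edges


def renumber(adhesions: Sequence[Adhesion], start: int = 0) -> list[Adhesion]:
    """Reassign sequential ids (used after merging lists)."""
    return [replace(ad, id=start + i) for i, ad in enumerate(adhesions)]
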