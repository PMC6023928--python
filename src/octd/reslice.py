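"""Curved reslicing of cube scans along the canalicular path.

The canaliculus crosses many B-scans, so no single acquired frame shows it
end to end. This module traces a centerline through a segmented lumen,
reconstructs a longitudinal image by sampling full axial columns along an
en-face curve (curved planar reformation), and extracts cross-sections
perpendicular to the path at arbitrary arc-length stations — the planes on
which all morphometry is performed.

Coordinates are physical µm in the package's fixed (axial, slow, fast)
axis order; voxel centers sit at ``index * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse import csgraph
from skimage.morphology import skeletonize

from .volume import OCTVolume

__all__ = [
    "CenterlinePath",
    "ResliceImage",
    "trace_centerline",
    "longitudinal_reslice",
    "cross_section",
]

_SNAP_TOL = 1e-6


def _snap(c: np.ndarray) -> np.ndarray:
    """Round coordinates that are within 1e-6 of an integer lattice point.

    Keeps axis-aligned reslices bit-identical to direct slicing despite
    floating-point arithmetic on physical coordinates.
    """
    r = np.round(c)
    return np.where(np.abs(c - r) < _SNAP_TOL, r, c)


@dataclass
class CenterlinePath:
    """Ordered 3D points (µm, (z, y, x)) with cumulative arc length."""

    points: np.ndarray  # (N, 3)
    arc_length: np.ndarray  # (N,), cumulative, starts at 0
    source: str = "auto-traced"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.arc_length = np.asarray(self.arc_length, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 2:
            raise ValueError("a centerline needs >= 2 points of (z, y, x) µm")
        if np.any(np.diff(self.arc_length) <= 0):
            raise ValueError("arc length must be strictly increasing")

    @property
    def total_length(self) -> float:
        return float(self.arc_length[-1])

    def point_at(self, s: float) -> np.ndarray:
        """Linear interpolation of the path at arc length ``s`` µm."""
        if not 0 <= s <= self.total_length + _SNAP_TOL:
            raise ValueError(
                f"s={s:.1f} µm outside the path (total length {self.total_length:.1f} µm)"
            )
        return np.array(
            [np.interp(s, self.arc_length, self.points[:, k]) for k in range(3)]
        )

    def tangent_at(self, s: float) -> np.ndarray:
        """Unit tangent at arc length ``s`` (central finite difference)."""
        h = max(np.median(np.diff(self.arc_length)), 1e-3)
        s0 = max(0.0, s - h)
        s1 = min(self.total_length, s + h)
        d = self.point_at(s1) - self.point_at(s0)
        nrm = np.linalg.norm(d)
        if nrm == 0:
            raise ValueError("degenerate tangent (coincident path points)")
        return d / nrm


@dataclass
class ResliceImage:
    """A 2D resampled image with pixel spacing (row, col) µm and provenance."""

    pixels: np.ndarray
    pixel_spacing: tuple[float, float]
    provenance: dict
    valid: np.ndarray | None = None  # False where samples fell outside the volume

    def __post_init__(self) -> None:
        if not self.provenance:
            raise ValueError("provenance must be populated")
        if any(s <= 0 for s in self.pixel_spacing):
            raise ValueError("pixel spacing must be positive")


def _resample_polyline(points: np.ndarray, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline (µm) to uniform arc-length spacing ≈ ``step``."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        raise ValueError("polyline has zero length")
    n = max(1, int(round(total / step)))
    s_new = np.linspace(0.0, total, n + 1)
    out = np.column_stack(
        [np.interp(s_new, s, points[:, k]) for k in range(points.shape[1])]
    )
    return out, s_new


def _moving_average(points: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return points
    pad = window // 2
    padded = np.pad(points, ((pad, pad), (0, 0)), mode="edge")
    kernel = np.ones(window) / window
    return np.column_stack(
        [np.convolve(padded[:, k], kernel, mode="valid") for k in range(points.shape[1])]
    )


def _select_component(
    mask: np.ndarray, seed: np.ndarray, radius_vox: float
) -> tuple[np.ndarray, np.ndarray]:
    """Pick the connected component containing (or nearest to) the seed.

    Returns the component mask and a seed voxel guaranteed to lie inside it.
    """
    comps, _ = ndimage.label(mask, structure=np.ones((3, 3, 3), bool))
    seed_i = np.round(seed).astype(int)
    if all(0 <= s < n for s, n in zip(seed_i, mask.shape)) and mask[tuple(seed_i)]:
        return comps == comps[tuple(seed_i)], seed_i
    fg = np.argwhere(mask)
    d = np.linalg.norm(fg - seed, axis=1)
    j = int(np.argmin(d))
    if d[j] > radius_vox:
        raise ValueError(
            f"seed is {d[j]:.1f} voxels from the nearest lumen voxel "
            f"(limit {radius_vox})"
        )
    return comps == comps[tuple(fg[j])], fg[j]


_OFFSETS_26 = np.array(
    [
        (a, b, c)
        for a in (-1, 0, 1)
        for b in (-1, 0, 1)
        for c in (-1, 0, 1)
        if (a, b, c) != (0, 0, 0)
    ]
)


def _voxel_graph(points: np.ndarray, spacing: np.ndarray, shape) -> sparse.csr_matrix:
    """26-connectivity graph over a voxel set, edges weighted by physical length."""
    flat = np.full(shape, -1, dtype=np.int64)
    flat[tuple(points.T)] = np.arange(len(points))
    rows, cols, wts = [], [], []
    off_w = np.linalg.norm(_OFFSETS_26 * spacing, axis=1)
    for o, w in zip(_OFFSETS_26, off_w):
        q = points + o
        ok = np.all((q >= 0) & (q < shape), axis=1)
        j = flat[tuple(q[ok].T)]
        hit = j >= 0
        rows.append(np.arange(len(points))[ok][hit])
        cols.append(j[hit])
        wts.append(np.full(hit.sum(), w))
    return sparse.csr_matrix(
        (np.concatenate(wts), (np.concatenate(rows), np.concatenate(cols))),
        shape=(len(points), len(points)),
    )


def _extend_ends_to_mask(
    points: np.ndarray, comp: np.ndarray, spacing: np.ndarray, origin: np.ndarray
) -> np.ndarray:
    """Prolong a polyline's first/last segment to the component boundary."""

    def inside(p: np.ndarray) -> bool:
        idx = np.round((p - origin) / spacing).astype(int)
        return all(0 <= i < n for i, n in zip(idx, comp.shape)) and comp[tuple(idx)]

    out = [points]
    step = float(np.min(spacing)) / 2.0
    for end, ref, prepend in ((points[0], points[1], True), (points[-1], points[-2], False)):
        d = end - ref
        nrm = np.linalg.norm(d)
        if nrm == 0:
            continue
        d /= nrm
        p = end.copy()
        while inside(p + step * d):
            p = p + step * d
        if np.linalg.norm(p - end) > step:
            out = [p[None, :], *out] if prepend else [*out, p[None, :]]
    return np.vstack(out)


def trace_centerline(
    lumen_mask: np.ndarray,
    spacing: tuple[float, float, float],
    punctum_seed: tuple[int, int, int],
    *,
    method: Literal["shells", "skeleton"] = "shells",
    smooth_window: int = 5,
    step_um: float = 25.0,
    seed_search_radius_vox: float = 10.0,
) -> CenterlinePath:
    """Trace the canalicular centerline through a binary lumen mask.

    ``shells`` (default) orders the seed-containing component by geodesic
    distance from the punctal seed and takes the centroid of each
    equal-distance shell: robust for the flat, ribbon-like horizontal lumen,
    whose 3D thinning skeleton is a medial *surface* rather than a curve.
    ``skeleton`` instead skeletonizes the component and follows the
    maximal-geodesic-length skeleton branch from the seed. Both variants are
    smoothed with a moving average and resampled to a uniform arc step.
    """
    lumen_mask = np.asarray(lumen_mask, dtype=bool)
    if not lumen_mask.any():
        raise ValueError("empty lumen mask")
    spacing = np.asarray(spacing, dtype=float)
    seed = np.asarray(punctum_seed, dtype=float)
    component, seed_in = _select_component(lumen_mask, seed, seed_search_radius_vox)

    # crop to the component for speed
    idx = np.argwhere(component)
    lo = np.maximum(idx.min(0) - 1, 0)
    hi = np.minimum(idx.max(0) + 2, component.shape)
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    comp = component[box]
    seed_local = seed_in - lo

    if method == "shells":
        vox = np.argwhere(comp)
        graph = _voxel_graph(vox, spacing, comp.shape)
        start = int(np.argmin(np.linalg.norm((vox - seed_local) * spacing, axis=1)))
        dist = csgraph.dijkstra(graph, indices=start, directed=False)
        dist[~np.isfinite(dist)] = -1
        bin_um = max(step_um, 2 * float(np.max(spacing)))
        bins = np.floor(dist / bin_um).astype(int)
        order = np.unique(bins[bins >= 0])
        coords = (vox + lo) * spacing
        points = np.array([coords[bins == k].mean(axis=0) for k in order])
        if len(points) < 2:
            raise ValueError("component too small to trace a centerline")
        # bin centroids sit ~half a bin inside each end: extrapolate the
        # first/last segment out to geodesic distances 0 and max
        sbar = np.array([dist[bins == k].mean() for k in order])
        d01, dn1 = sbar[1] - sbar[0], sbar[-1] - sbar[-2]
        head = points[0] - (points[1] - points[0]) * (sbar[0] / d01) if d01 > 0 else None
        tail = (
            points[-1] + (points[-1] - points[-2]) * ((dist.max() - sbar[-1]) / dn1)
            if dn1 > 0
            else None
        )
        parts = [p for p in (head,) if p is not None] + [points] + [
            p for p in (tail,) if p is not None
        ]
        points = np.vstack([np.atleast_2d(p) for p in parts])
    elif method == "skeleton":
        skel = skeletonize(comp)
        pts = np.argwhere(skel)
        if len(pts) < 2:  # blob too small to skeletonize: use extreme voxels
            vox = np.argwhere(comp)
            proj = vox @ spacing
            pts = vox[[int(np.argmin(proj)), int(np.argmax(proj))]]
            if np.array_equal(pts[0], pts[1]):
                raise ValueError("component too small to trace a centerline")
        graph = _voxel_graph(pts, spacing, comp.shape)
        start = int(np.argmin(np.linalg.norm((pts - seed_local) * spacing, axis=1)))
        dist, pred = csgraph.dijkstra(
            graph, indices=start, return_predecessors=True, directed=False
        )
        dist[~np.isfinite(dist)] = -1
        end = int(np.argmax(dist))
        chain = [end]
        while chain[-1] != start:
            prev = pred[chain[-1]]
            if prev < 0:
                break
            chain.append(int(prev))
        chain.reverse()
        points = (pts[chain] + lo) * spacing
        if len(points) < 2:
            raise ValueError("centerline collapsed to a single point")
        # thinning erodes tube end caps: walk each end out to the mask edge
        points = _extend_ends_to_mask(points, comp, spacing, lo * spacing)
    else:
        raise ValueError(f"unknown centerline method {method!r}")

    points = _moving_average(points, smooth_window)
    points, s = _resample_polyline(points, step_um)
    return CenterlinePath(points, s, source=f"auto-traced ({method})")


def longitudinal_reslice(
    vol: OCTVolume,
    enface_curve_um: np.ndarray,
    *,
    step_um: float | None = None,
    order: int = 1,
) -> ResliceImage:
    """Curved planar reformation: full axial columns along an en-face curve.

    ``enface_curve_um`` is an ordered list of (slow, fast) positions in µm.
    The curve is resampled at uniform arc steps (default: the finer in-plane
    spacing); each output column is the axial intensity profile at that curve
    point, interpolated bilinearly in-plane.
    """
    dz, dy, dx = vol.spacing
    curve = np.asarray(enface_curve_um, dtype=float)
    if curve.ndim != 2 or curve.shape[1] != 2 or len(curve) < 2:
        raise ValueError("enface_curve_um must be (M, 2) points of (slow, fast) µm")
    ny, nx = vol.shape[1], vol.shape[2]
    bad = [
        (i, tuple(p))
        for i, p in enumerate(curve)
        if not (0 <= p[0] <= (ny - 1) * dy and 0 <= p[1] <= (nx - 1) * dx)
    ]
    if bad:
        raise ValueError(f"curve leaves the en-face bounds at points {bad}")
    if step_um is None:
        step_um = min(dy, dx)
    samples, s = _resample_polyline(curve, step_um)
    iy = _snap(samples[:, 0] / dy)
    ix = _snap(samples[:, 1] / dx)
    nz = vol.shape[0]
    zz = np.repeat(np.arange(nz, dtype=float), len(samples))
    yy = np.tile(iy, nz)
    xx = np.tile(ix, nz)
    out = ndimage.map_coordinates(
        vol.voxels.astype(np.float64), [zz, yy, xx], order=order, mode="nearest"
    ).reshape(nz, len(samples))
    return ResliceImage(
        pixels=out,
        pixel_spacing=(dz, float(s[1] - s[0])),
        provenance={
            "kind": "longitudinal_reslice",
            "n_curve_points": int(len(curve)),
            "arc_step_um": float(s[1] - s[0]),
            "total_arc_um": float(s[-1]),
            "interpolation_order": order,
        },
    )


def cross_section(
    vol: OCTVolume,
    path: CenterlinePath,
    s: float,
    halfwidth_um: float,
    *,
    order: int = 1,
    fill: float | None = None,
    step_um: float | None = None,
    frame: Literal["enface", "3d"] = "enface",
) -> ResliceImage:
    """Cross-section perpendicular to the path at arc-length station ``s``.

    The sampling plane passes through ``path(s)`` and is spanned by the
    axial unit vector and the in-plane unit normal perpendicular to the
    tangent's en-face projection (``frame="3d"`` instead uses a fully 3D
    perpendicular frame, for steeply descending path segments). Rows cover
    the volume's full axial range; columns cover ±``halfwidth_um`` at the
    native in-plane spacing. Samples outside the volume receive ``fill``
    (default: the volume minimum, a proxy for the air level) and are marked
    in ``valid``.
    """
    dz, dy, dx = vol.spacing
    p = path.point_at(s)
    t = path.tangent_at(s)

    if frame == "enface" and np.hypot(t[1], t[2]) > 1e-9:
        # in-plane perpendicular of the en-face tangent; oriented so a path
        # along +fast yields columns running toward +slow
        n = np.array([0.0, t[2], -t[1]])
    else:  # steep/vertical tangent: any 3D perpendicular, preferring in-plane
        ref = np.array([0.0, 1.0, 0.0]) if abs(t[1]) < 0.9 else np.array([0.0, 0.0, 1.0])
        n = np.cross(t, ref)
    n = n / np.linalg.norm(n)

    if step_um is None:
        step_um = dy if abs(n[1]) * dy >= abs(n[2]) * dx else dx
    m = int(np.floor(halfwidth_um / step_um))
    u = np.arange(-m, m + 1) * step_um

    if frame == "enface":
        nz = vol.shape[0]
        zc = np.repeat(np.arange(nz, dtype=float), len(u))
        yc = np.tile(_snap((p[1] + u * n[1]) / dy), nz)
        xc = np.tile(_snap((p[2] + u * n[2]) / dx), nz)
        row_spacing = dz
        shape = (nz, len(u))
    else:
        v = np.cross(t, n)  # completes the orthonormal frame
        kmax = int(np.floor(halfwidth_um / dz))
        w = np.arange(-kmax, kmax + 1) * dz
        zc = _snap((p[0] + np.add.outer(w * v[0], u * n[0])).ravel() / dz)
        yc = _snap((p[1] + np.add.outer(w * v[1], u * n[1])).ravel() / dy)
        xc = _snap((p[2] + np.add.outer(w * v[2], u * n[2])).ravel() / dx)
        row_spacing = dz
        shape = (len(w), len(u))

    if fill is None:
        fill = float(np.min(vol.voxels))
    inside = (
        (zc >= 0) & (zc <= vol.shape[0] - 1)
        & (yc >= 0) & (yc <= vol.shape[1] - 1)
        & (xc >= 0) & (xc <= vol.shape[2] - 1)
    )
    out = ndimage.map_coordinates(
        vol.voxels.astype(np.float64), [zc, yc, xc], order=order,
        mode="constant", cval=fill,
    )
    out[~inside] = fill
    return ResliceImage(
        pixels=out.reshape(shape),
        pixel_spacing=(row_spacing, step_um),
        valid=inside.reshape(shape),
        provenance={
            "kind": "cross_section",
            "station_s_um": float(s),
            "halfwidth_um": float(halfwidth_um),
            "frame": frame,
            "fill_value": fill,
            "interpolation_order": order,
            "center_zyx_um": [float(c) for c in p],
            "normal_zyx": [float(c) for c in n],
        },
    )
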