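"""Lumen morphometry on resliced sections.

Implements the measurement protocol: maximum anteroposterior (axial) lumen
length of the vertical segment on a longitudinal section; anteroposterior
and transverse lumen lengths, lumen area and epithelium thickness on
cross-sections of the horizontal segment, averaged over three stations
placed 1 mm apart along the lumen.

Extent convention (used everywhere): a run of k pixels spans k × spacing
(voxel-as-cell), so a single pixel has extent equal to one spacing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import OCTVolume, TISSUE_CORRECTED
from .reslice import CenterlinePath, ResliceImage, cross_section, longitudinal_reslice
from .segment import SurfaceMap

__all__ = [
    "CrossSectionMetrics",
    "MorphometryReport",
    "SegmentSplit",
    "measure_vertical_ap",
    "measure_cross_section",
    "measure_horizontal",
    "split_segments",
    "vertical_ap_from_mask",
]


@dataclass
class CrossSectionMetrics:
    """Per-station lumen measurements (lengths µm, area mm²)."""

    station_arc_length_um: float
    ap_length_um: float
    transverse_length_um: float
    lumen_area_mm2: float
    epithelium_thickness_um: float | None  # None when no epithelium mask given

    def __post_init__(self) -> None:
        for name in ("ap_length_um", "transverse_length_um", "lumen_area_mm2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        bound = self.ap_length_um * self.transverse_length_um / 1e6  # mm²
        if self.lumen_area_mm2 > bound * (1 + 1e-9):
            raise ValueError("lumen area exceeds its bounding-box bound")


@dataclass
class MorphometryReport:
    """Three-station aggregate of horizontal-segment cross-section metrics."""

    stations: list[CrossSectionMetrics]
    vertical_ap_length_um: float | None = None

    def _values(self, field: str) -> np.ndarray:
        vals = [getattr(s, field) for s in self.stations]
        return np.array([v for v in vals if v is not None], dtype=float)

    def mean(self, field: str) -> float:
        v = self._values(field)
        return float(v.mean()) if v.size else float("nan")

    def sd(self, field: str) -> float:
        """Sample SD over stations; NaN when fewer than two stations."""
        v = self._values(field)
        return float(v.std(ddof=1)) if v.size > 1 else float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "station": i,
                "arc_length_um": s.station_arc_length_um,
                "ap_length_um": s.ap_length_um,
                "transverse_length_um": s.transverse_length_um,
                "lumen_area_mm2": s.lumen_area_mm2,
                "epithelium_thickness_um": s.epithelium_thickness_um,
            }
            for i, s in enumerate(self.stations)
        ]
        agg = {
            "station": "mean",
            "arc_length_um": np.nan,
            "ap_length_um": self.mean("ap_length_um"),
            "transverse_length_um": self.mean("transverse_length_um"),
            "lumen_area_mm2": self.mean("lumen_area_mm2"),
            "epithelium_thickness_um": self.mean("epithelium_thickness_um"),
        }
        return pd.DataFrame(rows + [agg])


def _runs_extent(mask: np.ndarray, axis: int) -> np.ndarray:
    """Per-line extent (max - min + 1) of True pixels along ``axis``; 0 if none."""
    any_line = mask.any(axis=axis)
    n = mask.shape[axis]
    coords = np.arange(n)
    shape = [1, 1]
    shape[axis] = n
    c = coords.reshape(shape)
    first = np.where(mask, c, n).min(axis=axis)
    last = np.where(mask, c, -1).max(axis=axis)
    return np.where(any_line, last - first + 1, 0)


def measure_vertical_ap(
    longitudinal: ResliceImage, lumen_section_mask: np.ndarray
) -> float:
    """Maximum anteroposterior lumen length (µm) on a longitudinal section.

    The maximum over section columns of the axial extent of the lumen,
    times the row spacing.
    """
    m = np.asarray(lumen_section_mask, dtype=bool)
    if m.shape != longitudinal.pixels.shape:
        raise ValueError("mask shape does not match the longitudinal section")
    if not m.any():
        raise ValueError("empty lumen mask on the longitudinal section")
    dz = longitudinal.pixel_spacing[0]
    return float(_runs_extent(m, axis=0).max() * dz)


def measure_cross_section(
    section_mask: np.ndarray,
    epi_mask: np.ndarray | None,
    spacing: tuple[float, float],
    station_arc_length_um: float = 0.0,
) -> CrossSectionMetrics:
    """Measure one horizontal-segment cross-section.

    ``spacing`` is (row=axial, col=in-plane) pixel spacing in µm. AP length
    is the maximum per-column axial extent; transverse length the maximum
    per-row in-plane extent; area the pixel count times pixel area (mm²).
    Epithelium thickness is the mean, over epithelial pixels bordering the
    lumen, of the distance through the epithelium to surrounding tissue,
    evaluated on the Euclidean distance transform of lumen+epithelium.
    """
    m = np.asarray(section_mask, dtype=bool)
    if not m.any():
        raise ValueError("empty lumen mask in cross-section")
    dz, dcol = spacing
    ap = float(_runs_extent(m, axis=0).max() * dz)
    tr = float(_runs_extent(m, axis=1).max() * dcol)
    area_mm2 = float(m.sum() * dz * dcol / 1e6)

    epi_thickness: float | None = None
    if epi_mask is not None:
        e = np.asarray(epi_mask, dtype=bool)
        if e.any():
            # anchor the inner border on the epithelium's own enclosed cavity
            # where it exists: a lumen mask eroded/dilated by segmentation
            # noise then cannot drag border pixels into the shell interior
            cavity = ndimage.binary_fill_holes(e) & ~e
            inner = cavity if cavity.any() else m
            fg = m | e | inner
            dist = ndimage.distance_transform_edt(fg, sampling=spacing)
            border = e & ndimage.binary_dilation(
                inner, structure=ndimage.generate_binary_structure(2, 1)
            )
            if border.any():
                epi_thickness = float(dist[border].mean())
    return CrossSectionMetrics(
        station_arc_length_um=float(station_arc_length_um),
        ap_length_um=ap,
        transverse_length_um=tr,
        lumen_area_mm2=area_mm2,
        epithelium_thickness_um=epi_thickness,
    )


def _mask_volume(mask: np.ndarray, spacing) -> OCTVolume:
    return OCTVolume(mask.astype(np.uint8), spacing, medium=TISSUE_CORRECTED)


def measure_horizontal(
    lumen_mask: np.ndarray,
    spacing: tuple[float, float, float],
    path: CenterlinePath,
    start_s_um: float,
    *,
    n_stations: int = 3,
    interval_um: float = 1000.0,
    epi_mask: np.ndarray | None = None,
    halfwidth_um: float = 1800.0,
) -> MorphometryReport:
    """Cross-section metrics at ``n_stations`` stations 1 mm apart, aggregated.

    Sections are extracted perpendicular to the path with nearest-neighbour
    sampling (labels must not mix) and measured individually; the report
    exposes means and sample SDs over stations.
    """
    last = start_s_um + (n_stations - 1) * interval_um
    if last > path.total_length:
        raise ValueError(
            f"path too short: stations need arc length {last:.0f} µm but only "
            f"{path.total_length:.0f} µm is available"
        )
    mask_vol = _mask_volume(np.asarray(lumen_mask, dtype=bool), spacing)
    epi_vol = (
        _mask_volume(np.asarray(epi_mask, dtype=bool), spacing)
        if epi_mask is not None
        else None
    )
    stations = []
    for i in range(n_stations):
        s = start_s_um + i * interval_um
        sec = cross_section(mask_vol, path, s, halfwidth_um, order=0, fill=0.0)
        lum2d = sec.pixels > 0.5
        epi2d = None
        if epi_vol is not None:
            esec = cross_section(epi_vol, path, s, halfwidth_um, order=0, fill=0.0)
            epi2d = esec.pixels > 0.5
        stations.append(
            measure_cross_section(lum2d, epi2d, sec.pixel_spacing, station_arc_length_um=s)
        )
    return MorphometryReport(stations=stations)


@dataclass
class SegmentSplit:
    """Arc-length windows of the vertical and horizontal path segments (µm)."""

    vertical: tuple[float, float] | None  # None when no axial prefix exists
    horizontal: tuple[float, float]
    no_vertical_warning: bool = False

    @property
    def split_s_um(self) -> float:
        return self.horizontal[0]


def split_segments(
    path: CenterlinePath,
    surface: SurfaceMap | None = None,
    *,
    angle_threshold_deg: float = 45.0,
) -> SegmentSplit:
    """Split the path into its vertical and horizontal segments.

    The vertical window is the maximal path prefix whose tangent stays
    within ``angle_threshold_deg`` of the axial direction; the remainder is
    horizontal. ``surface`` is accepted for interface symmetry (the path is
    expected to start at the punctum on the surface) but not needed by the
    tangent criterion.
    """
    cos_thr = np.cos(np.deg2rad(angle_threshold_deg))
    seg = np.diff(path.points, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    good = seg_len > 0
    axial_frac = np.abs(seg[good, 0]) / seg_len[good]
    s_mid = path.arc_length[:-1][good]
    below = np.nonzero(axial_frac < cos_thr)[0]
    if len(below) == 0:  # purely vertical
        return SegmentSplit(
            vertical=(0.0, path.total_length),
            horizontal=(path.total_length, path.total_length),
        )
    first_non_axial = below[0]
    if first_non_axial == 0:  # no axial prefix at all
        return SegmentSplit(
            vertical=None,
            horizontal=(0.0, path.total_length),
            no_vertical_warning=True,
        )
    s_split = float(s_mid[first_non_axial])
    return SegmentSplit(vertical=(0.0, s_split), horizontal=(s_split, path.total_length))


def _enface_arc(curve: np.ndarray, coord: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative en-face arc length of a 2D polyline and one coordinate track."""
    s = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(curve, axis=0), axis=1))]
    )
    return s, curve[:, coord]


def _half_max_extent_um(profile: np.ndarray, r0: int, r1: int, dz: float) -> float | None:
    """Sub-voxel axial extent of a bright run via half-maximum edge crossings.

    ``profile`` is a (lightly smoothed) axial intensity column; [r0, r1] the
    voxel run located by the mask. Each edge position is interpolated where
    the profile crosses midway between the run plateau and the local
    background beyond that edge — the caliper convention that removes the
    partial-volume bias of voxel counting. Returns None when an edge cannot
    be bracketed (run touching the volume border).
    """
    n = len(profile)
    plateau = float(np.median(profile[r0 : r1 + 1]))

    def crossing(outward: int, edge: int) -> float | None:
        bg_lo = edge + 2 * outward
        bg_hi = edge + 7 * outward
        sl = profile[max(min(bg_lo, bg_hi), 0) : max(bg_lo, bg_hi) + 1]
        if sl.size == 0:
            return None
        thr = 0.5 * (plateau + float(np.median(sl)))
        k = edge
        # the mask edge may sit below threshold (e.g. a marginal voxel):
        # retreat into the run until the crossing is bracketed
        while r0 <= k <= r1 and profile[k] < thr:
            k -= outward
        if not r0 <= k <= r1 or profile[k] < thr:
            return None
        while 0 <= k + outward < n and profile[k + outward] >= thr:
            k += outward
        if not 0 <= k + outward < n:
            return None
        a, b = profile[k], profile[k + outward]
        frac = (a - thr) / (a - b) if a != b else 0.5
        return (k + outward * float(np.clip(frac, 0.0, 1.0))) * dz

    top = crossing(-1, r0)
    bottom = crossing(+1, r1)
    if top is None or bottom is None:
        return None
    return bottom - top


def vertical_ap_from_mask(
    lumen_mask: np.ndarray,
    spacing: tuple[float, float, float],
    path: CenterlinePath,
    split: SegmentSplit,
    surface: SurfaceMap | None = None,
    intensity: np.ndarray | None = None,
) -> float:
    """Vertical-segment AP length from a 3D mask via a longitudinal reslice.

    Builds the longitudinal section along the path's en-face projection,
    restricts it to the columns over the vertical window's en-face footprint
    (at least the punctal column) and applies :func:`measure_vertical_ap`.
    When a surface map is given, columns whose lumen reaches to within two
    voxels of the conjunctiva (the open punctum) are closed up to the
    surface: the vertical AP run starts at the conjunctival plane, and the
    sharp air/contrast edge otherwise clips the topmost voxel.

    With an ``intensity`` volume (ideally the smoothed volume the
    segmentation thresholded), the extent is refined to sub-voxel precision
    by half-maximum edge crossings of the axial profile at each candidate
    column — the caliper convention, which removes the one-voxel
    partial-volume bias of counting mask voxels across two interfaces.
    """
    if split.vertical is None:
        raise ValueError("path has no vertical segment")
    mask_vol = _mask_volume(np.asarray(lumen_mask, dtype=bool), spacing)
    curve = path.points[:, 1:3]
    sec = longitudinal_reslice(mask_vol, curve, order=0)
    m2d = sec.pixels > 0.5
    if surface is not None:
        dz = sec.pixel_spacing[0]
        dy, dx = surface.enface_spacing
        ny, nx = surface.heights_um.shape
        # surface row under each reslice column (nearest en-face sample)
        n_cols = m2d.shape[1]
        s_cols = np.arange(n_cols) * sec.pixel_spacing[1]
        col_pts = np.column_stack(
            [
                np.interp(s_cols, *_enface_arc(curve), left=curve[0, 0], right=curve[-1, 0]),
                np.interp(s_cols, *_enface_arc(curve, coord=1), left=curve[0, 1], right=curve[-1, 1]),
            ]
        )
        iy = np.clip(np.round(col_pts[:, 0] / dy).astype(int), 0, ny - 1)
        ix = np.clip(np.round(col_pts[:, 1] / dx).astype(int), 0, nx - 1)
        surf_row = np.round(surface.heights_um[iy, ix] / dz).astype(int)
        for j in range(n_cols):
            rows = np.nonzero(m2d[:, j])[0]
            if rows.size and 0 <= surf_row[j] <= rows[0] <= surf_row[j] + 2:
                m2d[surf_row[j] : rows[0], j] = True

    # en-face arc length of the vertical prefix
    n_pts = np.searchsorted(path.arc_length, split.vertical[1], side="right")
    enface = path.points[: max(n_pts, 2), 1:3]
    s_v_enface = float(np.linalg.norm(np.diff(enface, axis=0), axis=1).sum())
    step = sec.pixel_spacing[1]
    n_cols_v = max(1, int(np.floor(s_v_enface / step)) + 1)

    if intensity is not None:
        ivol = OCTVolume(np.asarray(intensity, dtype=np.float32), spacing,
                         medium=TISSUE_CORRECTED)
        isec = longitudinal_reslice(ivol, curve, order=1)
        dz_row = sec.pixel_spacing[0]
        best = None
        for j in range(min(n_cols_v, m2d.shape[1])):
            rows = np.nonzero(m2d[:, j])[0]
            if not rows.size:
                continue
            ext = _half_max_extent_um(isec.pixels[:, j], rows[0], rows[-1], dz_row)
            if ext is not None and (best is None or ext > best):
                best = ext
        if best is not None:
            return float(best)

    return measure_vertical_ap(
        ResliceImage(sec.pixels[:, :n_cols_v], sec.pixel_spacing, sec.provenance),
        m2d[:, :n_cols_v],
    )
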