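"""Canalicular drainage function: ROI intensity curves and washout half-life.

The functional readout is the time–intensity curve of the contrast-filled
lumen, normalized by subtracting the mean grayscale of an air region
(background), and the elimination half-life T1/2: the time from the maximum
intensity to the first sample falling strictly below half that maximum.
Curves sampled every minute quantize the estimate upward, so T1/2 for a true
exponential half-life h lands at the first whole minute strictly beyond h.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volume import OCTVolume, VolumeSeries

__all__ = [
    "ROISpec",
    "TimeIntensityCurve",
    "WashoutResult",
    "CohortWashout",
    "extract_section",
    "roi_mean",
    "build_curve",
    "compute_t_half",
    "cohort_summary",
]

#: Minimum total lumen ROI area (µm²): smaller regions are too speckle-noisy.
MIN_LUMEN_ROI_AREA_UM2 = 100.0


@dataclass(frozen=True)
class ROISpec:
    """Circular region(s) of interest on a 2D section.

    ``circles`` are (row_um, col_um, radius_um) in the section's physical
    frame. For a lumen target the summed nominal circle area must exceed
    100 µm² (multiple circles may be combined when the lumen is too narrow
    for a single compliant circle); pixels covered by several circles are
    counted once.
    """

    circles: tuple[tuple[float, float, float], ...]
    target: str = "lumen"

    def __post_init__(self) -> None:
        if not self.circles:
            raise ValueError("ROISpec needs at least one circle")
        if any(r <= 0 for _, _, r in self.circles):
            raise ValueError("circle radii must be positive")
        if self.target not in ("lumen", "air"):
            raise ValueError(f"unknown ROI target {self.target!r}")
        if self.target == "lumen" and self.total_area_um2 <= MIN_LUMEN_ROI_AREA_UM2:
            raise ValueError(
                f"lumen ROI area {self.total_area_um2:.1f} µm² is below the "
                f"{MIN_LUMEN_ROI_AREA_UM2:.0f} µm² minimum; add circles"
            )

    @property
    def total_area_um2(self) -> float:
        return float(sum(np.pi * r * r for _, _, r in self.circles))


def extract_section(
    vol: OCTVolume, axis: str, index: int
) -> tuple[np.ndarray, tuple[float, float]]:
    """A B-scan-like 2D section of a volume: ``axis`` is "slow" or "fast".

    Returns the image (axial rows) and its (row, col) pixel spacing in µm.
    """
    dz, dy, dx = vol.spacing
    if axis == "slow":
        return vol.voxels[:, index, :], (dz, dx)
    if axis == "fast":
        return vol.voxels[:, :, index], (dz, dy)
    raise ValueError(f"axis must be 'slow' or 'fast', got {axis!r}")


def roi_mean(
    image: np.ndarray, pixel_spacing: tuple[float, float], roi: ROISpec
) -> float:
    """Mean grayscale over all pixels whose centers fall inside any ROI circle.

    Overlapping circles never double-count a pixel. Raises if a circle lies
    outside the image or covers no pixel center.
    """
    img = np.asarray(image, dtype=float)
    dr, dc = pixel_spacing
    h, w = img.shape
    rows = np.arange(h) * dr
    cols = np.arange(w) * dc
    sel = np.zeros(img.shape, dtype=bool)
    for cr, cc, r in roi.circles:
        if not (0 <= cr <= rows[-1] and 0 <= cc <= cols[-1]):
            raise ValueError(
                f"ROI circle center ({cr:.1f}, {cc:.1f}) µm lies outside the "
                f"{rows[-1]:.0f} × {cols[-1]:.0f} µm image"
            )
        inside = (rows[:, None] - cr) ** 2 + (cols[None, :] - cc) ** 2 <= r * r
        if not inside.any():
            raise ValueError(
                f"ROI circle at ({cr:.1f}, {cc:.1f}) µm, r={r:.1f} µm covers no "
                "pixel center; enlarge it or refine the grid"
            )
        sel |= inside
    return float(img[sel].mean())


@dataclass
class TimeIntensityCurve:
    """Background-subtracted lumen intensity per time point (minutes)."""

    times_min: np.ndarray
    values: np.ndarray
    lumen_means: np.ndarray | None = None
    air_means: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_min.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if len(self.times_min) and np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        d = {"minute": self.times_min, "normalized": self.values}
        if self.lumen_means is not None:
            d["lumen_mean"] = self.lumen_means
        if self.air_means is not None:
            d["air_mean"] = self.air_means
        return pd.DataFrame(d)


def build_curve(
    series: VolumeSeries,
    lumen_roi: ROISpec,
    air_roi: ROISpec,
    *,
    section_axis: str = "slow",
    section_index: int = 0,
) -> TimeIntensityCurve:
    """Time–intensity curve from a volume series.

    Per frame, a 2D section is extracted (``section_axis``/``section_index``,
    the plane the ROIs were drawn on) and the normalized value is
    mean(lumen ROI) − mean(air ROI).
    """
    lumen_vals, air_vals = [], []
    for _, frame in series:
        img, spacing = extract_section(frame, section_axis, section_index)
        lumen_vals.append(roi_mean(img, spacing, lumen_roi))
        air_vals.append(roi_mean(img, spacing, air_roi))
    lumen_vals = np.array(lumen_vals)
    air_vals = np.array(air_vals)
    return TimeIntensityCurve(
        np.asarray(series.timestamps_min, dtype=float),
        lumen_vals - air_vals,
        lumen_means=lumen_vals,
        air_means=air_vals,
    )


@dataclass
class WashoutResult:
    """T1/2 of the contrast washout, with explicit censoring state."""

    t_peak_min: float
    peak_value: float
    t_cross_min: float | None
    t_half_min: float | None
    censored: bool


def compute_t_half(curve: TimeIntensityCurve) -> WashoutResult:
    """Threshold-crossing washout half-life.

    The peak is the earliest maximum of the normalized curve; the crossing
    is the earliest later sample whose value is strictly below half the
    peak. With no such sample inside the observation window the result is
    censored (a plateau at exactly half the peak never crosses).
    """
    if len(curve.values) < 2:
        raise ValueError("need at least two samples to compute T1/2")
    i_peak = int(np.argmax(curve.values))  # argmax returns the earliest tie
    t_peak = float(curve.times_min[i_peak])
    peak = float(curve.values[i_peak])
    after = curve.values[i_peak + 1 :]
    below = np.nonzero(after < peak / 2.0)[0]
    if len(below) == 0:
        return WashoutResult(t_peak, peak, None, None, censored=True)
    i_cross = i_peak + 1 + int(below[0])
    t_cross = float(curve.times_min[i_cross])
    return WashoutResult(t_peak, peak, t_cross, t_cross - t_peak, censored=False)


@dataclass
class CohortWashout:
    """Cohort mean ± SD of T1/2 over non-censored eyes."""

    mean_min: float
    sd_min: float
    n_used: int
    n_censored: int


def cohort_summary(results: list[WashoutResult]) -> CohortWashout:
    """Arithmetic mean and sample SD of T1/2; censored eyes counted, not imputed."""
    vals = np.array([r.t_half_min for r in results if not r.censored], dtype=float)
    n_cens = sum(r.censored for r in results)
    if vals.size == 0:
        raise ValueError("all results are censored: no T1/2 to summarize")
    sd = float(vals.std(ddof=1)) if vals.size > 1 else float("nan")
    return CohortWashout(float(vals.mean()), sd, int(vals.size), int(n_cens))
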