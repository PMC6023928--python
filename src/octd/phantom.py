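"""Synthetic OCT dacryography phantoms of the lacrimal canaliculus.

The phantom emulates a contrast-enhanced anterior-segment cube scan of the
medial eyelid: an air gap above a conjunctival surface, a flask-shaped
vertical canalicular segment opening at the punctum, a flat ribbon-shaped
horizontal segment running parallel to the surface, an epithelial shell
around the lumen and a muscle cuff around that. Lumen intensity follows a
rise-to-peak / exponential-washout time course, and every tissue class is
modulated by multiplicative unit-mean gamma speckle.

Raw OCT measures optical path length along the beam: a structure of physical
depth ``d`` spans ``n * d`` of raw axial scale below the surface (``n`` the
tissue refractive index). The phantom renders in that raw geometry, so the
standard refractive correction (divide the axial scale by ``n``) restores
physical sizes — ground-truth label volumes therefore carry the *corrected*
spacing, matching the grid on which all analysis runs.

Default geometry uses the healthy-cohort mean morphometry (vertical AP
356 µm; horizontal AP 143 µm, transverse 2900 µm; epithelium 89 µm) so that
recovering those numbers end-to-end is a meaningful test.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np
from scipy import ndimage

from .volume import OCTVolume, VolumeSeries, AcquisitionMetadata

__all__ = [
    "PhantomSpec",
    "LabelVolume",
    "LABELS",
    "build_geometry",
    "kinetics_curve",
    "render_frame",
    "generate_series",
    "save_series",
]

#: Integer label codes used by :class:`LabelVolume`.
LABELS = {"air": 0, "tissue": 1, "epithelium": 2, "lumen": 3, "muscle": 4}

ObstructionMode = Literal["none", "punctal", "canalicular"]


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic eye.

    Lengths are physical µm; intensities are arbitrary grayscale units in a
    nominal [0, 255] range. ``spacing_air`` is the raw (optical, in-air)
    voxel spacing; the default grid downsamples the instrument's 1024 × 400
    A-scan cube to 512 × 200 × 256 voxels while preserving the physical
    field of view (5 mm axial, 7 × 7 mm en face).
    """

    grid_shape: tuple[int, int, int] = (512, 200, 256)
    spacing_air: tuple[float, float, float] = (5000.0 / 512, 7000.0 / 200, 7000.0 / 256)
    refractive_index: float = 1.42
    conjunctiva_depth: float = 300.0  # raw (optical) µm of air above the surface

    # morphology (physical µm); defaults are the healthy-cohort means
    vertical_ap_diameter: float = 356.0
    vertical_length: float = 250.0  # depth of the horizontal lumen axis
    horizontal_ap_height: float = 143.0
    horizontal_transverse_width: float = 2900.0
    horizontal_length: float = 4000.0
    epithelium_thickness: float = 89.0
    flask_neck_radius: float = 50.0
    flask_max_radius: float = 300.0
    muscle_thickness: float = 150.0
    punctum_yx: tuple[float, float] = (3500.0, 1400.0)  # en-face position, µm

    # intensities (grayscale units); pre-contrast tears are transparent, so
    # the lumen baseline sits at the air level
    tissue_mean_intensity: float = 90.0
    epithelium_mean_intensity: float = 60.0
    muscle_mean_intensity: float = 75.0
    lumen_baseline_intensity: float = 10.0
    air_mean_intensity: float = 10.0
    air_noise_sigma: float = 2.0
    contrast_peak_intensity: float = 220.0

    # kinetics
    peak_time: float = 1.0  # min
    washout_half_life: float = 6.0  # min

    # noise / reproducibility
    speckle_shape: float = 4.0  # gamma shape; inf = noiseless
    rng_seed: int = 0

    # pathology
    obstruction_mode: ObstructionMode = "none"
    blind_extremity_depth: float = 259.0  # punctal mode only, physical µm

    def __post_init__(self) -> None:
        lengths = dict(
            vertical_ap_diameter=self.vertical_ap_diameter,
            vertical_length=self.vertical_length,
            horizontal_ap_height=self.horizontal_ap_height,
            horizontal_transverse_width=self.horizontal_transverse_width,
            horizontal_length=self.horizontal_length,
            epithelium_thickness=self.epithelium_thickness,
            conjunctiva_depth=self.conjunctiva_depth,
            washout_half_life=self.washout_half_life,
        )
        for name, v in lengths.items():
            if v <= 0:
                raise ValueError(f"{name} must be > 0 (got {v})")
        if self.air_mean_intensity >= self.tissue_mean_intensity:
            raise ValueError("air must be darker than tissue")
        if self.contrast_peak_intensity <= self.lumen_baseline_intensity:
            raise ValueError("contrast peak must exceed the lumen baseline")
        if self.peak_time < 0:
            raise ValueError("peak_time must be >= 0")
        if self.speckle_shape <= 0:
            raise ValueError("speckle_shape must be positive (use inf for noiseless)")
        if self.obstruction_mode not in ("none", "punctal", "canalicular"):
            raise ValueError(f"unknown obstruction_mode {self.obstruction_mode!r}")

    @property
    def spacing_corrected(self) -> tuple[float, float, float]:
        """Voxel spacing after the refractive axial correction (physical µm)."""
        dz, dy, dx = self.spacing_air
        return (dz / self.refractive_index, dy, dx)


@dataclass
class LabelVolume:
    """Ground-truth tissue labels on the rendered lattice.

    ``spacing`` is the refraction-corrected (physical) spacing, i.e. the
    grid every analysis stage works on after `correct_refraction`.
    """

    labels: np.ndarray  # uint8, codes from LABELS
    spacing: tuple[float, float, float]

    def mask(self, name: str) -> np.ndarray:
        return self.labels == LABELS[name]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]


def _axial_depth_um(spec: PhantomSpec) -> np.ndarray:
    """Physical tissue depth below the conjunctiva per axial index (<0 in air)."""
    nz = spec.grid_shape[0]
    dz_air = spec.spacing_air[0]
    z_opt = np.arange(nz) * dz_air
    return (z_opt - spec.conjunctiva_depth) / spec.refractive_index


def build_geometry(spec: PhantomSpec) -> LabelVolume:
    """Rasterize the canalicular geometry into a ground-truth label volume.

    The vertical segment is a flask: a solid of revolution below the punctum
    whose axial (anteroposterior) extent equals ``vertical_ap_diameter`` and
    whose en-face radius swells from the punctal neck to ``flask_max_radius``
    mid-depth. The horizontal segment is an elliptic-cross-section ribbon
    (axes ``horizontal_ap_height`` × ``horizontal_transverse_width``) centred
    ``vertical_length`` below the surface, running along the fast axis.

    ``punctal`` mode closes the punctum and shifts the lumen down so its
    shallowest point sits ``blind_extremity_depth`` below the conjunctiva;
    ``canalicular`` mode ends the horizontal lumen mid-course with a taper.
    """
    nz, ny, nx = spec.grid_shape
    dz_t, dy, dx = spec.spacing_corrected
    depth = _axial_depth_um(spec)  # (nz,)
    y_um = np.arange(ny) * dy
    x_um = np.arange(nx) * dx
    y0, x0 = spec.punctum_yx

    shift = spec.blind_extremity_depth if spec.obstruction_mode == "punctal" else 0.0
    v_ap = spec.vertical_ap_diameter
    ribbon_depth = spec.vertical_length + shift
    a_half = spec.horizontal_ap_height / 2.0
    t_half = spec.horizontal_transverse_width / 2.0

    # sizing checks against the physical extent of the grid
    max_depth_needed = max(shift + v_ap, ribbon_depth + a_half) + spec.epithelium_thickness
    depth_avail = depth[-1]
    msgs = []
    if max_depth_needed > depth_avail:
        msgs.append(
            f"axial: geometry needs {max_depth_needed:.0f} µm of tissue depth, "
            f"grid provides {depth_avail:.0f} µm"
        )
    margin = spec.epithelium_thickness + spec.muscle_thickness
    if y0 - max(spec.flask_max_radius, t_half) < -margin or y0 + max(
        spec.flask_max_radius, t_half
    ) > y_um[-1] + margin:
        msgs.append("slow axis: flask/ribbon transverse extent exceeds the grid")
    if x0 - spec.flask_max_radius < 0 or x0 + spec.horizontal_length > x_um[-1]:
        msgs.append(
            f"fast axis: punctum at {x0:.0f} µm plus horizontal length "
            f"{spec.horizontal_length:.0f} µm exceeds the {x_um[-1]:.0f} µm grid"
        )
    if msgs:
        raise ValueError("phantom geometry does not fit the grid: " + "; ".join(msgs))

    labels = np.where(depth >= 0, LABELS["tissue"], LABELS["air"]).astype(np.uint8)
    labels = np.broadcast_to(labels[:, None, None], (nz, ny, nx)).copy()

    # --- vertical (flask) segment -----------------------------------------
    u = (depth - shift) / v_ap  # 0 at flask top, 1 at flask bottom
    r_flask = np.where(
        (u >= 0) & (u <= 1),
        spec.flask_neck_radius
        + (spec.flask_max_radius - spec.flask_neck_radius) * np.sin(np.pi * np.clip(u, 0, 1)),
        -1.0,
    )
    rho2 = (y_um[:, None] - y0) ** 2 + (x_um[None, :] - x0) ** 2  # (ny, nx)
    lumen = rho2[None, :, :] <= np.where(r_flask > 0, r_flask**2, -1.0)[:, None, None]

    # --- horizontal (ribbon) segment --------------------------------------
    length = spec.horizontal_length
    if spec.obstruction_mode == "canalicular":
        length *= 0.55
    taper_zone = 600.0 if spec.obstruction_mode == "canalicular" else 0.0
    along = x_um - x0  # distance along the ribbon
    f = np.ones(nx)
    f[(along < 0) | (along > length)] = 0.0
    if taper_zone > 0:
        in_taper = (along > length - taper_zone) & (along <= length)
        f[in_taper] = (length - along[in_taper]) / taper_zone
    with np.errstate(divide="ignore", invalid="ignore"):
        ell = (
            ((depth[:, None, None] - ribbon_depth) / a_half) ** 2
            + ((y_um[None, :, None] - y0) / t_half) ** 2
        )
    ribbon = (f[None, None, :] > 0) & (ell <= f[None, None, :] ** 2)
    lumen |= ribbon
    lumen &= depth[:, None, None] >= 0  # never above the surface

    # --- epithelium shell and muscle cuff (cropped EDT for speed) ---------
    pad_um = spec.epithelium_thickness + spec.muscle_thickness + 3 * max(dz_t, dy, dx)
    idx = np.argwhere(lumen)
    lo = np.maximum(idx.min(0) - np.ceil(pad_um / np.array([dz_t, dy, dx])).astype(int), 0)
    hi = np.minimum(
        idx.max(0) + 1 + np.ceil(pad_um / np.array([dz_t, dy, dx])).astype(int),
        [nz, ny, nx],
    )
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    dist = ndimage.distance_transform_edt(~lumen[box], sampling=(dz_t, dy, dx))
    tissue_box = labels[box] == LABELS["tissue"]
    epi = (dist > 0) & (dist <= spec.epithelium_thickness) & tissue_box
    mus = (
        (dist > spec.epithelium_thickness)
        & (dist <= spec.epithelium_thickness + spec.muscle_thickness)
        & tissue_box
    )
    labels[box][mus] = LABELS["muscle"]
    labels[box][epi] = LABELS["epithelium"]
    labels[lumen] = LABELS["lumen"]
    return LabelVolume(labels, spec.spacing_corrected)


def kinetics_curve(t: float | np.ndarray, spec: PhantomSpec) -> float | np.ndarray:
    """Mean lumen intensity at time ``t`` minutes after contrast instillation.

    Linear rise from the baseline at t=0 to the peak at ``peak_time``, then
    exponential washout of the contrast component with ``washout_half_life``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    base = spec.lumen_baseline_intensity
    amp = spec.contrast_peak_intensity - base
    if spec.peak_time == 0:
        rise = np.full_like(t, spec.contrast_peak_intensity)
    else:
        rise = base + amp * t / spec.peak_time
    decay = base + amp * np.exp2(-(t - spec.peak_time) / spec.washout_half_life)
    out = np.where(t <= spec.peak_time, rise, decay)
    return float(out) if out.ndim == 0 else out


def render_frame(
    labels: LabelVolume,
    spec: PhantomSpec,
    t: float,
    seed: int | np.random.SeedSequence | None = None,
) -> OCTVolume:
    """Render one raw (air-referenced) volume at time ``t``.

    Every tissue class is its mean intensity times unit-mean gamma speckle
    of shape ``speckle_shape`` (infinite shape → noiseless); air gets additive
    Gaussian noise only. The long-run mean over any label therefore equals
    that label's mean intensity.
    """
    rng = np.random.default_rng(seed)
    means = np.zeros(5, dtype=np.float32)
    means[LABELS["air"]] = spec.air_mean_intensity
    means[LABELS["tissue"]] = spec.tissue_mean_intensity
    means[LABELS["epithelium"]] = spec.epithelium_mean_intensity
    means[LABELS["lumen"]] = float(kinetics_curve(t, spec))
    means[LABELS["muscle"]] = spec.muscle_mean_intensity
    mean_img = means[labels.labels]
    if math.isinf(spec.speckle_shape):
        vox = mean_img.astype(np.float32)
    else:
        k = spec.speckle_shape
        speckle = rng.gamma(k, 1.0 / k, size=labels.labels.shape).astype(np.float32)
        vox = mean_img * speckle
    air = labels.labels == LABELS["air"]
    if np.any(air):
        vox[air] = spec.air_mean_intensity + spec.air_noise_sigma * rng.standard_normal(
            int(air.sum())
        ).astype(np.float32)
    meta = AcquisitionMetadata(refractive_index=spec.refractive_index)
    return OCTVolume(vox, spec.spacing_air, medium="air-referenced", metadata=meta)


def generate_series(spec: PhantomSpec) -> tuple[VolumeSeries, LabelVolume]:
    """Generate the full acquisition: 11 frames at minutes 0..10 plus ground truth.

    Per-frame RNG streams are spawned from ``spec.rng_seed`` so the series is
    bit-reproducible for a given spec.
    """
    labels = build_geometry(spec)
    root = np.random.SeedSequence(spec.rng_seed)
    frames = [
        render_frame(labels, spec, float(t), seed=child)
        for t, child in zip(range(11), root.spawn(11))
    ]
    return VolumeSeries(frames, list(range(11))), labels


def save_series(
    series: VolumeSeries, labels: LabelVolume, spec: PhantomSpec, outdir: str | Path
) -> Path:
    """Write frames as ``frame_t{minute:02d}.tif``, labels, spec and a manifest."""
    import tifffile

    from .volume import write_volume

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    for t, frame in series:
        name = f"frame_t{int(t):02d}.tif"
        write_volume(frame, outdir / name)  # TIFF + spacing/medium sidecar
        files.append(name)
    tifffile.imwrite(outdir / "labels.tif", labels.labels, photometric="minisblack")
    (outdir / "phantom_spec.json").write_text(json.dumps(asdict(spec), indent=2))
    manifest = {
        "files": files,
        "labels": "labels.tif",
        "timestamps_min": series.timestamps_min,
        "spacing_air_um": list(spec.spacing_air),
        "spacing_corrected_um": list(spec.spacing_corrected),
        "medium": "air-referenced",
        "refractive_index": spec.refractive_index,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
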