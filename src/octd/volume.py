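"""Core OCT volume data model, TIFF I/O, and refractive-index axial correction.

Axis convention, fixed package-wide: voxel grids are indexed
``(axial, slow, fast)`` — axial is depth along the beam (rows of a B-scan),
slow is the B-scan index, fast is the A-scan index within a B-scan. Physical
coordinates are ``index * spacing`` at voxel centers, in micrometres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from scipy import ndimage

__all__ = [
    "AcquisitionMetadata",
    "OCTVolume",
    "VolumeSeries",
    "correct_refraction",
    "axial_resolution_in_tissue",
    "read_volume",
    "write_volume",
]

#: Media states for the axial scale of a volume.
AIR_REFERENCED = "air-referenced"
TISSUE_CORRECTED = "tissue-corrected"


@dataclass(frozen=True)
class AcquisitionMetadata:
    """Swept-source acquisition parameters, stored as provenance only.

    ``a_scan_rate`` / ``b_scan_rate`` are kept verbatim as strings: the
    stated rates are internally inconsistent with the stated cube-scan
    duration, so no computation may depend on them.
    """

    center_wavelength_nm: float = 1310.0
    sweep_range_nm: float = 96.0
    illumination_power_mw: float = 14.0
    a_scan_rate: str = "50 Hz (as stated)"
    b_scan_rate: str = "100 Hz (as stated)"
    refractive_index: float = 1.42
    axial_resolution_air_um: float = 13.0

    def __post_init__(self) -> None:
        if self.refractive_index < 1:
            raise ValueError("refractive_index must be >= 1")


@dataclass
class OCTVolume:
    """A 3D OCT scalar grid with voxel spacing in µm.

    Parameters
    ----------
    voxels : ndarray, shape (axial, slow, fast)
    spacing : (dz, dy, dx) in µm
    medium : "air-referenced" or "tissue-corrected"
    metadata : AcquisitionMetadata
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    medium: str = AIR_REFERENCED
    metadata: AcquisitionMetadata = field(default_factory=AcquisitionMetadata)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array (axial, slow, fast)")
        if min(self.voxels.shape) < 2:
            raise ValueError("every dimension must have at least 2 samples")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three strictly positive values (µm)")
        if self.medium not in (AIR_REFERENCED, TISSUE_CORRECTED):
            raise ValueError(f"unknown medium state: {self.medium!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical extent per axis (voxel-as-cell: n * spacing)."""
        return tuple(n * s for n, s in zip(self.voxels.shape, self.spacing))


@dataclass
class VolumeSeries:
    """Time-stamped OCT volumes on one shared grid (minutes post-instillation)."""

    frames: list[OCTVolume]
    timestamps_min: list[float]

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.timestamps_min):
            raise ValueError("frames and timestamps must have equal length")
        t = np.asarray(self.timestamps_min, dtype=float)
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.frames:
            ref = self.frames[0]
            for f in self.frames[1:]:
                if f.shape != ref.shape or f.spacing != ref.spacing:
                    raise ValueError("all frames must share shape and spacing")
        self.timestamps_min = [float(x) for x in t]

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(zip(self.timestamps_min, self.frames))


def correct_refraction(
    vol: OCTVolume, n: float = 1.42, *, resample: bool = False
) -> OCTVolume:
    """Correct the axial (incident-direction) scale for the tissue refractive index.

    The raw axial scale is an optical path length in air; dividing by the
    tissue refractive index ``n`` converts it to geometric length in tissue.
    By default this rescales the axial spacing (``dz -> dz / n``) and leaves
    voxel values untouched; with ``resample=True`` the volume is instead
    interpolated onto a grid with the original spacing covering the corrected
    extent (``round(nz / n)`` axial samples).

    Raises
    ------
    ValueError
        If the volume is already tissue-corrected (guards against dividing
        twice) or ``n < 1``.
    """
    if n < 1:
        raise ValueError("refractive index must be >= 1")
    if vol.medium == TISSUE_CORRECTED:
        raise ValueError(
            "volume is already tissue-corrected; refusing to divide the axial "
            "length by the refractive index twice"
        )
    dz, dy, dx = vol.spacing
    if not resample:
        return OCTVolume(vol.voxels, (dz / n, dy, dx), TISSUE_CORRECTED, vol.metadata)
    nz = vol.voxels.shape[0]
    nz_new = max(2, int(round(nz / n)))
    # sample the compressed physical extent at the original dz
    src_rows = np.arange(nz_new) * n
    coords = np.meshgrid(
        src_rows,
        np.arange(vol.voxels.shape[1]),
        np.arange(vol.voxels.shape[2]),
        indexing="ij",
    )
    out = ndimage.map_coordinates(
        vol.voxels.astype(np.float64), coords, order=1, mode="nearest"
    )
    return OCTVolume(out, (dz, dy, dx), TISSUE_CORRECTED, vol.metadata)


def axial_resolution_in_tissue(res_air_um: float, n: float) -> float:
    """Axial resolution in tissue: resolution in air divided by the refractive index."""
    if res_air_um <= 0:
        raise ValueError("axial resolution in air must be positive")
    if n < 1:
        raise ValueError("refractive index must be >= 1")
    return res_air_um / n


# ---------------------------------------------------------------------------
# TIFF + JSON-sidecar I/O


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json") if path.suffix != ".json" else path


def write_volume(vol: OCTVolume, path: str | Path) -> Path:
    """Write a volume as a multi-page grayscale TIFF plus a JSON sidecar.

    The sidecar carries shape, spacing (µm), medium state, dtype and
    acquisition metadata; the voxel round-trip is lossless.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, vol.voxels, photometric="minisblack")
    sidecar = {
        "shape": list(vol.voxels.shape),
        "spacing_um": list(vol.spacing),
        "medium": vol.medium,
        "dtype": str(vol.voxels.dtype),
        "metadata": asdict(vol.metadata),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def read_volume(
    path: str | Path, spacing_um: Sequence[float] | None = None
) -> OCTVolume:
    """Read a multi-page grayscale TIFF volume.

    Spacing comes from the JSON sidecar written by :func:`write_volume`, or
    must be supplied explicitly — it is never guessed.
    """
    path = Path(path)
    voxels = tifffile.imread(path)
    if voxels.ndim == 2:
        voxels = voxels[np.newaxis]
    if voxels.ndim != 3:
        raise ValueError(
            f"{path} is not a grayscale volume: page shape implies {voxels.ndim} dims"
        )
    sidecar = _sidecar_path(path)
    medium = AIR_REFERENCED
    metadata = AcquisitionMetadata()
    if sidecar.exists():
        info = json.loads(sidecar.read_text())
        if spacing_um is None:
            spacing_um = info.get("spacing_um")
        medium = info.get("medium", medium)
        if "metadata" in info:
            metadata = AcquisitionMetadata(**info["metadata"])
    if spacing_um is None or len(tuple(spacing_um)) != 3:
        raise ValueError(
            f"voxel spacing for {path} is unknown: provide spacing_um=(dz, dy, dx) "
            "in µm or a JSON sidecar with a 'spacing_um' entry"
        )
    return OCTVolume(voxels, tuple(spacing_um), medium, metadata)


def with_voxels(vol: OCTVolume, voxels: np.ndarray) -> OCTVolume:
    """A copy of ``vol`` carrying new voxel data on the same grid."""
    return replace(vol, voxels=voxels)
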