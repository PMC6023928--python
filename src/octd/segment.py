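"""Lumen extraction and 3D reconstruction.

The contrast-filled lumen is a high-intensity band that separates cleanly
from epithelium and tarsal tissue, so extraction is threshold-based: the
volume is lightly smoothed, a threshold is computed over sub-surface
(tissue) voxels, candidates are closed morphologically and the connected
component at the seed is kept. The conjunctival surface map provides the
reference for blind-extremity depth in punctal obstruction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import marching_cubes
import trimesh

from .volume import OCTVolume

__all__ = [
    "SurfaceMap",
    "LumenMask",
    "detect_surface",
    "segment_lumen",
    "reconstruct_mesh",
    "find_blind_extremity",
    "BlindExtremity",
]


@dataclass
class SurfaceMap:
    """Axial position (µm) of the conjunctival surface over the en-face plane."""

    heights_um: np.ndarray  # (slow, fast)
    enface_spacing: tuple[float, float]  # (dy, dx) µm
    valid: np.ndarray | None = None


@dataclass
class LumenMask:
    """Binary lumen mask on the volume lattice, with its extraction record."""

    mask: np.ndarray
    spacing: tuple[float, float, float]
    method_record: dict

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("lumen mask is empty")
        _, n = ndimage.label(self.mask, structure=np.ones((3, 3, 3), bool))
        if n != 1:
            raise ValueError(f"lumen mask must be a single connected component (got {n})")


def detect_surface(
    vol: OCTVolume, *, axial_sigma: float = 2.0, median_size: int = 3
) -> SurfaceMap:
    """Locate the air/conjunctiva interface per en-face position.

    Each A-scan is smoothed axially; the surface is the first sample whose
    intensity exceeds the midpoint between the air and tissue intensity
    levels (medians of the two Otsu classes of the whole volume). The height
    map is median-filtered to suppress speckle outliers.
    """
    vox = vol.voxels.astype(np.float32)
    sm = ndimage.gaussian_filter1d(vox, sigma=axial_sigma, axis=0)
    # air lies above tissue (precondition): read the air level off the top
    # rows and the tissue level off the bottom half of the volume
    top, bottom = sm[:3], sm[sm.shape[0] // 2 :]
    m_air, m_tis = float(np.median(top)), float(np.median(bottom))
    mad_air = float(np.median(np.abs(top - m_air)))
    mad_tis = float(np.median(np.abs(bottom - m_tis)))
    if m_tis - m_air <= 3.0 * (mad_air + mad_tis):
        raise ValueError(
            "no air/tissue contrast detected: the volume top and bottom have "
            "the same intensity level (is there air above the tissue?)"
        )
    midpoint = 0.5 * (m_air + m_tis)
    above = sm > midpoint
    # two consecutive supra-threshold samples: a single speckle-bled air
    # voxel must not trigger the surface early
    above = above[:-1] & above[1:]
    has = above.any(axis=0)
    idx = np.argmax(above, axis=0).astype(float)
    if has.mean() < 0.5 or np.median(idx[has]) < 2:
        raise ValueError(
            "no air/tissue interface: most A-scans exceed the air level at the "
            "volume top (is there air above the tissue?)"
        )
    fill = float(np.median(idx[has]))
    idx[~has] = fill
    idx = ndimage.median_filter(idx, size=median_size)
    dz = vol.spacing[0]
    return SurfaceMap(idx * dz, (vol.spacing[1], vol.spacing[2]), valid=has)


def segment_lumen(
    frame: OCTVolume,
    seed_voxel: tuple[int, int, int],
    method: str = "otsu-in-tissue",
    *,
    surface: SurfaceMap | None = None,
    smooth_sigma: float = 0.8,
    closing_radius: int = 1,
    quantile: float = 0.995,
    fixed_threshold: float | None = None,
    seed_search_radius_vox: float = 10.0,
) -> LumenMask:
    """Extract the contrast-filled lumen as a single connected component.

    ``method`` is one of ``otsu-in-tissue`` (Otsu over sub-surface voxels,
    the default), ``quantile`` (upper quantile of sub-surface voxels) or
    ``fixed`` (explicit ``fixed_threshold``). The frame is smoothed with a
    Gaussian of ``smooth_sigma`` voxels first; candidates are closed with a
    1-voxel-radius structuring element, then the component containing (or
    nearest, within 10 voxels of) the seed is kept. All parameters used are
    stored in ``method_record``.
    """
    if surface is None:
        surface = detect_surface(frame)
    dz = frame.spacing[0]
    surf_idx = np.round(surface.heights_um / dz).astype(int)

    sm = ndimage.gaussian_filter(frame.voxels.astype(np.float32), sigma=smooth_sigma)
    nz = frame.shape[0]
    subsurface = np.arange(nz)[:, None, None] >= surf_idx[None, :, :]
    tissue_vals = sm[subsurface]

    if method == "otsu-in-tissue":
        thr = float(threshold_otsu(tissue_vals))
        # the lumen occupies ~1% of tissue: if Otsu latched onto a split
        # between dark tissue classes instead, retry on the bright half
        if thr < float(np.quantile(tissue_vals, 0.75)):
            thr = float(threshold_otsu(tissue_vals[tissue_vals > np.median(tissue_vals)]))
    elif method == "quantile":
        thr = float(np.quantile(tissue_vals, quantile))
    elif method == "fixed":
        if fixed_threshold is None:
            raise ValueError("method='fixed' requires fixed_threshold")
        thr = float(fixed_threshold)
    else:
        raise ValueError(f"unknown segmentation method {method!r}")

    cand = (sm > thr) & subsurface
    if not cand.any():
        raise ValueError(f"threshold {thr:.1f} leaves no candidate voxels")
    structure = ndimage.generate_binary_structure(3, 1)  # radius-1 ball
    cand = ndimage.binary_closing(cand, structure=structure, iterations=closing_radius)

    comps, _ = ndimage.label(cand, structure=np.ones((3, 3, 3), bool))
    seed = np.asarray(seed_voxel)
    in_bounds = all(0 <= s < n for s, n in zip(seed, cand.shape))
    if in_bounds and comps[tuple(seed)] > 0:
        comp_id = comps[tuple(seed)]
    else:
        fg = np.argwhere(cand)
        d = np.linalg.norm(fg - seed, axis=1)
        j = int(np.argmin(d))
        if d[j] > seed_search_radius_vox:
            raise ValueError(
                f"no lumen component near the seed: nearest candidate voxel is "
                f"{d[j]:.1f} voxels away (limit {seed_search_radius_vox})"
            )
        comp_id = comps[tuple(fg[j])]
    mask = comps == comp_id
    record = {
        "method": method,
        "threshold": thr,
        "smooth_sigma_vox": smooth_sigma,
        "closing_radius_vox": closing_radius,
        "seed_voxel": [int(s) for s in seed],
        "quantile": quantile if method == "quantile" else None,
    }
    return LumenMask(mask, frame.spacing, record)


def reconstruct_mesh(mask: LumenMask) -> trimesh.Trimesh:
    """Marching-cubes isosurface of the mask at level 0.5, vertices in µm.

    The mask is zero-padded by one voxel so components touching the volume
    boundary are capped (the mesh is always watertight up to the grid edge).
    """
    padded = np.pad(mask.mask, 1).astype(np.float32)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=mask.spacing)
    verts = verts - np.asarray(mask.spacing)
    # marching_cubes orients faces inward for a bright interior: flip for
    # outward normals (positive enclosed volume)
    return trimesh.Trimesh(vertices=verts, faces=faces[:, ::-1], process=False)


@dataclass
class BlindExtremity:
    """Depth of the shallowest lumen point below the conjunctival surface."""

    depth_um: float
    location_enface_um: tuple[float, float]  # (slow, fast)
    open_punctum: bool


def find_blind_extremity(mask: LumenMask, surface: SurfaceMap) -> BlindExtremity:
    """Depth (µm, along the axial direction) from the conjunctiva to the lumen.

    Returns the axial distance between the shallowest lumen voxel and the
    surface height directly above it. A lumen reaching to within 1.5 axial
    voxels of the surface is reported as an open punctum with depth 0 (the
    surface row and the lumen top row each quantize by up to one voxel).
    """
    dz, dy, dx = mask.spacing
    idx = np.argwhere(mask.mask)
    depths = idx[:, 0] * dz - surface.heights_um[idx[:, 1], idx[:, 2]]
    j = int(np.argmin(depths))
    loc = (idx[j, 1] * dy, idx[j, 2] * dx)
    depth = float(depths[j])
    if depth < 1.5 * dz:
        return BlindExtremity(0.0, loc, open_punctum=True)
    return BlindExtremity(depth, loc, open_punctum=False)
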