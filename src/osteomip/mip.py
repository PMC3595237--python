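"""Surface detection, articular masking, and subchondral maximum intensity projection.

The projection is orthographic along a grid axis: specimens are assumed
scanned with the bone's longitudinal axis perpendicular to the scan plane, so
the plafond — the horizontally oriented part of the joint surface — projects
cleanly onto the slice grid.  Regions of the articular surface that descend
steeply (the medial malleolus facet) are removed from the mask by a surface
inclination threshold, since such near-vertical surface is not loaded in
axial compression and would contaminate the pixel-count ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import DensityVolume

__all__ = [
    "SurfaceField",
    "ArticularMask",
    "MipMap",
    "detect_surface",
    "articular_mask",
    "project_mip",
    "rescale_to_8bit",
]

#: sentinel stored at unmasked MIP pixels; outside any radiodensity range used
MIP_SENTINEL = -1.0


@dataclass
class SurfaceField:
    """First-bone depth along the line of sight, per projected column.

    depth : (nx, ny) depth of the first bone voxel in mm (NaN where invalid)
    valid : (nx, ny) bool, True where the column intersects bone
    spacing : in-plane spacing (mm) of the projected grid, then axial spacing
    smoothed : whether a 3x3 median filter was applied to depth
    """

    depth: np.ndarray
    valid: np.ndarray
    spacing: tuple[float, float, float]
    smoothed: bool = False


@dataclass
class ArticularMask:
    """Columns retained for analysis, with the parameters that produced them."""

    mask: np.ndarray
    max_inclination_deg: float
    min_component_px: int


@dataclass
class MipMap:
    """Projected maxima over the articular mask.

    values : (nx, ny); ``MIP_SENTINEL`` (or 0 after 8-bit rescale) off-mask
    mask : the ArticularMask the values are defined on
    depth_used : subchondral depth window in mm
    truncated : bool grid, True where the window was clipped at the volume end
    window : (lo, hi) once rescaled to 8 bits, else None
    """

    values: np.ndarray
    mask: ArticularMask
    depth_used: float
    truncated: np.ndarray | None = None
    window: tuple[float, float] | None = None


def detect_surface(
    volume: DensityVolume,
    bone_threshold: float,
    smooth: bool = True,
) -> SurfaceField:
    """Locate the articular surface as the first supra-threshold voxel per column.

    Walking each projected column along the projection axis, the surface depth
    is (first index with value >= bone_threshold) x axial spacing.  Columns
    that never reach the threshold are marked invalid.  A 3x3 median filter
    (on by default) suppresses single-voxel spikes in the depth field; whether
    it ran is recorded on the result.
    """
    vol = volume.oriented()
    vals = vol.values
    dz = vol.spacing[0]

    above = vals >= bone_threshold
    valid = above.any(axis=0)
    first = above.argmax(axis=0)  # 0 where no voxel passes; masked by `valid`
    depth = first.astype(float) * dz
    if smooth and valid.any():
        filled = np.where(valid, depth, np.nanmax(depth[valid]))
        depth = ndimage.median_filter(filled, size=3)
    depth = np.where(valid, depth, np.nan)
    return SurfaceField(
        depth=depth,
        valid=valid,
        spacing=(vol.spacing[1], vol.spacing[2], dz),
        smoothed=smooth,
    )


def articular_mask(
    surface: SurfaceField,
    max_inclination_deg: float = 45.0,
    min_component_px: int = 8,
    largest_only: bool = False,
) -> ArticularMask:
    """Build the analysis mask, excluding steep (malleolar) surface.

    The local surface gradient is taken by central differences on the depth
    field (mm per mm); a column is kept when the corresponding inclination
    from horizontal, atan(|grad|), is at most ``max_inclination_deg``.
    Connected components smaller than ``min_component_px`` are dropped, so
    isolated threshold crossings do not speckle the mask; this keeps the mask
    monotone in the threshold (relaxing it never removes a pixel).
    ``largest_only=True`` additionally restricts to the single largest
    component, for specimens where a second joint facet survives the
    inclination cut.
    """
    if not surface.valid.any():
        warnings.warn("surface has no valid columns; mask is empty")
        return ArticularMask(
            mask=np.zeros_like(surface.valid),
            max_inclination_deg=max_inclination_deg,
            min_component_px=min_component_px,
        )
    dx, dy = surface.spacing[0], surface.spacing[1]
    depth = np.where(surface.valid, surface.depth, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        gx, gy = np.gradient(depth, dx, dy)
        grad_mag = np.hypot(gx, gy)
        incl = np.degrees(np.arctan(grad_mag))
    keep = surface.valid & np.isfinite(incl) & (incl <= max_inclination_deg)

    if keep.any():
        labels, n = ndimage.label(keep)
        sizes = ndimage.sum_labels(np.ones_like(labels, dtype=float), labels,
                                   index=range(1, n + 1))
        big = [i + 1 for i, s in enumerate(sizes) if s >= min_component_px]
        if big and largest_only:
            big = [big[int(np.argmax([sizes[i - 1] for i in big]))]]
        keep = np.isin(labels, big) if big else np.zeros_like(keep)
    if not keep.any():
        warnings.warn("no column satisfies the inclination threshold; mask is empty")
    return ArticularMask(
        mask=keep,
        max_inclination_deg=max_inclination_deg,
        min_component_px=min_component_px,
    )


def project_mip(
    volume: DensityVolume,
    surface: SurfaceField,
    mask: ArticularMask,
    depth_mm: float = 3.0,
) -> MipMap:
    """Maximum intensity projection through the subchondral depth window.

    For each masked column, the value is the maximum voxel in
    [surface_depth, surface_depth + depth_mm] along the line of sight.  If
    the window runs off the end of the volume it is truncated and the pixel
    flagged.  Unmasked pixels hold a sentinel outside the data range.
    """
    if depth_mm <= 0:
        raise ValueError("depth_mm must be positive")
    vol = volume.oriented()
    vals = vol.values
    nz = vals.shape[0]
    dz = vol.spacing[0]

    m = mask.mask & surface.valid
    start = np.zeros(m.shape, dtype=int)
    start[m] = np.rint(surface.depth[m] / dz).astype(int)
    n_win = int(np.floor(depth_mm / dz)) + 1
    stop = start + n_win  # exclusive
    truncated = m & (stop > nz)
    stop = np.minimum(stop, nz)

    z = np.arange(nz)[:, None, None]
    in_window = (z >= start[None]) & (z < stop[None]) & m[None]
    stack = np.where(in_window, vals, -np.inf)
    out = stack.max(axis=0)
    values = np.where(m, out, MIP_SENTINEL)
    return MipMap(
        values=values,
        mask=ArticularMask(m, mask.max_inclination_deg, mask.min_component_px),
        depth_used=depth_mm,
        truncated=truncated,
    )


def rescale_to_8bit(mip: MipMap, window_lo: float, window_hi: float) -> MipMap:
    """Linearly window a MIP to 8-bit gray values 0-255.

    v -> round(255 * (v - lo) / (hi - lo)), round-half-up, clamped to
    [0, 255].  The window is fixed per study, not fitted per specimen: only
    an absolute scale shared across specimens lets a specimen have an empty
    top bin (a max/total ratio of exactly 0).
    """
    if not window_lo < window_hi:
        raise ValueError(f"degenerate window [{window_lo}, {window_hi}]")
    m = mip.mask.mask
    scaled = 255.0 * (mip.values - window_lo) / (window_hi - window_lo)
    scaled = np.floor(scaled + 0.5)  # round half up
    scaled = np.clip(scaled, 0, 255)
    values = np.where(m, scaled, 0).astype(np.uint8)
    return MipMap(
        values=values,
        mask=mip.mask,
        depth_used=mip.depth_used,
        truncated=mip.truncated,
        window=(window_lo, window_hi),
    )
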