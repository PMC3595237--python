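"""Synthetic epiphysis phantoms and ratio datasets.

Real subjects of this kind of study are museum CT scans of distal limb-bone
epiphyses.  The phantom generator builds a volume with the features the
downstream pipeline relies on: a quasi-horizontal articular surface described
by a smooth height field, a thin subchondral plate whose surface density
carries localized high-density patches, trabecular filler below the plate,
and an optional steep-walled "malleolus" flange that the articular mask is
expected to exclude.  Alongside the volume it returns the exact ground truth
(surface depth, articular mask, noise-free surface density) so every imaging
stage can be checked against construction.

Radiodensity units are abstract rather than calibrated Hounsfield units: the
downstream analysis windows values to 8 bits with one fixed study-wide
window, mirroring analyses that pool scanners with differing calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import DensityVolume

__all__ = [
    "DensityPatch",
    "MalleolusSpec",
    "PhantomSpec",
    "GroundTruth",
    "GroupSpec",
    "generate_epiphysis_phantom",
    "generate_ratio_dataset",
]


class InvalidSpecError(ValueError):
    """Raised when a phantom specification violates its invariants."""


@dataclass(frozen=True)
class DensityPatch:
    """Circular high-density patch on the subchondral plate.

    center : (x, y) in voxel units of the projected grid
    radius_mm : patch radius in mm
    peak_value : plate surface density inside the patch (>= plate base)
    """

    center: tuple[float, float]
    radius_mm: float
    peak_value: float


@dataclass(frozen=True)
class MalleolusSpec:
    """Steep flange descriptor: a strip of the surface that drops away.

    The flange occupies ``x >= position`` (projected-grid rows); across
    ``width_mm`` the surface descends ``drop_depth_mm`` toward the viewer,
    producing a wall whose inclination greatly exceeds any plausible
    plafond slope.
    """

    position: int
    width_mm: float
    drop_depth_mm: float


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic distal-epiphysis volume.

    ``grid_shape`` is (nz, nx, ny) with axis 0 the line of sight
    (distal -> proximal); ``voxel_spacing`` is mm per axis in the same
    order.  ``surface_profile`` is (z0_mm, slope_x, slope_y, curv) of the
    height field  z(x,y) = z0 + sx*x + sy*y + curv*(x^2 + y^2)  in mm,
    with x, y centred voxel coordinates.
    """

    grid_shape: tuple[int, int, int] = (48, 40, 40)
    voxel_spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    surface_profile: tuple[float, float, float, float] = (4.0, 0.0, 0.0, 0.0)
    plate_thickness: float = 3.0
    density_patches: tuple[DensityPatch, ...] = ()
    background_value: float = 0.0
    trabecular_value: float = 60.0
    plate_base_value: float = 100.0
    malleolus: MalleolusSpec | None = None
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(s) <= 0 for s in self.grid_shape) or len(self.grid_shape) != 3:
            raise InvalidSpecError(f"grid_shape must be 3 positive ints, got {self.grid_shape}")
        if any(s <= 0 for s in self.voxel_spacing):
            raise InvalidSpecError(f"voxel_spacing must be positive, got {self.voxel_spacing}")
        if self.plate_thickness <= 0:
            raise InvalidSpecError("plate_thickness must be positive")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be non-negative")
        for p in self.density_patches:
            if p.radius_mm <= 0:
                raise InvalidSpecError("patch radius must be positive")
            if p.peak_value < self.plate_base_value:
                raise InvalidSpecError("patch peak below plate base value")
        if self.malleolus is not None and (
            self.malleolus.width_mm <= 0 or self.malleolus.drop_depth_mm <= 0
        ):
            raise InvalidSpecError("malleolus width and drop depth must be positive")


@dataclass
class GroundTruth:
    """Noise-free construction record for one phantom.

    surface_depth : (nx, ny) first-bone depth per column, mm
    articular_mask_true : (nx, ny) bool, True on the plafond (flange excluded)
    surface_density_true : (nx, ny) max plate density per column, noise-free
    """

    surface_depth: np.ndarray
    articular_mask_true: np.ndarray
    surface_density_true: np.ndarray


def _surface_depth_field(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Return (depth_mm, flange_mask) on the (nx, ny) projected grid."""
    _, nx, ny = spec.grid_shape
    z0, sx, sy, curv = spec.surface_profile
    x = (np.arange(nx) - (nx - 1) / 2.0) * spec.voxel_spacing[1]
    y = (np.arange(ny) - (ny - 1) / 2.0) * spec.voxel_spacing[2]
    xx, yy = np.meshgrid(x, y, indexing="ij")
    depth = z0 + sx * xx + sy * yy + curv * (xx**2 + yy**2)

    flange = np.zeros((nx, ny), dtype=bool)
    if spec.malleolus is not None:
        m = spec.malleolus
        x_abs = np.arange(nx)[:, None] * np.ones((1, ny))
        ramp = (x_abs - m.position) * spec.voxel_spacing[1]  # mm past flange start
        in_flange = ramp >= 0
        # surface descends toward the viewer across the flange width
        drop = np.clip(ramp / m.width_mm, 0.0, 1.0) * m.drop_depth_mm
        depth = np.where(in_flange, depth - drop, depth)
        flange = in_flange
    nz = spec.grid_shape[0]
    max_depth = (nz - 1) * spec.voxel_spacing[0]
    depth = np.clip(depth, spec.voxel_spacing[0], max_depth - spec.plate_thickness)
    return depth, flange


def _surface_density_field(spec: PhantomSpec) -> np.ndarray:
    """Plate surface density per column: base value plus patch peaks."""
    _, nx, ny = spec.grid_shape
    density = np.full((nx, ny), float(spec.plate_base_value))
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    for p in spec.density_patches:
        cx, cy = p.center
        r2 = ((xx - cx) * spec.voxel_spacing[1]) ** 2 + ((yy - cy) * spec.voxel_spacing[2]) ** 2
        density = np.where(r2 <= p.radius_mm**2, np.maximum(density, p.peak_value), density)
    return density


def generate_epiphysis_phantom(spec: PhantomSpec) -> tuple[DensityVolume, GroundTruth]:
    """Build a phantom volume and its ground truth.

    Along every (x, y) column the volume is background above the surface,
    plate material (at the column's surface density) within
    ``plate_thickness`` below it, and trabecular filler beneath.  Gaussian
    noise of ``spec.noise_sd`` is added everywhere when requested; with the
    same spec and seed the volume is bit-identical on regeneration.
    """
    depth_mm, flange = _surface_depth_field(spec)
    density = _surface_density_field(spec)
    nz, nx, ny = spec.grid_shape
    dz = spec.voxel_spacing[0]

    z_mm = np.arange(nz)[:, None, None] * dz
    below = z_mm >= depth_mm[None, :, :]
    in_plate = below & (z_mm < (depth_mm + spec.plate_thickness)[None, :, :])

    values = np.full(spec.grid_shape, float(spec.background_value))
    values[below] = spec.trabecular_value
    values = np.where(in_plate, density[None, :, :], values)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)

    volume = DensityVolume(values=values, spacing=spec.voxel_spacing, projection_axis=0)
    truth = GroundTruth(
        surface_depth=depth_mm,
        articular_mask_true=~flange,
        surface_density_true=density,
    )
    return volume, truth


@dataclass(frozen=True)
class GroupSpec:
    """Gait-group distribution of a pixel ratio: label, n, mean, SD."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.mean <= 1.0):
            raise InvalidSpecError(f"mean must be in [0,1], got {self.mean}")
        if self.sd < 0:
            raise InvalidSpecError("sd must be non-negative")
        if self.n < 1:
            raise InvalidSpecError("n must be >= 1")


def generate_ratio_dataset(groups: list[GroupSpec], seed: int = 0) -> "pd.DataFrame":
    """Draw per-specimen ratios from truncated normal group distributions.

    For each group, ``n`` draws from Normal(mean, sd) truncated to [0, 1]
    by rejection (ratios are bounded; observed values sit near 0).  Returns
    a tidy DataFrame with columns specimen_id, gait, value.
    """
    import pandas as pd

    if not groups:
        raise InvalidSpecError("groups must be non-empty")
    rng = np.random.default_rng(seed)
    rows = []
    for g in groups:
        if g.sd == 0:
            draws = np.full(g.n, g.mean)
        else:
            draws = np.empty(g.n)
            filled = 0
            while filled < g.n:
                cand = rng.normal(g.mean, g.sd, size=2 * (g.n - filled) + 8)
                cand = cand[(cand >= 0.0) & (cand <= 1.0)]
                take = min(len(cand), g.n - filled)
                draws[filled : filled + take] = cand[:take]
                filled += take
        for i, v in enumerate(draws):
            rows.append({"specimen_id": f"{g.label}-{i:03d}", "gait": g.label, "value": float(v)})
    return pd.DataFrame(rows)
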