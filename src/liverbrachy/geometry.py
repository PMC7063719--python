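"""Voxel phantoms: grids, HU-threshold tissue segmentation, structure
overrides, slice interpolation and contour rasterization.

Conventions
-----------
* Grids are axis-aligned; ``values`` has shape ``(nx, ny, nz)``; ``origin``
  is the centre of voxel (0, 0, 0) in mm; indices are 0-based.
* Segmentation bands are half-open ``[lower, upper)`` in HU:
  air [-1024, -900), lung [-900, -199), adipose [-199, 0),
  soft tissue [0, 201), cortical bone [201, inf).  HU below -1024 is
  clamped to air, HU above 2000 is still called cortical bone; both emit a
  warning.
* A contour voxel belongs to a structure iff its centre lies inside the
  slice polygon (even-odd rule).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .physics_data import Material, load_material

__all__ = [
    "VoxelGrid",
    "SegmentedPhantom",
    "StructureSet",
    "segment_hu",
    "apply_override",
    "interpolate_slices",
    "rasterize_contours",
    "HU_BAND_EDGES",
    "SEGMENTATION_TISSUES",
]

# Half-open band edges (HU); values below the first edge are air.
HU_BAND_EDGES = np.array([-900.0, -199.0, 0.0, 201.0])
SEGMENTATION_TISSUES = ("air", "lung", "adipose", "soft_tissue", "cortical_bone")

HU_MIN, HU_MAX_ASSIGNED = -1024.0, 2000.0


@dataclass
class VoxelGrid:
    """A scalar field on a regular axis-aligned voxel grid."""

    values: np.ndarray  # (nx, ny, nz)
    spacing: np.ndarray  # mm per axis
    origin: np.ndarray = None  # mm, centre of voxel (0,0,0)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive on all axes")
        if self.origin is None:
            self.origin = np.zeros(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def shape(self):
        return self.values.shape

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-centre coordinates along one axis, mm."""
        n = self.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def same_geometry(self, other: "VoxelGrid") -> bool:
        return (self.shape == other.shape
                and np.allclose(self.spacing, other.spacing)
                and np.allclose(self.origin, other.origin))

    def with_values(self, values: np.ndarray) -> "VoxelGrid":
        return VoxelGrid(values, self.spacing.copy(), self.origin.copy())


@dataclass
class SegmentedPhantom:
    """Material-index and density grids plus the material list."""

    material_index: VoxelGrid  # integer values
    density: VoxelGrid  # g/cm^3
    materials: list  # ordered Material list

    def __post_init__(self):
        idx = self.material_index.values
        if idx.min() < 0 or idx.max() >= len(self.materials):
            raise ValueError("material index out of range")

    def material_name_grid(self) -> np.ndarray:
        names = np.array([m.name for m in self.materials])
        return names[self.material_index.values]


@dataclass
class StructureSet:
    """Named binary masks sharing the phantom grid, with clinical roles."""

    masks: dict  # name -> VoxelGrid (bool values)
    roles: dict = field(default_factory=dict)  # name -> "liver"|"CTV"|"OAR:<type>"|"body"

    def aligned(self, grid: VoxelGrid) -> bool:
        return all(m.same_geometry(grid) for m in self.masks.values())

    def by_role(self, role_prefix: str) -> dict:
        return {n: m for n, m in self.masks.items()
                if self.roles.get(n, "").startswith(role_prefix)}


def _segmentation_materials(patient_sex: str) -> list:
    if patient_sex not in ("male", "female"):
        raise ValueError("patient_sex must be 'male' or 'female'")
    soft = f"soft_tissue_{patient_sex}"
    return [load_material(n)
            for n in ("air", "lung", "adipose", soft, "cortical_bone")]


def segment_hu(hu: VoxelGrid, patient_sex: str = "male") -> SegmentedPhantom:
    """Assign a reference tissue to every voxel from its HU value.

    The soft-tissue band resolves to the male or female variant
    (1.03 vs 1.02 g/cm^3) according to ``patient_sex``.  Pure function of
    (HU, sex): repeated calls yield identical phantoms.
    """
    values = np.asarray(hu.values, dtype=float)
    if np.any(values < HU_MIN):
        warnings.warn(f"HU below {HU_MIN:g} clamped to air", stacklevel=2)
        values = np.maximum(values, HU_MIN)
    if np.any(values > HU_MAX_ASSIGNED):
        warnings.warn(
            f"HU above {HU_MAX_ASSIGNED:g} assigned to cortical bone",
            stacklevel=2)
    materials = _segmentation_materials(patient_sex)
    index = np.searchsorted(HU_BAND_EDGES, values, side="right").astype(np.int16)
    densities = np.array([m.density for m in materials])
    return SegmentedPhantom(
        material_index=hu.with_values(index),
        density=hu.with_values(densities[index]),
        materials=materials,
    )


def apply_override(phantom: SegmentedPhantom, mask: VoxelGrid,
                   material: Material) -> SegmentedPhantom:
    """Reassign all voxels under ``mask`` to ``material``.

    Used for the liver (homogeneous reference liver regardless of HU) and
    for contrast-corrupted organ voxels (reset to soft tissue).  Returns a
    new phantom; the input is untouched.
    """
    if not mask.same_geometry(phantom.material_index):
        raise ValueError("override mask is not aligned with the phantom grid")
    m = np.asarray(mask.values, dtype=bool)
    materials = list(phantom.materials)
    try:
        mat_idx = next(i for i, existing in enumerate(materials)
                       if existing.name == material.name
                       and existing.density == material.density)
    except StopIteration:
        materials.append(material)
        mat_idx = len(materials) - 1
    index = phantom.material_index.values.copy()
    dens = phantom.density.values.copy()
    index[m] = mat_idx
    dens[m] = material.density
    return SegmentedPhantom(
        material_index=phantom.material_index.with_values(index),
        density=phantom.density.with_values(dens),
        materials=materials,
    )


def interpolate_slices(grid: VoxelGrid, target_z_spacing: float,
                       binary: bool = False) -> VoxelGrid:
    """Linearly resample along the slice (z) axis to a finer spacing.

    In-plane sampling is untouched; first and last slice positions are
    preserved.  With ``binary=True`` the interpolated field is thresholded
    at 0.5 (for structure masks).
    """
    if target_z_spacing <= 0:
        raise ValueError("target z spacing must be positive")
    sz = grid.spacing[2]
    if target_z_spacing > sz + 1e-9:
        raise ValueError(
            f"target spacing {target_z_spacing} mm coarser than source {sz} mm")
    nz = grid.shape[2]
    if nz == 1 or abs(target_z_spacing - sz) < 1e-12:
        return grid.with_values(np.asarray(grid.values).copy())
    span = sz * (nz - 1)
    n_new = int(round(span / target_z_spacing)) + 1
    # index coordinates of the new slices in the old slice axis
    zi = np.linspace(0.0, nz - 1.0, n_new)
    lo = np.floor(zi).astype(int)
    hi = np.minimum(lo + 1, nz - 1)
    w = zi - lo
    vals = np.asarray(grid.values, dtype=float)
    out = vals[:, :, lo] * (1.0 - w) + vals[:, :, hi] * w
    if binary:
        out = out >= 0.5
    new_spacing = np.array([grid.spacing[0], grid.spacing[1],
                            span / (n_new - 1)])
    return VoxelGrid(out, new_spacing, grid.origin.copy())


def _point_in_polygon(px, py, poly):
    """Even-odd rule test, vectorised over points."""
    inside = np.zeros(px.shape, dtype=bool)
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        crosses = (y1 > py) != (y2 > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (px < xint)
    return inside


def rasterize_contours(contours, grid: VoxelGrid) -> VoxelGrid:
    """Binary mask from per-slice closed polygons.

    ``contours`` is a list of ``{"z_mm": float, "points": [[x, y], ...]}``
    entries in mm.  Each polygon is assigned to the nearest slice; several
    polygons on one slice combine by the even-odd rule (holes supported).
    A polygon needs at least three vertices; an explicitly closed polygon
    (first point repeated) is accepted.
    """
    mask = np.zeros(grid.shape, dtype=bool)
    xs = grid.axis_coords(0)
    ys = grid.axis_coords(1)
    zs = grid.axis_coords(2)
    px, py = np.meshgrid(xs, ys, indexing="ij")
    for entry in contours:
        pts = np.asarray(entry["points"], dtype=float)
        if len(pts) >= 2 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) < 3:
            raise ValueError("polygon must have at least 3 distinct vertices")
        k = int(np.argmin(np.abs(zs - entry["z_mm"])))
        if abs(zs[k] - entry["z_mm"]) > grid.spacing[2] / 2 + 1e-9:
            continue  # contour plane outside the grid
        mask[:, :, k] ^= _point_in_polygon(px, py, pts)
    return grid.with_values(mask)


def structure_volume_cm3(mask: VoxelGrid) -> float:
    """Structure volume from voxel count times voxel volume."""
    return float(np.count_nonzero(mask.values)) * mask.voxel_volume_cm3
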