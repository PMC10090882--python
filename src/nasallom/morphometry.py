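"""Voxel and mesh morphometry: label volumes, isosurface areas, hulls.

Conventions
-----------
* Grid axes are ordered (x, y, z) with x the rostrocaudal axis.
* Voxel-centre coordinates: world = origin + (index + 0.5) * spacing.
* Surface areas are measured on a marching-cubes isosurface of the label's
  indicator field after a light Gaussian smoothing (sigma = 1 voxel), which
  removes the systematic staircase over-estimate of binary isosurfaces; for
  structures thin enough that smoothing erases them the raw binary
  isosurface is used instead.  The method constant for a single 1-mm voxel
  is the octahedron through the half-way isolevel crossings, area sqrt(3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.ndimage import gaussian_filter
from scipy.spatial import ConvexHull, QhullError
from skimage import measure

__all__ = [
    "DEFAULT_LABELS",
    "DegenerateHullError",
    "EmptyRegionError",
    "LabelNotFoundError",
    "LabeledVolume",
    "NonWatertightMeshError",
    "SurfaceMesh",
    "convex_hull_volume",
    "label_surface_area",
    "label_volume",
    "measure_specimen",
    "mesh_volume",
]

DEFAULT_LABELS = {"background": 0, "bone": 1, "main_airway": 2, "olfactory": 3}

SMOOTH_SIGMA_VOXELS = 1.0


class LabelNotFoundError(KeyError):
    pass


class EmptyRegionError(ValueError):
    pass


class NonWatertightMeshError(ValueError):
    pass


class DegenerateHullError(ValueError):
    pass


@dataclass
class LabeledVolume:
    """A 3D integer label map with anisotropic voxel spacing in mm."""

    grid: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    labels: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_LABELS))

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError("grid must be 3-dimensional")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise ValueError("grid must hold integer labels")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive on all axes")
        if any(v < 0 for v in self.labels.values()):
            raise ValueError("label values must be non-negative")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def label_value(self, name: str) -> int:
        try:
            return self.labels[name]
        except KeyError:
            raise LabelNotFoundError(
                f"label {name!r} not in table {sorted(self.labels)}"
            ) from None

    def mask(self, *names: str) -> np.ndarray:
        """Boolean mask of the union of the named labels."""
        m = np.zeros(self.grid.shape, dtype=bool)
        for name in names:
            m |= self.grid == self.label_value(name)
        return m

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.asarray(self.origin, dtype=float)
        hi = lo + np.asarray(self.grid.shape) * np.asarray(self.spacing)
        return lo, hi

    def voxel_centers(self) -> list[np.ndarray]:
        """Per-axis world coordinates of voxel centres (broadcastable)."""
        idx = np.indices(self.grid.shape, dtype=float)
        return [
            (idx[k] + 0.5) * self.spacing[k] + self.origin[k] for k in range(3)
        ]


@dataclass
class SurfaceMesh:
    """A triangle mesh in mm coordinates."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face indices out of range")

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)


def label_volume(vol: LabeledVolume, label: str) -> float:
    """Volume (mm^3) of a label: voxel count times the voxel volume."""
    return float(vol.mask(label).sum()) * vol.voxel_volume


def _mask_surface_mesh(mask: np.ndarray, spacing, sigma=SMOOTH_SIGMA_VOXELS):
    pad = np.pad(mask, 2).astype(float)
    field_ = gaussian_filter(pad, sigma) if sigma else pad
    if field_.max() <= 0.5:
        field_ = pad  # structure too thin for smoothing; use the binary field
    verts, faces, _, _ = measure.marching_cubes(field_, level=0.5, spacing=tuple(spacing))
    return verts, faces


def label_surface_area(vol: LabeledVolume, label: str, *names: str) -> float:
    """Isosurface area (mm^2) of the boundary of a label (or label union)."""
    mask = vol.mask(label, *names)
    if not mask.any():
        raise EmptyRegionError(f"label {label!r} is empty")
    verts, faces = _mask_surface_mesh(mask, vol.spacing)
    return float(measure.mesh_surface_area(verts, faces))


def mesh_volume(mesh: SurfaceMesh | trimesh.Trimesh) -> float:
    """Enclosed volume (mm^3) of a closed mesh, orientation-independent."""
    tm = mesh.as_trimesh() if isinstance(mesh, SurfaceMesh) else mesh
    if not tm.is_watertight:
        raise NonWatertightMeshError(
            "mesh is not watertight; every edge must be shared by exactly two faces"
        )
    return float(abs(tm.volume))


def convex_hull_volume(points) -> float:
    """Volume (mm^3) of the convex hull of a point cloud or mesh vertices."""
    if isinstance(points, (SurfaceMesh, trimesh.Trimesh)):
        points = points.vertices
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 4:
        raise DegenerateHullError("need at least 4 points in 3D")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateHullError(f"degenerate (coplanar?) input: {exc}") from exc
    return float(hull.volume)


def measure_specimen(
    vol: LabeledVolume,
    bone_label: str = "bone",
    airway_label: str = "main_airway",
    olfactory_label: str = "olfactory",
) -> dict[str, float]:
    """All size parameters of one labelled head volume.

    Returns skull volume (bone label), convex-hull head-model volume (hull
    of the bone isosurface vertices), whole-nasal-cavity volume/area
    (airway plus olfactory labels) and respiratory-region volume/area
    (airway label only), keyed by the measurement-table column names.
    """
    bone_mask = vol.mask(bone_label)
    if not bone_mask.any():
        raise EmptyRegionError(f"bone label {bone_label!r} is empty")
    skull_vol = label_volume(vol, bone_label)
    verts, _ = _mask_surface_mesh(bone_mask, vol.spacing, sigma=0)
    hull_vol = convex_hull_volume(verts + np.asarray(vol.origin))

    airway_mask = vol.mask(airway_label)
    if not airway_mask.any():
        raise EmptyRegionError(f"airway label {airway_label!r} is empty")
    olf_empty = not vol.mask(olfactory_label).any()

    resp_vol = label_volume(vol, airway_label)
    resp_sa = label_surface_area(vol, airway_label)
    if olf_empty:
        nasal_vol, nasal_sa = resp_vol, resp_sa
    else:
        nasal_vol = resp_vol + label_volume(vol, olfactory_label)
        nasal_sa = label_surface_area(vol, airway_label, olfactory_label)
    return {
        "skull_vol_mm3": skull_vol,
        "hull_vol_mm3": hull_vol,
        "nasal_sa_mm2": nasal_sa,
        "nasal_vol_mm3": nasal_vol,
        "resp_sa_mm2": resp_sa,
        "resp_vol_mm3": resp_vol,
    }
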