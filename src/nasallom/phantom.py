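"""Voxel skull phantoms with analytically known cavity geometry.

A phantom is a box-shell "skull" (bone label) enclosing an ellipsoidal
"nasal cavity" split by a plane into main-airway and olfactory partitions.
Because ellipsoid volumes, plane-cut partitions (cap/slab formulas) and a
surface-area series approximation are available in closed form, every
downstream morphometric and reconstruction operation can be validated
against analytic truth.

Default geometry places planes midway between voxel-centre coordinates so
that half-cuts are not biased by a voxel layer sitting exactly on the
plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .morphometry import DEFAULT_LABELS, LabeledVolume
from .reconstruct import ConstraintLandmarks, Plane

__all__ = [
    "GeometryError",
    "PhantomSpec",
    "ellipsoid_area_thomsen",
    "ellipsoid_plane_partition",
    "ellipsoid_volume",
    "generate_skull_phantom",
    "sphere_cap_volume",
]


class GeometryError(ValueError):
    pass


def ellipsoid_volume(a: float, b: float, c: float) -> float:
    return 4.0 / 3.0 * np.pi * a * b * c


def ellipsoid_area_thomsen(a: float, b: float, c: float, p: float = 1.6075) -> float:
    """Thomsen's series approximation of the ellipsoid surface area.

    Maximum relative error about 1.1% over all aspect ratios; exact for
    spheres.
    """
    ap, bp, cp = a**p, b**p, c**p
    return 4.0 * np.pi * ((ap * bp + ap * cp + bp * cp) / 3.0) ** (1.0 / p)


def sphere_cap_volume(r: float, h: float) -> float:
    """Volume of a spherical cap of height h (0 <= h <= 2r)."""
    h = min(max(h, 0.0), 2.0 * r)
    return np.pi * h * h * (3.0 * r - h) / 3.0


def ellipsoid_plane_partition(
    center, semi_axes, plane_point, plane_normal
) -> tuple[float, float]:
    """Analytic volumes of the two parts of an ellipsoid cut by a plane.

    Returns ``(v_neg, v_pos)``: the volume on the negative and positive
    side of the plane's normal.  The ellipsoid is mapped to the unit ball,
    where the plane remains a plane and the cut is a spherical cap.
    """
    center = np.asarray(center, dtype=float)
    axes = np.asarray(semi_axes, dtype=float)
    n = np.asarray(plane_normal, dtype=float)
    nn = np.linalg.norm(n)
    if nn == 0:
        raise GeometryError("plane normal must be nonzero")
    n = n / nn
    p0 = np.asarray(plane_point, dtype=float)
    # signed distance of plane from ellipsoid centre in unit-ball coordinates
    d = float(np.dot(p0 - center, n))
    n_ball = n * axes  # S^T n for S = diag(a, b, c)
    d_ball = d / np.linalg.norm(n_ball)
    total = ellipsoid_volume(*axes)
    if d_ball >= 1.0:
        return total, 0.0
    if d_ball <= -1.0:
        return 0.0, total
    cap_unit = sphere_cap_volume(1.0, 1.0 - d_ball)  # cap on positive side
    v_pos = cap_unit / (4.0 / 3.0 * np.pi) * total
    return total - v_pos, v_pos


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of one synthetic skull phantom (all lengths in mm).

    The skull is the shell between ``skull_outer`` and the box shrunk by
    ``wall_thickness``; the cavity ellipsoid must fit strictly inside the
    hollow interior.  ``split_plane`` partitions the cavity: its positive
    (normal) side becomes the olfactory label.
    """

    grid_shape: tuple[int, int, int] = (96, 64, 64)
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    skull_outer: tuple[tuple[float, float], ...] = ((4.0, 44.0), (4.0, 28.0), (4.0, 28.0))
    wall_thickness: float = 1.5
    cavity_center: tuple[float, float, float] = (24.0, 16.0, 16.0)
    cavity_semi_axes: tuple[float, float, float] = (10.0, 8.0, 6.0)
    split_point: tuple[float, float, float] = (30.0, 16.0, 16.0)
    split_normal: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self):
        inner = self.inner_box
        c = np.asarray(self.cavity_center)
        ax = np.asarray(self.cavity_semi_axes)
        if (ax <= 0).any():
            raise GeometryError("cavity semi-axes must be positive")
        for k in range(3):
            if c[k] - ax[k] <= inner[k][0] or c[k] + ax[k] >= inner[k][1]:
                raise GeometryError("cavity ellipsoid must lie strictly inside the skull interior")

    @property
    def inner_box(self) -> tuple[tuple[float, float], ...]:
        t = self.wall_thickness
        return tuple((lo + t, hi - t) for lo, hi in self.skull_outer)

    # analytic truths -----------------------------------------------------
    @property
    def cavity_volume(self) -> float:
        return ellipsoid_volume(*self.cavity_semi_axes)

    @property
    def cavity_area(self) -> float:
        return ellipsoid_area_thomsen(*self.cavity_semi_axes)

    def partition_volumes(self) -> tuple[float, float]:
        """(main airway, olfactory) analytic volumes under the split plane."""
        v_neg, v_pos = ellipsoid_plane_partition(
            self.cavity_center, self.cavity_semi_axes, self.split_point, self.split_normal
        )
        return v_neg, v_pos

    @property
    def skull_volume(self) -> float:
        outer = np.prod([hi - lo for lo, hi in self.skull_outer])
        inner = np.prod([hi - lo for lo, hi in self.inner_box])
        return float(outer - inner)

    @property
    def hull_volume(self) -> float:
        return float(np.prod([hi - lo for lo, hi in self.skull_outer]))


def _default_landmarks(spec: PhantomSpec) -> ConstraintLandmarks:
    cx, cy, cz = spec.cavity_center
    ax, ay, az = spec.cavity_semi_axes
    return ConstraintLandmarks(
        nostril_plane=Plane(point=(cx - ax, cy, cz), normal=(1.0, 0.0, 0.0)),
        antrum_boundary=Plane(point=(cx, cy, cz - az - 0.5), normal=(0.0, 0.0, 1.0)),
        choana_plane=Plane(point=spec.split_point, normal=(-1.0, 0.0, 0.0)),
        mesethmoid_point=(cx + ax + 0.25, cy, cz),
    )


def generate_skull_phantom(
    spec: PhantomSpec | None = None,
) -> tuple[LabeledVolume, ConstraintLandmarks, dict]:
    """Voxelize a phantom; return (label volume, landmarks, analytic truths).

    Labels: 0 background, 1 bone, 2 main airway, 3 olfactory.  A voxel
    belongs to a region when its centre does (centre convention:
    world = origin + (index + 0.5) * spacing).
    """
    spec = spec or PhantomSpec()
    shape = spec.grid_shape
    sp = np.asarray(spec.spacing, dtype=float)
    org = np.asarray(spec.origin, dtype=float)
    idx = np.indices(shape, dtype=float)
    world = [(idx[k] + 0.5) * sp[k] + org[k] for k in range(3)]

    def in_box(box):
        m = np.ones(shape, dtype=bool)
        for k, (lo, hi) in enumerate(box):
            m &= (world[k] >= lo) & (world[k] <= hi)
        return m

    bone = in_box(spec.skull_outer) & ~in_box(spec.inner_box)
    c = np.asarray(spec.cavity_center)
    axv = np.asarray(spec.cavity_semi_axes)
    cav = (
        sum(((world[k] - c[k]) / axv[k]) ** 2 for k in range(3)) <= 1.0
    )
    n = np.asarray(spec.split_normal, dtype=float)
    n = n / np.linalg.norm(n)
    p0 = np.asarray(spec.split_point, dtype=float)
    signed = sum((world[k] - p0[k]) * n[k] for k in range(3))
    olf = cav & (signed > 0)
    main = cav & ~olf

    grid = np.zeros(shape, dtype=np.int16)
    grid[bone] = DEFAULT_LABELS["bone"]
    grid[main] = DEFAULT_LABELS["main_airway"]
    grid[olf] = DEFAULT_LABELS["olfactory"]
    vol = LabeledVolume(
        grid=grid, spacing=tuple(sp), origin=tuple(org), labels=dict(DEFAULT_LABELS)
    )
    v_main, v_olf = spec.partition_volumes()
    truths = {
        "cavity_vol_mm3": spec.cavity_volume,
        "cavity_sa_mm2": spec.cavity_area,
        "main_airway_vol_mm3": v_main,
        "olfactory_vol_mm3": v_olf,
        "skull_vol_mm3": spec.skull_volume,
        "hull_vol_mm3": spec.hull_volume,
    }
    return vol, _default_landmarks(spec), truths
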