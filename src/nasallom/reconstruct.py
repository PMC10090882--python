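"""Fossil airway reconstruction and placement between allometric lines.

The bony-bounded nasal cavity of a fossil skull is the maximum space the
facial and palatal bones could have enclosed; the soft-tissue airway
occupied only part of it.  Four osteological constraints crop that space
to a maximum main airway:

I.   the fleshy nostril sits at the rostralmost bony nostril (rostral cut),
II.  the maxillary antrum region bounds the main passage ventrally
     (dorsal-side retention),
III. the fleshy choana sits at the caudal edge of the bony choana
     (caudal cut for the main airway), and
IV.  the olfactory cavity reaches the rostral terminus of the median
     septum of the mesethmoid (caudal cap of the olfactory partition).

A scalar 40-60% soft-tissue correction then brackets the plausible
airway volume, and the corrected fossil is placed relative to the
endotherm and ectotherm regression lines via the dimensionless index
rho = (y - y_ecto) / (y_endo - y_ecto), which is 0 on the ectotherm line
and 1 on the endotherm line.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .allometry import AllometricFit

__all__ = [
    "ConstraintLandmarks",
    "FossilPlacement",
    "LandmarkOutOfBoundsError",
    "Plane",
    "UndefinedIndexError",
    "add_mirrored_component",
    "crop_main_airway",
    "place_fossil",
    "soft_tissue_corrected_range",
]


class LandmarkOutOfBoundsError(ValueError):
    pass


class UndefinedIndexError(ZeroDivisionError):
    pass


@dataclass(frozen=True)
class Plane:
    """An oriented plane in world (mm) coordinates: point plus unit normal."""

    point: tuple[float, float, float]
    normal: tuple[float, float, float]

    def __post_init__(self):
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ValueError("plane normal must be a nonzero vector")
        object.__setattr__(self, "normal", tuple(n / norm))
        object.__setattr__(self, "point", tuple(float(v) for v in self.point))

    def signed_distance(self, coords) -> np.ndarray:
        """Signed distance of points to the plane (positive along normal).

        *coords* is a length-3 sequence of (broadcastable) coordinate
        arrays, e.g. :meth:`LabeledVolume.voxel_centers`.
        """
        return sum(
            (coords[k] - self.point[k]) * self.normal[k] for k in range(3)
        )

    @staticmethod
    def from_surface(vertices, toward_point) -> "Plane":
        """Least-squares plane through a triangulated surface's vertices.

        The normal is oriented toward *toward_point* (an interior airway
        seed), so "dorsal of the surface" is its positive side.  This is
        the planar reduction used when a curved antrum wall is supplied
        as a mesh.
        """
        v = np.asarray(vertices, dtype=float)
        centroid = v.mean(axis=0)
        _, _, vt = np.linalg.svd(v - centroid, full_matrices=False)
        normal = vt[-1]
        if np.dot(np.asarray(toward_point) - centroid, normal) < 0:
            normal = -normal
        return Plane(point=tuple(centroid), normal=tuple(normal))


@dataclass(frozen=True)
class ConstraintLandmarks:
    """The four osteological constraint landmarks, in world coordinates.

    Plane normals point toward the retained (airway) side: the nostril
    plane's normal points caudally, the choana plane's rostrally and the
    antrum boundary's dorsally (toward the main passage).
    """

    nostril_plane: Plane
    antrum_boundary: Plane
    choana_plane: Plane
    mesethmoid_point: tuple[float, float, float]

    def to_dict(self) -> dict:
        return {
            "nostril_plane": {"point": self.nostril_plane.point, "normal": self.nostril_plane.normal},
            "antrum_boundary": {
                "point": self.antrum_boundary.point,
                "normal": self.antrum_boundary.normal,
            },
            "choana_plane": {"point": self.choana_plane.point, "normal": self.choana_plane.normal},
            "mesethmoid_point": tuple(float(v) for v in self.mesethmoid_point),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConstraintLandmarks":
        def plane(key):
            return Plane(point=tuple(d[key]["point"]), normal=tuple(d[key]["normal"]))

        return cls(
            nostril_plane=plane("nostril_plane"),
            antrum_boundary=plane("antrum_boundary"),
            choana_plane=plane("choana_plane"),
            mesethmoid_point=tuple(d["mesethmoid_point"]),
        )


def _check_in_bounds(vol, lm: ConstraintLandmarks):
    lo, hi = vol.world_bounds()
    points = {
        "nostril_plane": lm.nostril_plane.point,
        "antrum_boundary": lm.antrum_boundary.point,
        "choana_plane": lm.choana_plane.point,
        "mesethmoid_point": lm.mesethmoid_point,
    }
    for name, p in points.items():
        p = np.asarray(p, dtype=float)
        if (p < lo).any() or (p > hi).any():
            raise LandmarkOutOfBoundsError(
                f"{name} at {tuple(p)} lies outside the volume bounds {tuple(lo)}-{tuple(hi)}"
            )


def crop_main_airway(vol, lm: ConstraintLandmarks, cavity_labels=("main_airway", "olfactory")):
    """Apply the four constraints to the bony-bounded cavity of *vol*.

    Returns a new :class:`~nasallom.morphometry.LabeledVolume` in which the
    input cavity voxels are partitioned exactly into ``main_airway``
    (satisfying constraints I-III), ``olfactory`` (caudal of the choana up
    to the mesethmoid cap, constraint IV) and ``excluded_cavity`` (the
    rest); the bone label is carried through unchanged.
    """
    from .morphometry import LabeledVolume  # local import to avoid a cycle

    _check_in_bounds(vol, lm)
    cavity = vol.mask(*[l for l in cavity_labels if l in vol.labels])
    coords = vol.voxel_centers()
    caudal_of_nostril = lm.nostril_plane.signed_distance(coords) >= 0
    dorsal_of_antrum = lm.antrum_boundary.signed_distance(coords) >= 0
    rostral_of_choana = lm.choana_plane.signed_distance(coords) >= 0
    main = cavity & caudal_of_nostril & dorsal_of_antrum & rostral_of_choana
    # constraint IV: caudal cap normal to the rostrocaudal (x) axis
    mes_x = float(lm.mesethmoid_point[0])
    olf = cavity & ~rostral_of_choana & (coords[0] <= mes_x)
    if not main.any():
        warnings.warn(
            "constraint planes leave no main-airway voxels (degenerate ordering?)",
            stacklevel=2,
        )
    labels = dict(vol.labels)
    labels.setdefault("excluded_cavity", max(labels.values()) + 1)
    labels.setdefault("main_airway", max(labels.values()) + 1)
    labels.setdefault("olfactory", max(labels.values()) + 1)
    grid = np.asarray(vol.grid).copy()
    grid[cavity] = labels["excluded_cavity"]
    grid[main] = labels["main_airway"]
    grid[olf] = labels["olfactory"]
    return LabeledVolume(grid=grid, spacing=vol.spacing, origin=vol.origin, labels=labels)


def soft_tissue_corrected_range(
    bony_volume: float, fraction_lo: float = 0.40, fraction_hi: float = 0.60
) -> tuple[float, float]:
    """Bracket the soft-tissue airway volume as a fraction of the bony one.

    In extant diapsids the soft-tissue airway occupies roughly 40-60% of
    the bony-bounded nasal passage; the returned interval is
    ``(lo * V, hi * V)``.
    """
    if bony_volume < 0:
        raise ValueError("bony volume must be non-negative")
    if not (0 < fraction_lo <= fraction_hi <= 1):
        raise ValueError(
            f"fractions must satisfy 0 < lo <= hi <= 1, got ({fraction_lo}, {fraction_hi})"
        )
    return (fraction_lo * bony_volume, fraction_hi * bony_volume)


def add_mirrored_component(measured_volume: float, component_volume: float) -> float:
    """Complete a bilaterally asymmetric measurement by mirroring.

    When bones are preserved on one side only, the contralateral volume is
    taken equal to the preserved side's and added.
    """
    if measured_volume < 0 or component_volume < 0:
        raise ValueError("volumes must be non-negative")
    return measured_volume + component_volume


@dataclass
class FossilPlacement:
    """Position of a fossil relative to the two groups' fitted lines."""

    x: float
    y_bony: float
    y_corrected_range: tuple[float, float]
    predicted_endo: float
    predicted_ecto: float
    relative_index_bony: float
    relative_index_corrected: tuple[float, float]
    prediction_se: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "x": self.x,
            "y_bony": self.y_bony,
            "y_corrected_range": list(self.y_corrected_range),
            "predicted_endo": self.predicted_endo,
            "predicted_ecto": self.predicted_ecto,
            "relative_index_bony": self.relative_index_bony,
            "relative_index_corrected": list(self.relative_index_corrected),
            "prediction_se": dict(self.prediction_se),
        }


def place_fossil(
    x: float,
    y: float,
    fit_endo: AllometricFit,
    fit_ecto: AllometricFit,
    correction: tuple[float, float] = (0.40, 0.60),
) -> FossilPlacement:
    """Place a fossil (log10 x, log10 bony y) between two fitted lines.

    rho = (y - yhat_ecto) / (yhat_endo - yhat_ecto) is reported for the
    bony volume and for both endpoints of the soft-tissue-corrected range
    (the correction is multiplicative on the raw volume, hence additive,
    log10(fraction), in log space).  Estimate standard errors of the two
    predictions are attached when the fits carry coefficient covariances.
    """
    yhat_e = float(fit_endo.predict(x))
    yhat_c = float(fit_ecto.predict(x))
    denom = yhat_e - yhat_c
    if denom == 0:
        raise UndefinedIndexError("fitted lines coincide at x; relative index undefined")

    def rho(val):
        return (val - yhat_c) / denom

    lo, hi = soft_tissue_corrected_range(1.0, *correction)
    y_lo = y + float(np.log10(lo))
    y_hi = y + float(np.log10(hi))
    se = {}
    for name, fit, yhat in (("endo", fit_endo, yhat_e), ("ecto", fit_ecto, yhat_c)):
        if fit.coef_cov is not None:
            v = np.array([1.0, x])
            se[name] = float(np.sqrt(v @ np.asarray(fit.coef_cov) @ v))
    return FossilPlacement(
        x=float(x),
        y_bony=float(y),
        y_corrected_range=(y_lo, y_hi),
        predicted_endo=yhat_e,
        predicted_ecto=yhat_c,
        relative_index_bony=rho(y),
        relative_index_corrected=(rho(y_lo), rho(y_hi)),
        prediction_se=se,
    )
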