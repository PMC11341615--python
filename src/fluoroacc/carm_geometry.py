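"""Cone-beam C-arm view model.

A fluoroscopic view is described by the source-to-image distance (SID), the
source-to-isocenter distance (SOD), and the gantry angulation (primary:
LAO positive / RAO negative; secondary: CRA positive / CAU negative).
Patient coordinates are right-handed with the origin at the isocenter,
+x patient-left, +y patient-anterior, +z cranial. In the AP view the source
sits posterior to the patient and the beam travels along +y.

Detector coordinates (u, v) are in millimetres in the detector plane with
the origin at the principal point (detector centre). The v axis points
cranially in the AP view and u is oriented so that a point displaced toward
patient-left projects to positive u — the image as seen from the source.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

logger = logging.getLogger("fluoroacc")

_AX_X = np.array([1.0, 0.0, 0.0])
_AX_Y = np.array([0.0, 1.0, 0.0])
_AX_Z = np.array([0.0, 0.0, 1.0])


class DegenerateProjectionError(ValueError):
    """Raised when a 3D point cannot be projected (at or behind the source)."""


class DegenerateConfigurationError(ValueError):
    """Raised for view configurations that do not admit a solution."""


@dataclass(frozen=True)
class Point3D:
    """3D position in patient space, millimetres, origin at the isocenter."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.as_array())):
            raise ValueError("Point3D components must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @staticmethod
    def from_array(a) -> "Point3D":
        a = np.asarray(a, dtype=float)
        return Point3D(float(a[0]), float(a[1]), float(a[2]))

    def distance_to(self, other: "Point3D") -> float:
        return float(np.linalg.norm(self.as_array() - other.as_array()))


@dataclass(frozen=True)
class DetectorPoint:
    """In-plane detector coordinates in mm, origin at the principal point."""

    u_mm: float
    v_mm: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.u_mm) and np.isfinite(self.v_mm)):
            raise ValueError("DetectorPoint components must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.u_mm, self.v_mm], dtype=float)

    def distance_to(self, other: "DetectorPoint") -> float:
        return float(np.linalg.norm(self.as_array() - other.as_array()))


@dataclass(frozen=True)
class ProjectionLine:
    """Ray from the X-ray source through a detector location."""

    origin: Point3D
    direction: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-12:
            raise ValueError(f"direction must be a unit vector, got norm {n!r}")
        object.__setattr__(self, "direction", d)

    def point_at(self, t: float) -> Point3D:
        return Point3D.from_array(self.origin.as_array() + t * self.direction)


@dataclass(frozen=True)
class CArmGeometry:
    """One fluoroscopic view of a monoplane C-arm system.

    Parameters
    ----------
    sid_mm : source-to-image (detector) distance.
    sod_mm : source-to-isocenter distance.
    primary_deg : primary angulation, LAO positive / RAO negative.
    secondary_deg : secondary angulation, CRA positive / CAU negative.
    pixel_spacing_mm : detector pixel edge length (I/O-level only; all
        computations are carried out in mm at the detector plane).
    label : free-text view name.
    """

    sid_mm: float
    sod_mm: float
    primary_deg: float = 0.0
    secondary_deg: float = 0.0
    pixel_spacing_mm: float = 0.2
    label: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.sod_mm < self.sid_mm):
            raise ValueError(
                f"require 0 < sod_mm < sid_mm, got sod={self.sod_mm}, sid={self.sid_mm}"
            )
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")

    @property
    def magnification(self) -> float:
        """Detector/isocenter scale factor SID/SOD (always > 1)."""
        return self.sid_mm / self.sod_mm

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "sid_mm": self.sid_mm,
            "sod_mm": self.sod_mm,
            "primary_deg": self.primary_deg,
            "secondary_deg": self.secondary_deg,
            "pixel_spacing_mm": self.pixel_spacing_mm,
        }

    @staticmethod
    def from_dict(d: dict) -> "CArmGeometry":
        return CArmGeometry(
            sid_mm=float(d["sid_mm"]),
            sod_mm=float(d["sod_mm"]),
            primary_deg=float(d.get("primary_deg", 0.0)),
            secondary_deg=float(d.get("secondary_deg", 0.0)),
            pixel_spacing_mm=float(d.get("pixel_spacing_mm", 0.2)),
            label=str(d.get("label", "")),
        )

    @staticmethod
    def from_json(path) -> "CArmGeometry":
        return CArmGeometry.from_dict(json.loads(Path(path).read_text()))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def view_frame(geom: CArmGeometry):
    """Source position, detector centre, and detector axes of a view.

    The view axis points from the source toward the detector through the
    isocenter: at zero angulation it is +y (AP); the primary angle rotates
    it about +z toward +x (LAO positive) and the secondary angle then tilts
    it toward +z (CRA positive).

    Returns ``(source, detector_center, u_axis, v_axis, view_axis)`` where
    the axes are mutually orthonormal unit vectors.
    """
    alpha = np.radians(geom.primary_deg)
    beta = np.radians(geom.secondary_deg)
    w = np.array(
        [np.sin(alpha) * np.cos(beta), np.cos(alpha) * np.cos(beta), np.sin(beta)]
    )
    # v: cranial direction orthogonalized against the view axis; falls back
    # to the anterior direction for (near-)axial beams.
    ref = _AX_Z if abs(w @ _AX_Z) < 1.0 - 1e-9 else _AX_Y
    v = ref - (ref @ w) * w
    v /= np.linalg.norm(v)
    u = np.cross(w, v)
    source = Point3D.from_array(-geom.sod_mm * w)
    detector_center = Point3D.from_array((geom.sid_mm - geom.sod_mm) * w)
    return source, detector_center, u, v, w


def magnification(geom: CArmGeometry) -> float:
    """Scale factor between isocenter-plane and detector-plane lengths."""
    return geom.magnification


def project_point(geom: CArmGeometry, p: Point3D) -> DetectorPoint:
    """Cone-beam projection of a 3D point onto the detector.

    Raises
    ------
    DegenerateProjectionError
        If ``p`` lies at or behind the source plane.
    """
    source, center, u, v, w = view_frame(geom)
    d = p.as_array() - source.as_array()
    depth = d @ w
    if depth <= 1e-9:
        raise DegenerateProjectionError(
            f"point at depth {depth:.3g} mm is not on the detector side of the source"
        )
    hit = source.as_array() + (geom.sid_mm / depth) * d
    rel = hit - center.as_array()
    return DetectorPoint(float(rel @ u), float(rel @ v))


def backproject(geom: CArmGeometry, d: DetectorPoint) -> ProjectionLine:
    """Ray from the source through the 3D detector location of ``d``."""
    source, center, u, v, _ = view_frame(geom)
    hit = center.as_array() + d.u_mm * u + d.v_mm * v
    direction = hit - source.as_array()
    direction /= np.linalg.norm(direction)
    return ProjectionLine(origin=source, direction=direction)
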