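"""3D localization of a radio-opaque device marker from fluoroscopic views.

Two-view localization triangulates the marker as the midpoint between the
Nadir points of the two back-projected rays (the mutually closest points on
the two skew lines). Single-view localization, used when only one angulation
is available, takes the closest point on the single back-projected ray to a
co-registered 3D reference position; the resulting distance is a lower bound
on the true 3D error because displacement along the view axis is invisible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .carm_geometry import (
    CArmGeometry,
    DegenerateConfigurationError,
    DetectorPoint,
    Point3D,
    ProjectionLine,
    backproject,
    project_point,
    view_frame,
)

logger = logging.getLogger("fluoroacc")

HARD_MIN_ANGLE_DEG = 1.0
WARN_ANGLE_DEG = 30.0


@dataclass(frozen=True)
class LinePairNadir:
    """Mutually closest points of two skew projection lines."""

    nadir_a: Point3D
    nadir_b: Point3D
    gap_mm: float
    midpoint: Point3D


@dataclass(frozen=True)
class MarkerLocalization:
    """Two-view 3D marker reconstruction.

    ``p_pair`` is the midpoint between the two Nadir points; ``gap_mm``
    inside ``nadirs`` measures how far the two rays are from intersecting.
    """

    p_pair: Point3D
    nadirs: LinePairNadir
    angular_separation_deg: float

    def to_dict(self) -> dict:
        return {
            "p_pair": list(self.p_pair.as_array()),
            "nadir_a": list(self.nadirs.nadir_a.as_array()),
            "nadir_b": list(self.nadirs.nadir_b.as_array()),
            "gap_mm": self.nadirs.gap_mm,
            "angular_separation_deg": self.angular_separation_deg,
        }


def closest_points_between_lines(a: ProjectionLine, b: ProjectionLine) -> LinePairNadir:
    """Nadir points of two lines: the unique pair of mutually closest points.

    Solves the 2x2 normal equations of ``min_{t,u} ||a(t) - b(u)||^2``.

    Raises
    ------
    DegenerateConfigurationError
        If the lines are (near-)parallel.
    """
    da, db = a.direction, b.direction
    cross = np.cross(da, db)
    if np.linalg.norm(cross) <= 1e-10:
        sep = np.degrees(np.arccos(np.clip(abs(da @ db), -1.0, 1.0)))
        raise DegenerateConfigurationError(
            f"projection lines are (near-)parallel: angular separation {sep:.4f} deg"
        )
    r = b.origin.as_array() - a.origin.as_array()
    # [ da.da  -da.db ] [t]   [ da.r ]
    # [ da.db  -db.db ] [u] = [ db.r ]
    m = np.array([[da @ da, -(da @ db)], [da @ db, -(db @ db)]])
    t, u = np.linalg.solve(m, np.array([da @ r, db @ r]))
    pa = a.origin.as_array() + t * da
    pb = b.origin.as_array() + u * db
    return LinePairNadir(
        nadir_a=Point3D.from_array(pa),
        nadir_b=Point3D.from_array(pb),
        gap_mm=float(np.linalg.norm(pa - pb)),
        midpoint=Point3D.from_array(0.5 * (pa + pb)),
    )


def angular_separation_deg(geom1: CArmGeometry, geom2: CArmGeometry) -> float:
    """Angle between the view axes of two geometries, in [0, 180] degrees."""
    w1 = view_frame(geom1)[4]
    w2 = view_frame(geom2)[4]
    return float(np.degrees(np.arccos(np.clip(w1 @ w2, -1.0, 1.0))))


def triangulate_pair(
    geom1: CArmGeometry,
    d1: DetectorPoint,
    geom2: CArmGeometry,
    d2: DetectorPoint,
    min_angle_deg: float = HARD_MIN_ANGLE_DEG,
    warn_angle_deg: float = WARN_ANGLE_DEG,
) -> MarkerLocalization:
    """Triangulate one marker from its detector positions in two views.

    Back-projects both detector points and returns the midpoint between the
    Nadir points of the two rays. Views separated by less than
    ``warn_angle_deg`` trigger a warning (triangulation precision degrades
    along the near-common view axis); separations below ``min_angle_deg``
    are rejected.
    """
    sep = angular_separation_deg(geom1, geom2)
    if min(sep, 180.0 - sep) < min_angle_deg:
        raise DegenerateConfigurationError(
            f"view axes separated by {sep:.3f} deg (< {min_angle_deg} deg hard floor)"
        )
    if min(sep, 180.0 - sep) < warn_angle_deg:
        warnings.warn(
            f"small angular separation ({sep:.1f} deg) between views; "
            "3D localization precision is degraded",
            stacklevel=2,
        )
    nadirs = closest_points_between_lines(backproject(geom1, d1), backproject(geom2, d2))
    return MarkerLocalization(
        p_pair=nadirs.midpoint, nadirs=nadirs, angular_separation_deg=sep
    )


def reprojection_error(
    geom: CArmGeometry, p: Point3D, d_observed: DetectorPoint
) -> float:
    """Detector-plane distance (mm) between the projection of ``p`` and the
    observed marker location — the per-view consistency check of a two-view
    reconstruction."""
    return project_point(geom, p).distance_to(d_observed)


def nadir_on_line(line: ProjectionLine, q: Point3D):
    """Closest point on a projection line to a 3D reference point.

    Returns ``(nadir, distance_mm)``: the single-view marker estimate and
    the perpendicular point-line distance used as its error sample.
    """
    o = line.origin.as_array()
    t = (q.as_array() - o) @ line.direction
    nadir = o + t * line.direction
    return Point3D.from_array(nadir), float(np.linalg.norm(q.as_array() - nadir))
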