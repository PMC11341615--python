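"""Closed-form accuracy budget for marker localization.

Marker-identification error in each modality is bounded by the half
diagonal of the underlying voxel (2D for the X-ray detector pixel, 3D for
the CMR voxel). The detector-plane error is scaled to the isocenter by the
geometric magnification, combined in root-sum-square with the intrinsic
geometry error of the X-ray system to give the two-view 3D localization
error, re-projected to the image plane for the detector-plane consistency
bound, and finally combined with the CMR identification error for the total
3D error of the image-fusion chain:

    eps_2dxr     = pixel * sqrt(2) / 2
    eps_cmr      = voxel * sqrt(3) / 2
    eps_2dxr_iso = eps_2dxr / magnification
    eps_3dxr     = sqrt(eps_2dxr_iso^2 + eps_geo^2)
    eps_2dxrproj = eps_3dxr * magnification
    eps_tot      = sqrt(eps_3dxr^2 + eps_cmr^2)

Single-view localization degrades accuracy but contributes no extra term to
``eps_tot``, which is defined for the two-view reconstruction.

With ``round_intermediates=True`` each chained value is rounded to 0.1 mm
before entering the next formula; this mode reproduces a published-style
display chain. Full precision is the scientific default for new analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


def half_diagonal(edge_mm: float, dims: int) -> float:
    """Half diagonal of a square pixel (dims=2) or cubic voxel (dims=3)."""
    if edge_mm <= 0:
        raise ValueError("edge must be positive")
    if dims not in (2, 3):
        raise ValueError("dims must be 2 or 3")
    return edge_mm * math.sqrt(dims) / 2.0


def _round01(x: float) -> float:
    return round(x, 1)


@dataclass(frozen=True)
class ErrorBudgetParams:
    """Inputs of the error budget.

    cmr_voxel_mm : reconstructed isotropic CMR voxel edge (default 1.3).
    xr_pixel_mm : detector pixel edge (default 0.283, giving a 0.2 mm
        half diagonal).
    geo_error_mm : intrinsic X-ray geometry error (default 0.2).
    magnification : detector/isocenter scale (default 1.5).
    round_intermediates : round each chained value to 0.1 mm before reuse.
    """

    cmr_voxel_mm: float = 1.3
    xr_pixel_mm: float = 0.2 * 2 / math.sqrt(2)
    geo_error_mm: float = 0.2
    magnification: float = 1.5
    round_intermediates: bool = False

    def __post_init__(self) -> None:
        if min(self.cmr_voxel_mm, self.xr_pixel_mm, self.geo_error_mm) <= 0:
            raise ValueError("all lengths must be positive")
        if self.magnification <= 1:
            raise ValueError("magnification must exceed 1")

    @staticmethod
    def from_dict(d: dict) -> "ErrorBudgetParams":
        return ErrorBudgetParams(**d)


@dataclass(frozen=True)
class ErrorBudget:
    """Chained error quantities, each at full precision with a 0.1 mm
    display-rounded companion."""

    eps_2dxr_mm: float
    eps_cmr_mm: float
    eps_2dxr_iso_mm: float
    eps_xr_geo_mm: float
    eps_3dxr_mm: float
    eps_2dxr_proj_mm: float
    eps_tot_mm: float

    def to_dict(self) -> dict:
        full = {
            "eps_2dxr_mm": self.eps_2dxr_mm,
            "eps_cmr_mm": self.eps_cmr_mm,
            "eps_2dxr_iso_mm": self.eps_2dxr_iso_mm,
            "eps_xr_geo_mm": self.eps_xr_geo_mm,
            "eps_3dxr_mm": self.eps_3dxr_mm,
            "eps_2dxr_proj_mm": self.eps_2dxr_proj_mm,
            "eps_tot_mm": self.eps_tot_mm,
        }
        return {
            "full_precision_mm": full,
            "display_mm": {k: _round01(v) for k, v in full.items()},
        }


def propagate_budget(params: ErrorBudgetParams) -> ErrorBudget:
    """Chain the error budget from pixel/voxel sizes to the total 3D error."""
    rnd = _round01 if params.round_intermediates else (lambda x: x)
    eps_2dxr = rnd(half_diagonal(params.xr_pixel_mm, 2))
    eps_cmr = rnd(half_diagonal(params.cmr_voxel_mm, 3))
    eps_geo = rnd(params.geo_error_mm)
    eps_2dxr_iso = rnd(eps_2dxr / params.magnification)
    eps_3dxr = rnd(math.hypot(eps_2dxr_iso, eps_geo))
    eps_2dxr_proj = rnd(eps_3dxr * params.magnification)
    eps_tot = rnd(math.hypot(eps_3dxr, eps_cmr))
    return ErrorBudget(
        eps_2dxr_mm=eps_2dxr,
        eps_cmr_mm=eps_cmr,
        eps_2dxr_iso_mm=eps_2dxr_iso,
        eps_xr_geo_mm=eps_geo,
        eps_3dxr_mm=eps_3dxr,
        eps_2dxr_proj_mm=eps_2dxr_proj,
        eps_tot_mm=eps_tot,
    )
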