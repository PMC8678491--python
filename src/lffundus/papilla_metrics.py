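"""Papilla (optic cup) depth measurement and calibration.

The cup depth is the virtual-depth difference between the ground of the
optic nerve head and its periphery, sampled as circle-area means on the
depth map (20 px circles for in-vivo style measurements, 85 px including the
complete ground for the eye model), averaged over the horizontal and
vertical reference directions, and converted to metric mm by dividing by the
axial magnification (2.25).  Linear calibration against ground-truth model
depths is an ordinary least-squares fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .depth_map import DepthMap
from .image_quality import PapillaGeometry
from .plenoptic_model import MagnificationModel, virtual_to_metric_depth
from .synthetic_data import ParameterError

__all__ = [
    "NoSampleError",
    "DepthSample",
    "PapillaDepthResult",
    "CalibrationFit",
    "sample_mean_depth",
    "papilla_depth",
    "model_papilla_depth",
    "fit_linear_calibration",
    "depth_profile",
]


class NoSampleError(ValueError):
    """The sampling circle contains no valid depth pixel."""


@dataclass(frozen=True)
class DepthSample:
    """Mean virtual depth over a circular averaging area."""

    center_px: tuple[float, float]
    area_px: int
    mean_v: float
    n_valid: int


@dataclass(frozen=True)
class PapillaDepthResult:
    """Horizontal/vertical/mean cup depth in v-mm and metric mm."""

    depth_h_vmm: float
    depth_v_vmm: float
    depth_mean_vmm: float
    depth_mm: float


@dataclass(frozen=True)
class CalibrationFit:
    """OLS fit of measured depth against ground truth."""

    slope: float
    offset: float
    r_squared: float
    residuals: np.ndarray


def sample_mean_depth(dmap: DepthMap, center_px, area_px: int) -> DepthSample:
    """Mean depth over a circle containing ``area_px`` pixels.

    The circle radius is ``sqrt(area / pi)``; only valid pixels contribute,
    and their count is recorded.  A circle without any valid pixel raises
    :class:`NoSampleError`.
    """
    if area_px < 1:
        raise ParameterError("averaging area must be >= 1 px")
    h, w = dmap.values.shape
    cx, cy = center_px
    r = math.sqrt(area_px / math.pi)
    x0, x1 = max(int(cx - r) - 1, 0), min(int(cx + r) + 2, w)
    y0, y1 = max(int(cy - r) - 1, 0), min(int(cy + r) + 2, h)
    if x0 >= x1 or y0 >= y1:
        raise NoSampleError(f"sampling circle at {center_px} lies outside the map")
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
    sel = inside & dmap.valid[y0:y1, x0:x1]
    n = int(np.count_nonzero(sel))
    if n == 0:
        raise NoSampleError(f"no valid depth inside the circle at {center_px}")
    return DepthSample(
        center_px=(float(cx), float(cy)),
        area_px=area_px,
        mean_v=float(dmap.values[y0:y1, x0:x1][sel].mean()),
        n_valid=n,
    )


def papilla_depth(
    dmap: DepthMap,
    base_center,
    rim_center_h,
    rim_center_v,
    area_px: int,
    mag: MagnificationModel,
) -> PapillaDepthResult:
    """Cup depth from one ground sample and two rim reference samples.

    ``depth_h`` is the absolute difference between the horizontal rim
    reference and the ground, ``depth_v`` the vertical analogue; both are
    averaged and converted to mm via the axial magnification.
    """
    base = sample_mean_depth(dmap, base_center, area_px)
    rim_h = sample_mean_depth(dmap, rim_center_h, area_px)
    rim_v = sample_mean_depth(dmap, rim_center_v, area_px)
    depth_h = abs(rim_h.mean_v - base.mean_v)
    depth_v = abs(rim_v.mean_v - base.mean_v)
    mean_vmm = (depth_h + depth_v) / 2.0
    return PapillaDepthResult(
        depth_h_vmm=float(depth_h),
        depth_v_vmm=float(depth_v),
        depth_mean_vmm=float(mean_vmm),
        depth_mm=virtual_to_metric_depth(mean_vmm, mag),
    )


def model_papilla_depth(
    dmap: DepthMap,
    geom: PapillaGeometry,
    mag: MagnificationModel,
    area_px: int = 85,
    rim_ring_factor: float = 1.5,
) -> PapillaDepthResult:
    """Eye-model cup depth: ground sample vs flat-surround annulus references.

    The ground is sampled with an 85 px circle including the complete cup
    ground; the periphery references sit on the flat surround at
    ``rim_ring_factor`` papilla radii east/west (horizontal) and north/south
    (vertical) of the center, averaged pairwise.
    """
    cx, cy = geom.center_px
    rr = rim_ring_factor * geom.radius_px
    base = sample_mean_depth(dmap, (cx, cy), area_px)
    east = sample_mean_depth(dmap, (cx + rr, cy), area_px)
    west = sample_mean_depth(dmap, (cx - rr, cy), area_px)
    north = sample_mean_depth(dmap, (cx, cy - rr), area_px)
    south = sample_mean_depth(dmap, (cx, cy + rr), area_px)
    depth_h = abs((east.mean_v + west.mean_v) / 2 - base.mean_v)
    depth_v = abs((north.mean_v + south.mean_v) / 2 - base.mean_v)
    mean_vmm = (depth_h + depth_v) / 2.0
    return PapillaDepthResult(
        depth_h_vmm=float(depth_h),
        depth_v_vmm=float(depth_v),
        depth_mean_vmm=float(mean_vmm),
        depth_mm=virtual_to_metric_depth(mean_vmm, mag),
    )


def fit_linear_calibration(pairs) -> CalibrationFit:
    """OLS line through (truth, measured) pairs with R-squared and residuals."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 2:
        raise ParameterError("need >= 2 (truth, measured) pairs")
    truth, measured = arr[:, 0], arr[:, 1]
    if np.allclose(truth, truth[0]):
        raise ParameterError("singular fit: all truth values identical")
    res = stats.linregress(truth, measured)
    residuals = measured - (res.slope * truth + res.intercept)
    return CalibrationFit(
        slope=float(res.slope),
        offset=float(res.intercept),
        r_squared=float(res.rvalue**2),
        residuals=residuals,
    )


def depth_profile(dmap: DepthMap, line_px, mag: MagnificationModel):
    """Metric-corrected depth samples along a pixel line.

    ``line_px`` is a sequence of (x, y) map pixels; invalid pixels are
    skipped.  Returns a list of (position_px, depth_mm) with position the
    distance along the line from its first point.
    """
    pts = np.asarray(line_px, dtype=float).reshape(-1, 2)
    h, w = dmap.values.shape
    out = []
    origin = pts[0]
    for x, y in pts:
        xi, yi = int(round(x)), int(round(y))
        if not (0 <= xi < w and 0 <= yi < h):
            raise ParameterError(f"profile point ({x}, {y}) outside the map")
        if not dmap.valid[yi, xi]:
            continue
        pos = float(np.hypot(x - origin[0], y - origin[1]))
        out.append((pos, virtual_to_metric_depth(dmap.values[yi, xi], mag)))
    return out
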