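"""Optical and image-quality metrics of the light-field fundus system.

Covers the MTF measurement from a back-illuminated edge target (average of 50
row profiles of 400 px, differentiation, Fourier transform, object-space
frequency axis), grayscale disc erosion for bubble-artifact-robust intensity
sampling, Michelson vessel contrast, papilla-centered geometry from N/E/S/W
rim marks, and counting of reconstructed depth positions inside the circular
evaluation ROI (diameter 5.5 papilla radii).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .depth_map import DepthMap
from .plenoptic_model import GeometryError
from .synthetic_data import ParameterError

__all__ = [
    "MTFCurve",
    "MTFLandmarks",
    "PapillaGeometry",
    "ContrastResult",
    "DegenerateEdgeError",
    "mtf_from_edge",
    "mtf_landmarks",
    "erode_disc",
    "michelson_contrast",
    "papilla_center",
    "count_depth_positions",
]


class DegenerateEdgeError(ValueError):
    """The edge ROI contains no usable intensity transition."""


@dataclass(frozen=True)
class MTFCurve:
    """Modulation transfer vs object-space spatial frequency."""

    freq_cyc_per_mm: np.ndarray
    amplitude: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.freq_cyc_per_mm, dtype=float)
        a = np.asarray(self.amplitude, dtype=float)
        if f.ndim != 1 or f.shape != a.shape:
            raise ParameterError("frequency and amplitude must be matching 1-D arrays")
        if np.any(f < 0) or np.any(np.diff(f) <= 0):
            raise ParameterError("frequencies must be non-negative and increasing")
        object.__setattr__(self, "freq_cyc_per_mm", f)
        object.__setattr__(self, "amplitude", a)


@dataclass(frozen=True)
class MTFLandmarks:
    """Half-amplitude frequency and cutoff (frequency of minimum amplitude)."""

    freq_at_half: float | None
    cutoff: float


@dataclass(frozen=True)
class PapillaGeometry:
    """Papilla center and radius from the four rim marks.

    Center: midpoint of the east/west marks horizontally and of the
    north/south marks vertically; radius: the larger half-extension (185 px
    at full scale).
    """

    rim_marks: dict
    center_px: tuple[float, float]
    radius_px: float


@dataclass(frozen=True)
class ContrastResult:
    """Per-venule Michelson contrasts (three venules) and their mean."""

    positions: list
    values: tuple
    mean: float


def mtf_from_edge(
    image: np.ndarray,
    edge_roi: tuple[int, int],
    pixel_pitch_um: float,
    lateral_mag: float,
    n_rows: int = 50,
    row_len: int = 400,
    window: bool = False,
    compensate_diff: bool = True,
) -> MTFCurve:
    """MTF from a near-vertical dark/bright edge.

    Averages ``n_rows`` row profiles of ``row_len`` pixels starting at
    ``edge_roi = (row0, col0)``, differentiates the average edge profile,
    Fourier transforms it, and normalizes the DC term to 1.  The frequency
    axis converts to object-space cycles/mm through the pixel pitch and the
    lateral magnification.  ``compensate_diff`` divides out the sinc response
    of the finite-difference derivative; ``window`` applies a Hann window to
    the line-spread function (off by default: plain differentiation + FFT).
    """
    img = np.asarray(image, dtype=float)
    r0, c0 = edge_roi
    if r0 < 0 or c0 < 0 or r0 + n_rows > img.shape[0] or c0 + row_len > img.shape[1]:
        raise ParameterError("edge ROI outside the image")
    profile = img[r0 : r0 + n_rows, c0 : c0 + row_len].mean(axis=0)
    if np.ptp(profile) < 1e-9 * max(abs(profile).max(), 1.0):
        raise DegenerateEdgeError("no intensity transition in the edge ROI")
    lsf = np.diff(profile)
    if window:
        lsf = lsf * np.hanning(len(lsf))
    spec = np.abs(np.fft.rfft(lsf))
    freqs_px = np.fft.rfftfreq(len(lsf), d=1.0)
    if spec[0] <= 0:
        raise DegenerateEdgeError("degenerate edge: zero net transition")
    amp = spec / spec[0]
    if compensate_diff:
        s = np.ones_like(freqs_px)
        nz = freqs_px > 0
        s[nz] = np.sin(np.pi * freqs_px[nz]) / (np.pi * freqs_px[nz])
        amp = amp / s
    freq_obj = freqs_px / (pixel_pitch_um * 1e-3) / lateral_mag
    return MTFCurve(freq_obj, amp)


def mtf_landmarks(curve: MTFCurve) -> MTFLandmarks:
    """Half-amplitude crossing (first, linearly interpolated) and cutoff
    (frequency of the curve's minimum amplitude)."""
    f = curve.freq_cyc_per_mm
    a = curve.amplitude
    freq_half = None
    below = np.where(a < 0.5)[0]
    for i in below:
        if i == 0:
            freq_half = float(f[0])
            break
        a0, a1 = a[i - 1], a[i]
        if a0 >= 0.5:
            t = (a0 - 0.5) / (a0 - a1)
            freq_half = float(f[i - 1] + t * (f[i] - f[i - 1]))
            break
    cutoff = float(f[int(np.argmin(a))])
    return MTFLandmarks(freq_half, cutoff)


def erode_disc(image: np.ndarray, radius_px: int = 8) -> np.ndarray:
    """Grayscale (minimum) erosion with a disc-shaped structuring element.

    Stores the lowest gray value inside the disc at its center; at the
    borders the element is clipped to the image.
    """
    if radius_px < 0:
        raise ParameterError("radius must be non-negative")
    k = 2 * radius_px + 1
    oy, ox = np.mgrid[-radius_px : radius_px + 1, -radius_px : radius_px + 1]
    footprint = ox**2 + oy**2 <= radius_px**2
    # 'nearest' padding replicates in-bounds pixels whose disc offsets shrink
    # toward the border, which equals clipping the element to the image
    return ndimage.grey_erosion(image, footprint=footprint, mode="nearest")


def michelson_contrast(eroded_image: np.ndarray, vessel_pos, background_pos) -> float:
    """Michelson contrast (Imax - Imin) / (Imax + Imin) between on-vessel and
    background samples of the eroded image."""
    img = np.asarray(eroded_image, dtype=float)

    def _at(pos):
        x, y = pos
        xi, yi = int(round(x)), int(round(y))
        if not (0 <= xi < img.shape[1] and 0 <= yi < img.shape[0]):
            raise ParameterError(f"position {pos} outside the image")
        return img[yi, xi]

    i_vessel = _at(vessel_pos)
    i_bg = _at(background_pos)
    i_max, i_min = max(i_vessel, i_bg), min(i_vessel, i_bg)
    if i_max + i_min == 0:
        raise ParameterError("undefined contrast: both samples are zero")
    return float((i_max - i_min) / (i_max + i_min))


def papilla_center(rim_marks: dict) -> PapillaGeometry:
    """Papilla geometry from the clockwise N/E/S/W rim marks.

    The horizontal center halves the east-west distance, the vertical center
    the north-south distance; the radius is the larger half-extension.
    """
    try:
        N, E, S, W = (np.asarray(rim_marks[k], dtype=float) for k in "NESW")
    except KeyError as exc:
        raise ParameterError(f"missing rim mark {exc}") from exc
    if np.allclose(E, W) or np.allclose(N, S):
        raise GeometryError("degenerate rim marks: opposite marks coincide")
    cx = (E[0] + W[0]) / 2
    cy = (N[1] + S[1]) / 2
    radius = max(abs(E[0] - W[0]) / 2, abs(N[1] - S[1]) / 2)
    return PapillaGeometry(
        rim_marks={k: tuple(np.asarray(rim_marks[k], dtype=float)) for k in "NESW"},
        center_px=(float(cx), float(cy)),
        radius_px=float(radius),
    )


def auto_venule_positions(
    eroded_image: np.ndarray,
    center_px,
    papilla_radius_px: float,
    n_venules: int = 3,
    flank_offset_px: float = 13.0,
    n_angles: int = 720,
):
    """Select measurement positions for the ring contrast in synthetic mode.

    Samples the eroded image along the ring at twice the papilla radius,
    takes the ``n_venules`` darkest well-separated local minima as the vessel
    positions, and places two background positions on opposite sides of each
    vessel along the ring.  Returns a list of (vessel_pos, (bg1, bg2)).
    """
    img = np.asarray(eroded_image, dtype=float)
    cx, cy = center_px
    R = 2.0 * papilla_radius_px
    theta = np.linspace(0, 2 * math.pi, n_angles, endpoint=False)
    px = cx + R * np.cos(theta)
    py = cy + R * np.sin(theta)
    inb = (px >= 0) & (px < img.shape[1]) & (py >= 0) & (py < img.shape[0])
    vals = np.full(n_angles, np.inf)
    vals[inb] = ndimage.map_coordinates(img, [py[inb], px[inb]], order=1)
    order = np.argsort(vals)
    min_sep = 0.35  # rad
    chosen: list[int] = []
    for idx in order:
        if not np.isfinite(vals[idx]):
            break
        th = theta[idx]
        if all(
            min(abs(th - theta[c]), 2 * math.pi - abs(th - theta[c])) > min_sep
            for c in chosen
        ):
            chosen.append(int(idx))
        if len(chosen) == n_venules:
            break
    dth = flank_offset_px / R
    out = []
    for idx in chosen:
        th = theta[idx]
        vessel = (cx + R * math.cos(th), cy + R * math.sin(th))
        bgs = tuple(
            (cx + R * math.cos(th + s * dth), cy + R * math.sin(th + s * dth))
            for s in (-1.0, 1.0)
        )
        out.append((vessel, bgs))
    return out


def ring_contrast(
    eroded_image: np.ndarray,
    center_px,
    papilla_radius_px: float,
    positions=None,
) -> ContrastResult:
    """Averaged Michelson vessel contrast on the 2x-papilla-radius ring.

    Each venule contributes one Michelson value computed between the mean of
    its two background samples and its on-vessel sample; the result's mean is
    the arithmetic mean over the venules.
    """
    img = np.asarray(eroded_image, dtype=float)
    if positions is None:
        positions = auto_venule_positions(img, center_px, papilla_radius_px)
    if not positions:
        raise ParameterError("no venule positions available")
    values = []
    kept = []
    for vessel, bgs in positions:
        vx, vy = int(round(vessel[0])), int(round(vessel[1]))
        i_vessel = img[vy, vx]
        i_bg = float(
            np.mean([img[int(round(b[1])), int(round(b[0]))] for b in bgs])
        )
        i_max, i_min = max(i_bg, i_vessel), min(i_bg, i_vessel)
        if i_max + i_min == 0:
            raise ParameterError("undefined contrast on the ring")
        values.append(float((i_max - i_min) / (i_max + i_min)))
        kept.append((vessel, bgs))
    return ContrastResult(
        positions=kept, values=tuple(values), mean=float(np.mean(values))
    )


def count_depth_positions(
    dmap: DepthMap, geom: PapillaGeometry, roi_factor: float = 5.5
) -> int:
    """Number of valid depth-map pixels inside the evaluation ROI.

    The ROI is the circle of diameter ``roi_factor`` times the papilla radius
    centered on the papilla, clipped to the map."""
    h, w = dmap.valid.shape
    cx, cy = geom.center_px
    r = roi_factor * geom.radius_px / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
    return int(np.count_nonzero(dmap.valid & inside))
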