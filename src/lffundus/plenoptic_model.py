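"""Camera geometry of a focused plenoptic ("plenoptic 2.0") fundus imager.

A focused plenoptic camera re-images an intermediate image of the retina
through a hexagonal microlens array (MLA); every microlens projects a small,
slightly shifted subimage of the scene onto the sensor.  Depth follows from
the parallax between neighboring subimages: a scene point seen by two lenses
separated by a baseline ``b`` (pixels) at disparity ``d`` (pixels) sits at
virtual depth ``v = b / d``, the Perwass–Wietzke convention in units of the
MLA-to-sensor distance.  Virtual depth differences are converted to metric
object-space depth by dividing by the axial magnification, the square of the
lateral magnification of the fore-optics (1.5 laterally, hence 2.25 axially
for the reference configuration).

This module holds the sensor / MLA / magnification descriptions, the hex-grid
construction with its three interleaved focal-length types, the disparity to
virtual-depth triangulation, and the JSON camera-configuration interface.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "GeometryError",
    "TriangulationError",
    "LENS_TYPES",
    "SensorSpec",
    "MicrolensArray",
    "MagnificationModel",
    "VirtualDepth",
    "CameraConfig",
    "build_hex_grid",
    "lens_neighbors",
    "disparity_to_virtual_depth",
    "virtual_to_metric_depth",
    "full_camera",
    "desk_camera",
]


class GeometryError(ValueError):
    """Invalid sensor/MLA geometry."""


class TriangulationError(ValueError):
    """Triangulation impossible (non-positive disparity)."""


#: The three interleaved focal-length types of the multi-focus MLA.
LENS_TYPES = ("near", "middle", "far")

# Axial-coordinate offsets of the six hex neighbors.
_HEX_NEIGHBOR_OFFSETS = ((1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1))


@dataclass(frozen=True)
class SensorSpec:
    """Monochrome CMOS sensor: raster size, pixel pitch and bit depth."""

    width_px: int
    height_px: int
    pixel_pitch_um: float
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.width_px < 1 or self.height_px < 1:
            raise GeometryError("sensor dimensions must be >= 1 px")
        if self.pixel_pitch_um <= 0:
            raise GeometryError("pixel pitch must be positive")
        if self.bit_depth not in (8, 16):
            raise GeometryError("bit depth must be 8 or 16")

    @property
    def full_scale(self) -> int:
        """Largest representable gray value."""
        return (1 << self.bit_depth) - 1

    @property
    def diagonal_mm(self) -> float:
        """Sensor diagonal in mm (9.33 mm for the 4024x3036 @ 1.85 um reference sensor)."""
        return math.hypot(self.width_px, self.height_px) * self.pixel_pitch_um * 1e-3


@dataclass(eq=False)
class MicrolensArray:
    """Hexagonal grid of microlens centers on the sensor.

    ``centers_xy`` holds (x, y) sensor coordinates (0-based, pixel centers at
    integer coordinates); ``axial_qr`` the integer axial hex coordinates used
    for neighbor lookup, and ``lens_type`` the per-lens focal-length label
    index into :data:`LENS_TYPES`.
    """

    lens_pitch_um: float
    pitch_px: float
    centers_xy: np.ndarray  # (N, 2) float
    axial_qr: np.ndarray  # (N, 2) int
    lens_type: np.ndarray  # (N,) int in {0, 1, 2}
    orientation: float = 0.0  # rad; one lattice axis at this angle to sensor rows
    axes: np.ndarray = field(default=None)  # (2, 2): lattice basis vectors in px

    def __post_init__(self) -> None:
        self.centers_xy = np.asarray(self.centers_xy, dtype=float).reshape(-1, 2)
        self.axial_qr = np.asarray(self.axial_qr, dtype=int).reshape(-1, 2)
        self.lens_type = np.asarray(self.lens_type, dtype=int).reshape(-1)
        self._index = {tuple(qr): i for i, qr in enumerate(map(tuple, self.axial_qr))}

    def __len__(self) -> int:
        return len(self.centers_xy)

    @property
    def footprint_radius_px(self) -> float:
        return self.pitch_px / 2.0

    def lens_type_name(self, lens_id: int) -> str:
        return LENS_TYPES[self.lens_type[lens_id]]

    def lens_id_at(self, q: int, r: int) -> int | None:
        return self._index.get((q, r))


@dataclass(frozen=True)
class MagnificationModel:
    """Lateral / axial magnification of the fore-optics.

    The axial magnification equals the square of the lateral one; depth in
    virtual units divides by it to reach object-space mm.  The nominal depth
    resolution of the reference setup (18 um) is carried as metadata only.
    """

    lateral_mag: float
    axial_mag: float = None  # type: ignore[assignment]
    depth_resolution_um: float | None = None

    def __post_init__(self) -> None:
        if self.lateral_mag <= 0:
            raise GeometryError("lateral magnification must be positive")
        if self.axial_mag is None:
            object.__setattr__(self, "axial_mag", self.lateral_mag**2)
        if abs(self.axial_mag - self.lateral_mag**2) > 1e-9:
            raise GeometryError("axial magnification must equal lateral_mag**2")


@dataclass(frozen=True)
class VirtualDepth:
    """A (dimensionless) virtual depth; 'v-mm' once scaled by the map scale."""

    v: float

    def __post_init__(self) -> None:
        if not self.v > 0:
            raise TriangulationError("virtual depth must be positive")

    def __float__(self) -> float:
        return float(self.v)


def build_hex_grid(
    sensor: SensorSpec,
    lens_pitch_um: float,
    orientation: float = 0.0,
    offset_px: tuple[float, float] = (0.0, 0.0),
) -> MicrolensArray:
    """Construct the hexagonal MLA whose full subimage footprints fit the sensor.

    One lattice axis runs at ``orientation`` radians to the sensor rows; the
    grid is anchored so that (for zero offset) one lens center coincides with
    the sensor center.  Lens types are assigned by the proper 3-coloring
    ``(q - r) mod 3`` of the axial hex coordinates, so no two adjacent lenses
    share a focal-length type.
    """
    pitch_px = lens_pitch_um / sensor.pixel_pitch_um
    if pitch_px < 3.0:
        raise GeometryError(
            f"lens pitch spans {pitch_px:.2f} px; at least 3 px are required"
        )
    a1 = pitch_px * np.array([math.cos(orientation), math.sin(orientation)])
    a2 = pitch_px * np.array(
        [math.cos(orientation + math.pi / 3), math.sin(orientation + math.pi / 3)]
    )
    center0 = np.array(
        [(sensor.width_px - 1) / 2 + offset_px[0], (sensor.height_px - 1) / 2 + offset_px[1]]
    )
    nmax = int(math.ceil((sensor.width_px + sensor.height_px) / pitch_px)) + 2
    q, r = np.meshgrid(np.arange(-nmax, nmax + 1), np.arange(-nmax, nmax + 1), indexing="ij")
    q = q.ravel()
    r = r.ravel()
    centers = center0 + q[:, None] * a1 + r[:, None] * a2
    rad = pitch_px / 2.0
    tol = 1e-9
    # Full footprint containment within the sensor's pixel extent [-0.5, n-0.5].
    ok = (
        (centers[:, 0] - rad >= -0.5 - tol)
        & (centers[:, 0] + rad <= sensor.width_px - 0.5 + tol)
        & (centers[:, 1] - rad >= -0.5 - tol)
        & (centers[:, 1] + rad <= sensor.height_px - 0.5 + tol)
    )
    q, r, centers = q[ok], r[ok], centers[ok]
    order = np.lexsort((q, r))
    q, r, centers = q[order], r[order], centers[order]
    types = np.mod(q - r, 3)
    return MicrolensArray(
        lens_pitch_um=lens_pitch_um,
        pitch_px=pitch_px,
        centers_xy=centers,
        axial_qr=np.stack([q, r], axis=1),
        lens_type=types,
        orientation=orientation,
        axes=np.stack([a1, a2]),
    )


def lens_neighbors(mla: MicrolensArray, lens_id: int) -> list[tuple[int, float]]:
    """First-ring hex neighbors of ``lens_id`` with their baselines in pixels."""
    if not 0 <= lens_id < len(mla):
        raise LookupError(f"unknown lens id {lens_id}")
    q0, r0 = mla.axial_qr[lens_id]
    out: list[tuple[int, float]] = []
    for dq, dr in _HEX_NEIGHBOR_OFFSETS:
        j = mla.lens_id_at(q0 + dq, r0 + dr)
        if j is not None:
            baseline = float(np.linalg.norm(mla.centers_xy[j] - mla.centers_xy[lens_id]))
            out.append((j, baseline))
    return out


def disparity_to_virtual_depth(disparity_px: float, baseline_px: float) -> VirtualDepth:
    """Triangulate: ``v = baseline / disparity`` (strictly decreasing in disparity)."""
    if baseline_px <= 0:
        raise GeometryError("baseline must be positive")
    if disparity_px <= 0:
        raise TriangulationError("no triangulation for non-positive disparity")
    return VirtualDepth(baseline_px / disparity_px)


def virtual_to_metric_depth(v_mm: float | VirtualDepth, mag: MagnificationModel) -> float:
    """Convert a virtual-depth difference (v-mm) to object-space mm.

    Divides by the axial magnification (2.25 for the reference 1.5x lateral
    magnification); linear by construction.
    """
    if mag.axial_mag <= 0:
        raise GeometryError("axial magnification must be positive")
    return float(v_mm) / mag.axial_mag


@dataclass(frozen=True)
class CameraConfig:
    """Complete camera description, serializable to/from the JSON config.

    ``reference_virtual_depth`` is the virtual depth at which a fundus point
    of zero elevation is rendered (the simulation's focal anchoring), and
    ``map_scale_vmm`` converts raw virtual depth to the map's "v-mm" units
    (default 1.0: v-mm equals v).
    """

    sensor: SensorSpec
    lens_pitch_um: float
    magnification: MagnificationModel
    mla_orientation_deg: float = 0.0
    mla_offset_px: tuple[float, float] = (0.0, 0.0)
    reference_virtual_depth: float = 3.2
    map_scale_vmm: float = 1.0

    def build_mla(self) -> MicrolensArray:
        return build_hex_grid(
            self.sensor,
            self.lens_pitch_um,
            orientation=math.radians(self.mla_orientation_deg),
            offset_px=self.mla_offset_px,
        )

    @property
    def pitch_px(self) -> float:
        return self.lens_pitch_um / self.sensor.pixel_pitch_um

    @property
    def mm_per_px_object(self) -> float:
        """Object-space mm spanned by one sensor pixel."""
        return self.sensor.pixel_pitch_um * 1e-3 / self.magnification.lateral_mag

    def to_dict(self) -> dict:
        return {
            "sensor": {
                "width_px": self.sensor.width_px,
                "height_px": self.sensor.height_px,
                "pixel_pitch_um": self.sensor.pixel_pitch_um,
                "bit_depth": self.sensor.bit_depth,
            },
            "mla": {
                "lens_pitch_um": self.lens_pitch_um,
                "orientation_deg": self.mla_orientation_deg,
                "offset_px": list(self.mla_offset_px),
            },
            "magnification": {
                "lateral": self.magnification.lateral_mag,
                "depth_resolution_um": self.magnification.depth_resolution_um,
            },
            "rendering": {
                "reference_virtual_depth": self.reference_virtual_depth,
                "map_scale_vmm": self.map_scale_vmm,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraConfig":
        rend = d.get("rendering", {})
        return cls(
            sensor=SensorSpec(**d["sensor"]),
            lens_pitch_um=d["mla"]["lens_pitch_um"],
            mla_orientation_deg=d["mla"].get("orientation_deg", 0.0),
            mla_offset_px=tuple(d["mla"].get("offset_px", (0.0, 0.0))),
            magnification=MagnificationModel(
                lateral_mag=d["magnification"]["lateral"],
                depth_resolution_um=d["magnification"].get("depth_resolution_um"),
            ),
            reference_virtual_depth=rend.get("reference_virtual_depth", 3.0),
            map_scale_vmm=rend.get("map_scale_vmm", 1.0),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CameraConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def full_camera() -> CameraConfig:
    """The full-size reference configuration: 4024x3036 @ 1.85 um, 80 um hex MLA."""
    return CameraConfig(
        sensor=SensorSpec(4024, 3036, 1.85, 16),
        lens_pitch_um=80.0,
        magnification=MagnificationModel(lateral_mag=1.5, depth_resolution_um=18.0),
    )


def desk_camera() -> CameraConfig:
    """Reduced-scale default camera (1006x759 px, ~14.4 px lens pitch).

    The raster is the full sensor's divided by four per axis, at three times
    its pixel pitch, keeping the physical 80 um MLA: the subimage footprint
    still holds a 5 px matching patch (with its interpolation margin) at the
    working virtual depths, and the lens pitch stays - as on the full sensor
    - non-integer in pixels, so subimage sampling phases decorrelate across
    lens pairs instead of aliasing coherently.
    """
    return CameraConfig(
        sensor=SensorSpec(1006, 759, 5.55, 16),
        lens_pitch_um=80.0,
        magnification=MagnificationModel(lateral_mag=1.5, depth_resolution_um=18.0),
    )
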