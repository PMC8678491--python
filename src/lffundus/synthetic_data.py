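"""Synthetic eye-model scenes and raw light-field rendering.

The generator emulates a 1:1 physical eye phantom: a spherical fundus of
radius 10 mm carrying an optic-disc excavation (interchangeable cup depths
0.2 / 0.4 / 0.8 / 1.0 mm), hand-painted vessels (here seeded smooth curves
radiating from the disc), and a wavelength-dependent reflectance texture.
Raw plenoptic captures are rendered with an exact inverse of the depth
estimation contract: a scene point at virtual depth ``v`` appears displaced
by ``baseline / v`` pixels between adjacent subimages.  Virtual depth is tied
to the surface elevation ``z`` (mm of axial sag plus cup) through

    v(x, y) = v_ref + axial_mag * z(x, y)

so a metric cup depth of ``d`` mm produces a virtual depth step of
``axial_mag * d`` v-units, which the downstream metric correction divides out
again.  Subimages are non-inverted pinhole views (the physical per-lenslet
image inversion cancels in disparity and is omitted); occlusion at steep cup
walls is not modeled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .plenoptic_model import CameraConfig, MicrolensArray, SensorSpec

__all__ = [
    "ParameterError",
    "DomainError",
    "RenderError",
    "SpectralContrastModel",
    "FundusScene",
    "RawLightField",
    "make_fundus_scene",
    "scene_depth",
    "render_raw_lightfield",
    "render_edge_target",
    "inject_artifacts",
    "BANDS_NM",
    "ARTIFACT_KINDS",
]


class ParameterError(ValueError):
    """Scene or artifact parameters outside their valid range."""


class DomainError(ValueError):
    """Query point outside the imaged field."""


class RenderError(ValueError):
    """Scene and camera are inconsistent."""


#: Illumination bandpass centers of the illumination filter set (nm).
BANDS_NM = (450, 520, 600, 650)

ARTIFACT_KINDS = ("checkerboard_reflection", "hex_blur_dots", "fixation_needle")

# Fraction of full scale reached by a unit-reflectance surface.
_ILLUMINATION = 0.82


@dataclass(frozen=True)
class SpectralContrastModel:
    """Wavelength dependence of vessel contrast and choroid visibility.

    Vessel Michelson contrast peaks in the green (520 nm) where hemoglobin
    absorption is strong, and collapses in the red (650 nm) where blood
    reflects; the choroid becomes progressively visible at long wavelengths
    but carries too little contrast for depth estimation.
    """

    vessel_contrast: dict = field(
        default_factory=lambda: {450: 0.50, 520: 0.70, 600: 0.35, 650: 0.15}
    )
    choroid_visibility: dict = field(
        default_factory=lambda: {450: 0.0, 520: 0.05, 600: 0.35, 650: 0.65}
    )

    def __post_init__(self) -> None:
        c = self.vessel_contrast
        if not all(0.0 <= v <= 1.0 for v in c.values()):
            raise ParameterError("vessel contrasts must lie in [0, 1]")
        if 520 in c and c[520] != max(c.values()):
            raise ParameterError("vessel contrast must peak at 520 nm")
        if 650 in c and c[650] != min(c.values()):
            raise ParameterError("vessel contrast must be minimal at 650 nm")


@dataclass(eq=False)
class FundusScene:
    """Parametric fundus surface plus per-band reflectance texture.

    The depth surface is analytic (sphere sag + cup profile); the texture
    components (vessel mask, speckle mottling, choroid pattern) are seeded
    rasters on an internal mm-grid so that rendering is independent of the
    camera raster actually used.
    """

    fundus_radius_mm: float
    papilla_depth_mm: float
    papilla_radius_mm: float
    papilla_center_mm: tuple[float, float]
    cup_profile: str
    background_reflectance: float
    band_nm: int
    seed: int
    spectral: SpectralContrastModel
    field_size_mm: tuple[float, float]
    vessels: list  # list of (polyline_mm (K,2), width_mm (K,))
    # internal texture rasters (row-major, y then x), mm grid
    _grid_mm_per_px: float = 0.004
    _vessel_mask: np.ndarray = None
    _speckle: np.ndarray = None
    _choroid: np.ndarray = None

    # -- geometry ---------------------------------------------------------

    def _cup(self, dist_mm: np.ndarray) -> np.ndarray:
        t = dist_mm / self.papilla_radius_mm
        if self.cup_profile == "flat_bottom_steep_wall":
            flat = 0.55
            x = np.clip((1.0 - t) / (1.0 - flat), 0.0, 1.0)
            prof = 3 * x**2 - 2 * x**3  # smoothstep: flat bottom, steep wall
        elif self.cup_profile == "cosine":
            prof = np.where(t < 1.0, np.cos(np.pi * np.clip(t, 0, 1) / 2) ** 2, 0.0)
        else:  # pragma: no cover - guarded in make_fundus_scene
            raise ParameterError(f"unknown cup profile {self.cup_profile!r}")
        return self.papilla_depth_mm * prof

    def depth_mm(self, x_mm, y_mm, check_domain: bool = True) -> np.ndarray:
        """Axial sag of the fundus surface (mm, positive away from the camera).

        Sphere sag relative to the apex at the optical axis, plus the cup
        contribution inside the papilla; exactly ``papilla_depth_mm`` extra at
        the papilla center.
        """
        x = np.asarray(x_mm, dtype=float)
        y = np.asarray(y_mm, dtype=float)
        wx, wy = self.field_size_mm
        if check_domain and (
            np.any(np.abs(x) > wx / 2 + 1e-9) or np.any(np.abs(y) > wy / 2 + 1e-9)
        ):
            raise DomainError("query point outside the imaged field")
        r2 = x**2 + y**2
        R = self.fundus_radius_mm
        sag = R - np.sqrt(np.maximum(R**2 - r2, 0.0))
        dist = np.hypot(x - self.papilla_center_mm[0], y - self.papilla_center_mm[1])
        return sag + self._cup(dist)

    # -- texture ----------------------------------------------------------

    def _grid_shape(self) -> tuple[int, int]:
        wx, wy = self.field_size_mm
        return (
            int(round(wy / self._grid_mm_per_px)) + 1,
            int(round(wx / self._grid_mm_per_px)) + 1,
        )

    def _mm_to_grid(self, x_mm: np.ndarray, y_mm: np.ndarray) -> np.ndarray:
        ny, nx = self._grid_shape()
        gx = np.asarray(x_mm) / self._grid_mm_per_px + (nx - 1) / 2
        gy = np.asarray(y_mm) / self._grid_mm_per_px + (ny - 1) / 2
        return np.stack([gy, gx])

    def reflectance_grid(self, band_nm: int | None = None) -> np.ndarray:
        """Reflectance texture in [0, 1] on the internal mm grid."""
        band = self.band_nm if band_nm is None else band_nm
        if band not in self.spectral.vessel_contrast:
            raise ParameterError(f"unknown band {band} nm")
        C = self.spectral.vessel_contrast[band]
        a_speckle = 0.25 * C + 0.03
        a_choroid = 0.03 * self.spectral.choroid_visibility[band]
        ny, nx = self._grid_shape()
        x = (np.arange(nx) - (nx - 1) / 2) * self._grid_mm_per_px
        y = (np.arange(ny) - (ny - 1) / 2) * self._grid_mm_per_px
        xx, yy = np.meshgrid(x, y)
        dist = np.hypot(xx - self.papilla_center_mm[0], yy - self.papilla_center_mm[1])
        # the pale optic disc: soft-edged brightening inside the papilla
        disc = np.clip((self.papilla_radius_mm - dist) / 0.05, 0.0, 1.0)
        base = self.background_reflectance * (1.0 + 0.35 * disc)
        base = base * (1.0 + a_speckle * self._speckle + a_choroid * self._choroid)
        vessel_factor = (1.0 - C) / (1.0 + C)
        refl = base * vessel_factor**self._vessel_mask
        return np.clip(refl, 0.0, 1.0)

    def sample_reflectance(self, x_mm, y_mm, band_nm: int | None = None) -> np.ndarray:
        grid = self.reflectance_grid(band_nm)
        return ndimage.map_coordinates(
            grid, self._mm_to_grid(x_mm, y_mm), order=1, mode="nearest"
        )


@dataclass(eq=False)
class RawLightField:
    """A raw plenoptic capture: 16-bit raster plus the camera that took it."""

    pixels: np.ndarray
    camera: CameraConfig
    mla: MicrolensArray
    band_nm: int
    seed: int

    def __post_init__(self) -> None:
        s = self.camera.sensor
        if self.pixels.shape != (s.height_px, s.width_px):
            raise RenderError("raster dimensions do not match the sensor")

    @property
    def sensor(self) -> SensorSpec:
        return self.camera.sensor


def make_fundus_scene(
    papilla_depth_mm: float,
    band_nm: int = 520,
    seed: int = 0,
    *,
    fundus_radius_mm: float = 10.0,
    papilla_radius_mm: float = 0.6,
    papilla_center_mm: tuple[float, float] = (0.35, 0.10),
    cup_profile: str = "flat_bottom_steep_wall",
    background_reflectance: float = 0.45,
    field_size_mm: tuple[float, float] = (5.4, 4.2),
    n_vessels: int = 8,
    spectral: SpectralContrastModel | None = None,
) -> FundusScene:
    """Build a seeded fundus scene; deterministic for a fixed seed.

    Vessels are smooth seeded curves radiating outward from the disc rim;
    their start angles avoid the four cardinal directions so the rim can be
    marked N/E/S/W without vessel overlap.  Mottled background texture
    ("speckle") stands in for the fine pigment/lacquer structure the matcher
    needs; a low-frequency choroid pattern appears at long wavelengths.
    """
    if papilla_depth_mm < 0:
        raise ParameterError("papilla depth must be non-negative")
    if cup_profile not in ("flat_bottom_steep_wall", "cosine"):
        raise ParameterError(f"unknown cup profile {cup_profile!r}")
    if not 0.0 <= background_reflectance <= 1.0:
        raise ParameterError("background reflectance must lie in [0, 1]")
    spectral = spectral or SpectralContrastModel()
    if band_nm not in spectral.vessel_contrast:
        raise ParameterError(f"unknown band {band_nm} nm")

    rng = np.random.default_rng(seed)
    scene = FundusScene(
        fundus_radius_mm=fundus_radius_mm,
        papilla_depth_mm=papilla_depth_mm,
        papilla_radius_mm=papilla_radius_mm,
        papilla_center_mm=papilla_center_mm,
        cup_profile=cup_profile,
        background_reflectance=background_reflectance,
        band_nm=band_nm,
        seed=seed,
        spectral=spectral,
        field_size_mm=field_size_mm,
        vessels=[],
    )
    mmpp = scene._grid_mm_per_px
    ny, nx = scene._grid_shape()

    # --- vessels: seeded smooth curves from the rim outward ---------------
    cardinal = np.array([0.0, 0.5, 1.0, 1.5]) * math.pi
    vessels = []
    vmask = np.zeros((ny, nx), dtype=float)
    r_out = 0.5 * math.hypot(*field_size_mm)
    for _ in range(n_vessels):
        while True:
            theta0 = rng.uniform(0, 2 * math.pi)
            if np.min(np.abs(np.angle(np.exp(1j * (theta0 - cardinal))))) > 0.22:
                break
        freq = rng.uniform(0.5, 1.5)
        phase = rng.uniform(0, 2 * math.pi)
        amp = rng.uniform(0.10, 0.35)
        w0 = rng.uniform(0.018, 0.030)
        rr = np.arange(papilla_radius_mm * 0.85, r_out, 0.5 * mmpp)
        # wiggle anchored at zero on the rim so start angles keep clear of the
        # cardinal rim-mark directions
        theta = theta0 + amp * (
            np.sin(freq * (rr - rr[0]) * 2.0 + phase) - math.sin(phase)
        )
        px = papilla_center_mm[0] + rr * np.cos(theta)
        py = papilla_center_mm[1] + rr * np.sin(theta)
        frac = (rr - rr[0]) / (rr[-1] - rr[0])
        width = w0 * (1 - frac) + 0.010 * frac
        vessels.append((np.stack([px, py], axis=1), width))
        # stamp tapered disks along the centerline
        gx = px / mmpp + (nx - 1) / 2
        gy = py / mmpp + (ny - 1) / 2
        rad_px = np.maximum(width / 2 / mmpp, 0.8)
        inside = (gx >= 0) & (gx < nx) & (gy >= 0) & (gy < ny)
        for cx, cy, rp in zip(gx[inside], gy[inside], rad_px[inside]):
            x0, x1 = int(cx - rp), int(cx + rp) + 1
            y0, y1 = int(cy - rp), int(cy + rp) + 1
            x0c, y0c = max(x0, 0), max(y0, 0)
            x1c, y1c = min(x1, nx), min(y1, ny)
            sub = vmask[y0c:y1c, x0c:x1c]
            yy, xx = np.ogrid[y0c:y1c, x0c:x1c]
            np.maximum(sub, ((xx - cx) ** 2 + (yy - cy) ** 2 <= rp**2) * 1.0, out=sub)
    vmask = ndimage.gaussian_filter(vmask, 2.0)
    scene.vessels = vessels
    scene._vessel_mask = np.clip(vmask, 0.0, 1.0)

    # --- mottled background and choroid pattern ---------------------------
    fine = ndimage.gaussian_filter(rng.standard_normal((ny, nx)), 0.012 / mmpp)
    coarse = ndimage.gaussian_filter(rng.standard_normal((ny, nx)), 0.028 / mmpp)
    speckle = fine / fine.std() + coarse / coarse.std()
    scene._speckle = speckle / speckle.std()
    choroid = ndimage.gaussian_filter(rng.standard_normal((ny, nx)), 0.12 / mmpp)
    scene._choroid = choroid / choroid.std()
    return scene


def scene_depth(scene: FundusScene, x_mm, y_mm):
    """Axial depth (mm sag) of the fundus surface at object coordinates."""
    return scene.depth_mm(x_mm, y_mm)


def _virtual_depth_field(scene: FundusScene, camera: CameraConfig, x_mm, y_mm):
    z = scene.depth_mm(x_mm, y_mm, check_domain=False)
    return camera.reference_virtual_depth + camera.magnification.axial_mag * z


def render_raw_lightfield(
    scene: FundusScene,
    camera: CameraConfig,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> RawLightField:
    """Render the raw plenoptic capture of a scene.

    Each microlens forms a non-inverted pinhole view: the subimage pixel at
    offset ``u`` from lens center ``c`` samples the scene texture at the
    virtual-image position ``X = c + u * v(X)`` (fixed-point iterated), which
    makes the inter-subimage disparity of a point at virtual depth ``v``
    exactly ``baseline / v``.  Each footprint is a hard circular vignette;
    additive Gaussian noise of ``noise_sd`` (fraction of full scale) is
    applied on the linear intensity before quantization.
    """
    sensor = camera.sensor
    mm_per_px = camera.mm_per_px_object
    wx, wy = scene.field_size_mm
    fov_x = sensor.width_px * mm_per_px
    fov_y = sensor.height_px * mm_per_px
    if fov_x > wx + 1e-9 or fov_y > wy + 1e-9:
        raise RenderError("scene field does not cover the camera field of view")

    mla = camera.build_mla()
    H, W = sensor.height_px, sensor.width_px
    cx0, cy0 = (W - 1) / 2, (H - 1) / 2

    # texture and virtual-depth fields sampled on the sensor-plane grid
    xs = (np.arange(W) - cx0) * mm_per_px
    ys = (np.arange(H) - cy0) * mm_per_px
    xx, yy = np.meshgrid(xs, ys)
    tex = scene.sample_reflectance(xx, yy)
    # pixel-aperture band-limit: one sensor pixel integrates ~v texture pixels
    # of the v-times minified subimage view, approximated by a Gaussian at the
    # reference virtual depth
    tex = ndimage.gaussian_filter(tex, 0.3 * camera.reference_virtual_depth)
    vfield = _virtual_depth_field(scene, camera, xx, yy)

    r_foot = mla.footprint_radius_px
    k = int(math.ceil(r_foot))
    oy, ox = np.mgrid[-k : k + 1, -k : k + 1]
    offs = np.stack([ox.ravel(), oy.ravel()], axis=1)  # (K,2) x,y

    c = mla.centers_xy  # (N,2)
    cr = np.rint(c).astype(int)
    pix = cr[:, None, :] + offs[None, :, :]  # (N,K,2)
    u = pix - c[:, None, :]
    mask = (np.einsum("nkd,nkd->nk", u, u) <= r_foot**2) & (
        (pix[..., 0] >= 0) & (pix[..., 0] < W) & (pix[..., 1] >= 0) & (pix[..., 1] < H)
    )
    pu = u[mask]  # (M,2)
    ppix = pix[mask]
    pcen = np.broadcast_to(c[:, None, :], pix.shape)[mask]

    # fixed-point iteration X = c + u * v(X); v varies slowly laterally
    v = ndimage.map_coordinates(vfield, [ppix[:, 1], ppix[:, 0]], order=1, mode="nearest")
    for _ in range(3):
        X = pcen + pu * v[:, None]
        v = ndimage.map_coordinates(vfield, [X[:, 1], X[:, 0]], order=1, mode="nearest")
    X = pcen + pu * v[:, None]
    vals = ndimage.map_coordinates(tex, [X[:, 1], X[:, 0]], order=1, mode="nearest")

    raw = np.zeros((H, W), dtype=float)
    raw[ppix[:, 1], ppix[:, 0]] = _ILLUMINATION * vals * sensor.full_scale
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        raw = raw + rng.normal(0.0, noise_sd * sensor.full_scale, size=raw.shape)
    raw = np.clip(np.rint(raw), 0, sensor.full_scale)
    dtype = np.uint16 if sensor.bit_depth == 16 else np.uint8
    return RawLightField(raw.astype(dtype), camera, mla, scene.band_nm, seed)


def render_edge_target(
    camera: CameraConfig,
    blur_sigma_px: float,
    angle_deg: float = 90.0,
    size: tuple[int, int] = (400, 160),
) -> tuple[np.ndarray, np.ndarray]:
    """Back-illuminated straight-edge target for MTF measurement.

    Returns a pair of rasters (the light-field total-focus equivalent and a
    conventional-camera image at half sampling): a dark-to-bright edge of the
    given orientation (90 deg = vertical by convention), blurred by a
    Gaussian of ``blur_sigma_px``.  ``sigma = 0`` yields an ideal step whose
    edge-spread follows the Gaussian CDF otherwise.
    """
    if blur_sigma_px < 0:
        raise ParameterError("blur sigma must be non-negative")
    W, Hh = size
    full = camera.sensor.full_scale
    lo, hi = 0.06 * full, 0.90 * full

    def _edge(w: int, h: int, sigma: float) -> np.ndarray:
        xx, yy = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
        nrm = math.radians(angle_deg - 90.0)
        s = (xx - ((w - 1) / 2 + 0.25)) * math.cos(nrm) + (
            yy - ((h - 1) / 2 + 0.25)
        ) * math.sin(nrm)
        if sigma == 0:
            t = (s > 0).astype(float)
        else:
            from scipy.special import ndtr

            t = ndtr(s / sigma)
        return np.rint(lo + (hi - lo) * t).astype(np.uint16)

    lf = _edge(W, Hh, blur_sigma_px)
    conventional = _edge(W // 2, Hh // 2, blur_sigma_px / 2)
    return lf, conventional


def inject_artifacts(
    raw: RawLightField, kinds: Sequence[str], seed: int = 0
) -> RawLightField:
    """Overlay typical acquisition artifact classes on a raw capture.

    ``checkerboard_reflection`` raises local mean intensity in alternating
    blurred tiles (corneal/lens back reflections); ``hex_blur_dots`` adds
    round blurred dots aligned with the MLA lattice (red-light reflections);
    ``fixation_needle`` draws the internal fixation needle as a straight
    high-contrast line.  An empty kind set returns an identical copy.
    """
    unknown = set(kinds) - set(ARTIFACT_KINDS)
    if unknown:
        raise ParameterError(f"unknown artifact kinds: {sorted(unknown)}")
    img = raw.pixels.astype(float)
    H, W = img.shape
    full = raw.sensor.full_scale
    rng = np.random.default_rng(seed)
    pitch = raw.mla.pitch_px

    if "checkerboard_reflection" in kinds:
        tile = max(int(round(6 * pitch)), 8)
        yy, xx = np.mgrid[0:H, 0:W]
        checker = ((xx // tile + yy // tile) % 2).astype(float)
        cx, cy = rng.uniform(0.3, 0.7) * W, rng.uniform(0.3, 0.7) * H
        region = np.exp(-(((xx - cx) / (0.35 * W)) ** 2 + ((yy - cy) / (0.35 * H)) ** 2))
        img = img + 0.18 * full * ndimage.gaussian_filter(checker, pitch / 3) * region

    if "hex_blur_dots" in kinds:
        splat = np.zeros((H, W), dtype=float)
        for x, y in raw.mla.centers_xy:
            x0, y0 = int(math.floor(x)), int(math.floor(y))
            fx, fy = x - x0, y - y0
            for dy in (0, 1):
                for dx in (0, 1):
                    px, py = x0 + dx, y0 + dy
                    if 0 <= px < W and 0 <= py < H:
                        wgt = (fx if dx else 1 - fx) * (fy if dy else 1 - fy)
                        splat[py, px] += wgt
        sigma = max(pitch / 6.0, 1.0)
        dots = ndimage.gaussian_filter(splat, sigma)
        if dots.max() > 0:
            dots = dots / dots.max()
        img = img + 0.12 * full * dots

    if "fixation_needle" in kinds:
        theta = rng.uniform(0, math.pi)
        n = np.array([-math.sin(theta), math.cos(theta)])
        p0 = np.array([W / 2 + rng.uniform(-0.1, 0.1) * W, H / 2 + rng.uniform(-0.1, 0.1) * H])
        yy, xx = np.mgrid[0:H, 0:W]
        dist = np.abs((xx - p0[0]) * n[0] + (yy - p0[1]) * n[1])
        img = np.where(dist < 1.5, 0.95 * full, img)

    img = np.clip(np.rint(img), 0, full).astype(raw.pixels.dtype)
    return RawLightField(img, raw.camera, raw.mla, raw.band_nm, raw.seed)
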