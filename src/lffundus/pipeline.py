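"""Packaged experiments: eye-model depth study and spectral study.

``run_model_study`` reproduces the eye-model experiment: for every cup depth
in the configured set and every seeded replicate a scene is generated,
rendered, depth-estimated, densified, and its cup depth measured with the
85 px averaging circle; the measured metric depths are then calibrated
linearly against the printed model depths.  ``run_spectral_study`` renders
the same scene at each illumination band and evaluates the eroded-image
Michelson vessel contrast and the number of reconstructed depth positions in
the 5.5-papilla-radius ROI, reporting which band maximizes each.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .depth_estimation import MatchingParams, estimate_depth
from .depth_map import (
    BilateralParams,
    DepthMap,
    FillParams,
    bilateral_smooth,
    fill_and_filter,
    rasterize_depth,
    render_total_focus,
)
from .image_quality import (
    PapillaGeometry,
    count_depth_positions,
    erode_disc,
    papilla_center,
    ring_contrast,
)
from .papilla_metrics import CalibrationFit, fit_linear_calibration, model_papilla_depth
from .plenoptic_model import CameraConfig, desk_camera
from .synthetic_data import (
    BANDS_NM,
    FundusScene,
    ParameterError,
    make_fundus_scene,
    render_raw_lightfield,
)

__all__ = [
    "ExperimentConfig",
    "RunConfig",
    "ModelStudyReport",
    "SpectralStudyReport",
    "scene_papilla_geometry",
    "process_raw",
    "run_model_study",
    "run_spectral_study",
]

log = logging.getLogger("lffundus")

_SEED_MOD = 2**31


@dataclass(frozen=True)
class ExperimentConfig:
    """Study conditions: depth set, replicates, bands, seeds, noise.

    A physical bench campaign would take ~30 captures per model depth; the default here is
    5 seeded replicates at the reduced desk scale.  The model study renders
    at the low bench noise level; the spectral study uses a higher noise
    level emulating the photon-starved in-vivo captures.
    """

    depths_mm: tuple = (0.2, 0.4, 0.8, 1.0)
    replicates: int = 5
    bands_nm: tuple = (450, 520, 600, 650)
    base_seed: int = 0
    noise_sd: float = 0.005
    spectral_noise_sd: float = 0.02
    papilla_radius_mm: float = 0.6
    papilla_center_mm: tuple = (0.35, 0.10)

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.depths_mm):
            raise ParameterError("model depths must be non-negative")
        if self.replicates < 0:
            raise ParameterError("replicates must be >= 0")
        unknown = set(self.bands_nm) - set(BANDS_NM)
        if unknown:
            raise ParameterError(f"unknown bands: {sorted(unknown)}")

    def to_dict(self) -> dict:
        return {
            "depths_mm": list(self.depths_mm),
            "replicates": self.replicates,
            "bands_nm": list(self.bands_nm),
            "base_seed": self.base_seed,
            "noise_sd": self.noise_sd,
            "spectral_noise_sd": self.spectral_noise_sd,
            "papilla_radius_mm": self.papilla_radius_mm,
            "papilla_center_mm": list(self.papilla_center_mm),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        for key in ("depths_mm", "bands_nm", "papilla_center_mm"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def make_scene(self, depth_mm: float, band_nm: int, seed: int) -> FundusScene:
        return make_fundus_scene(
            depth_mm,
            band_nm=band_nm,
            seed=seed,
            papilla_radius_mm=self.papilla_radius_mm,
            papilla_center_mm=self.papilla_center_mm,
        )


@dataclass(frozen=True)
class RunConfig:
    """Complete run configuration; defaults reproduce the reference parameter set."""

    camera: CameraConfig = field(default_factory=desk_camera)
    matching: MatchingParams = field(default_factory=MatchingParams)
    fill: FillParams = field(default_factory=FillParams)
    bilateral: BilateralParams = field(default_factory=BilateralParams)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)

    def to_dict(self) -> dict:
        return {
            "camera": self.camera.to_dict(),
            "matching": self.matching.to_dict(),
            "fill": self.fill.to_dict(),
            "bilateral": self.bilateral.to_dict(),
            "experiment": self.experiment.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            camera=CameraConfig.from_dict(d["camera"]) if "camera" in d else desk_camera(),
            matching=MatchingParams.from_dict(d.get("matching", {})),
            fill=FillParams.from_dict(d.get("fill", {})),
            bilateral=BilateralParams.from_dict(d.get("bilateral", {})),
            experiment=ExperimentConfig.from_dict(d.get("experiment", {})),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(eq=False)
class ModelStudyReport:
    rows: pd.DataFrame
    fit: CalibrationFit
    n_failed: int


@dataclass(eq=False)
class SpectralStudyReport:
    rows: pd.DataFrame
    best_band_contrast_nm: int
    best_band_count_nm: int


def _derive_seed(base: int, k: int) -> int:
    return (base * 100003 + k * 1009 + 17) % _SEED_MOD


def scene_papilla_geometry(
    scene: FundusScene, camera: CameraConfig, map_resolution: tuple[int, int]
) -> PapillaGeometry:
    """Ground-truth papilla rim marks of a scene, in depth-map pixels.

    Substitutes manual N/E/S/W rim marking with the
    generator's known papilla center and radius.
    """
    W, H = camera.sensor.width_px, camera.sensor.height_px
    out_w, out_h = map_resolution
    mm = camera.mm_per_px_object

    def to_map(x_mm: float, y_mm: float) -> tuple[float, float]:
        xr = x_mm / mm + (W - 1) / 2
        yr = y_mm / mm + (H - 1) / 2
        return ((xr + 0.5) * out_w / W - 0.5, (yr + 0.5) * out_h / H - 0.5)

    cx, cy = scene.papilla_center_mm
    r = scene.papilla_radius_mm
    marks = {
        "N": to_map(cx, cy - r),
        "E": to_map(cx + r, cy),
        "S": to_map(cx, cy + r),
        "W": to_map(cx - r, cy),
    }
    return papilla_center(marks)


def process_raw(raw, config: RunConfig) -> DepthMap:
    """Raw capture -> filtered, smoothed depth map (the standard chain)."""
    points = estimate_depth(raw, config.matching)
    dmap = rasterize_depth(
        points, map_scale_vmm=config.camera.map_scale_vmm
    )
    dmap = fill_and_filter(dmap, config.fill)
    return bilateral_smooth(dmap, config.bilateral)


def _provenance(config: RunConfig, seed: int) -> dict:
    cfg = config.to_dict()
    digest = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()
    return {
        "config": cfg,
        "config_sha256": digest,
        "seed": seed,
        "versions": {
            "lffundus": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }


def run_model_study(
    config: RunConfig, out_dir: str | Path | None = None, seed: int = 0
) -> ModelStudyReport:
    """Eye-model depth study: scene -> raw -> depth map -> cup depth -> fit.

    Each (depth, replicate) pair gets its own derived seed; stage failures
    are logged per scene and skipped.  Raises if more than half of all scenes
    fail or the fit is impossible.
    """
    exp = config.experiment
    if exp.replicates == 0:
        raise ParameterError("model study needs at least one replicate")
    rows = []
    n_failed = 0
    k = 0
    for depth in exp.depths_mm:
        for rep in range(exp.replicates):
            scene_id = f"d{depth:.1f}_r{rep}"
            rep_seed = _derive_seed(seed + exp.base_seed, k)
            k += 1
            try:
                scene = exp.make_scene(depth, band_nm=520, seed=rep_seed)
                raw = render_raw_lightfield(
                    scene, config.camera, noise_sd=exp.noise_sd, seed=rep_seed
                )
                dmap = process_raw(raw, config)
                geom = scene_papilla_geometry(
                    scene, config.camera, (dmap.resolution[0], dmap.resolution[1])
                )
                res = model_papilla_depth(dmap, geom, config.camera.magnification)
            except Exception:  # noqa: BLE001 - per-scene robustness
                log.exception("model study scene %s failed", scene_id)
                n_failed += 1
                continue
            rows.append(
                {
                    "scene_id": scene_id,
                    "true_depth_mm": depth,
                    "depth_h_vmm": res.depth_h_vmm,
                    "depth_v_vmm": res.depth_v_vmm,
                    "depth_mean_vmm": res.depth_mean_vmm,
                    "depth_mm": res.depth_mm,
                }
            )
    total = len(exp.depths_mm) * exp.replicates
    if n_failed > total / 2:
        raise RuntimeError(f"{n_failed}/{total} model-study scenes failed")
    df = pd.DataFrame(rows)
    fit = fit_linear_calibration(df[["true_depth_mm", "depth_mm"]].to_numpy())
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "model_study.csv", index=False)
        (out / "calibration.json").write_text(
            json.dumps(
                {"slope": fit.slope, "offset": fit.offset, "r_squared": fit.r_squared},
                indent=2,
            )
        )
        (out / "provenance.json").write_text(
            json.dumps(_provenance(config, seed), indent=2)
        )
    return ModelStudyReport(rows=df, fit=fit, n_failed=n_failed)


def run_spectral_study(
    config: RunConfig,
    out_dir: str | Path | None = None,
    seed: int = 0,
    papilla_depth_mm: float = 0.8,
) -> SpectralStudyReport:
    """Per-band Michelson contrast and depth-position count on one scene.

    The same scene geometry is rendered at every configured band; vessel
    contrast is measured on the eroded total-focus image at the ring of twice
    the papilla radius, depth positions are counted in the 5.5-radius ROI.
    """
    exp = config.experiment
    scene_seed = _derive_seed(seed + exp.base_seed, 9001)
    rows = []
    for band in exp.bands_nm:
        scene = exp.make_scene(papilla_depth_mm, band_nm=band, seed=scene_seed)
        raw = render_raw_lightfield(
            scene, config.camera, noise_sd=exp.spectral_noise_sd, seed=scene_seed + band
        )
        dmap = process_raw(raw, config)
        tf = render_total_focus(raw, dmap)
        eroded = erode_disc(tf, 8)
        # papilla geometry in total-focus pixels for the contrast ring
        th, tw = tf.shape
        geom_tf = scene_papilla_geometry(scene, config.camera, (tw, th))
        contrast = ring_contrast(eroded, geom_tf.center_px, geom_tf.radius_px)
        geom_map = scene_papilla_geometry(
            scene, config.camera, (dmap.resolution[0], dmap.resolution[1])
        )
        count = count_depth_positions(dmap, geom_map)
        rows.append(
            {
                "band_nm": band,
                "michelson_mean": contrast.mean,
                "michelson_sd": float(np.std(contrast.values)),
                "depth_position_count": count,
            }
        )
    df = pd.DataFrame(rows)
    df["count_normalized"] = df["depth_position_count"] / df["depth_position_count"].max()
    best_contrast = int(df.loc[df["michelson_mean"].idxmax(), "band_nm"])
    best_count = int(df.loc[df["depth_position_count"].idxmax(), "band_nm"])
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "spectral_study.csv", index=False)
        (out / "spectral_summary.json").write_text(
            json.dumps(
                {
                    "best_band_contrast_nm": best_contrast,
                    "best_band_count_nm": best_count,
                },
                indent=2,
            )
        )
        (out / "provenance.json").write_text(
            json.dumps(_provenance(config, seed), indent=2)
        )
    return SpectralStudyReport(
        rows=df, best_band_contrast_nm=best_contrast, best_band_count_nm=best_count
    )
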