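"""Sparse depth recovery from a raw light-field capture.

For every stride-spaced patch inside every enabled microlens subimage the
matcher searches along the three hexagonal baseline directions of the MLA for
the correlation peak against the neighboring subimage, refines the lag by a
three-point parabola, and triangulates ``v = baseline / disparity``.  Points
are gated by the minimum normalized cross-correlation, the minimum patch
standard deviation (a contrast proxy), the configured depth range, and an
optional reverse-match consistency check; the surviving points of all
baseline pairs are pooled.

Defaults reproduce the reference processing parameters: minimum correlation
0.860, minimum standard deviation 0.006 of full scale, patch diameter 5 px,
patch stride 1 px, all three lens types enabled, depth range 0-130 %, and the
consistency check enabled.  Preprocessing (gradation line, denoise,
sharpening, ROI crop) is disabled in the reference configuration and accordingly a no-op.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import ndimage

from .plenoptic_model import LENS_TYPES
from .synthetic_data import ParameterError, RawLightField

__all__ = [
    "MatchingParams",
    "SparseDepthPoints",
    "patch_std",
    "correlate_patches",
    "estimate_depth",
    "preprocess",
]


@dataclass(frozen=True)
class MatchingParams:
    """Patch-matching configuration (defaults: the reference expert-mode settings).

    ``depth_range_pct`` maps percent onto the virtual-depth axis with 0 % at
    ``v_window[0]`` and 100 % at ``v_window[1]`` (values above 100 %
    extrapolate), so the default (0, 130) with window (1, 10) admits
    v in [1.0, 12.7].  ``lag_step_px`` sets the correlation sampling grid
    along the baseline before subpixel refinement.
    """

    min_correlation: float = 0.860
    min_std_dev: float = 0.006
    patch_diameter_px: int = 5
    patch_stride_px: int = 1
    enabled_lens_types: frozenset = frozenset(LENS_TYPES)
    depth_range_pct: tuple[float, float] = (0.0, 130.0)
    consistency_check: bool = True
    v_window: tuple[float, float] = (1.0, 10.0)
    lag_step_px: float = 0.5
    consistency_tol_px: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_correlation <= 1.0:
            raise ParameterError("min_correlation must lie in [0, 1]")
        if self.min_std_dev < 0:
            raise ParameterError("min_std_dev must be non-negative")
        if self.patch_diameter_px < 3 or self.patch_diameter_px % 2 == 0:
            raise ParameterError("patch diameter must be odd and >= 3")
        if self.patch_stride_px < 1:
            raise ParameterError("patch stride must be >= 1")
        if self.depth_range_pct[0] >= self.depth_range_pct[1]:
            raise ParameterError("depth range: min % must be below max %")
        if self.v_window[0] <= 0 or self.v_window[0] >= self.v_window[1]:
            raise ParameterError("v_window must be positive and increasing")
        if self.lag_step_px <= 0:
            raise ParameterError("lag_step_px must be positive")
        unknown = set(self.enabled_lens_types) - set(LENS_TYPES)
        if unknown:
            raise ParameterError(f"unknown lens types: {sorted(unknown)}")
        object.__setattr__(self, "enabled_lens_types", frozenset(self.enabled_lens_types))

    @property
    def effective_v_range(self) -> tuple[float, float]:
        v0, v1 = self.v_window
        span = v1 - v0
        lo = v0 + self.depth_range_pct[0] / 100.0 * span
        hi = v0 + self.depth_range_pct[1] / 100.0 * span
        return (max(lo, 1e-6), hi)

    def to_dict(self) -> dict:
        return {
            "min_correlation": self.min_correlation,
            "min_std_dev": self.min_std_dev,
            "patch_diameter_px": self.patch_diameter_px,
            "patch_stride_px": self.patch_stride_px,
            "enabled_lens_types": sorted(self.enabled_lens_types),
            "depth_range_pct": list(self.depth_range_pct),
            "consistency_check": self.consistency_check,
            "v_window": list(self.v_window),
            "lag_step_px": self.lag_step_px,
            "consistency_tol_px": self.consistency_tol_px,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MatchingParams":
        d = dict(d)
        if "enabled_lens_types" in d:
            d["enabled_lens_types"] = frozenset(d["enabled_lens_types"])
        for key in ("depth_range_pct", "v_window"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(eq=False)
class SparseDepthPoints:
    """Triangulated (x, y, v, correlation) samples in raw-raster coordinates."""

    x_px: np.ndarray
    y_px: np.ndarray
    v: np.ndarray
    correlation: np.ndarray
    lens_a: np.ndarray
    lens_b: np.ndarray
    image_size: tuple[int, int]  # (width, height) of the raw raster

    def __len__(self) -> int:
        return len(self.v)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_px": self.x_px,
                "y_px": self.y_px,
                "v": self.v,
                "correlation": self.correlation,
                "lens_a": self.lens_a,
                "lens_b": self.lens_b,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def empty(cls, image_size: tuple[int, int]) -> "SparseDepthPoints":
        z = np.zeros(0)
        return cls(z, z, z, z, z.astype(int), z.astype(int), image_size)


def _normalize(pixels: np.ndarray, full_scale: float | None) -> tuple[np.ndarray, float]:
    if full_scale is None:
        if np.issubdtype(pixels.dtype, np.integer):
            full_scale = float(np.iinfo(pixels.dtype).max)
        else:
            full_scale = 1.0
    return pixels.astype(float) / full_scale, full_scale


def _patch_offsets(diameter: int) -> np.ndarray:
    pr = (diameter - 1) // 2
    oy, ox = np.mgrid[-pr : diameter - pr, -pr : diameter - pr]
    return np.stack([ox.ravel(), oy.ravel()], axis=1).astype(float)  # (P, 2) x,y


def _sample_patch(img: np.ndarray, center_xy, diameter: int) -> np.ndarray:
    offs = _patch_offsets(diameter)
    cx, cy = center_xy
    return ndimage.map_coordinates(
        img, [cy + offs[:, 1], cx + offs[:, 0]], order=1, mode="nearest"
    )


def patch_std(pixels: np.ndarray, center_xy, diameter: int, full_scale: float | None = None) -> float:
    """Population standard deviation of a patch, as a fraction of full scale.

    ``full_scale`` defaults to the integer dtype's maximum (or 1.0 for float
    input already normalized to [0, 1]).
    """
    img, _ = _normalize(np.asarray(pixels), full_scale)
    return float(np.std(_sample_patch(img, center_xy, diameter)))


def _parabola_offset(cl: float, c0: float, cr: float) -> float:
    """Subpixel vertex offset in lag-grid units; ties break toward smaller lag."""
    denom = cl - 2.0 * c0 + cr
    if denom >= 0:  # flat or degenerate: keep the integer grid point
        return 0.0
    delta = 0.5 * (cl - cr) / denom
    return float(np.clip(delta, -0.5, 0.5))


def correlate_patches(
    image_a: np.ndarray,
    image_b: np.ndarray,
    center_xy,
    direction,
    lags: Iterable[float],
    patch_diameter_px: int = 5,
    subpixel: bool = True,
    full_scale: float | None = None,
) -> tuple[float, float]:
    """Match one patch of ``image_a`` against ``image_b`` along a baseline.

    The two rasters share a local coordinate frame; the scene content of the
    patch at ``center_xy`` in A is assumed displaced by ``-direction * lag``
    in B.  Normalized cross-correlation is evaluated on the given lag grid
    and the peak refined by a three-point parabola.  Returns
    ``(disparity_px, correlation)``; ``(nan, -1.0)`` for an empty search
    range or a structureless patch.
    """
    a_img, _ = _normalize(np.asarray(image_a), full_scale)
    b_img, _ = _normalize(np.asarray(image_b), full_scale)
    lags = np.asarray(list(lags), dtype=float)
    if lags.size == 0:
        return (float("nan"), -1.0)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    pa = _sample_patch(a_img, center_xy, patch_diameter_px)
    sa = pa.std()
    if sa == 0:
        return (float("nan"), -1.0)
    corrs = np.empty(lags.size)
    for k, lag in enumerate(lags):
        cb = (center_xy[0] - d[0] * lag, center_xy[1] - d[1] * lag)
        pb = _sample_patch(b_img, cb, patch_diameter_px)
        sb = pb.std()
        if sb == 0:
            corrs[k] = -2.0
            continue
        corrs[k] = float(np.mean((pa - pa.mean()) * (pb - pb.mean())) / (sa * sb))
    k = int(np.argmax(corrs))
    lag = lags[k]
    if subpixel and 0 < k < lags.size - 1 and corrs[k - 1] > -2 and corrs[k + 1] > -2:
        step = lags[k + 1] - lags[k]
        lag = lag + step * _parabola_offset(corrs[k - 1], corrs[k], corrs[k + 1])
    return (float(lag), float(corrs[k]))


def preprocess(raw: RawLightField) -> RawLightField:
    """Raw-image preprocessing stage; every step is disabled in the
    reference configuration, so this is the documented identity."""
    return raw


def _lag_grid(baseline: float, v_lo: float, v_hi: float, step: float) -> np.ndarray:
    lo = max(baseline / v_hi, step)
    hi = baseline / v_lo
    start = math.ceil(lo / step - 1e-9) * step
    if start > hi + 1e-9:
        return np.zeros(0)
    return np.arange(start, hi + 1e-9, step)


def estimate_depth(raw: RawLightField, params: MatchingParams | None = None) -> SparseDepthPoints:
    """Sparse virtual-depth points from a raw capture (vectorized matcher).

    Matching is pairwise along each positive hex lattice direction and the
    accepted points of all pairs are pooled; the exact multi-view aggregation
    of the commercial software is proprietary.  Point coordinates are the
    virtual-image positions ``c + u * v`` in raw-raster pixels.
    """
    params = params or MatchingParams()
    if not params.enabled_lens_types:
        raise ParameterError("no lens types enabled")
    mla = raw.mla
    sensor = raw.sensor
    img = raw.pixels.astype(float) / sensor.full_scale
    d = params.patch_diameter_px
    pr = (d - 1) // 2
    r_foot = mla.footprint_radius_px
    # patch pixels plus their bilinear-interpolation support must stay inside
    # the circular footprint, hence the (pr + 1) margin
    r_contain = r_foot - (pr + 1) * math.sqrt(2.0)
    if r_contain < 0.0:
        raise ParameterError("patch diameter too large for the lens pitch")

    # patch centers: stride lattice of integer offsets inside the footprint
    kmax = int(math.floor(r_contain))
    steps = np.arange(-kmax, kmax + 1, params.patch_stride_px)
    ux, uy = np.meshgrid(steps, steps)
    u_all = np.stack([ux.ravel(), uy.ravel()], axis=1).astype(float)
    u_all = u_all[np.einsum("ij,ij->i", u_all, u_all) <= r_contain**2]
    if len(u_all) == 0:
        return SparseDepthPoints.empty((sensor.width_px, sensor.height_px))
    poff = _patch_offsets(d)  # (P, 2)
    P = len(poff)

    type_ok = np.isin(
        mla.lens_type, [LENS_TYPES.index(t) for t in params.enabled_lens_types]
    )
    centers = mla.centers_xy
    v_lo, v_hi = params.effective_v_range

    # precompute all source patches: (N, n_u, P)
    coords = centers[:, None, None, :] + u_all[None, :, None, :] + poff[None, None, :, :]
    A = ndimage.map_coordinates(
        img, [coords[..., 1].ravel(), coords[..., 0].ravel()], order=1, mode="nearest"
    ).reshape(len(centers), len(u_all), P)
    A_mean = A.mean(axis=2)
    A_std = A.std(axis=2)

    out_x, out_y, out_v, out_c, out_a, out_b = [], [], [], [], [], []

    qr_index = {tuple(qr): i for i, qr in enumerate(map(tuple, mla.axial_qr))}
    for dq, dr in ((1, 0), (0, 1), (1, -1)):
        # lens pairs along this lattice direction
        ia, jb = [], []
        for i, (q0, r0) in enumerate(map(tuple, mla.axial_qr)):
            j = qr_index.get((q0 + dq, r0 + dr))
            if j is not None and type_ok[i] and type_ok[j]:
                ia.append(i)
                jb.append(j)
        if not ia:
            continue
        ia = np.asarray(ia)
        jb = np.asarray(jb)
        vec = centers[jb[0]] - centers[ia[0]]
        baseline = float(np.linalg.norm(vec))
        unit = vec / baseline
        lags = _lag_grid(baseline, v_lo, v_hi, params.lag_step_px)
        if lags.size == 0:
            continue

        cand: dict[str, list] = {k: [] for k in ("i", "j", "u", "lag", "corr")}
        for iu, u in enumerate(u_all):
            tgt = u[None, :] - unit[None, :] * lags[:, None]  # (L, 2)
            lag_ok = np.einsum("ld,ld->l", tgt, tgt) <= r_contain**2
            lags_u = lags[lag_ok]
            if lags_u.size == 0:
                continue
            a = A[ia, iu]  # (M, P)
            am = A_mean[ia, iu]
            asd = A_std[ia, iu]
            M = len(ia)
            L = lags_u.size
            bc = (
                centers[jb][:, None, None, :]
                + u[None, None, None, :]
                - unit[None, None, None, :] * lags_u[None, :, None, None]
                + poff[None, None, :, :]
            )  # (M, L, P, 2)
            B = ndimage.map_coordinates(
                img, [bc[..., 1].ravel(), bc[..., 0].ravel()], order=1, mode="nearest"
            ).reshape(M, L, P)
            bm = B.mean(axis=2)
            bs = B.std(axis=2)
            cov = np.einsum("mlp,mp->ml", B, a) / P - bm * am[:, None]
            denom = asd[:, None] * bs
            with np.errstate(divide="ignore", invalid="ignore"):
                corr = np.where(denom > 0, cov / denom, -2.0)
            k_best = np.argmax(corr, axis=1)
            rows = np.arange(M)
            c_best = corr[rows, k_best]
            lag_best = lags_u[k_best]
            # subpixel parabola where both neighbors exist on this lag grid
            refinable = (k_best > 0) & (k_best < L - 1)
            if np.any(refinable):
                r_ = rows[refinable]
                kb = k_best[refinable]
                cl = corr[r_, kb - 1]
                c0 = corr[r_, kb]
                crr = corr[r_, kb + 1]
                usable = (cl > -2) & (crr > -2)
                denom2 = cl - 2 * c0 + crr
                with np.errstate(divide="ignore", invalid="ignore"):
                    delta = np.where(
                        usable & (denom2 < 0),
                        np.clip(0.5 * (cl - crr) / denom2, -0.5, 0.5),
                        0.0,
                    )
                lag_best = lag_best.copy()
                lag_best[refinable] = lag_best[refinable] + params.lag_step_px * delta
            v = baseline / lag_best
            keep = (
                (asd >= params.min_std_dev)
                & (bs[rows, k_best] >= params.min_std_dev)
                & (c_best >= params.min_correlation)
                & (v >= v_lo)
                & (v <= v_hi)
            )
            if not np.any(keep):
                continue
            cand["i"].append(ia[keep])
            cand["j"].append(jb[keep])
            cand["u"].append(np.broadcast_to(u, (int(keep.sum()), 2)).copy())
            cand["lag"].append(lag_best[keep])
            cand["corr"].append(c_best[keep])

        if not cand["i"]:
            continue
        ci = np.concatenate(cand["i"])
        cj = np.concatenate(cand["j"])
        cu = np.concatenate(cand["u"])
        clag = np.concatenate(cand["lag"])
        ccorr = np.concatenate(cand["corr"])

        if params.consistency_check and len(ci):
            keep = _reverse_consistent(
                img, centers, ci, cj, cu, clag, unit, lags, r_contain, poff, params
            )
            ci, cj, cu, clag, ccorr = ci[keep], cj[keep], cu[keep], clag[keep], ccorr[keep]

        vv = baseline / clag
        pos = centers[ci] + cu * vv[:, None]
        out_x.append(pos[:, 0])
        out_y.append(pos[:, 1])
        out_v.append(vv)
        out_c.append(ccorr)
        out_a.append(ci)
        out_b.append(cj)

    if not out_x:
        return SparseDepthPoints.empty((sensor.width_px, sensor.height_px))
    return SparseDepthPoints(
        x_px=np.concatenate(out_x),
        y_px=np.concatenate(out_y),
        v=np.concatenate(out_v),
        correlation=np.concatenate(out_c),
        lens_a=np.concatenate(out_a).astype(int),
        lens_b=np.concatenate(out_b).astype(int),
        image_size=(sensor.width_px, sensor.height_px),
    )


def _reverse_consistent(
    img, centers, ci, cj, cu, clag, unit, lags, r_contain, poff, params
) -> np.ndarray:
    """Reverse-match each candidate (B -> A) and keep it only when the reverse
    landing position is within ``consistency_tol_px`` of the source patch."""
    P = len(poff)
    M = len(ci)
    u_rev = np.rint(cu - unit[None, :] * clag[:, None])  # (M, 2) landing offsets in B
    src = (
        centers[cj][:, None, :] + u_rev[:, None, :] + poff[None, :, :]
    )  # (M, P, 2)
    S = ndimage.map_coordinates(
        img, [src[..., 1].ravel(), src[..., 0].ravel()], order=1, mode="nearest"
    ).reshape(M, P)
    sm = S.mean(axis=1)
    ss = S.std(axis=1)
    L = lags.size
    # validity: the reverse target patch must stay inside lens A's footprint
    tgt_off = u_rev[:, None, :] + unit[None, None, :] * lags[None, :, None]  # (M, L, 2)
    valid = np.einsum("mld,mld->ml", tgt_off, tgt_off) <= r_contain**2
    corr = np.full((M, L), -3.0)
    for k in range(L):
        rows = np.where(valid[:, k])[0]
        if rows.size == 0:
            continue
        tc = centers[ci[rows]][:, None, :] + tgt_off[rows, k][:, None, :] + poff[None, :, :]
        T = ndimage.map_coordinates(
            img, [tc[..., 1].ravel(), tc[..., 0].ravel()], order=1, mode="nearest"
        ).reshape(rows.size, P)
        tm = T.mean(axis=1)
        ts = T.std(axis=1)
        cov = np.einsum("mp,mp->m", T, S[rows]) / P - tm * sm[rows]
        denom = ss[rows] * ts
        with np.errstate(divide="ignore", invalid="ignore"):
            corr[rows, k] = np.where(denom > 0, cov / denom, -2.0)
    any_valid = valid.any(axis=1)
    k_best = np.argmax(corr, axis=1)
    rows = np.arange(M)
    lag_rev = lags[np.clip(k_best, 0, L - 1)]
    refinable = (k_best > 0) & (k_best < L - 1)
    if np.any(refinable):
        r_ = rows[refinable]
        kb = k_best[refinable]
        cl = corr[r_, kb - 1]
        c0 = corr[r_, kb]
        crr = corr[r_, kb + 1]
        usable = (cl > -2) & (crr > -2)
        denom2 = cl - 2 * c0 + crr
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = np.where(
                usable & (denom2 < 0), np.clip(0.5 * (cl - crr) / denom2, -0.5, 0.5), 0.0
            )
        lag_rev = lag_rev.copy()
        lag_rev[refinable] = lag_rev[refinable] + params.lag_step_px * delta
    landing = u_rev + unit[None, :] * lag_rev[:, None]
    err = np.linalg.norm(landing - cu, axis=1)
    return any_valid & (err <= params.consistency_tol_px)
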