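"""Deterministic pre-processing chain and its exact geometric inverse.

The chain is crop (centred on the LV-cavity centroid) → reshape to a fixed
grid by appending empty slices → slice-wise adaptive histogram equalisation
→ non-local-means denoising.  Every geometric step is recorded in a
:class:`PreprocessRecord` so that predictions can be placed back on the
original scanner grid exactly (integer-exact for label content inside the
crop window).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import exposure, restoration

from .io import CAVITY, LabelMap, Volume

DEFAULT_TARGET = (96, 96, 16)


class CavityNotFoundError(ValueError):
    """No LV-cavity voxels available to centre the crop on."""


@dataclass
class PreprocessRecord:
    """Geometry bookkeeping needed to invert crop-and-reshape."""

    origin_shape: tuple[int, int, int]
    crop_offset: tuple[int, int]          # (r0, c0), may be negative near edges
    z_offset: int                         # first original slice kept
    pad_slices: int                       # all-zero slices appended at the end
    target_shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    enhancement_params: dict = field(default_factory=dict)
    denoise_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.pad_slices < 0:
            raise ValueError("pad_slices must be >= 0")


def locate_lv_centroid(labels_or_probs) -> tuple[int, int]:
    """In-plane centroid (row, col) of the LV cavity, pooled over slices.

    Accepts a :class:`LabelMap` (class-1 voxels) or a per-class probability
    grid of shape (classes, rows, cols, slices) whose channel 1 is the
    cavity.  Raises :class:`CavityNotFoundError` when no cavity mass exists;
    callers fall back to the image centre.
    """
    if isinstance(labels_or_probs, LabelMap):
        w = (labels_or_probs.labels == CAVITY).astype(np.float64)
    else:
        arr = np.asarray(labels_or_probs)
        if arr.ndim == 4:
            w = arr[CAVITY].astype(np.float64)
        elif arr.ndim == 3:  # bare label grid
            w = (arr == CAVITY).astype(np.float64)
        else:
            raise ValueError(f"expected 3D labels or 4D probs, got {arr.shape}")
    total = w.sum()
    if total <= 0:
        raise CavityNotFoundError("no LV-cavity voxels found")
    rr, cc = np.meshgrid(np.arange(w.shape[0]), np.arange(w.shape[1]),
                         indexing="ij")
    win = w.sum(axis=2)
    r = float((rr * win).sum() / total)
    c = float((cc * win).sum() / total)
    return int(round(r)), int(round(c))


def _copy_window(src: np.ndarray, dst: np.ndarray,
                 r0: int, c0: int, z0: int, invert: bool = False) -> None:
    """Copy the overlap of an (r0, c0, z0)-offset window between grids."""
    R, C, S = (src.shape if not invert else dst.shape)
    Tr, Tc, Ts = (dst.shape if not invert else src.shape)
    rs, re = max(r0, 0), min(r0 + Tr, R)
    cs, ce = max(c0, 0), min(c0 + Tc, C)
    zs, ze = max(z0, 0), min(z0 + Ts, S)
    if rs >= re or cs >= ce or zs >= ze:
        return
    big = (slice(rs, re), slice(cs, ce), slice(zs, ze))
    small = (slice(rs - r0, re - r0), slice(cs - c0, ce - c0),
             slice(zs - z0, ze - z0))
    if invert:
        dst[big] = src[small]
    else:
        dst[small] = src[big]


def crop_and_reshape(volume: Volume, centroid: tuple[int, int],
                     target: tuple[int, int, int] = DEFAULT_TARGET,
                     allow_z_crop: bool = False,
                     ) -> tuple[Volume, PreprocessRecord]:
    """Crop an in-plane window centred at `centroid` and pad to `target`.

    Border-crossing windows are zero-padded so the centroid stays centred.
    Volumes with more slices than the target raise unless `allow_z_crop`,
    in which case a centred slice range is kept.
    """
    Tr, Tc, Ts = target
    if Tr % 2 or Tc % 2:
        raise ValueError("target must be even in-plane")
    R, C, S = volume.data.shape
    r0 = int(centroid[0]) - Tr // 2
    c0 = int(centroid[1]) - Tc // 2
    if S > Ts:
        if not allow_z_crop:
            raise ValueError(
                f"{S} slices exceed target {Ts}; pass allow_z_crop=True "
                "to keep a centred slice range")
        z0 = (S - Ts) // 2
        pad = 0
    else:
        z0 = 0
        pad = Ts - S
    out = np.zeros(target, dtype=volume.data.dtype)
    _copy_window(volume.data, out, r0, c0, z0)
    rec = PreprocessRecord(origin_shape=(R, C, S), crop_offset=(r0, c0),
                           z_offset=z0, pad_slices=pad, target_shape=target,
                           spacing=volume.spacing)
    cropped = Volume(data=out, spacing=volume.spacing, origin_shape=(R, C, S),
                     crop_offset=(r0, c0))
    return cropped, rec


def crop_labels(labels: LabelMap, rec: PreprocessRecord) -> LabelMap:
    """Apply a recorded crop to a label map (training-time convenience)."""
    out = np.zeros(rec.target_shape, dtype=np.uint8)
    _copy_window(labels.labels, out, rec.crop_offset[0], rec.crop_offset[1],
                 rec.z_offset)
    return LabelMap(labels=out, spacing=labels.spacing)


def restore_geometry(pred: LabelMap, rec: PreprocessRecord) -> LabelMap:
    """Place a prediction made on the target grid back on the original grid.

    Appended empty slices are dropped; voxels outside the crop window are
    background.  Exact inverse of :func:`crop_and_reshape` for label content
    within the window.
    """
    if tuple(pred.shape) != tuple(rec.target_shape):
        raise ValueError(
            f"prediction shape {pred.shape} != record target {rec.target_shape}")
    out = np.zeros(rec.origin_shape, dtype=np.uint8)
    kept = rec.target_shape[2] - rec.pad_slices
    trimmed = pred.labels[:, :, :kept]
    dst = np.zeros(rec.origin_shape, dtype=np.uint8)
    _copy_window(trimmed, dst, rec.crop_offset[0], rec.crop_offset[1],
                 rec.z_offset, invert=True)
    out = dst
    return LabelMap(labels=out, spacing=rec.spacing)


def enhance_contrast(volume: Volume, clip_limit: float = 0.01,
                     tiles: int = 8) -> Volume:
    """Slice-wise adaptive histogram equalisation (CLAHE); output in [0, 1].

    The volume is min-max rescaled first; constant volumes are returned
    unchanged after the (degenerate) rescale.
    """
    data = volume.data.astype(np.float64)
    lo, hi = float(data.min()), float(data.max())
    if hi <= lo:
        out = np.clip(data, 0.0, 1.0)
        return Volume(out.astype(np.float32), volume.spacing,
                      volume.origin_shape, volume.crop_offset)
    data = (data - lo) / (hi - lo)
    out = np.empty_like(data)
    R, C, _ = data.shape
    kernel = (max(R // tiles, 1), max(C // tiles, 1))
    for s in range(data.shape[2]):
        sl = data[:, :, s]
        if sl.max() <= sl.min():
            out[:, :, s] = sl
        else:
            out[:, :, s] = exposure.equalize_adapthist(
                sl, kernel_size=kernel, clip_limit=clip_limit)
    return Volume(out.astype(np.float32), volume.spacing,
                  volume.origin_shape, volume.crop_offset)


def denoise(volume: Volume, patch_size: int = 5, search: int = 11,
            h: float | None = None) -> Volume:
    """3D non-local-means denoising; strength defaults to 0.8·σ̂ (estimated).

    ``h=0`` is the identity.
    """
    data = volume.data.astype(np.float64)
    if h is None:
        sigma = float(restoration.estimate_sigma(data))
        h = 0.8 * sigma if np.isfinite(sigma) else 0.0
    if h <= 0:
        out = data
    else:
        out = restoration.denoise_nl_means(
            data, patch_size=patch_size, patch_distance=(search - 1) // 2,
            h=h, fast_mode=True)
    return Volume(out.astype(np.float32), volume.spacing,
                  volume.origin_shape, volume.crop_offset)


def preprocess_volume(volume: Volume, centroid: tuple[int, int] | None,
                      target: tuple[int, int, int] = DEFAULT_TARGET,
                      clahe: dict | None = None, nlm: dict | None = None,
                      allow_z_crop: bool = False,
                      ) -> tuple[Volume, PreprocessRecord]:
    """Full chain: crop → reshape → equalise → denoise.

    ``centroid=None`` falls back to the image centre (the no-ground-truth,
    no-first-pass case).
    """
    if centroid is None:
        centroid = (volume.data.shape[0] // 2, volume.data.shape[1] // 2)
    cropped, rec = crop_and_reshape(volume, centroid, target,
                                    allow_z_crop=allow_z_crop)
    clahe = clahe or {}
    nlm = nlm or {}
    enhanced = enhance_contrast(cropped, **clahe)
    result = denoise(enhanced, **nlm)
    rec.enhancement_params = {"clip_limit": clahe.get("clip_limit", 0.01),
                              "tiles": clahe.get("tiles", 8)}
    rec.denoise_params = {"patch_size": nlm.get("patch_size", 5),
                          "search": nlm.get("search", 11),
                          "h": nlm.get("h")}
    return result, rec
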