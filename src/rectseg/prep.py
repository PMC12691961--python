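"""Preprocessing and augmentation for pelvic CT volumes.

Mirrors a standard radiotherapy auto-segmentation pipeline: resampling to
an isotropic 1 mm lattice, z-score intensity normalization, cropping to a
pelvic region of interest, extraction of the binary rectum mask from the
multi-class annotation (label 3), and geometric/intensity augmentation
(in-plane rotation up to +-15 degrees, axis flips, scaling in [0.9, 1.1],
Gaussian intensity shifts).

Interpolation policy: trilinear for images, nearest-neighbour for masks and
label maps, so masks stay binary and labels stay integral.  Out-of-bounds
regions after a geometric transform are filled with air intensity for
images and 0 for masks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .imgio import SegMask, VolumeGrid

__all__ = [
    "AugmentConfig",
    "resample_isotropic",
    "zscore_normalize",
    "crop_pelvic_roi",
    "extract_rectum_mask",
    "augment",
    "AIR_FILL_HU",
]

#: Fill value (HU) for image voxels mapped from outside the original grid.
AIR_FILL_HU = -1000.0

LABEL_RECTUM = 3


@dataclass
class AugmentConfig:
    """Bounds of the random augmentation draws.

    ``rotation_max_deg`` bounds the in-plane (axial) rotation angle;
    ``flip_axes`` lists axes eligible for a random flip; ``scale_range``
    bounds the isotropic zoom factor; ``intensity_shift_sd`` is the sd (HU)
    of an additive global intensity shift.
    """

    rotation_max_deg: float = 15.0
    flip_axes: tuple[int, ...] = (0,)
    scale_range: tuple[float, float] = (0.9, 1.1)
    intensity_shift_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rotation_max_deg < 0:
            raise ValueError("rotation_max_deg must be >= 0")
        lo, hi = self.scale_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid scale_range: {self.scale_range}")


def resample_isotropic(grid, target_spacing: float = 1.0, mode: str | None = None):
    """Resample a grid to isotropic ``target_spacing`` mm.

    Linear interpolation for :class:`VolumeGrid` images, nearest for
    :class:`SegMask`; requesting linear interpolation of a mask is an
    error.  The physical extent is preserved within one output voxel.
    """
    if target_spacing <= 0:
        raise ValueError("target_spacing must be > 0")
    is_mask = isinstance(grid, SegMask)
    if mode is None:
        mode = "nearest" if is_mask else "linear"
    if is_mask and mode == "linear":
        raise ValueError("linear interpolation is not permitted for masks")

    spacing = np.asarray(grid.spacing, dtype=float)
    target = np.full(3, float(target_spacing))
    if np.allclose(spacing, target):
        return grid  # identity resample

    zoom = spacing / target
    values = grid.values
    if is_mask or mode == "nearest":
        out = ndimage.zoom(values.astype(np.uint8), zoom, order=0, mode="grid-constant",
                           cval=0, grid_mode=True)
        out = out.astype(bool) if is_mask else out
    else:
        out = ndimage.zoom(values.astype(np.float32), zoom, order=1,
                           mode="grid-constant", cval=AIR_FILL_HU, grid_mode=True)
    cls = SegMask if is_mask else VolumeGrid
    return cls(values=out, spacing=tuple(target), origin=grid.origin)


def zscore_normalize(grid: VolumeGrid, region: Optional[SegMask] = None) -> VolumeGrid:
    """Normalize intensities to zero mean, unit sd over ``region`` (or all).

    Raises ``ValueError("zero variance")`` on a constant image, and requires
    a non-empty region when one is supplied.
    """
    values = np.asarray(grid.values, dtype=np.float64)
    if region is not None:
        if region.values.shape != values.shape:
            raise ValueError("region lattice does not match image lattice")
        sel = region.values
        if not sel.any():
            raise ValueError("empty normalization region")
        sample = values[sel]
    else:
        sample = values.ravel()
    mean = sample.mean()
    sd = sample.std()
    if sd == 0:
        raise ValueError("zero variance: cannot z-score a constant image")
    return grid.with_values(((values - mean) / sd).astype(np.float32))


def crop_pelvic_roi(grid: VolumeGrid, labels: VolumeGrid, margin_mm: float = 0.0):
    """Crop image and label map to the body bounding box plus a margin.

    The body is every non-air voxel (label > 0).  The crop is the tight
    bounding box expanded by ``margin_mm`` (converted to voxels per axis)
    and clipped to the grid; the rectum, being body tissue, is always
    fully inside the crop.
    """
    body = np.asarray(labels.values) > 0
    if not body.any():
        raise ValueError("empty body mask: nothing to crop to")
    spacing = np.asarray(grid.spacing)
    lo, hi = [], []
    for axis in range(3):
        proj = np.any(body, axis=tuple(a for a in range(3) if a != axis))
        idx = np.flatnonzero(proj)
        pad = int(np.ceil(margin_mm / spacing[axis]))
        lo.append(max(0, idx[0] - pad))
        hi.append(min(body.shape[axis], idx[-1] + 1 + pad))
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    new_origin = tuple(
        o + a * s for o, a, s in zip(grid.origin, lo, spacing)
    )
    cropped_img = VolumeGrid(values=grid.values[sl], spacing=grid.spacing, origin=new_origin)
    cropped_lab = VolumeGrid(values=labels.values[sl], spacing=labels.spacing, origin=new_origin)
    return cropped_img, cropped_lab


def extract_rectum_mask(labels: VolumeGrid) -> SegMask:
    """Binary rectum mask: 1 exactly where the label map equals 3.

    An empty result is allowed but flagged with a warning.
    """
    values = np.asarray(labels.values)
    if not np.issubdtype(values.dtype, np.integer) and values.dtype != bool:
        if not np.all(values == np.round(values)):
            raise ValueError("label map must be integer-valued")
        values = values.astype(np.int32)
    mask = values == LABEL_RECTUM
    if not mask.any():
        warnings.warn("no rectum (label 3) voxels found; returning empty mask")
    return SegMask(values=mask, spacing=labels.spacing, origin=labels.origin)


def _apply_geometric(values, angle_deg, flips, scale, order, cval):
    out = np.asarray(values, dtype=np.float32)
    for axis in flips:
        out = np.flip(out, axis=axis)
    if angle_deg != 0.0:
        out = ndimage.rotate(out, angle_deg, axes=(0, 1), reshape=False,
                             order=order, mode="constant", cval=cval)
    if scale != 1.0:
        # zoom about the volume center at fixed shape
        shape = np.asarray(out.shape, dtype=float)
        center = (shape - 1) / 2.0
        matrix = np.eye(out.ndim) / scale
        offset = center - matrix @ center
        out = ndimage.affine_transform(out, matrix, offset=offset, order=order,
                                       mode="constant", cval=cval)
    return out


def augment(sample, config: AugmentConfig, draw_seed: int):
    """Apply one random augmentation draw to an (image, mask) pair.

    The same geometric transform (flip, in-plane rotation, isotropic scale)
    is applied to both; the image additionally receives a global intensity
    shift.  Deterministic for a fixed ``draw_seed``.
    """
    grid, mask = sample
    if np.asarray(grid.values).shape != np.asarray(mask.values).shape:
        raise ValueError("image and mask lattices do not match")
    rng = np.random.default_rng(draw_seed)
    angle = float(rng.uniform(-config.rotation_max_deg, config.rotation_max_deg))
    flips = tuple(a for a in config.flip_axes if rng.random() < 0.5)
    lo, hi = config.scale_range
    scale = float(rng.uniform(lo, hi))
    shift = float(rng.normal(0.0, config.intensity_shift_sd)) if config.intensity_shift_sd > 0 else 0.0

    img_out = _apply_geometric(grid.values, angle, flips, scale, order=1, cval=AIR_FILL_HU)
    img_out = img_out + shift
    mask_out = _apply_geometric(mask.values.astype(np.float32), angle, flips, scale,
                                order=0, cval=0.0) > 0.5
    return (
        grid.with_values(img_out.astype(np.float32)),
        SegMask(values=mask_out, spacing=mask.spacing, origin=mask.origin),
    )
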