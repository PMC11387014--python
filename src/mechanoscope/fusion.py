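"""Extended-depth-of-field fusion of volumes acquired at stepped focal depths.

A high-NA objective confines reliable imaging to a thin slab around each
focal plane. Acquiring several volumes at partially overlapping focal depths
and blending them with axial Gaussian weights centered at each volume's focal
plane extends the usable depth range. Weights are normalized to sum to one
per voxel so that constant fields (and physical units) survive fusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np


@dataclass
class FocalStack:
    """Congruent scalar volumes (modulus kPa, intensity, or SNR dB) with foci.

    ``z_offset_um`` is a known axial translation per volume (applied by
    ``align_stack`` before fusion); ``valid`` optionally masks unusable
    voxels per volume (weight zero).
    """

    volumes: List[np.ndarray]
    focal_depths_um: Sequence[float]
    voxel_pitch_z_um: float
    z_offset_um: Sequence[float] | None = None
    valid: List[np.ndarray] | None = None

    def __post_init__(self) -> None:
        if len(self.volumes) == 0:
            raise ValueError("focal stack must contain at least one volume")
        if len(self.volumes) != len(self.focal_depths_um):
            raise ValueError("one focal depth per volume required")
        shape = self.volumes[0].shape
        if any(v.shape != shape for v in self.volumes):
            raise ValueError("stack volumes must be congruent")
        d = np.asarray(self.focal_depths_um, dtype=float)
        if len(d) > 1 and np.any(np.diff(d) <= 0):
            raise ValueError("focal depths must be strictly ordered")
        if self.valid is not None and any(v.shape != shape for v in self.valid):
            raise ValueError("validity masks must be congruent with volumes")


def align_stack(stack: FocalStack) -> FocalStack:
    """Resample each volume onto the common grid by its known axial offset.

    Linear interpolation along z (exact for affine profiles); voxels shifted
    in from outside the volume replicate the edge value and are invalidated.
    """
    if stack.z_offset_um is None or not np.any(np.asarray(stack.z_offset_um)):
        return stack
    dz = stack.voxel_pitch_z_um
    nz = stack.volumes[0].shape[2]
    out_vols, out_valid = [], []
    valid_in = stack.valid or [np.ones_like(v, dtype=bool) for v in stack.volumes]
    zi = np.arange(nz, dtype=float)
    for vol, val, off in zip(stack.volumes, valid_in, stack.z_offset_um):
        shift = off / dz
        if abs(shift) >= nz:
            raise ValueError("z offset larger than the volume extent")
        src = zi + shift
        lo = np.clip(np.floor(src).astype(int), 0, nz - 1)
        hi = np.clip(lo + 1, 0, nz - 1)
        frac = np.clip(src - lo, 0.0, 1.0)
        out_vols.append(vol[:, :, lo] * (1.0 - frac) + vol[:, :, hi] * frac)
        inside = (src >= 0) & (src <= nz - 1)
        out_valid.append(val[:, :, lo] & val[:, :, hi] & inside)
    return FocalStack(
        volumes=out_vols,
        focal_depths_um=stack.focal_depths_um,
        voxel_pitch_z_um=dz,
        z_offset_um=None,
        valid=out_valid,
    )


@dataclass
class FusedVolume:
    data: np.ndarray
    valid: np.ndarray
    gap_flagged: np.ndarray = field(repr=False, default=None)
    coverage: np.ndarray = field(repr=False, default=None)


def fuse(stack: FocalStack, weight_fwhm_um: float = 12.0) -> FusedVolume:
    """Per-voxel Gaussian-weighted blend of the aligned stack.

    Each volume contributes with an axial Gaussian weight centered at its
    focal plane (FWHM ``weight_fwhm_um``), normalized to sum to one per
    voxel, so the fused value is a convex combination of the contributing
    volumes. Voxels with all weights zero (numerically uncovered or all
    volumes invalid) are marked invalid. Voxels lying inside a focal-depth
    gap and farther than one weight FWHM from every focal plane are
    ``gap_flagged`` (with a warning): their value is an interpolation across
    a coverage hole rather than a focused measurement.
    """
    stack = align_stack(stack)
    nz = stack.volumes[0].shape[2]
    z = (np.arange(nz) + 0.5) * stack.voxel_pitch_z_um
    k = 4.0 * np.log(2.0) / weight_fwhm_um**2

    num = np.zeros_like(stack.volumes[0], dtype=float)
    den = np.zeros_like(num)
    valid_in = stack.valid or [np.ones(v.shape, dtype=bool) for v in stack.volumes]
    for vol, val, f in zip(stack.volumes, valid_in, stack.focal_depths_um):
        w = np.exp(-k * (z - f) ** 2)[None, None, :] * val
        num += w * np.nan_to_num(vol)
        den += w
    covered = den > np.finfo(float).tiny
    with np.errstate(invalid="ignore"):
        data = np.where(covered, num / np.where(covered, den, 1.0), np.nan)

    depths = np.asarray(stack.focal_depths_um, dtype=float)
    d_min = np.min(np.abs(z[:, None] - depths[None, :]), axis=1)
    in_gap_z = (z > depths.min()) & (z < depths.max()) & (d_min > weight_fwhm_um)
    gap = np.broadcast_to(in_gap_z, data.shape).copy()
    if gap.any():
        warnings.warn(
            "focal-depth coverage gap larger than the weight FWHM; "
            "affected voxels flagged",
            stacklevel=2,
        )
    return FusedVolume(data=data, valid=covered, gap_flagged=gap, coverage=den)
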