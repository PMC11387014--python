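"""Spheroid segmentation and core/periphery morphometry.

The spheroid is segmented from the structural OCM volume (min-max
normalization, fixed 0.5 threshold, largest 26-connected component, hole
filling). An edge-smoothed mask (20 x 20 kernel of ones, keep coverage
>= 0.95) suppresses boundary fuzz and protrusions; the spheroid is then split
per en-face plane into a core -- pixels within half the local boundary radius
of the centroid -- and a periphery, with protrusions outside the smoothed
mask always assigned to the periphery. Regional Young's modulus statistics
are taken in the en-face plane(s) at the spheroid center.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List

import numpy as np
import pandas as pd
from scipy import ndimage

from .reconstruct import ModulusVolume

BACKGROUND, CORE, PERIPHERY = 0, 1, 2


class SegmentationError(ValueError):
    pass


def _normalize(volume: np.ndarray) -> np.ndarray:
    vol = np.asarray(volume, dtype=float)
    lo, hi = float(np.nanmin(vol)), float(np.nanmax(vol))
    if not np.isfinite(lo) or not np.isfinite(hi) or hi <= lo:
        raise SegmentationError("volume is constant; nothing to segment")
    return (vol - lo) / (hi - lo)


def segment_spheroids(volume: np.ndarray, threshold: float = 0.5, min_voxels: int = 1000) -> List[np.ndarray]:
    """All spheroid masks above ``min_voxels``, largest first.

    Min-max normalization makes the result invariant to affine intensity
    scaling; components are 26-connected; enclosed holes are filled per mask.
    """
    binary = _normalize(volume) >= threshold
    if not binary.any():
        raise SegmentationError("empty mask after thresholding")
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    labels, n = ndimage.label(binary, structure=structure)
    counts = np.bincount(labels.ravel())[1:]
    order = np.argsort(counts)[::-1]
    masks = []
    for k in order:
        if counts[k] < min_voxels and masks:
            break
        masks.append(ndimage.binary_fill_holes(labels == k + 1))
    return masks


def segment_spheroid(volume: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Single contiguous mask of the main (largest) spheroid."""
    return segment_spheroids(volume, threshold=threshold, min_voxels=1)[0]


def smooth_mask(mask: np.ndarray, kernel_size: int = 20, coverage: float = 0.95) -> np.ndarray:
    """Edge-smoothing by neighborhood coverage, per en-face plane.

    A pixel is retained iff at least ``coverage`` of its
    ``kernel_size x kernel_size`` neighborhood lies inside the input mask
    (integer window counting, so the threshold is exact). Works on 2-D masks
    or plane-by-plane on 3-D ``[x, y, z]`` masks. Masks smaller than the
    kernel pass through unchanged with a warning.
    """
    mask = np.asarray(mask, dtype=bool)
    two_d = mask.ndim == 2
    planes = mask[..., None] if two_d else mask
    if planes.shape[0] < kernel_size or planes.shape[1] < kernel_size:
        warnings.warn("mask smaller than smoothing kernel; passthrough", stacklevel=2)
        return mask
    need = int(np.ceil(coverage * kernel_size**2))
    out = np.empty_like(planes)
    for k in range(planes.shape[2]):
        counts = ndimage.uniform_filter(
            planes[:, :, k].astype(float), size=kernel_size, mode="constant", cval=0.0
        ) * (kernel_size**2)
        out[:, :, k] = np.rint(counts).astype(int) >= need
    return out[:, :, 0] if two_d else out


def smoothing_recession_px(kernel_size: int = 20, coverage: float = 0.95) -> float:
    """Distance a straight boundary recedes under ``smooth_mask``.

    Window coverage at depth d inside a half-plane is (k/2 + d)/k, which
    first reaches ``coverage`` at d = (coverage - 0.5) * k.
    """
    return (coverage - 0.5) * kernel_size


def mask_centroid(mask: np.ndarray):
    """Unweighted center of mass of the mask, in voxel coordinates (x, y, z)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise SegmentationError("empty mask has no centroid")
    coords = np.argwhere(mask)
    return tuple(coords.mean(axis=0))


@dataclass
class RegionLabels:
    """Core/periphery partition of a spheroid mask."""

    mask: np.ndarray
    label: np.ndarray  # uint8 codes: 0 background, 1 core, 2 periphery
    centroid: tuple
    central_plane: int
    spheroid_id: int = 0


def _boundary_radius_by_angle(plane_mask: np.ndarray, cx: float, cy: float, n_bins: int = 360):
    """Max radius of mask pixels per angle bin around (cx, cy); 0 if empty."""
    xs, ys = np.nonzero(plane_mask)
    R = np.zeros(n_bins)
    if xs.size == 0:
        return R
    dx, dy = xs - cx, ys - cy
    r = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    bins = ((theta + np.pi) / (2 * np.pi) * n_bins).astype(int) % n_bins
    np.maximum.at(R, bins, r)
    # fill empty bins from circular neighbors so rays between samples behave
    empty = R == 0
    if empty.any() and not empty.all():
        idx = np.arange(n_bins)
        good = idx[~empty]
        Rg = R[~empty]
        # circular nearest-neighbor fill
        ext = np.concatenate([good - n_bins, good, good + n_bins])
        Re = np.concatenate([Rg, Rg, Rg])
        pos = np.searchsorted(ext, idx[empty])
        left = np.clip(pos - 1, 0, ext.size - 1)
        right = np.clip(pos, 0, ext.size - 1)
        choose_right = np.abs(ext[right] - idx[empty]) < np.abs(idx[empty] - ext[left])
        R[empty] = np.where(choose_right, Re[right], Re[left])
    return R


def split_core_periphery(
    mask: np.ndarray,
    centroid=None,
    core_fraction: float = 0.5,
    kernel_size: int = 20,
    coverage: float = 0.95,
) -> RegionLabels:
    """Label each mask voxel core or periphery, per en-face plane.

    For each plane the local boundary radius R(theta) is measured on the
    edge-smoothed mask along the ray through each pixel and corrected for the
    known recession of the smoothing operator, so that an ideal disc of
    radius R yields a core of radius ``core_fraction * R``. A pixel is core
    iff r <= core_fraction * R(theta) and it lies inside the smoothed mask;
    protrusion pixels outside the smoothed mask are always periphery.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3-D (x, y, z)")
    if centroid is None:
        centroid = mask_centroid(mask)
    cx, cy, cz = centroid
    ic = tuple(int(round(c)) for c in centroid)
    inside_grid = all(0 <= ic[a] < mask.shape[a] for a in range(3))
    if not inside_grid or not mask[ic]:
        raise SegmentationError("centroid lies outside the mask")

    smoothed = smooth_mask(mask, kernel_size=kernel_size, coverage=coverage)
    offset = smoothing_recession_px(kernel_size, coverage)
    n_bins = 360
    label = np.zeros(mask.shape, dtype=np.uint8)
    xs = np.arange(mask.shape[0])[:, None]
    ys = np.arange(mask.shape[1])[None, :]
    r = np.hypot(xs - cx, ys - cy)
    theta_bin = ((np.arctan2(ys - cy, xs - cx) + np.pi) / (2 * np.pi) * n_bins).astype(int) % n_bins
    for k in range(mask.shape[2]):
        plane = mask[:, :, k]
        if not plane.any():
            continue
        sm = smoothed[:, :, k]
        R = _boundary_radius_by_angle(sm, cx, cy, n_bins)
        R_eff = np.where(R > 0, R + offset, 0.0)
        core = plane & sm & (r <= core_fraction * R_eff[theta_bin])
        label[:, :, k][plane] = PERIPHERY
        label[:, :, k][core] = CORE
    return RegionLabels(
        mask=mask,
        label=label,
        centroid=tuple(float(c) for c in centroid),
        central_plane=int(round(cz)),
    )


def region_stats(
    modulus: ModulusVolume,
    labels: RegionLabels,
    half_planes: int = 0,
    spheroid_id: int = 0,
) -> pd.DataFrame:
    """Mean +/- SD Young's modulus per region at the central en-face plane(s).

    ``half_planes`` widens the slab to ``central_plane +/- half_planes``.
    Regions with no valid modulus voxels are omitted with a warning. SD uses
    the n-1 (sample) denominator.
    """
    if modulus.E_kpa.shape != labels.label.shape:
        raise ValueError("modulus and labels are not congruent")
    z0 = labels.central_plane
    zs = range(max(0, z0 - half_planes), min(labels.label.shape[2], z0 + half_planes + 1))
    slab = np.zeros(labels.label.shape, dtype=bool)
    for k in zs:
        slab[:, :, k] = True
    rows = []
    for name, code in (("core", CORE), ("periphery", PERIPHERY)):
        sel = (labels.label == code) & slab & modulus.valid
        vals = modulus.E_kpa[sel]
        if vals.size == 0:
            warnings.warn(f"region {name!r} has no valid modulus voxels; omitted", stacklevel=2)
            continue
        rows.append(
            {
                "spheroid_id": spheroid_id,
                "region": name,
                "mean_kPa": float(vals.mean()),
                "sd_kPa": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "n_voxels": int(vals.size),
            }
        )
    return pd.DataFrame(rows, columns=["spheroid_id", "region", "mean_kPa", "sd_kPa", "n_voxels"])
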