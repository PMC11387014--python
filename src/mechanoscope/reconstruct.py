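"""Phase-to-modulus reconstruction chain for compression OCE.

Given a loaded/unloaded pair of complex OCM volumes the chain is:

1. ``phase_difference`` -- wrapped phase of the kernel-averaged conjugate
   product, with an intensity-based regression weight per voxel;
2. ``phase_to_displacement`` -- double-pass phase sensitivity,
   ``u_z = lambda0 * dphi / (4 pi n)``;
3. ``estimate_strain`` -- weighted least-squares slope of displacement with
   depth over a short axial window, after lateral Gaussian smoothing;
4. ``layer_stress_map`` -- strain in the compliant layer just beyond the
   layer-sample interface, converted to stress through the layer's
   pre-characterized stress-strain curve (one stress value per A-line);
5. ``young_modulus`` -- tangent modulus E = sigma / eps per voxel under the
   uniaxial-stress assumption.

``elasticity_resolution`` combines the optical and signal-processing
responses in Gaussian quadrature to give the resolution of the modulus map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
from scipy import ndimage

from .calibration import LayerCalibration
from .containers import AcquisitionGeometry, ComplexOCMVolume, congruent


@dataclass
class DisplacementField:
    """Axial displacement u_z (nm, toward the window positive) per voxel.

    ``unwrapped`` records that the phase was axially unwrapped: each column
    may then carry an arbitrary 2*pi displacement offset, harmless to axial
    slopes but fatal to lateral averaging of u_z itself.
    """

    u_z: np.ndarray
    weight: np.ndarray
    valid: np.ndarray
    geometry: AcquisitionGeometry
    unwrapped: bool = False


@dataclass
class StrainField:
    """Local axial strain (dimensionless, compression positive) per voxel."""

    strain_z: np.ndarray
    valid: np.ndarray
    geometry: AcquisitionGeometry
    weight: np.ndarray | None = None
    window_fwhm_um: float = 15.0
    smoothing_fwhm_um: float = 5.0


@dataclass
class StressMap:
    """Interface stress sigma (kPa) and interface depth (um) per (x, y)."""

    sigma_kpa: np.ndarray
    interface_depth_um: np.ndarray
    valid: np.ndarray


@dataclass
class ModulusVolume:
    """Reconstructed Young's modulus (kPa) with validity and provenance."""

    E_kpa: np.ndarray
    valid: np.ndarray
    resolution_fwhm_um: Tuple[float, float, float]
    geometry: AcquisitionGeometry
    focal_depth_um: float | None = None
    provenance: dict = field(default_factory=dict)


def _odd_size(extent_um: float, pitch_um: float) -> int:
    """Kernel size in voxels covering ``extent_um``, odd and >= 1."""
    n = max(1, round(extent_um / pitch_um))
    return n if n % 2 == 1 else n + 1


def phase_difference(
    unloaded: ComplexOCMVolume,
    loaded: ComplexOCMVolume,
    averaging_kernel_um: Tuple[float, float, float] = (3.0, 3.0, 0.0),
):
    """Wrapped phase difference and regression weight per voxel.

    The phase is the argument of the box-kernel-averaged conjugate product
    ``loaded * conj(unloaded)`` (Kasai-style estimator); averaging over a few
    speckles suppresses the unreliable phase of dark-speckle voxels. The
    weight is the kernel-averaged mean intensity of the two volumes, a
    linear-scale SNR proxy (WLS is invariant to its overall scale).

    Returns
    -------
    (dphi, weight)
        ``dphi`` wrapped to (-pi, pi], ``weight`` >= 0, both per voxel.
    """
    if not congruent(unloaded, loaded):
        raise ValueError("loaded/unloaded volumes must be congruent in shape and metadata")
    pitch = unloaded.geometry.voxel_pitch_um
    size = tuple(_odd_size(e, p) for e, p in zip(averaging_kernel_um, pitch))
    prod = loaded.data * np.conj(unloaded.data)
    avg_re = ndimage.uniform_filter(prod.real, size=size, mode="nearest")
    avg_im = ndimage.uniform_filter(prod.imag, size=size, mode="nearest")
    dphi = np.arctan2(avg_im, avg_re)
    intensity = 0.5 * (np.abs(unloaded.data) ** 2 + np.abs(loaded.data) ** 2)
    weight = ndimage.uniform_filter(intensity, size=size, mode="nearest")
    return dphi, np.maximum(weight, 0.0)


def phase_to_displacement(
    dphi: np.ndarray,
    geometry: AcquisitionGeometry,
    weight: np.ndarray | None = None,
    unwrap_axial: bool = False,
) -> DisplacementField:
    """Convert phase difference to axial displacement in nanometers.

    ``u_z = lambda0 * dphi / (4 pi n)`` (double-pass through a medium of
    index n). With ``unwrap_axial`` the phase is first unwrapped along depth,
    for acquisitions actuated beyond the |dphi| < pi regime; local strain
    estimates are unaffected by the 2*pi column offsets unwrapping can leave
    behind in low-SNR stretches.
    """
    dphi = np.asarray(dphi, dtype=float)
    if unwrap_axial:
        dphi = np.unwrap(dphi, axis=2)
    scale = geometry.wavelength_nm / (4.0 * np.pi * geometry.refractive_index)
    u_z = scale * dphi
    if weight is None:
        weight = np.ones_like(u_z)
    valid = weight > 0
    w = np.where(valid, weight, 0.0)
    return DisplacementField(
        u_z=u_z, weight=w, valid=valid, geometry=geometry, unwrapped=unwrap_axial
    )


def _moving_sums(arr: np.ndarray, n: int) -> np.ndarray:
    """Axial moving window sum with zero padding (window truncates at edges)."""
    return ndimage.uniform_filter1d(arr, size=n, axis=2, mode="constant", cval=0.0) * n


def _lateral_weighted_gaussian(arr, w, fwhm_um, pitch_xy):
    """Weight-normalized lateral Gaussian smoothing; returns (arr_sm, w_sm)."""
    sig = fwhm_um / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma = (sig / pitch_xy[0], sig / pitch_xy[1], 0.0)
    wa = ndimage.gaussian_filter(w * np.nan_to_num(arr), sigma=sigma, mode="nearest")
    w_sm = ndimage.gaussian_filter(w, sigma=sigma, mode="nearest")
    with np.errstate(invalid="ignore"):
        arr_sm = np.where(w_sm > 0, wa / np.where(w_sm > 0, w_sm, 1.0), np.nan)
    return arr_sm, w_sm


def estimate_strain(
    disp: DisplacementField,
    window_fwhm_axial_um: float = 15.0,
    smoothing_fwhm_lateral_um: float = 5.0,
) -> StrainField:
    """Axial strain as the WLS slope of displacement versus depth.

    The displacement is smoothed laterally with a plain Gaussian (FWHM
    ``smoothing_fwhm_lateral_um``); the strain at each voxel is then the
    weighted least-squares slope of u_z against physical depth over an axial
    window of ``window_fwhm_axial_um``, using the displacement weights.
    Compression is positive. Voxels whose window carries zero total weight
    are marked invalid.

    The lateral smoothing is deliberately unweighted: speckle-intensity
    weighting would make the lateral mixing proportions fluctuate with depth,
    which converts lateral displacement gradients (e.g. across the stress
    shadow of a stiff inclusion) into spurious axial slopes. With fixed
    proportions the smoothed column remains an exact convex combination of
    neighboring columns at every depth, so slopes mix linearly.

    The smoothing and the regression are both linear in u_z and therefore
    commute; for unwrapped displacement fields the smoothing is applied to
    the strain after the per-column regression instead of to u_z before it,
    because unwrapping leaves per-column 2*pi offsets that axial slopes
    ignore but lateral averages of u_z do not.
    """
    px, py, dz = disp.geometry.voxel_pitch_um
    n = max(3, _odd_size(window_fwhm_axial_um, dz))
    smooth_after = disp.unwrapped

    w = disp.weight
    u = disp.u_z
    if smoothing_fwhm_lateral_um > 0 and not smooth_after:
        sig = smoothing_fwhm_lateral_um / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        u = ndimage.gaussian_filter(u, sigma=(sig / px, sig / py, 0.0), mode="nearest")

    z = (np.arange(u.shape[2]) + 0.5) * dz * 1e3  # nm, matches u units
    zb = np.broadcast_to(z, u.shape)
    s_w = _moving_sums(w, n)
    s_wz = _moving_sums(w * zb, n)
    s_wu = _moving_sums(w * u, n)
    s_wzz = _moving_sums(w * zb * zb, n)
    s_wzu = _moving_sums(w * zb * u, n)

    denom = s_w * s_wzz - s_wz**2
    # scale-aware degeneracy cutoff: denom ~ s_w^2 * var(z) for healthy windows
    tiny = np.finfo(float).tiny
    ok = denom > n * tiny * (1.0 + s_wzz)
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = np.where(ok, (s_w * s_wzu - s_wz * s_wu) / np.where(ok, denom, 1.0), np.nan)
    # u_z positive toward the window and growing with depth under compression,
    # so the raw nm/nm slope is already compression-positive and dimensionless.
    strain = slope
    valid = ok & np.isfinite(strain)

    if smoothing_fwhm_lateral_um > 0 and smooth_after:
        w_strain = np.where(valid, w, 0.0)
        strain, w = _lateral_weighted_gaussian(strain, w_strain, smoothing_fwhm_lateral_um, (px, py))
        valid = (w > 0) & np.isfinite(strain)

    return StrainField(
        strain_z=np.where(valid, strain, np.nan),
        valid=valid,
        geometry=disp.geometry,
        weight=w,
        window_fwhm_um=n * dz,
        smoothing_fwhm_um=smoothing_fwhm_lateral_um,
    )


def detect_interface(
    structural: np.ndarray,
    geometry: AcquisitionGeometry,
    search_band_um: Tuple[float, float] | None = None,
    median_size: int = 5,
    smoothing_sigma_vox: Tuple[float, float, float] = (2.0, 2.0, 1.5),
):
    """Per-column depth of the layer-sample interface from an intensity step.

    Looks for the maximum axial intensity-gradient magnitude within the search
    band. The volume is smoothed in 3-D first: speckle intensity fluctuates
    by 100% per voxel, so lateral averaging is needed before the material
    step dominates the axial gradient. Columns with no detectable gradient
    are filled from neighbors and flagged.
    Returns ``(interface_depth_um, flagged)`` over (x, y).
    """
    vol = np.asarray(structural, dtype=float)
    dz = geometry.voxel_pitch_um[2]
    nz = vol.shape[2]
    z = (np.arange(nz) + 0.5) * dz
    lo, hi = (0.0, nz * dz) if search_band_um is None else search_band_um
    band = (z >= lo) & (z <= hi)
    if band.sum() < 3:
        raise ValueError("search band must span >= 3 voxels")

    smooth = ndimage.gaussian_filter(vol, sigma=smoothing_sigma_vox, mode="nearest")
    grad = np.abs(np.gradient(smooth, axis=2))
    grad_band = grad[:, :, band]
    z_band = z[band]
    idx = np.argmax(grad_band, axis=2)
    depth = z_band[idx]

    peak = np.max(grad_band, axis=2)
    span = float(vol.max() - vol.min())
    flagged = peak <= 1e-9 * (span + 1e-300) if span > 0 else np.ones_like(peak, bool)
    if flagged.all():
        return depth, flagged
    if flagged.any():
        depth = depth.copy()
        depth[flagged] = np.median(depth[~flagged])
    depth = ndimage.median_filter(depth, size=median_size, mode="nearest")
    return depth, flagged


def layer_stress_map(
    strain: StrainField,
    interface_depth_um: np.ndarray,
    calibration: LayerCalibration,
    band_gap_um: float = 10.0,
    band_width_um: float = 45.0,
) -> StressMap:
    """Stress at the layer-sample interface from layer-side strain.

    Layer strain is weight-averaged over the axial band
    ``[interface + gap, interface + gap + width]`` on the layer side of the
    interface, then converted through the calibration curve. One stress value
    per A-line column. The band must fit inside the imaged volume for the
    typical (median) column; individual columns whose detected interface sits
    anomalously deep have their band truncated at the volume end and are
    invalidated if nothing remains.
    """
    dz = strain.geometry.voxel_pitch_um[2]
    nz = strain.strain_z.shape[2]
    z = (np.arange(nz) + 0.5) * dz
    iface = np.broadcast_to(np.asarray(interface_depth_um, float)[..., None], strain.strain_z.shape)
    lo = iface + band_gap_um
    hi = iface + band_gap_um + band_width_um
    if np.median(np.asarray(interface_depth_um)) + band_gap_um + band_width_um > nz * dz:
        raise ValueError("layer averaging band extends beyond the imaged volume")
    in_band = (z >= lo) & (z <= hi) & strain.valid

    w = strain.weight if strain.weight is not None else np.ones_like(strain.strain_z)
    w = np.where(in_band, w, 0.0)
    eps = np.where(in_band, np.nan_to_num(strain.strain_z), 0.0)
    wsum = w.sum(axis=2)
    ok = wsum > 0
    with np.errstate(invalid="ignore"):
        eps_bar = np.where(ok, (w * eps).sum(axis=2) / np.where(ok, wsum, 1.0), np.nan)
    sigma = np.where(ok, calibration.stress(np.where(ok, eps_bar, 0.0)), np.nan)
    return StressMap(
        sigma_kpa=sigma,
        interface_depth_um=np.broadcast_to(np.asarray(interface_depth_um, float), sigma.shape).copy(),
        valid=ok & np.isfinite(sigma),
    )


def young_modulus(
    stress: StressMap,
    strain: StrainField,
    strain_floor: float = 1e-4,
    smoothing_fwhm_lateral_um: float | None = None,
    window_fwhm_axial_um: float | None = None,
    focal_depth_um: float | None = None,
) -> ModulusVolume:
    """Tangent modulus E = sigma / eps per sample voxel (uniaxial stress).

    Voxels with strain at or below ``strain_floor`` (noise-level or tensile)
    are masked invalid rather than raising. Only voxels on the sample side of
    the interface, at least half a regression window away from it, are valid:
    windows crossing the interface mix layer and sample strain.
    """
    eps = strain.strain_z
    if stress.sigma_kpa.shape != eps.shape[:2]:
        raise ValueError("stress map and strain field are not laterally congruent")
    dz = strain.geometry.voxel_pitch_um[2]
    nz = eps.shape[2]
    z = (np.arange(nz) + 0.5) * dz
    margin = strain.window_fwhm_um / 2.0
    in_sample = z[None, None, :] < (stress.interface_depth_um[..., None] - margin)
    in_sample &= z[None, None, :] > margin

    sigma = stress.sigma_kpa[..., None]
    valid = strain.valid & in_sample & stress.valid[..., None]
    valid = valid & (np.nan_to_num(eps) > strain_floor)
    with np.errstate(invalid="ignore", divide="ignore"):
        E = np.where(valid, sigma / np.where(valid, eps, 1.0), np.nan)
    smoothing = strain.smoothing_fwhm_um if smoothing_fwhm_lateral_um is None else smoothing_fwhm_lateral_um
    window = strain.window_fwhm_um if window_fwhm_axial_um is None else window_fwhm_axial_um
    res = elasticity_resolution(strain.geometry, smoothing, window)
    return ModulusVolume(
        E_kpa=E,
        valid=valid,
        resolution_fwhm_um=res,
        geometry=strain.geometry,
        focal_depth_um=focal_depth_um,
        provenance={
            "strain_floor": strain_floor,
            "smoothing_fwhm_lateral_um": smoothing,
            "window_fwhm_axial_um": window,
        },
    )


def elasticity_resolution(
    geometry: AcquisitionGeometry,
    smoothing_fwhm_lateral_um: float = 5.0,
    window_fwhm_axial_um: float = 15.0,
) -> Tuple[float, float, float]:
    """System resolution of the modulus map, per axis, in um FWHM.

    Convolution of Gaussian-equivalent optical and processing responses adds
    their FWHMs in quadrature: lateral smoothing against the lateral optical
    PSF, the axial regression window against the axial PSF. With the defaults
    (0.5, 0.5, 1.4) um optics, 5 um smoothing, and a 15 um window this gives
    approximately 5 x 5 x 15 um^3.
    """
    ox, oy, oz = geometry.ocm_resolution_fwhm_um
    rx = float(np.hypot(ox, smoothing_fwhm_lateral_um))
    ry = float(np.hypot(oy, smoothing_fwhm_lateral_um))
    rz = float(np.hypot(oz, window_fwhm_axial_um))
    return (rx, ry, rz)
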