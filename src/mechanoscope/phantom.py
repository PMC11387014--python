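"""Forward simulator of compression-OCE acquisitions with known ground truth.

A phantom is a block of hydrogel (optionally carrying spheroid-like
inclusions with distinct core and periphery moduli) of known thickness,
compressed quasi-statically in series with a 1 mm compliant layer between a
fixed imaging window and an actuator. The simulator realizes exactly the
mechanical model the reconstruction assumes -- uniaxial stress with
mechanically independent A-line columns -- so that recovery is exact up to
speckle and shot noise, and renders fully developed speckle OCM volume pairs
whose phase difference encodes the axial displacement.

Coordinates: z is depth from the window; the sample occupies
``z < sample_thickness`` and the compliant layer sits beyond it (only its
first stretch is inside the imaged grid). The window is fixed, so
displacement is zero at z = 0 and accumulates with depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Sequence, Tuple

import numpy as np

from .calibration import LayerCalibration
from .containers import AcquisitionGeometry, ComplexOCMVolume


class GeometryError(ValueError):
    """Raised when a phantom's geometry is internally inconsistent."""


@dataclass(frozen=True)
class Inclusion:
    """Spherical spheroid-like inclusion with a concentric stiffer/softer core.

    ``core_fraction`` is the core diameter as a fraction of the inclusion
    diameter; ``scattering_ratio`` is the backscatter intensity of the
    inclusion relative to the background gel (cell spheroids scatter far more
    strongly than dilute GelMA).
    """

    center_um: Tuple[float, float, float]
    radius_um: float
    core_modulus_kpa: float
    periphery_modulus_kpa: float
    core_fraction: float = 0.5
    scattering_ratio: float = 1000.0


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic compression-OCE acquisition."""

    grid_shape: Tuple[int, int, int] = (64, 64, 256)
    voxel_pitch_um: Tuple[float, float, float] = (2.0, 2.0, 1.8)
    layer_thickness_um: float = 1000.0
    layer_calibration: LayerCalibration = field(default_factory=lambda: LayerCalibration.linear(20.0))
    sample_thickness_um: float = 400.0
    background_modulus_kpa: float = 7.0
    inclusions: Tuple[Inclusion, ...] = ()
    bulk_displacement_um: float = 0.15
    speckle_mean_intensity: float = 100.0
    noise_floor: float = 1.0
    layer_intensity_ratio: float = 2.0
    focal_depths_um: Tuple[float, ...] | None = None
    envelope_fwhm_um: float = 12.0
    wavelength_nm: float = 800.0
    refractive_index: float = 1.35
    seed: int = 0

    def __post_init__(self) -> None:
        nx, ny, nz = self.grid_shape
        px, py, pz = self.voxel_pitch_um
        if self.background_modulus_kpa <= 0:
            raise GeometryError("background modulus must be positive")
        if self.bulk_displacement_um < 0:
            raise GeometryError("bulk displacement must be non-negative")
        stack = self.layer_thickness_um + self.sample_thickness_um
        if self.bulk_displacement_um / stack >= 0.05:
            raise GeometryError("bulk strain of the stack must stay below 5% (pre-strain bound)")
        extent = (nx * px, ny * py, nz * pz)
        for inc in self.inclusions:
            if inc.core_modulus_kpa <= 0 or inc.periphery_modulus_kpa <= 0:
                raise GeometryError("inclusion moduli must be positive")
            if not 0.0 < inc.core_fraction < 1.0:
                raise GeometryError("core_fraction must lie in (0, 1)")
            for c, e in zip(inc.center_um, extent):
                if c - inc.radius_um < 0 or c + inc.radius_um > e:
                    raise GeometryError("inclusion extends outside the grid")
            if inc.center_um[2] + inc.radius_um > self.sample_thickness_um:
                raise GeometryError("inclusion extends into the compliant layer")

    @property
    def geometry(self) -> AcquisitionGeometry:
        return AcquisitionGeometry(
            wavelength_nm=self.wavelength_nm,
            refractive_index=self.refractive_index,
            voxel_pitch_um=self.voxel_pitch_um,
        )

    def voxel_centers_um(self):
        """Coordinate vectors of voxel centers along each axis (um)."""
        return tuple(
            (np.arange(n) + 0.5) * p for n, p in zip(self.grid_shape, self.voxel_pitch_um)
        )

    def with_(self, **kw) -> "PhantomSpec":
        return replace(self, **kw)


@dataclass
class GroundTruthFields:
    """Simulator-side truth: modulus, displacement, strain, interface stress."""

    modulus_kpa: np.ndarray            # per voxel (layer voxels: layer tangent)
    displacement_z_nm: np.ndarray      # per voxel, toward the window positive
    strain_z: np.ndarray               # per voxel, compression positive
    interface_stress_kpa: np.ndarray   # per (x, y) column
    interface_depth_um: np.ndarray     # per (x, y)
    sample_mask: np.ndarray            # per voxel, True where z < sample thickness


def _region_masks(spec: PhantomSpec):
    """Boolean masks (inclusion, core) per voxel, nearest-center tie-break."""
    xs, ys, zs = spec.voxel_centers_um()
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    owner = np.full(spec.grid_shape, -1, dtype=int)
    best = np.full(spec.grid_shape, np.inf)
    for k, inc in enumerate(spec.inclusions):
        d2 = (X - inc.center_um[0]) ** 2 + (Y - inc.center_um[1]) ** 2 + (Z - inc.center_um[2]) ** 2
        inside = d2 <= inc.radius_um**2
        take = inside & (d2 < best)
        owner[take] = k
        best[take] = d2[take]
    return owner, best


def build_modulus_field(spec: PhantomSpec) -> np.ndarray:
    """Sample modulus field in kPa: background, core, or periphery per voxel.

    Overlapping inclusions: a contested voxel belongs to the inclusion whose
    center is nearer. The core is the concentric ball of diameter
    ``core_fraction`` times the inclusion diameter.
    """
    E = np.full(spec.grid_shape, spec.background_modulus_kpa, dtype=float)
    if not spec.inclusions:
        return E
    owner, best = _region_masks(spec)
    for k, inc in enumerate(spec.inclusions):
        mine = owner == k
        core = mine & (best <= (inc.core_fraction * inc.radius_um) ** 2)
        E[mine] = inc.periphery_modulus_kpa
        E[core] = inc.core_modulus_kpa
    return E


def solve_uniaxial_compression(modulus_field: np.ndarray, spec: PhantomSpec) -> GroundTruthFields:
    """Per-column uniaxial-stress solution of the layer + sample stack.

    For each (x, y) column the interface stress sigma solves

        layer_strain(sigma) * L_layer + sum_i (sigma / E_i) * h_i = delta

    with h_i the voxel heights of the sample voxels of that column and delta
    the actuator's bulk displacement. Columns are mechanically independent.
    Strain and cumulative displacement (zero at the fixed window) fill the
    whole imaged grid, including the visible stretch of the layer.
    """
    cal = spec.layer_calibration
    if np.any(np.diff(cal.stress_kpa) <= 0):
        raise ValueError("layer calibration must be monotone increasing")
    E = np.asarray(modulus_field, dtype=float)
    if E.shape != spec.grid_shape:
        raise ValueError("modulus field does not match the phantom grid")
    nx, ny, nz = spec.grid_shape
    dz = spec.voxel_pitch_um[2]
    z = (np.arange(nz) + 0.5) * dz
    sample = z < spec.sample_thickness_um
    sample_mask = np.broadcast_to(sample, E.shape)

    # series compliance of the sample voxels, per column (um per kPa)
    C = (dz / E[:, :, sample]).sum(axis=2)
    delta = spec.bulk_displacement_um
    if delta == 0:
        sigma = np.zeros((nx, ny))
        eps_layer = np.zeros((nx, ny))
    else:
        # bisect on the layer strain e so only the forward curve f is used:
        # g(e) = e * L_layer + f(e) * C - delta, strictly increasing in e.
        # g(delta / L_layer) >= 0 always, so the bracket needs no expansion.
        lo = np.zeros((nx, ny))
        hi = np.full((nx, ny), delta / spec.layer_thickness_um)
        for _ in range(90):
            mid = 0.5 * (lo + hi)
            g = mid * spec.layer_thickness_um + np.asarray(cal.stress(mid)) * C - delta
            hi = np.where(g >= 0, mid, hi)
            lo = np.where(g >= 0, lo, mid)
        eps_layer = 0.5 * (lo + hi)
        sigma = np.asarray(cal.stress(eps_layer), dtype=float)

    strain = np.empty_like(E)
    strain[:, :, sample] = sigma[:, :, None] / E[:, :, sample]
    strain[:, :, ~sample] = np.repeat(eps_layer[:, :, None], (~sample).sum(), axis=2)

    # cumulative integral from the window, evaluated at voxel centers
    cum = np.cumsum(strain * dz, axis=2)
    u_um = cum - 0.5 * strain * dz
    # ground-truth modulus: layer voxels carry the layer tangent at the
    # operating strain so sigma = E * eps holds wherever strain is defined
    modulus = E.copy()
    tangent = np.asarray(cal.tangent(eps_layer), dtype=float)
    modulus[:, :, ~sample] = np.repeat(tangent[:, :, None], (~sample).sum(), axis=2)

    return GroundTruthFields(
        modulus_kpa=modulus,
        displacement_z_nm=u_um * 1e3,
        strain_z=strain,
        interface_stress_kpa=sigma,
        interface_depth_um=np.full((nx, ny), float(spec.sample_thickness_um)),
        sample_mask=np.ascontiguousarray(sample_mask),
    )


def scattering_intensity(spec: PhantomSpec) -> np.ndarray:
    """Mean backscatter intensity per voxel (linear units, no envelope)."""
    xs, ys, zs = spec.voxel_centers_um()
    I = np.full(spec.grid_shape, spec.speckle_mean_intensity, dtype=float)
    layer = zs >= spec.sample_thickness_um
    I[:, :, layer] = spec.speckle_mean_intensity * spec.layer_intensity_ratio
    if spec.inclusions:
        owner, _ = _region_masks(spec)
        for k, inc in enumerate(spec.inclusions):
            I[owner == k] = spec.speckle_mean_intensity * inc.scattering_ratio
    return I


def _axial_envelope(spec: PhantomSpec, focal_depth_um: float | None) -> np.ndarray:
    if focal_depth_um is None:
        return np.ones(spec.grid_shape[2])
    z = (np.arange(spec.grid_shape[2]) + 0.5) * spec.voxel_pitch_um[2]
    w = spec.envelope_fwhm_um
    return np.exp(-4.0 * np.log(2.0) * (z - focal_depth_um) ** 2 / w**2)


def render_ocm_pair(
    truth: GroundTruthFields,
    spec: PhantomSpec,
    seed: int | None = None,
    focal_depth_um: float | None = None,
) -> Tuple[ComplexOCMVolume, ComplexOCMVolume]:
    """Render an (unloaded, loaded) speckle volume pair.

    The unloaded volume is fully developed speckle (complex circular Gaussian
    per voxel) whose amplitude is shaped by a Gaussian confocal envelope
    centered at ``focal_depth_um`` (no envelope when ``None``). The loaded
    volume carries the per-voxel phase increment ``4 pi n u_z / lambda0``
    plus independent additive complex noise at the configured noise floor.
    A wrap-hazard flag is recorded when |dphi| reaches pi anywhere.
    """
    if truth.strain_z.shape != spec.grid_shape:
        raise ValueError("ground truth and spec are not on the same grid")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    geometry = spec.geometry

    I = scattering_intensity(spec) * _axial_envelope(spec, focal_depth_um) ** 2
    amp = np.sqrt(I / 2.0)
    speckle = amp * (rng.standard_normal(spec.grid_shape) + 1j * rng.standard_normal(spec.grid_shape))

    phi = (
        4.0 * np.pi * spec.refractive_index * truth.displacement_z_nm / spec.wavelength_nm
    )
    hazard = bool(np.max(np.abs(phi)) >= np.pi)
    noise = 0.0
    if spec.noise_floor > 0:
        namp = np.sqrt(spec.noise_floor / 2.0)
        noise = namp * (
            rng.standard_normal(spec.grid_shape) + 1j * rng.standard_normal(spec.grid_shape)
        )
    loaded_data = speckle * np.exp(1j * phi) + noise

    meta = {"bulk_displacement_um": spec.bulk_displacement_um}
    unloaded = ComplexOCMVolume(
        data=speckle, geometry=geometry, focal_depth_um=focal_depth_um,
        noise_power=spec.noise_floor, wrap_hazard=hazard, meta=dict(meta),
    )
    loaded = ComplexOCMVolume(
        data=loaded_data, geometry=geometry, focal_depth_um=focal_depth_um,
        noise_power=spec.noise_floor, wrap_hazard=hazard, meta=dict(meta),
    )
    return unloaded, loaded


def render_focal_stack(truth: GroundTruthFields, spec: PhantomSpec) -> List[Tuple[ComplexOCMVolume, ComplexOCMVolume]]:
    """Render one pair per configured focal depth with independent speckle."""
    depths: Sequence[float | None]
    if spec.focal_depths_um:
        depths = list(spec.focal_depths_um)
    else:
        depths = [None]
    seeds = np.random.SeedSequence(spec.seed).generate_state(len(depths)) % (2**31)
    return [
        render_ocm_pair(truth, spec, seed=int(s), focal_depth_um=d)
        for s, d in zip(seeds, depths)
    ]


@dataclass
class FluorescenceStack:
    """Two-channel fluorescence stack co-registered to the OCM grid.

    Channel 0: point-like nuclei; channel 1: membrane outline of each
    inclusion boundary. ``nuclei_um`` holds the generated nucleus centers.
    """

    channels: np.ndarray  # (2, nx, ny, nz)
    nuclei_um: np.ndarray  # (n, 3)


def render_fluorescence(
    spec: PhantomSpec,
    seed: int | None = None,
    nucleus_density_per_um3: float = 2e-3,
    periphery_core_density_ratio: float = 2.0,
) -> FluorescenceStack:
    """Scatter nuclei inside each inclusion and outline its membrane.

    Nuclei are a Poisson point process, denser in the periphery shell than in
    the core by ``periphery_core_density_ratio``; every nucleus lies inside
    its inclusion ball. Empty inclusion lists yield empty channels.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    channels = np.zeros((2,) + tuple(spec.grid_shape), dtype=np.float32)
    nuclei: list[np.ndarray] = []
    pitch = np.asarray(spec.voxel_pitch_um)

    for inc in spec.inclusions:
        R = inc.radius_um
        rc = inc.core_fraction * R
        vol_core = 4.0 / 3.0 * np.pi * rc**3
        vol_shell = 4.0 / 3.0 * np.pi * (R**3 - rc**3)
        lam_core = nucleus_density_per_um3 * vol_core
        lam_shell = nucleus_density_per_um3 * periphery_core_density_ratio * vol_shell
        for lam, r_lo, r_hi in ((lam_core, 0.0, rc), (lam_shell, rc, R)):
            n = rng.poisson(lam)
            if n == 0:
                continue
            # radius via inverse-CDF within the shell, direction uniform
            u = rng.random(n)
            r = (r_lo**3 + u * (r_hi**3 - r_lo**3)) ** (1.0 / 3.0)
            v = rng.standard_normal((n, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            pts = np.asarray(inc.center_um) + r[:, None] * v
            nuclei.append(pts)
            idx = np.floor(pts / pitch).astype(int)
            np.clip(idx, 0, np.asarray(spec.grid_shape) - 1, out=idx)
            for i, j, k in idx:
                channels[0, i, j, k] += 1.0

        xs, ys, zs = spec.voxel_centers_um()
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        d = np.sqrt(
            (X - inc.center_um[0]) ** 2 + (Y - inc.center_um[1]) ** 2 + (Z - inc.center_um[2]) ** 2
        )
        shell_halfwidth = float(np.max(pitch))
        channels[1][np.abs(d - R) <= shell_halfwidth] = 1.0

    pts_all = np.concatenate(nuclei, axis=0) if nuclei else np.empty((0, 3))
    return FluorescenceStack(channels=channels, nuclei_um=pts_all)
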