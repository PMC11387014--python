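"""Shared in-memory containers for acquisitions.

Conventions used across the package:

* volumes are numpy arrays indexed ``[x, y, z]`` with z the axial (depth)
  axis, increasing away from the imaging window; voxel centers sit at
  ``(i + 0.5) * pitch``;
* lengths are in micrometers unless a field name says otherwise
  (wavelength and displacement are in nanometers);
* compression is positive: compressive strain, stress, and displacement
  toward the window are all positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Optical and sampling geometry of a phase-sensitive OCM acquisition.

    Parameters
    ----------
    wavelength_nm
        Central wavelength of the source (nm).
    refractive_index
        Bulk refractive index of the medium used to convert optical phase to
        physical displacement (hydrogel is close to water).
    voxel_pitch_um
        Physical voxel pitch per (x, y, z) axis in micrometers.
    ocm_resolution_fwhm_um
        Optical point-spread FWHM per axis in micrometers (in air).
    """

    wavelength_nm: float = 800.0
    refractive_index: float = 1.35
    voxel_pitch_um: Tuple[float, float, float] = (2.0, 2.0, 2.0)
    ocm_resolution_fwhm_um: Tuple[float, float, float] = (0.5, 0.5, 1.4)

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")
        if self.refractive_index <= 0:
            raise ValueError("refractive index must be positive")
        if any(p <= 0 for p in self.voxel_pitch_um):
            raise ValueError("voxel pitches must be positive")
        if any(r <= 0 for r in self.ocm_resolution_fwhm_um):
            raise ValueError("resolution FWHMs must be positive")

    @property
    def z_coords_um(self):
        raise AttributeError("grid-dependent; use volume.z_coords_um")


@dataclass
class ComplexOCMVolume:
    """Complex backscatter volume with acquisition metadata.

    ``data`` is complex-valued, indexed ``[x, y, z]``. ``focal_depth_um`` is
    the depth of the confocal focal plane (``None`` for idealized rendering
    without a depth-of-field envelope).
    """

    data: np.ndarray
    geometry: AcquisitionGeometry
    focal_depth_um: float | None = None
    noise_power: float = 0.0
    wrap_hazard: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("OCM volume must be 3-D (x, y, z)")
        if not np.iscomplexobj(self.data):
            self.data = self.data.astype(np.complex128)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    @property
    def z_coords_um(self) -> np.ndarray:
        """Depth of each axial voxel center from the window, in um."""
        dz = self.geometry.voxel_pitch_um[2]
        return (np.arange(self.shape[2]) + 0.5) * dz

    def intensity(self) -> np.ndarray:
        return np.abs(self.data) ** 2

    def snr_db(self) -> np.ndarray:
        """Per-voxel intensity SNR in dB relative to the noise power."""
        if self.noise_power <= 0:
            raise ValueError("noise power not recorded for this volume")
        return 10.0 * np.log10(np.maximum(self.intensity(), 1e-300) / self.noise_power)


def congruent(a: ComplexOCMVolume, b: ComplexOCMVolume) -> bool:
    return (
        a.shape == b.shape
        and a.geometry.voxel_pitch_um == b.geometry.voxel_pitch_um
        and a.geometry.wavelength_nm == b.geometry.wavelength_nm
        and a.geometry.refractive_index == b.geometry.refractive_index
    )
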