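"""Compliant-layer stress-strain calibration.

The compliant silicone layer compressed in series with the sample acts as a
distributed stress sensor: its measured strain, pushed through a
pre-characterized monotone stress-strain curve, gives the stress transmitted
to the layer-sample interface. This module fits that curve from calibration
samples and evaluates it (and its tangent and inverse) anywhere in range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator


class CalibrationError(ValueError):
    """Raised when calibration samples cannot yield a monotone curve."""


@dataclass
class LayerCalibration:
    """Monotone stress-strain response ``sigma = f(eps)`` of the layer.

    Anchored at ``f(0) = 0`` and strictly increasing over the fitted range.
    ``strain`` is dimensionless (compression positive), ``stress_kpa`` in kPa.
    """

    strain: np.ndarray
    stress_kpa: np.ndarray
    _f: PchipInterpolator = field(init=False, repr=False)
    _df: PchipInterpolator = field(init=False, repr=False)
    _finv: PchipInterpolator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        eps = np.asarray(self.strain, dtype=float)
        sig = np.asarray(self.stress_kpa, dtype=float)
        if eps.ndim != 1 or eps.shape != sig.shape:
            raise CalibrationError("strain and stress samples must be 1-D and congruent")
        order = np.argsort(eps)
        eps, sig = eps[order], sig[order]
        if not np.isclose(eps[0], 0.0):
            eps = np.concatenate([[0.0], eps])
            sig = np.concatenate([[0.0], sig])
        else:
            sig[0] = 0.0  # anchor exactly
        if np.any(np.diff(eps) <= 0):
            raise CalibrationError("strain samples must be distinct")
        if np.any(np.diff(sig) <= 0):
            raise CalibrationError("stress samples must be strictly increasing with strain")
        self.strain, self.stress_kpa = eps, sig
        # Pchip preserves monotonicity of the data, so f is strictly
        # increasing and invertible on the sampled range.
        self._f = PchipInterpolator(eps, sig, extrapolate=True)
        self._df = self._f.derivative()
        self._finv = PchipInterpolator(sig, eps, extrapolate=True)

    def stress(self, strain):
        """Evaluate sigma = f(eps) in kPa."""
        return self._f(strain)

    def tangent(self, strain):
        """Tangent modulus df/deps in kPa."""
        return self._df(strain)

    def strain_at(self, stress_kpa):
        """Inverse map eps = f^-1(sigma)."""
        return self._finv(stress_kpa)

    @classmethod
    def linear(cls, modulus_kpa: float, max_strain: float = 0.2) -> "LayerCalibration":
        """Ideal linear-elastic layer of the given Young's modulus."""
        eps = np.linspace(0.0, max_strain, 9)
        return cls(strain=eps, stress_kpa=modulus_kpa * eps)


def fit_layer_calibration(samples) -> LayerCalibration:
    """Fit a monotone piecewise-cubic stress-strain curve through (0, 0).

    Parameters
    ----------
    samples
        Sequence of (strain, stress_kPa) pairs, or a 2-column array.

    Returns
    -------
    LayerCalibration
        Monotone interpolant with tangent available everywhere in range.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise CalibrationError("need >= 3 (strain, stress) samples")
    return LayerCalibration(strain=arr[:, 0], stress_kpa=arr[:, 1])
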