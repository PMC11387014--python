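"""File formats: HDF5 interchange, TIFF export, CSV tables, YAML configs.

HDF5 is the canonical lossless container (float64; complex volumes stored as
paired real/imag datasets; metadata as attributes). TIFF export is float32
with units and metadata recorded in the image description (multi-page along
z). Calibration tables are CSV with columns ``strain, stress_kPa``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .calibration import LayerCalibration
from .containers import AcquisitionGeometry, ComplexOCMVolume
from .phantom import GroundTruthFields


class FormatError(ValueError):
    pass


class SchemaError(ValueError):
    """A container is missing required metadata attributes."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(f"missing required metadata attributes: {', '.join(self.missing)}")


REQUIRED_GEOMETRY_ATTRS = ("wavelength_nm", "refractive_index", "voxel_pitch_um")


def _geometry_attrs(geometry: AcquisitionGeometry) -> dict:
    return {
        "wavelength_nm": geometry.wavelength_nm,
        "refractive_index": geometry.refractive_index,
        "voxel_pitch_um": np.asarray(geometry.voxel_pitch_um, dtype=float),
        "ocm_resolution_fwhm_um": np.asarray(geometry.ocm_resolution_fwhm_um, dtype=float),
    }


def _geometry_from_attrs(attrs) -> AcquisitionGeometry:
    missing = [k for k in REQUIRED_GEOMETRY_ATTRS if k not in attrs]
    if missing:
        raise SchemaError(missing)
    kw = {
        "wavelength_nm": float(attrs["wavelength_nm"]),
        "refractive_index": float(attrs["refractive_index"]),
        "voxel_pitch_um": tuple(np.asarray(attrs["voxel_pitch_um"], dtype=float)),
    }
    if "ocm_resolution_fwhm_um" in attrs:
        kw["ocm_resolution_fwhm_um"] = tuple(np.asarray(attrs["ocm_resolution_fwhm_um"], dtype=float))
    return AcquisitionGeometry(**kw)


def _write_complex(group: h5py.Group, name: str, vol: ComplexOCMVolume) -> None:
    g = group.create_group(name)
    g.create_dataset("real", data=vol.data.real)
    g.create_dataset("imag", data=vol.data.imag)
    for k, v in _geometry_attrs(vol.geometry).items():
        g.attrs[k] = v
    g.attrs["focal_depth_um"] = np.nan if vol.focal_depth_um is None else float(vol.focal_depth_um)
    g.attrs["noise_power"] = float(vol.noise_power)
    g.attrs["wrap_hazard"] = bool(vol.wrap_hazard)
    g.attrs["meta_json"] = json.dumps(vol.meta, sort_keys=True, default=str)


def _read_complex(g: h5py.Group) -> ComplexOCMVolume:
    geometry = _geometry_from_attrs(g.attrs)
    focal = float(g.attrs.get("focal_depth_um", np.nan))
    return ComplexOCMVolume(
        data=g["real"][()] + 1j * g["imag"][()],
        geometry=geometry,
        focal_depth_um=None if np.isnan(focal) else focal,
        noise_power=float(g.attrs.get("noise_power", 0.0)),
        wrap_hazard=bool(g.attrs.get("wrap_hazard", False)),
        meta=json.loads(g.attrs.get("meta_json", "{}")),
    )


def write_acquisition(path, pairs, truth: GroundTruthFields | None = None, attrs: dict | None = None) -> None:
    """Write (unloaded, loaded) pairs and optional ground truth to HDF5.

    Each pair goes under ``acq_<i>/unloaded`` and ``acq_<i>/loaded``; ground
    truth fields are separate datasets under ``ground_truth``.
    """
    with h5py.File(path, "w") as f:
        f.attrs["n_acquisitions"] = len(pairs)
        for k, v in (attrs or {}).items():
            f.attrs[k] = v
        for i, (unloaded, loaded) in enumerate(pairs):
            g = f.create_group(f"acq_{i:03d}")
            _write_complex(g, "unloaded", unloaded)
            _write_complex(g, "loaded", loaded)
        if truth is not None:
            g = f.create_group("ground_truth")
            g.create_dataset("modulus_kpa", data=truth.modulus_kpa)
            g.create_dataset("displacement_z_nm", data=truth.displacement_z_nm)
            g.create_dataset("strain_z", data=truth.strain_z)
            g.create_dataset("interface_stress_kpa", data=truth.interface_stress_kpa)
            g.create_dataset("interface_depth_um", data=truth.interface_depth_um)
            g.create_dataset("sample_mask", data=truth.sample_mask)


def read_acquisition(path):
    """Read pairs (and ground truth, if present) back from HDF5."""
    pairs, truth, attrs = [], None, {}
    with h5py.File(path, "r") as f:
        attrs = {k: f.attrs[k] for k in f.attrs}
        n = int(f.attrs.get("n_acquisitions", 0))
        for i in range(n):
            g = f[f"acq_{i:03d}"]
            pairs.append((_read_complex(g["unloaded"]), _read_complex(g["loaded"])))
        if "ground_truth" in f:
            g = f["ground_truth"]
            truth = GroundTruthFields(
                modulus_kpa=g["modulus_kpa"][()],
                displacement_z_nm=g["displacement_z_nm"][()],
                strain_z=g["strain_z"][()],
                interface_stress_kpa=g["interface_stress_kpa"][()],
                interface_depth_um=g["interface_depth_um"][()],
                sample_mask=g["sample_mask"][()].astype(bool),
            )
    return pairs, truth, attrs


def write_volume(path, data: np.ndarray, meta: dict | None = None, valid: np.ndarray | None = None) -> None:
    """Write a scalar volume to ``.h5`` (lossless float64) or ``.tif``/``.tiff``
    (float32, pages along z, metadata in the image description)."""
    path = Path(path)
    meta = meta or {}
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=np.asarray(data, dtype=np.float64))
            if valid is not None:
                f.create_dataset("valid", data=np.asarray(valid, dtype=bool))
            f.attrs["meta_json"] = json.dumps(meta, sort_keys=True, default=str)
    elif path.suffix in (".tif", ".tiff"):
        arr = np.asarray(data)
        if arr.dtype != np.uint8:
            arr = arr.astype(np.float32)
        tifffile.imwrite(path, np.moveaxis(arr, 2, 0), description=json.dumps(meta, sort_keys=True, default=str))
    else:
        raise FormatError(f"unknown volume format: {path.suffix!r} (use .h5 or .tif)")


def read_volume(path):
    """Inverse of :func:`write_volume`; returns ``(data, meta, valid)``."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            data = f["data"][()]
            valid = f["valid"][()].astype(bool) if "valid" in f else None
            meta = json.loads(f.attrs.get("meta_json", "{}"))
        return data, meta, valid
    if path.suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray()
            desc = tf.pages[0].description or "{}"
        try:
            meta = json.loads(desc)
        except json.JSONDecodeError:
            meta = {}
        return np.moveaxis(arr, 0, 2), meta, None
    raise FormatError(f"unknown volume format: {path.suffix!r} (use .h5 or .tif)")


def write_fluorescence_tiff(path, channels: np.ndarray, meta: dict | None = None) -> None:
    """Two-channel stack as channel-interleaved multi-page TIFF (page order
    z-major, channels interleaved within each z plane)."""
    ch = np.asarray(channels, dtype=np.float32)  # (2, nx, ny, nz)
    pages = np.moveaxis(ch, 3, 0).reshape(-1, ch.shape[1], ch.shape[2])
    tifffile.imwrite(path, pages, description=json.dumps(meta or {}, sort_keys=True, default=str))


def read_calibration_csv(path) -> LayerCalibration:
    """Calibration samples from CSV with columns ``strain, stress_kPa``."""
    df = pd.read_csv(path)
    missing = [c for c in ("strain", "stress_kPa") if c not in df.columns]
    if missing:
        raise SchemaError(missing)
    return LayerCalibration(strain=df["strain"].to_numpy(), stress_kpa=df["stress_kPa"].to_numpy())


def write_calibration_csv(path, calibration: LayerCalibration) -> None:
    pd.DataFrame({"strain": calibration.strain, "stress_kPa": calibration.stress_kpa}).to_csv(
        path, index=False
    )


def load_config(path) -> dict:
    """Structured text config (YAML, of which JSON is a subset)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError("config must be a mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    """sha256 of the canonical JSON serialization; stable under key order."""
    canon = json.dumps(cfg, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
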