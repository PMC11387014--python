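"""Pipeline driver: simulate -> elastogram -> fuse -> segment -> stats.

The driver ties the modules into one reproducible run. A run is described by
a plain config mapping (YAML on disk); every output artifact records the
seed and the config hash so a run can be reproduced bit-for-bit.

Stress sharing across a focal stack: every focal acquisition repeats the
same quasi-static load, but the depth-of-field envelope means only
acquisitions focused near the compliant layer can measure layer strain. The
driver estimates one stress map from the acquisition focused closest to the
layer averaging band and applies it to the strain field of every volume.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Tuple

import numpy as np
from scipy import ndimage

from . import io as msio
from .calibration import LayerCalibration
from .containers import ComplexOCMVolume
from .fusion import FocalStack, fuse
from .phantom import (
    Inclusion,
    PhantomSpec,
    build_modulus_field,
    render_focal_stack,
    solve_uniaxial_compression,
)
from .reconstruct import (
    ModulusVolume,
    StressMap,
    detect_interface,
    estimate_strain,
    layer_stress_map,
    phase_difference,
    phase_to_displacement,
    young_modulus,
)
from .segment import region_stats, segment_spheroid, split_core_periphery

logger = logging.getLogger("mechanoscope")


@dataclass(frozen=True)
class ProcessingParams:
    """Tunable signal-processing parameters of the reconstruction chain."""

    averaging_kernel_um: Tuple[float, float, float] = (3.0, 3.0, 0.0)
    smoothing_fwhm_lateral_um: float = 5.0
    window_fwhm_axial_um: float = 15.0
    strain_floor: float = 1e-4
    unwrap_axial: bool = False
    # the gap must exceed half the regression window so that no band
    # voxel's window straddles the interface and mixes sample strain in
    band_gap_um: float = 10.0
    band_width_um: float = 45.0
    interface_depth_um: float | None = None
    interface_search_band_um: Tuple[float, float] | None = None
    # voxels whose averaged intensity sits below this margin over the
    # calibrated noise power carry no displacement information (out-of-focus
    # or shadowed); their regression weight is zeroed rather than merely small
    weight_floor_snr_db: float = 6.0


@dataclass(frozen=True)
class SegmentationParams:
    threshold: float = 0.5
    kernel_size: int = 20
    coverage: float = 0.95
    core_fraction: float = 0.5
    presmooth_fwhm_um: Tuple[float, float, float] = (5.0, 5.0, 10.0)
    half_planes: int = 0


def spec_from_config(cfg: dict, seed: int | None = None) -> PhantomSpec:
    """Build a PhantomSpec from the ``phantom`` section of a run config."""
    ph = dict(cfg.get("phantom", {}))
    if "layer_modulus_kpa" in ph:
        ph["layer_calibration"] = LayerCalibration.linear(float(ph.pop("layer_modulus_kpa")))
    elif "layer_calibration_csv" in ph:
        ph["layer_calibration"] = msio.read_calibration_csv(ph.pop("layer_calibration_csv"))
    if "inclusions" in ph:
        ph["inclusions"] = tuple(
            Inclusion(
                center_um=tuple(i["center_um"]),
                radius_um=float(i["radius_um"]),
                core_modulus_kpa=float(i["core_modulus_kpa"]),
                periphery_modulus_kpa=float(i["periphery_modulus_kpa"]),
                core_fraction=float(i.get("core_fraction", 0.5)),
                scattering_ratio=float(i.get("scattering_ratio", 1000.0)),
            )
            for i in ph["inclusions"]
        )
    for key in ("grid_shape", "voxel_pitch_um", "focal_depths_um"):
        if key in ph and ph[key] is not None:
            ph[key] = tuple(ph[key])
    if seed is not None:
        ph["seed"] = int(seed)
    return PhantomSpec(**ph)


def processing_from_config(cfg: dict) -> ProcessingParams:
    pr = dict(cfg.get("processing", {}))
    for key in ("averaging_kernel_um", "interface_search_band_um"):
        if key in pr and pr[key] is not None:
            pr[key] = tuple(pr[key])
    return ProcessingParams(**pr)


def simulate(spec: PhantomSpec):
    """Forward model: modulus field, mechanics, and speckle rendering."""
    E = build_modulus_field(spec)
    truth = solve_uniaxial_compression(E, spec)
    pairs = render_focal_stack(truth, spec)
    return truth, pairs


def strain_from_pair(
    unloaded: ComplexOCMVolume,
    loaded: ComplexOCMVolume,
    params: ProcessingParams = ProcessingParams(),
):
    """Phase difference -> displacement -> strain for one acquisition."""
    dphi, weight = phase_difference(unloaded, loaded, params.averaging_kernel_um)
    if unloaded.noise_power > 0 and params.weight_floor_snr_db is not None:
        floor = unloaded.noise_power * 10.0 ** (params.weight_floor_snr_db / 10.0)
        weight = np.where(weight >= floor, weight, 0.0)
    disp = phase_to_displacement(
        dphi, unloaded.geometry, weight=weight, unwrap_axial=params.unwrap_axial
    )
    return estimate_strain(
        disp,
        window_fwhm_axial_um=params.window_fwhm_axial_um,
        smoothing_fwhm_lateral_um=params.smoothing_fwhm_lateral_um,
    )


def stress_from_strain(
    strain,
    structural: np.ndarray,
    calibration: LayerCalibration,
    params: ProcessingParams = ProcessingParams(),
) -> StressMap:
    """Interface detection (or configured override) plus layer stress map."""
    if params.interface_depth_um is not None:
        shape = strain.strain_z.shape[:2]
        iface = np.full(shape, float(params.interface_depth_um))
    else:
        iface, _ = detect_interface(
            structural, strain.geometry, search_band_um=params.interface_search_band_um
        )
    return layer_stress_map(
        strain,
        iface,
        calibration,
        band_gap_um=params.band_gap_um,
        band_width_um=params.band_width_um,
    )


def elastogram_pair(
    unloaded: ComplexOCMVolume,
    loaded: ComplexOCMVolume,
    calibration: LayerCalibration,
    params: ProcessingParams = ProcessingParams(),
    stress: StressMap | None = None,
) -> tuple[ModulusVolume, StressMap]:
    """Full chain on one pair; reuses a shared stress map when given."""
    strain = strain_from_pair(unloaded, loaded, params)
    if stress is None:
        stress = stress_from_strain(strain, unloaded.intensity(), calibration, params)
    E = young_modulus(
        stress,
        strain,
        strain_floor=params.strain_floor,
        focal_depth_um=unloaded.focal_depth_um,
    )
    return E, stress


def _layer_acquisition_index(spec: PhantomSpec, params: ProcessingParams) -> int:
    """Acquisition focused closest to the middle of the layer band."""
    if not spec.focal_depths_um:
        return 0
    target = spec.sample_thickness_um + params.band_gap_um + 0.5 * params.band_width_um
    depths = np.asarray(spec.focal_depths_um, dtype=float)
    return int(np.argmin(np.abs(depths - target)))


def reconstruct_stack(
    spec: PhantomSpec,
    pairs,
    params: ProcessingParams = ProcessingParams(),
    weight_fwhm_um: float | None = None,
):
    """Reconstruct every focal acquisition and fuse modulus and structure.

    Returns ``(modulus: ModulusVolume, stress, fused_structural)`` where the
    fused structural volume is linear-scale intensity for segmentation.
    """
    if weight_fwhm_um is None:
        weight_fwhm_um = spec.envelope_fwhm_um
    k_layer = _layer_acquisition_index(spec, params)
    strain_layer = strain_from_pair(*pairs[k_layer], params)
    stress = stress_from_strain(
        strain_layer, pairs[k_layer][0].intensity(), spec.layer_calibration, params
    )

    volumes, valids, intensities = [], [], []
    for unloaded, loaded in pairs:
        E, _ = elastogram_pair(unloaded, loaded, spec.layer_calibration, params, stress=stress)
        volumes.append(E.E_kpa)
        valids.append(E.valid)
        intensities.append(0.5 * (unloaded.intensity() + loaded.intensity()))
    geometry = pairs[0][0].geometry

    if len(pairs) == 1 or not spec.focal_depths_um:
        fused_E = np.where(valids[0], volumes[0], np.nan)
        fused_valid = valids[0]
        fused_struct = intensities[0]
    else:
        depths = list(spec.focal_depths_um)
        order = np.argsort(depths)
        stack_E = FocalStack(
            volumes=[volumes[i] for i in order],
            focal_depths_um=[depths[i] for i in order],
            voxel_pitch_z_um=geometry.voxel_pitch_um[2],
            valid=[valids[i] for i in order],
        )
        fused = fuse(stack_E, weight_fwhm_um=weight_fwhm_um)
        fused_E, fused_valid = fused.data, fused.valid
        stack_I = FocalStack(
            volumes=[intensities[i] for i in order],
            focal_depths_um=[depths[i] for i in order],
            voxel_pitch_z_um=geometry.voxel_pitch_um[2],
        )
        fused_struct = fuse(stack_I, weight_fwhm_um=weight_fwhm_um).data
        fused_struct = np.nan_to_num(fused_struct)

    modulus = ModulusVolume(
        E_kpa=fused_E,
        valid=fused_valid & np.isfinite(fused_E),
        resolution_fwhm_um=(
            float(np.hypot(geometry.ocm_resolution_fwhm_um[0], params.smoothing_fwhm_lateral_um)),
            float(np.hypot(geometry.ocm_resolution_fwhm_um[1], params.smoothing_fwhm_lateral_um)),
            float(np.hypot(geometry.ocm_resolution_fwhm_um[2], params.window_fwhm_axial_um)),
        ),
        geometry=geometry,
        provenance={"n_acquisitions": len(pairs)},
    )
    return modulus, stress, fused_struct


def segment_and_measure(
    modulus: ModulusVolume,
    structural: np.ndarray,
    seg: SegmentationParams = SegmentationParams(),
    spheroid_id: int = 0,
):
    """Segment the spheroid from structure and measure regional moduli."""
    pitch = modulus.geometry.voxel_pitch_um
    sig = [
        f / (2.0 * np.sqrt(2.0 * np.log(2.0))) / p
        for f, p in zip(seg.presmooth_fwhm_um, pitch)
    ]
    smooth = ndimage.gaussian_filter(np.asarray(structural, float), sigma=sig, mode="nearest")
    mask = segment_spheroid(smooth, threshold=seg.threshold)
    labels = split_core_periphery(
        mask,
        core_fraction=seg.core_fraction,
        kernel_size=seg.kernel_size,
        coverage=seg.coverage,
    )
    stats = region_stats(modulus, labels, half_planes=seg.half_planes, spheroid_id=spheroid_id)
    return labels, stats


def run_pipeline(cfg: dict, out_dir, seed: int | None = None) -> dict:
    """Execute the full pipeline from a config mapping; returns the manifest.

    Writes every intermediate artifact (acquisition, stress, modulus,
    labels, stats) plus a manifest and a log under ``out_dir``. The same
    config and seed reproduce every payload bit-for-bit.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    seed = int(cfg.get("seed", 0)) if seed is None else int(seed)
    chash = msio.config_hash({**cfg, "seed": seed})
    manifest = {"seed": seed, "config_hash": chash, "outputs": {}, "stages": []}
    stamp = {"seed": seed, "config_hash": chash}

    def _stage(name):
        logger.info("stage %s", name)
        manifest["stages"].append(name)

    try:
        _stage("simulate")
        spec = spec_from_config(cfg, seed=seed)
        truth, pairs = simulate(spec)
        acq_path = out / "acquisition.h5"
        msio.write_acquisition(acq_path, pairs, truth=truth, attrs=stamp)
        manifest["outputs"]["acquisition"] = acq_path.name

        _stage("elastogram")
        params = processing_from_config(cfg)
        modulus, stress, fused_struct = reconstruct_stack(
            spec, pairs, params, weight_fwhm_um=cfg.get("fusion", {}).get("weight_fwhm_um")
        )
        msio.write_volume(out / "modulus.h5", modulus.E_kpa, meta={**stamp, "units": "kPa"}, valid=modulus.valid)
        msio.write_volume(out / "structural.h5", fused_struct, meta={**stamp, "units": "linear intensity"})
        msio.write_volume(
            out / "stress.h5",
            stress.sigma_kpa[..., None],
            meta={**stamp, "units": "kPa", "kind": "interface stress map"},
        )
        manifest["outputs"]["modulus"] = "modulus.h5"
        manifest["outputs"]["structural"] = "structural.h5"
        manifest["outputs"]["stress"] = "stress.h5"

        if spec.inclusions:
            _stage("segment")
            seg_cfg = cfg.get("segmentation", {})
            seg = SegmentationParams(**{k: tuple(v) if k == "presmooth_fwhm_um" else v for k, v in seg_cfg.items()})
            labels, stats = segment_and_measure(modulus, fused_struct, seg)
            msio.write_volume(out / "labels.tif", labels.label.astype(np.uint8), meta=stamp)
            stats.to_csv(out / "region_stats.csv", index=False)
            manifest["outputs"]["labels"] = "labels.tif"
            manifest["outputs"]["region_stats"] = "region_stats.csv"

            _stage("stats")
            report = {
                "regions": stats.to_dict(orient="records"),
                **stamp,
            }
            (out / "report.json").write_text(json.dumps(report, indent=2))
            manifest["outputs"]["report"] = "report.json"
        else:
            _stage("stats")
            vals = modulus.E_kpa[modulus.valid]
            report = {
                "median_modulus_kpa": float(np.median(vals)),
                "n_valid_voxels": int(vals.size),
                **stamp,
            }
            (out / "report.json").write_text(json.dumps(report, indent=2))
            manifest["outputs"]["report"] = "report.json"
    except Exception as exc:
        stage = manifest["stages"][-1] if manifest["stages"] else "setup"
        logger.exception("pipeline aborted in stage %s", stage)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()

    manifest["completed"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
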