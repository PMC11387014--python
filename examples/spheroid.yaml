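# Spheroid phantom with dynamic focusing: simulate -> reconstruct -> fuse ->
# segment -> regional statistics. Same conditions as the README example.
seed: 5
phantom:
  grid_shape: [48, 48, 128]
  voxel_pitch_um: [2.0, 2.0, 2.0]
  sample_thickness_um: 180.0
  layer_thickness_um: 1000.0
  layer_modulus_kpa: 20.0
  background_modulus_kpa: 7.0
  bulk_displacement_um: 0.5
  speckle_mean_intensity: 100.0
  noise_floor: 1.0            # 20 dB SNR in the gel
  inclusions:
    - center_um: [48.0, 48.0, 90.0]
      radius_um: 40.0
      core_modulus_kpa: 10.0
      periphery_modulus_kpa: 24.0
      core_fraction: 0.5
  # focal planes every 10 um across the spheroid, plus one in the layer band
  focal_depths_um: [55.0, 65.0, 75.0, 85.0, 95.0, 105.0, 115.0, 125.0, 190.0]
processing:
  unwrap_axial: true           # 0.5 um actuation exceeds the |dphi| < pi regime
  interface_depth_um: 180.0    # designed sample thickness
segmentation:
  kernel_size: 12              # 24 x 24 um^2 edge-smoothing kernel at 2 um pitch
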