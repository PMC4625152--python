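# Demo pipeline configuration: a nanoparticle-labelled mouse phantom imaged
# through a pitch-8 crossed mesh at 2x magnification.
# Run:  sfhi pipeline --config examples/demo.yaml --out-dir scratch/demo
image_shape: [256, 256]
grid:
  pitch_px: 8
  duty: 0.05
  open_transmission: 0.95
  wire_transmission: 0.05
  orientation_deg: 0
geometry:
  source_detector_m: 1.6
  sample_position_m: 0.8
acquisition:
  fluence: 10000
  seed: 7
  noise: true
phantom:
  scatter_coupling: 0.05   # px^2 per (ug/cm^3)
  edge_sigma_px: 3.0       # soften tissue boundaries below the carrier band
  regions:
    - {name: body,    center: [128, 128], axes: [110, 85], optical_depth: 0.4, gold_ugcm3: 2.0}
    - {name: liver,   center: [100, 100], axes: [28, 38],  optical_depth: 0.2, gold_ugcm3: 8.0}
    - {name: tumor_1, center: [170, 160], axes: [14, 14],  optical_depth: 0.05, gold_ugcm3: 26.0}
    - {name: tumor_2, center: [90, 175],  axes: [12, 12],  optical_depth: 0.05, gold_ugcm3: 18.0}
rois:
  - {name: tumor_1, type: ellipse, center: [170, 160], axes: [8, 8], role: target}
  - {name: tumor_2, type: ellipse, center: [90, 175], axes: [7, 7], role: target}
  - {name: background, type: ellipse, center: [150, 70], axes: [12, 12], role: control}
overlay:
  colormap: magma
  alpha: 0.5
  threshold: 0.05
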