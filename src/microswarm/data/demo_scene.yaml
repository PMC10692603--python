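# Small demonstration scene: three-species community in a 500x400 um
# region with a potassium point source on the top-edge midline.
seed: 42
scene:
  field_width: 500.0
  field_height: 400.0
  pixel_size: 1.3
  frame_interval: 0.0735
  n_frames: 40
  source_position: [250.0, 0.0]
  noise_sd: 10.0
segmentation:
  threshold: 110
grid:
  cell_side: 170.0
microenvironments:
  - name: proximal_to_kcl
    cells: [A1, A2, A3]
    frames: [1, 40]
    species: zoospore
  - name: distant_from_kcl
    cells: [C1, C2, C3]
    frames: [1, 40]
    species: zoospore
comparisons:
  - a: proximal_to_kcl
    b: distant_from_kcl
    metric: mean_speed_ums
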