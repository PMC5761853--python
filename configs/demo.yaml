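# Demonstration run: simulate three hexagonal brush-border fields and
# analyze them end to end.  `mvlattice full --config configs/demo.yaml
# --out run_demo --seed 7` reproduces the README example.
seed: 7
out_dir: run_demo
format: tiff
simulate:
  n_images: 3
  field_nm: [2500.0, 2500.0]
  pixel_size_nm: 7.0
  lattice:
    lattice_class: hexagonal
    a: 169.0
    jitter_nm: 5.0
    vacancy: 0.13
  shape:
    kind: spherical_cap
    R_mv: 50.0
    h_mv: 100.0
  tip:
    R_tip: 30.0
  artifacts:
    row_offset_sd_nm: 1.0
    pixel_noise_sd_nm: 1.0
    scar_count: 1
preprocess: {}
detect: {}
lattice: {}
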