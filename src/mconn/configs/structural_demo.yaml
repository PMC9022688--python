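# Structural branch demo: two-bundle DWI phantom (straight + quarter arc),
# tensor fit, probabilistic tracking, endpoint connectome, graph metrics.
seed: 7
structural:
  phantom:
    grid_shape: [24, 24, 12]
    noise_sigma: 0.0
    bundles:
      - geometry: straight
        start: [3.0, 6.0, 5.5]
        end: [20.0, 6.0, 5.5]
        radius: 1.8
      - geometry: arc
        start: [4.0, 12.0, 5.5]
        end: [14.0, 22.0, 5.5]
        radius: 1.8
  tracking:
    n_samples_per_seed: 3
    dispersion_kappa: 150
    fa_stop: 0.15
    step_size: 0.5
  metrics:
    density: 0.5
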