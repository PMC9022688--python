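# Functional branch demo: 4-cluster phantom cohort, group ICA, RSN
# clustering, edge-wise group comparison, and a seed-based z map.
seed: 7
functional:
  phantom:
    grid_shape: [20, 20, 12]
    n_clusters: 4
    comps_per_cluster: 3
    w: 0.6
    anticorr: -0.5
    noise_sigma: 0.2
    n_noise_components: 2
    n_timepoints: 300
  hypo:
    cluster: 1
    w: 0.3
  n_per_group: 6
  ica:
    n_components: 12
  cluster_k: 4
  compare:
    alpha: 0.05
    test: t
  seedmap:
    component: 0
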