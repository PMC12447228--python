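# Full pipeline on a synthetic factorial experiment (24 rows).
seed: 1
input:
  mode: synthetic-experiment
  n_missing: 4
output_dir: multistress_run
glm:
  alpha: 0.05
  prune: true
sem:
  prune: true           # indicator loading screen (< 0.5 removed)
  loading_cutoff: 0.5
  bootstrap:
    n_boot: 1000        # raise to 10000 for publication-grade intervals
    ci_levels: [0.05, 0.95]
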