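# Online replication template: 92 observers, 167 pairs per task,
# response cue 100 ms after stimulus offset, high- vs low-level task.
template: exp2
n_boot: 1000
bin_width: 0.2
population:
  sigma_s: [3.5, 0.7]
  criterion: [0.0, 0.5]
  sigma_c: [0.5, 0.15]
  alpha: [0.2, 0.1]
  interval_bias: [0.0, 0.1]
# make the low-level task noisier at the confidence stage
condition_effects:
  low:
    delta_sigma_c: 0.3
mcmc:
  n_samples: 12000
  n_chains: 3
  burn_in: 1000
  thin: 3
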