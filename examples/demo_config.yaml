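# Small demonstration pipeline run: 4 events, noise-free, no LFP stage.
out_dir: demo_output
master_seed: 7
cohort:
  n_type1: 1
  n_type2: 1
  n_type3a: 1
  n_type3b: 1
  n_other: 0
  noise_sd: 0.0
  bleach_rate: 0.0
lfp:
  enabled: true
  n_biphasic: 1
  n_triphasic: 1
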