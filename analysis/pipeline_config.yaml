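# Bundled fixture configuration: one fully simulated cohort driven end to
# end through every stage. Thresholds are the published analysis defaults
# and are therefore not repeated here.
seed: 42
outdir: results/pipeline_report
simulation:
  seed: 42
  n_genes: 1200
  n_peaks: 600
  n_confident_peaks: 100
  n_noise_peaks: 100
  n_decoy_motifs: 10
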