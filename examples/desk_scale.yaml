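# Desk-scale override of the full-scale defaults (180-s stimulus, K=400):
# a complete pipeline run in minutes on one core.
#
#   strflearn run-all --config examples/desk_scale.yaml --outdir run/
total_duration_s: 60.0
K: 100
objectives:
  - [sustained, 125.0]
  - [sustained, 10.0]
  - [sparse, 0.0]
modes: [response]
max_iter: 30
seed: 0
n_clusters: 12
outdir: strflearn_run
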