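# Example end-to-end pipeline configuration:
#   dalearn run --config examples/run.yaml
# Small sizes so the full chain (simulate -> fit-behavior -> preprocess ->
# fit-encoding -> correlate) finishes in a few minutes on one CPU.
out_dir: runs/demo
seed: 4
n_mice: 2
n_sessions: 3
trials_per_session: 60
chains: 1
warmup: 100
draws: 100
n_basis: 4
contrast_metric: diff-of-norms
region: DMS
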