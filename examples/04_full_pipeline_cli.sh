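#!/usr/bin/env bash
# The same chain as a shell workflow: write a config, simulate a cohort to
# disk, then run every stage end to end.  Outputs land in ./scratch_demo.
set -euo pipefail

mkdir -p scratch_demo
cat > scratch_demo/config.yaml <<'YAML'
simulate:
  seed: 3
  groups:
    - label: HC
      n_subjects: 4
      subject: {n_channels: 8, fs: 250.0, duration: 8.0}
    - label: SCZ
      n_subjects: 4
      subject: {n_channels: 8, fs: 250.0, duration: 8.0}
      dose_mean: 800.0
      dose_sd: 300.0
trim: 0
orthogonalize: true
fdr_family: per-contrast
YAML

eegdfc simulate --config scratch_demo/config.yaml --out scratch_demo/cohort
eegdfc preprocess --in scratch_demo/cohort/HC01.csv --out scratch_demo/HC01_bands.h5
eegdfc connect --in scratch_demo/HC01_bands.h5 --out scratch_demo/iac
eegdfc cumulants --in scratch_demo/iac/iac_HC01_alpha.h5 --out scratch_demo/HC01_alpha.csv
eegdfc run-all --config scratch_demo/config.yaml --out scratch_demo/results
echo "results:" && ls scratch_demo/results
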