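#!/bin/sh
# Shell workflow: phantom -> encoded series -> spectrum image -> ROI CSV.
# Writes everything under ./velspec_out using the default configuration
# (multitube phantom, 30-encode asymmetric ladder, clean data).
set -e

cat > /tmp/velspec_demo.yaml <<'YAML'
phantom:
  kind: multitube
  shape: [24, 48, 48]
  bath: full          # thin slab: skip the spherical chamber
  model: uniform_area
encoding:
  n_encodes: 30
  scheme: asymmetric
  delta_v_cm_s: 0.576
corruption:
  noise_sd: 0.01
recon:
  detrend_order: null
  window: hanning
io:
  out_dir: velspec_out
  stem: demo
seed: 1
YAML

velspec make-phantom --config /tmp/velspec_demo.yaml
velspec encode --config /tmp/velspec_demo.yaml
velspec recon --config /tmp/velspec_demo.yaml
velspec roi --config /tmp/velspec_demo.yaml --label 9 --out velspec_out/demo_tube8.csv
velspec bloch --m1 2e-6 --out velspec_out/demo_response.csv
head -4 velspec_out/demo_tube8.csv
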