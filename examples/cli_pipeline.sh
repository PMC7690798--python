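#!/usr/bin/env bash
# Full shell pipeline: simulate DepMap-dialect inputs, scan them, then run
# the survival variant on the simulated patient cohort.
set -euo pipefail

out=${1:-/tmp/crossdep-demo}

crossdep simulate --n-genes 1000 --n-samples 40 --n-pos 15 --n-neg 15 \
    --seed 7 --cohort --n-patients 200 --cohort-genes 200 --out-dir "$out/sim"

crossdep scan --expression "$out/sim/expression.csv" \
    --efficacy "$out/sim/efficacy.csv" --assay shRNA --out-dir "$out/scan"

crossdep survival --expression "$out/sim/expression_cohort.tsv" \
    --clinical "$out/sim/clinical.tsv" --out-dir "$out/surv"

crossdep report --scan "$out/scan/scan.tsv"
echo "tables written under $out"
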