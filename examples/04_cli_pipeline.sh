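#!/usr/bin/env bash
# End-to-end pipeline through the command-line interface.
set -euo pipefail

out=$(mktemp -d)

vigncorr simulate --seed 7 --size 256 --n-slices 2 \
    --neurons-per-slice 80 --out-dir "$out/sim"
vigncorr estimate "$out/sim/stack_day0.tif" "$out/fields0.json"
vigncorr correct "$out/sim/stack_day0.tif" "$out/fields0.json" \
    "$out/corrected0.tif"
vigncorr evaluate "$out/sim/stack_day0.tif" "$out/sim/stack_day1.tif" \
    "$out/sim/neurons.csv" "$out/report"

echo "outputs in $out"
ls -R "$out"
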