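#!/bin/sh
# End-to-end shell pipeline on a simulated fixture.
# Stages: simulate -> filter -> sif -> forest -> weights -> stats -> footprint.
set -e

DIR=$(mktemp -d)
ocean simulate --topology chain --n-species 8 --seed 42 --effect-size 3.0 --out "$DIR/fix"
ocean filter   --network "$DIR/fix" --out "$DIR/filtered"
ocean sif      --network "$DIR/filtered" --out "$DIR/network.sif"
ocean forest   --sif "$DIR/network.sif" --out "$DIR/forest.json"
ocean weights  --forest "$DIR/forest.json" --penalty 0.8 --out "$DIR/weights.csv"
ocean stats    --abundance "$DIR/fix/areas.csv" --design "$DIR/fix/design.csv" \
               --contrast CASE-CTRL --out "$DIR/stats.csv"
ENZYME=$(python -c "import json;print(json.load(open('$DIR/fix/ground_truth.json'))['planted_root'])")
ocean footprint --weights "$DIR/weights.csv" --stats "$DIR/stats.csv" \
                --mapping "$DIR/fix/mapping.csv" --enzyme "$ENZYME" \
                --out "$DIR/scatter.csv"
echo "--- scatter table for $ENZYME ---"
cat "$DIR/scatter.csv"
rm -rf "$DIR"
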