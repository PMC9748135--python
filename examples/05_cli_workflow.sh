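#!/usr/bin/env bash
# The same pipeline as examples 01 and 04, driven from the shell.
# Every step writes a manifest.json (config + input hashes) for reproducibility.
set -euo pipefail

WORK=$(mktemp -d)
echo "working in $WORK"

# 1. simulate a small paired dataset (CSV count matrices + truth labels)
multidec simulate --outdir "$WORK/sim" --cells 400 --groups 4 \
    --genes 300 --second-features 20 --seed 7

# 2. preprocess, train, cluster; writes labels.tsv, embedding.tsv,
#    loss_log.tsv and model.pkl
multidec fit \
    --rna "$WORK/sim/rna_counts.csv" \
    --second "$WORK/sim/second_counts.csv" \
    --k 4 --hvg 0 \
    --pretrain-epochs 50 --recon-only-epochs 25 --max-cluster-epochs 20 \
    --seed 7 --outdir "$WORK/fit"

# 3. score against the planted labels
multidec evaluate \
    --labels "$WORK/fit/labels.tsv" \
    --truth "$WORK/sim/truth_labels.csv"

# 4. rank cluster markers; writes one .rnk file per cluster
multidec markers \
    --model "$WORK/fit/model.pkl" \
    --rna "$WORK/sim/rna_counts.csv" \
    --second "$WORK/sim/second_counts.csv" \
    --outdir "$WORK/markers"

ls "$WORK/markers"
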