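#!/usr/bin/env bash
# End-to-end shell workflow: simulate an experiment, run the partition
# pipeline, and rebuild the aggregates from the written files.
set -euo pipefail

out=xscar_cli_demo

# simulate (explicit seed required) and analyze in one command
xscar all --seed 7 --p-lead 0.8 -o "$out"

ls "$out"                         # bedGraphs, TSVs, run_summary.txt, sim/
head -3 "$out"/parental_partition.bedgraph
head -5 "$out"/parental_metaprofile.tsv

# stages can be re-run from the files a previous stage wrote
xscar aggregate -o "$out" \
    --genome "$out"/sim/genome.tsv --origins "$out"/sim/origins.bedgraph \
    --parental "$out"/sim/parental.bed --new "$out"/sim/new.bed \
    --input "$out"/sim/input.bed --flank 2500
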