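#!/usr/bin/env bash
# Optional end-to-end smoke test against the real external stack.
#
# NOT part of the test suite: it needs minimap2, ngmlr, sniffles and
# (optionally) truvari on PATH, plus a reference genome, and its outcome is
# stochastic and version-sensitive.  It reproduces the qualitative shape of
# the SV-calling experiment at desk scale: simulate an SV-bearing haplotype
# and error-bearing long reads, run the dual-mode pipeline, call SVs from
# the merged BAM, and compare against the implanted truth set.
#
# Usage: scripts/external_stack_smoke.sh <outdir>
set -euo pipefail

OUT=${1:-external_smoke}
mkdir -p "$OUT"

for tool in minimap2 ngmlr sniffles dualmap; do
    command -v "$tool" >/dev/null || { echo "missing: $tool" >&2; exit 1; }
done

# 1. synthetic reference + SV haplotype + ONT-like reads (~200 kb, 20x)
dualmap fixtures --outdir "$OUT/fixtures" \
    --length 200000 --n-reads 800 --read-len 5000 \
    --sub-rate 0.05 --indel-rate 0.04 --n-svs 20 --seed 1

# 2. dual-mode mapping at the default 90th-percentile cut-off
dualmap run \
    -i "$OUT/fixtures/reads.fastq" \
    -r "$OUT/fixtures/reference.fasta" \
    -o "$OUT/final.bam" -p 90 --preset ont \
    --workdir "$OUT/work" --keep-intermediates

# 3. SV calling from the merged BAM
sniffles --input "$OUT/final.bam" --vcf "$OUT/calls.vcf" --minsupport 2

# 4. compare with the implanted truth
echo "truth SVs:   $OUT/fixtures/sv_truth.vcf"
echo "called SVs:  $OUT/calls.vcf"
if command -v truvari >/dev/null; then
    truvari bench -b "$OUT/fixtures/sv_truth.vcf" -c "$OUT/calls.vcf" \
        -o "$OUT/truvari" || true
else
    echo "truvari not found; inspect the two VCFs manually"
fi
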