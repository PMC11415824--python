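# mehunter

Detection and genotyping of mobile-element variants (MEVs) — Alu, L1, and SVA
insertions (MEIs) and deletions (MEDs) — from long-read alignments, together
with a diploid read simulator and a benchmarking harness so that the whole
pipeline is testable end to end without any external data.

## Pipeline

1. **Signature extraction** (`mehunter.signatures`) — scans coordinate-sorted
   SAM/BAM and harvests INS/DEL signatures from CIGAR operations and from
   split-read (`SA` tag) segment gaps; builds a spanning-read index for
   genotyping.
2. **Clustering & consensus** (`mehunter.clustering`) — single-linkage
   chaining of signatures per locus with a size-ratio gate, then one
   consensus sequence per cluster (star alignment + column majority; an
   abPOA backend is used automatically when `pyabpoa` is installed).
   Deletion clusters take the reference sequence of the deleted interval.
3. **Two-round classification** (`mehunter.classify`) — round one: banded
   affine-gap Smith-Waterman (anchored on the best shared k-mer diagonal)
   against every library template on both strands, assigning a class when
   identity and template coverage clear their thresholds. Sequences left
   unclassified pass a k-mer prescreen and go to a pluggable second-round
   classifier; the bundled baseline is a per-class 6-mer-profile model, and
   a transformer-based classifier can be dropped in behind the same plugin
   contract. `--no-second-round` disables round two (ablation mode).
4. **Genotyping & output** (`mehunter.genotype`) — allele-frequency-band
   genotypes (0/1, 1/1) from supporting (DV) vs reference-spanning (DR)
   reads, written as deterministic single-sample VCF 4.2 with
   `SVTYPE/SVLEN/END/MECLASS/CROUND` and `GT:DR:DV`.

Supporting modules: `mehunter.melib` (template library; a built-in toy
library with one synthetic template per class means no repeat database is
required), `mehunter.simulate` (diploid genome + read simulator that emits
analytically projected alignments, truth VCF, FASTA, FASTQ — including a
trio mode), `mehunter.evaluate` (presence/genotype F1, FDR, trio Mendelian
discordance), `mehunter.bench` (simulate-call-evaluate harness).

## CLI

```bash
# simulate a 1 Mb diploid genome with implanted MEVs and ordinary SVs
mehunter simulate --out-dir sim --genome-length 1000000 \
    --mei 30 --med 30 --sv 60 --depth 30 --error-model hifi_like --seed 42

# call MEVs (-s = minimum supporting reads)
mehunter call --bam sim/reads.sam --ref sim/ref.fa --me-lib builtin \
    -s 3 -o calls.vcf

# score against the simulator's truth
mehunter evaluate --calls calls.vcf --truth sim/truth.vcf \
    --class-strict --report report.json

# trio Mendelian discordance
mehunter mdr --child c.vcf --father f.vcf --mother m.vcf
```

`--me-lib` accepts any FASTA of templates whose headers start with
`Alu`/`L1`/`LINE1`/`SVA` (case-insensitive), or `builtin`.

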