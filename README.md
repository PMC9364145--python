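# regscreen

Integrative ATAC-seq + RNA-seq screen for transcription factors that regulate
a target gene. The pipeline:

1. **Consensus open chromatin** — per-base, distinct-sample-supported
   consensus regions from per-sample peak calls (BED3/BED6/narrowPeak), with
   optional fixed-width standardization (default 500 bp).
2. **Promoter assignment** — strand-aware TSS windows (default −2000/+500)
   map consensus regions to genes; feature classes
   (promoter > exon > intron > intergenic) are reported.
3. **Accessibility quantification** — overlap-weighted signal sums per
   (region, sample), CPM + log2 normalized.
4. **TF screen** — correlate each panel TF's expression with the target
   promoter's per-region accessibility (Pearson or Spearman, two-sided
   t-transform p, BH FDR), rank with a deterministic total order. The built-in
   inflammatory panel is the 21-member union of the NF-κB, IRF and STAT
   families; arbitrary panels are accepted as plain symbol lists.
5. **Validation** — PWM motif scanning (JASPAR PFM input, log2-odds, both
   strands) of candidate regions and a width-preserving permutation test of
   ChIP-peak overlap.
6. **Gene-set association** — single-sample rank-based enrichment scores
   (ssGSEA-style, τ default 0.25) and the dual filter: sets correlating with
   BOTH the candidate TF and the target (r > 0.4, p < 0.05).

A first-class `synthetic` module generates paired cohorts in which a latent
activity drives regulator expression, target-promoter accessibility and
target expression — with decoy TFs, shared background open regions, depth
factors, boundary jitter and peak dropout — so the whole pipeline is
testable offline against known ground truth.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle
equivalence, statistical calibration, planted-regulator recovery,
end-to-end determinism).

## CLI

```sh
# full pipeline on a simulated cohort (writes manifest, report, all tables)
regscreen run --outdir out --seed 7

# or stage by stage
regscreen simulate --outdir out --seed 7
regscreen consensus out/cohort/peaks/*.narrowPeak \
    --min-support 0.9 --fixed-width 500 \
    --chrom-sizes out/cohort/chrom.sizes --out out/consensus.bed
regscreen quantify out/cohort/peaks/*.narrowPeak \
    --regions out/consensus.bed --out out/accessibility.tsv
regscreen screen --expression out/cohort/expression.tsv \
    --accessibility out/accessibility.tsv --target-gene CD274 \
    --out out/candidates.tsv
regscreen motif --fasta out/cohort/genome.fa --pfm out/cohort/motif.pfm \
    --regions out/consensus.bed --out out/motif_hits.bed
regscreen chip --chip-peaks out/cohort/chip.narrowPeak \
    --regions out/consensus.bed --chrom-sizes out/cohort/chrom.sizes
regscreen enrich --expression out/cohort/expression.tsv \
    --gmt out/cohort/gene_sets.gmt --tf-gene STAT2 --target-gene CD274 \
    --out out/associations.tsv
```

All commands accept a YAML config (`--config`) mirroring `PipelineConfig`;
`run` writes a `manifest.json` with parameters and input checksums, and
reruns with identical config are byte-identical.

## Coordinates

Intervals are 0-based half-open internally (BED convention); every
user-facing string is 1-based inclusive, e.g. `chr9:5449463-5449962`.
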