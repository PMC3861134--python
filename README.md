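# recland

Fine-scale recombination-landscape analysis for a genome whose hotspots are
not positioned by PRDM9-style motif binding. The package takes a genetic
map (cM/Mb rate track), a genome sequence, interval annotations and
outgroup-polarizable SNPs, and provides:

- **`recland.genetic_map`** — map I/O, hotspot calling against a local
  median background, strength classification, Lorenz/Gini concentration
  summaries, width-preserving interval randomization tests, and peak-set
  sharing/confirmation accounting.
- **`recland.matching`** — matched hotspot/coldspot pairs: same-width
  control windows on the same chromosome with GC content within 0.5
  percentage points, CpG content within 0.1 pp, no local rate elevation,
  tie-broken by SNP density.
- **`recland.motifs`** — exhaustive k-mer (k = 6..9) presence/absence
  enrichment between the matched sets, two-sided Fisher exact tests with
  Bonferroni correction, optional repeat/non-repeat masking.
- **`recland.bgc`** — outgroup parsimony polarization, W→S / S→W
  classification, CpG-creating-site flags, and the distance-binned
  AT→GC : GC→AT skew ratio around hotspot centers with hotspot-level
  bootstrap confidence bands (plus strength-stratified profiles).
- **`recland.features`** — feature-centered rate profiles (TSS, islands,
  peaks, repeats), nearest-feature distance partitions, windowed rate vs
  GC/CpG correlations, a GC+CpG multiple-regression sign check, and
  flanking-composition comparisons.
- **`recland.synthetic_data`** — a seeded, coalescent-free simulator for
  genomes with CpG-island-dense promoters, recombination maps whose
  hotspots colocate with islands, two-lineage polymorphisms with a
  configurable weak→strong transmission bias around hotspots, and
  two-stage peak sets — so every pipeline stage can be exercised against
  known ground truth.

All intervals are 0-based half-open (BED); map and SNP TSVs are 1-based on
disk with conversions confined to `recland.io`.

## Command line

```bash
recland simulate --out simdir --seed 3 --chrom-length 2000000 \
    --n-hotspots 20 --bias-b 0.7
recland callhotspots --map simdir/map.tsv --out hotspots.bed --fold 5 --flank-kb 100
recland lorenz --map simdir/map.tsv
recland overlap-test --a hotspots.bed --b simdir/islands.bed \
    --chrom-lengths simdir/chrom_lengths.tsv --n-rand 10000 --seed 1
recland compare-peaks --p simdir/peaks_stage1.bed --q simdir/peaks_stage2.bed
recland skew --snps simdir/snps_ingroup.tsv --hotspots simdir/true_hotspots.bed \
    --out skew.tsv --n-boot 200 --seed 1
recland motif-scan --hot hot.fa --cold cold.fa --out motifs.tsv
```

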