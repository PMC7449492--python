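# niptcnv

Detection of chromosomal microdeletions/microduplications from
low-coverage cell-free DNA whole-genome sequencing bin counts, together
with the evaluation machinery needed to measure its detection limits:

- **Genome binning & I/O** (`niptcnv.core`, `niptcnv.io`) — 20 kb bin
  grids, per-bin GC/mappability tracks, raw read-start binning, TSV/BED
  readers and writers, optional BAM binning via pysam.
- **Normalization** (`niptcnv.normalization`) — four steps trained on a
  euploid cohort: per-sample LOESS GC correction, removal of the first 15
  principal components on autosomes, masking of bins with low mean (< 3.0)
  or high cross-cohort variance (> 1.5) at the canonical 1M-read scale,
  and per-bin mean subtraction to center healthy profiles around zero.
- **Segmentation & calling** (`niptcnv.calling`) — circular binary
  segmentation (permutation-tested recursive max-t splits, numba kernels)
  and fetal-fraction-aware classification: a segment is called when its
  mean oversteps 75% of the theoretical level (`mb·ff/2` fetal,
  `mb·(1−ff)/2` maternal) and passes the 600 kb / 200 kb length gates.
- **Critical regions** (`niptcnv.critical_regions`) — derivation of
  syndrome critical regions from labelled deletion records by pathogenic
  per-base coverage profiling, starting at coverage cutoff 45 and lowering
  it until no pathogenic record falls entirely outside the region.
- **In-silico study engine** (`niptcnv.study`) — spike-in of artificial
  CNVs (bins multiplied by `1±ff/2` after normalization), binomial read
  downsampling, and sensitivity/specificity grids over fetal-fraction and
  read-count axes by deletion-size class.
- **Synthetic data** (`niptcnv.synth`) — seeded generators for a
  desk-scale mini-genome (~310 Mb, 3 autosomes + X/Y), euploid cohorts
  with Poisson counts, smooth GC bias and shared low-rank noise,
  aberrated case samples, and ISCA-like labelled deletion-record sets.
  Read depths are specified as full-genome equivalents so per-bin depth
  (and hence all thresholds) matches production scale.

## CLI

```sh
# generate a synthetic cohort and a case sample
niptcnv synth cohort --seed 7 --out work/cohort --n-samples 100
niptcnv synth case   --seed 7 --out work/case

# train the normalization model
niptcnv train --cohort work/cohort --genome work/cohort/genome.tsv \
              --out work/model.npz

# call CNVs on a sample (bin-count TSV), fetal fraction 12.6%
niptcnv call --sample work/case/case.tsv --model work/model.npz \
             --ff 0.126 --out-prefix work/calls

# derive a critical region from labelled deletion records
niptcnv derive-regions --records records.tsv --cutoff 45 --out region.tsv

# run a spike-in sensitivity study
niptcnv study --mode ff --model work/model.npz --regions regions.bed \
              --cohort work/cohort --out work/study --seed 1
```

Thresholds (`tau`, component count, filter cutoffs, CBS permutations,
minimum lengths) are configurable via a YAML file passed with `--config`;
defaults reproduce the published parameters.

## Conventions

Coordinates are 0-based half-open internally (BED-compatible); report
output is rendered 1-based inclusive. Raw bin profiles are integer read
counts; profile state advances strictly through
raw → gc_corrected → pca_normalized → centered.
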