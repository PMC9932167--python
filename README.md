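# th17pipe

Downstream analysis toolkit for multi-omics studies of Th17 cells: chromatin
accessibility (ATAC-seq), RNA-protein binding (RIP-seq), RNA 5-methylcytosine
(m⁵C) methylation (MeRIP-seq), transcription-factor occupancy (ChIP-seq),
mRNA decay assays, and single-cell colon composition profiling. It implements
the bespoke computations that sit *after* alignment and peak calling — the
steps a study would otherwise script by hand — as a tested, seedable package:

* **Null-peak depth normalization** (`th17pipe.atacnorm`). ATAC libraries are
  rescaled by "null" peaks: peaks overlapping the TSS (±500 bp) of genes that
  are highly expressed (mean RPKM > 5 in every condition) and near-constant
  across replicates (RPKM variance < 0.05). The per-sample sums of reads in
  these peaks, divided by their geometric mean, give scale factors
  `f_s = Σ_p c_{ps} / (∏_t Σ_p c_{pt})^{1/n}`; replicate agreement is then
  Pearson correlation of factor-weighted peak RPKM.
* **Reliable-gene (L1) filtering and target integration**
  (`th17pipe.integration`). The L1 universe keeps genes with mean mRNA
  RPKM > 1 in wild-type replicates and RPKM > 1 in every IP-input library;
  only IP/methylation peaks inside L1 genes count as targets. The module
  reports target-set overlap fractions and Venn counts, per-peak GC content
  against a length-preserving shuffled genomic background (two-sided
  rank-sum test), tertile grouping by promoter ChIP signal (TSS ±3 kb) with
  boxplot statistics and Mann–Whitney U comparisons, strand-oriented
  TSS→TTS metagene profiles (±3 kb flanks, scaled gene body), and
  accessibility–expression strata over the most expressed genes.
* **mRNA half-life estimation** (`th17pipe.decay`). Abundance after
  transcription shutoff is modelled as `N(t) = N₀·e^(−kt)`; after
  normalizing to t = 0, `ln N` is fitted by OLS on time and
  `t½ = ln 2 / k`. Condition arms are compared per timepoint (two-sided
  t-test) and by half-life ratio with a delta-method CI.
* **Rescue cell-type classification** (`th17pipe.composition`). Over a
  reference / disease / treated three-group design, a cell type is *altered*
  when `|log2 FC|` of its frequency exceeds 0.6 between reference and
  disease, and *rescued* when the treated group shifts it back past the same
  threshold in the opposite direction.
* **Synthetic data generation** (`th17pipe.simulate`). A seeded generator
  produces a complete desk-scale study — genome FASTA, gene GTF, peak BEDs,
  negative-binomial count tables with planted depth factors, a promoter
  ChIP signal track, decay time courses, and per-cell composition tables
  with planted disease/rescue effects — together with a `truth.json` of all
  planted parameters, so every stage can be validated against known ground
  truth without any external download.

## Worked example

Simulate a study and run every stage in one shot:

```sh
th17pipe run-all --seed 1 --out-dir results/demo
```

`results/demo/summary.json` then contains (abridged, actual output):

```json
{
  "atac_norm": {
    "n_null_peaks": 233,
    "scale_factors": {"wt_1": 0.4999, "wt_2": 0.9848, "ko_1": 1.9686, "ko_2": 1.0319}
  },
  "integration": {
    "n_l1": 260,
    "fractions": {"pct_nsun2_with_m5c": 81.11, "pct_rorgt_with_nsun2_m5c": 56.60},
    "background_mean_gc": 0.3994
  },
  "decay": {"wt": 60.81, "ko": 29.83, "half_life_ratio": 0.49},
  "composition": {
    "rescued": ["enterocyte", "fibroblast", "gd_t", "goblet",
                "ilc1", "ilc2", "monocyte", "neutrophil"]
  }
}
```

Reading the numbers: the generator planted depth factors (0.5, 1.0, 2.0,
1.0) and the null-peak normalization recovered them to within ~2% under
negative-binomial noise; 81.1% of methyltransferase-bound genes carry the
m⁵C mark and 56.6% of transcription-factor targets are both bound and
methylated, exactly as planted; the fitted half-lives (≈61 vs ≈30 min)
match the planted 60/30 min decay rates, i.e. losing the methyltransferase
halves transcript stability in this simulation; and the eight planted
rescue cell types are recovered exactly.

Each stage is also available as its own subcommand (`simulate`,
`atac-norm`, `integrate`, `decay`, `composition`) operating on standard
text formats (BED, GTF, bedGraph, FASTA, TSV), and as plain library
functions.

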