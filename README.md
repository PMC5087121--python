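# tipmap

Transposon insertion profiling analysis for genomic tiling microarrays.

The package takes per-array probe intensity tracks (log2 ratios over
ordered genomic probes) and produces ranked candidate transposable-element
insertion calls, calibrated detection cutoffs, a panel-level
presence/absence genotype matrix with locus categories, gene-set
enrichment statistics, and insertion-phenotype association results.  A
first-class synthetic-data module emulates the assay's signal structure —
amplicon-footprint peaks a few kb wide over consecutive probes, baseline
noise elsewhere, a cell panel sharing fixed, polymorphic and private
insertions — so the whole pipeline runs and is testable with no external
data.

## Pipeline stages

| module            | role |
|-------------------|------|
| `tipmap.simulate` | synthetic genomes, restriction maps, probe tracks, phenotype matrices with planted truth |
| `tipmap.peaks`    | descending-percentile sliding-window peak calling on a probe track |
| `tipmap.calibrate`| reference-insertion recovery curves and knee/fixed rank cutoffs |
| `tipmap.loci`     | panel-wide locus merging, known-insertion DB matching, category classification, summaries |
| `tipmap.enrich`   | exact hypergeometric gene-set over-representation, universe-controlled |
| `tipmap.assoc`    | point-biserial insertion-phenotype association with Bonferroni correction and cis/trans labelling |

Peak calling follows the published run settings (percent start 90, step 1,
76 steps, 1500 bp window, >= 4 probes above threshold, absolute floor 2,
top 5000 peaks); cutoffs default to the knee of the recovery curve with
fixed fallbacks of percentile > 70 (L1) and > 60 (Alu).  Loci with no
database match are classified novel polymorphic (>= 2 cell lines) or
singleton (exactly 1); singleton loci are tested only for cis
associations (anchor within 30 kb).

## CLI

All stages are exposed as `tipmap` subcommands operating on plain TSV/BED
files (0-based half-open coordinates):

```bash
tipmap simulate --out simdir --seed 1                 # tracks/, truth, DB, genes, phenotypes
tipmap peaks --track simdir/tracks/CL01_L1.track.tsv --out CL01_L1.peaks.tsv
tipmap calibrate --peaks CL01_L1.peaks.tsv --refdb simdir/knowndb.bed --out caldir
tipmap loci --peaks-dir retained/ --refdb simdir/knowndb.bed \
            --genes simdir/genes.tsv --out locidir
tipmap enrich --loci locidir/loci.tsv --universe simdir/genes.tsv \
              --sets mysets/ --select nonref --out enrichment.tsv
tipmap assoc --matrix locidir/presence_matrix.tsv --pheno simdir/phenotypes.tsv \
             --loci locidir/loci.tsv --out assocdir
```

`tipmap simulate --config sim.yaml` accepts a YAML file overriding any
`tipmap.config.SimConfig` field.

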