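# tripflow

A pipeline for measuring chromosomal position effects on reporter-gene
expression mean and noise (CV²) from barcoded-reporter experiments:

1. **barcode_calling** — read QC/demultiplexing and greedy collapse of
   sequencing-error mutants (Hamming radius 2) into genuine barcodes.
2. **pool_decoding** — k-of-n combinatorial pooling designs (e.g. 4 of 18;
   capacity C(n,k)) and decoding of barcode→clone assignments from pooled
   sequencing counts, including merged-signature pairs and multi-barcode
   clone exclusion.
3. **trip_mapping** — replicate-concordant integration-site assignment: reads
   are clustered per barcode/replicate and a site is kept only when both
   replicates' top candidates agree.
4. **expression_stats** — flow-cytometry gating (central FSC×SSC quantile
   box), IRFP-based internal-control separation, per-clone mean / variance /
   CV² and replicate aggregation and correlation.
5. **feature_integration** — windowed TF-signal enrichment (bedGraph tracks,
   50-kb window) and nearest-distance-to-chromatin-state features (BED4
   segmentations) at integration sites.
6. **association_analysis** — Spearman screening (|rho| > 0.2) plus
   multivariate OLS on log10 mean and log10 CV², with per-coefficient t/p
   statistics, optional stepwise selection, and a mean/noise orthogonality
   partition.
7. **synthetic_data** — a seeded generator for every input above with ground
   truth retained, so each stage is testable by recovery.

## CLI

The console script is installed as `pipeline` (alias `tripflow`):

```bash
pipeline simulate --config cfg.yaml --out data/        # synthetic dataset
pipeline call-barcodes --fastq data/barcode_reads.fastq --length 16 --radius 2 --out genuine.tsv
pipeline make-design --n-clones 300 --n-pools 18 --weight 4 --scheme balanced --out design.tsv
pipeline decode --counts data/pool_counts.tsv --design data/design.tsv --threshold 0.2 --out decoded.tsv
pipeline map-sites --rep1 data/trip_rep1.tsv --rep2 data/trip_rep2.tsv --window 10 --out sites.tsv
pipeline summarize --events data/flow_events.csv --out summaries.tsv
pipeline features --sites sites.tsv --tracks data/tracks/ --states data/states.bed \
    --expr summaries.aggregated.tsv --window 50000 --out matrix.tsv
pipeline associate --matrix matrix.tsv --rho-threshold 0.2 --alpha 0.05 --out-prefix assoc
```

A minimal `cfg.yaml`:

```yaml
n_clones: 300
seed: 42
n_pools: 18
signature_weight: 4
n_tf_tracks: 5
n_states: 8
chrom_lengths: [[chr1, 10000000], [chr2, 10000000], [chr3, 10000000]]
```

## File formats

Plain text throughout: FASTQ reads; TSV for counts, designs, mapped reads,
sites, summaries and feature matrices; CSV flow-event tables; bedGraph
signal tracks; BED4 state segmentations (0-based half-open); JSON ground
truth and metadata.
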