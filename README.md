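# regnomics

A tested re-implementation of the computational core of a single-cell
multi-omic analysis of an interferon-responsive endothelial state:

- **ISG-style module scoring** of a gene set against expression-bin-matched
  random background genes, with z-transformation and rank-based group tests
  (`signature_scoring`).
- **QC and differential statistics**: cell filtering (UMI 500–25,000,
  mitochondrial fraction ≤ 0.5%, doublet score ≤ 0.25%; ATAC nuclei FRiP ≥ 15%,
  fragments 30K–1,500K), library-size log normalization, Wilcoxon rank-sum
  marker detection (min.pct 0.01, log-FC threshold 0.25) with
  Benjamini–Hochberg adjustment, and a label-permutation test for cluster
  composition shifts between conditions (`differential_stats`).
- **Calibrated PWM scanning**: log2-odds scoring of both strands with an
  exact p-value threshold (default 1e-4) computed by convolving the
  discretized per-position score distributions, FIMO-style (`motif_scan`).
- **Normalized motif score (NMS)**: peaks assigned to genes overlapping the
  gene body or the 2-kb strand-aware promoter; NMS(gene, TF) =
  Σ accessibility × motif count / peak length (kb) over assigned peaks, with
  DEG-vs-background comparisons (`regulatory_score`).
- **TF-family co-occurrence networks**: Pearson correlation of per-peak
  family motif counts over a peak subset, partitioned with Newman's
  leading-eigenvector spectral modularity method (`tf_colocalization`).
- **Synthetic data with planted ground truth** so the whole pipeline is
  testable offline at desk scale (`synthetic_data`), plus strict readers and
  writers for FASTA, BED, MEME-minimal, Matrix Market and TSV tables
  (`io_formats`) and an orchestrating CLI (`pipeline_cli`).

## CLI

Full pipeline from one config file (YAML or JSON), or the packaged demo:

```bash
regnomics demo --outdir demo_out --seed 1
regnomics run config.yaml --outdir run_out
```

The demo simulates every input, then runs QC → module scoring → markers →
composition → motif scan → NMS → co-occurrence networks, writing TSV/JSON
outputs and a `manifest.json` with parameter snapshots and output hashes
(repeat runs with the same seed give identical hashes).

Per-stage subcommands for ad-hoc use:

```bash
regnomics simulate --outdir data --seed 1
regnomics score --mtx data/counts.mtx --features data/features.tsv \
    --barcodes data/barcodes.tsv --metadata data/cell_metadata.tsv \
    --gene-set panel.tsv --n-bins 24 --pool-factor 10 --seed 1 --out scores.tsv
regnomics scan --genome data/genome.fa --peaks data/peaks.bed \
    --motifs data/motifs.meme --pvalue 1e-4 --out hits.tsv
regnomics nms --hits hits.tsv --peaks data/peaks.bed \
    --access data/accessibility.tsv --genes data/genes.tsv \
    --families data/families.tsv --population popA --level family --out nms.tsv
regnomics network --hits hits.tsv --families data/families.tsv \
    --out-prefix net
```

Exit codes: 0 ok, 1 input/format error, 2 configuration error, 3 internal.

## Acceptance

Acceptance is property-based (oracle equivalence, planted-signal recovery,
statistical calibration) and implemented in `tests/test_acceptance.py`.
The report script runs the demo pipeline end to end and writes the (empty)
numeric-target report:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

```
src/regnomics/
  synthetic_data.py     simulators with planted ground truth
  io_formats.py         FASTA / BED / MEME-minimal / MTX / TSV readers+writers
  differential_stats.py QC, normalization, markers, BH, composition test
  signature_scoring.py  module scores, z-scores, group comparison
  motif_scan.py         log-odds scanning with exact p-value thresholds
  regulatory_score.py   peak→gene assignment and NMS
  tf_colocalization.py  family networks and spectral communities
  pipeline_cli.py       orchestration and CLI
```
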