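# imprintscan

Control-panel differential-methylation analysis for methylation-array data.
Given a normalized β-value matrix, a probe manifest, and a sample sheet
assigning samples to a control panel, patients, and mutation-corrected
clones, the package provides:

- **Preprocessing** — SNP/sex-chromosome/detection-p probe filters and a
  control-consistency filter (any control > 0.2 β from the control mean),
  plus β ↔ M conversion (`M = log2(β/(1−β))`, clipped).
- **DM calling** — per-unit outlier statistic against the control panel:
  a unit is differentially methylated when `|ΔM| > 3·SD(control M)` *and*
  `|Δβ| > 0.2` (Δβ vs the control median, ΔM vs the control mean), with
  hyper/hypo classification; works at CpG, 500 bp-bin, and region level.
- **Binning and clusters** — 500 bp genome tiles (≥2 CpGs), β averaging,
  and detection of clusters of ≥2 contiguous dm bins vs isolated bins.
- **Imprinted-DMR analysis** — a frozen 50-region iDMR fixture, the
  ≥3-probe / named-exclusion region filter (50 → 42 → 41), three-way
  grouping by control methylation (≥60% / 40–60% / <40%), region-level dm
  calls, and "recovered" classification in corrected clones
  (`|Δβ| < 0.2`), with per-clone/per-class recovery summaries.
- **Annotation & statistics** — multi-label genomic-element annotation,
  a seeded permutation (shuffle) overlap test, ChIP IP/input fold change
  with depth normalization, paired one-sided Wilcoxon + BH-FDR +
  rank-biserial effect size, and a two-sided two-sample rank test.
- **Synthetic data** — a truth-annotated generator emulating the full
  study design (11 controls, 2 patients, 2 corrected clones each,
  fibroblasts, planted hypomethylated bins/regions, resistant loci, ChIP
  counts), so every stage is testable without external downloads.

## Command line

```bash
imprintscan simulate --seed 1 --out-dir sim/           # synthetic bundle
imprintscan preprocess --beta sim/beta.tsv --manifest sim/manifest.tsv \
    --samples sim/samples.tsv --out-dir out/
imprintscan call --beta out/beta_filtered.tsv --manifest sim/manifest.tsv \
    --samples sim/samples.tsv --level bin --out calls.tsv
imprintscan idmr --beta sim/beta.tsv --regions sim/regions.bed \
    --manifest sim/manifest.tsv --samples sim/samples.tsv --out-dir idmr/
imprintscan enrich --fc-counts sim/chip.tsv --out stats.tsv
imprintscan overlap --a a.txt --b b.txt --universe u.txt --n-perm 99999 --seed 7
```

The full pipeline (preprocess → reference → CpG calls → bin calls →
clusters → iDMR analysis → recovery → annotation → enrichment) runs from a
single YAML config and emits per-stage TSVs plus a JSON run manifest:

```bash
imprintscan run --config run.yaml
```

Minimal `run.yaml`:

```yaml
beta: sim/beta.tsv
manifest: sim/manifest.tsv
samples: sim/samples.tsv
regions: sim/regions.bed
chip: sim/chip.tsv        # optional
out_dir: results/
```

## Conventions

All coordinates are 0-based half-open; chromosome names are matched
exactly; missing β is `NA`, never 0; all randomness flows through explicit
seeds.
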