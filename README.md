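# rrbskit

A simulation and analysis toolkit for reduced-representation bisulfite
sequencing (RRBS) studies of T-cell epigenetic reprogramming — in
particular the conversion of human Vγ9Vδ2 (γδ) T cells into FOXP3⁺
regulatory-like cells under TGF-β and phospho-Vitamin C (pVC), where the
readouts are genome-wide CpG methylation, demethylation of the
Treg-specific demethylated region (TSDR) of *FOXP3*, and functional
suppression assays.

The package is aimed at computational biologists who want a fully
self-contained, ground-truth-controlled reimplementation of that analysis
chain: every input is generated in-repo with known truth, so every stage
can be validated end to end.

## What it does

* **`synthio`** — synthetic inputs with known ground truth: a reference
  genome with genes/promoters/CpG islands, implanted CpG-dense
  differential cassettes and a 7-CpG TSDR-like locus; per-cytosine
  methylation profiles for the four culture arms (medium, pVC, TGF-β,
  TGF-β + pVC); in-silico MspI digestion (C^CGG), 40–220 bp size
  selection and directional bisulfite reads (FASTQ); pyrosequencing-style
  amplicon tables; cytometry event tables.
* **`bscore`** — collapsed-alphabet placement of bisulfite reads (C→T on
  the original-top strand, G→A on the original-bottom) and per-cytosine
  calls. The methylation level at a site is **m = mC / (mC + uC)**, the
  fraction of methylated-read observations among C/T observations.
* **`dmrcall`** — differentially methylated region discovery between two
  methylomes: sliding windows of ≥ 5 CpG (CHG/CHH) sites covered in both
  samples, a window passes when the coverage-pooled levels satisfy

  * fold change max(L₁, L₂)/min(L₁, L₂) ≥ 2,
  * two-sided Fisher exact p < 0.05 on the pooled 2×2 count table,
  * the samples are not both hypomethylated (max(L₁, L₂) ≥ 0.2),

  followed by collapse of overlapping passing windows and **iterative
  merging**: two nearby regions are joined whenever the spanning region,
  pooled over all qualifying sites, again meets every criterion; the
  final regions are mutually independent.
* **`sampstats`** — shared-site level matrices, Pearson correlation of
  samples, PCA on all common mCG sites, and mCG/mCHG/mCHH summaries per
  promoter/CGI/gene-body/genome.
* **`annotate`** — DMR-to-gene assignment (gene body + strand-aware
  promoter, TSS −2000/+500) and local hypergeometric gene-set
  over-representation against GMT files (significant at p ≤ 0.05).
* **`targeted`** — TSDR amplicon summaries: per-CpG percent methylation,
  the 7-CpG average, and the yellow (0%) → green (50%) → blue (100%)
  heat-map colour code.
* **`cytoquant`** — suppression-assay quantification: absolute counts by
  standard cell dilution assay (SCDA), `count = events_target /
  events_standard × n_standard_added`; relative expansion quotients
  (solo culture ≡ 1.0); and CFSE-low proliferating fractions with an
  automatic histogram-valley threshold.
* **`pipeline`** — one-config end-to-end runs with a checksummed
  manifest; identical config + seed ⇒ byte-identical outputs.
* **`reference`** — deliberately naive enumeration-based implementations
  (exact-integer Fisher test, brute-force DMR enumerator) used to
  validate the fast code paths.

## Worked example

```python
from rrbskit.pipeline import RunConfig, run_pipeline

cfg = RunConfig(seed=1, chrom_length=20_000, n_genes=10,
                n_truth_dmrs=4, mean_depth=15)
run_pipeline(cfg, "demo_run")
```

This simulates the four culture arms and runs the whole chain. In
`demo_run/dmrs_TGFb_vs_TGFb_pVC.tsv` the caller reports (columns
abridged):

```
chrom  start  end   n_sites  level1  level2  fold_change  fisher_p
chr1   2026   2209  21       0.890   0.205   4.34         6.4e-57
chr1   7222   7327  19       0.892   0.210   4.24         6.6e-76
```

— hypermethylated regions in the TGF-β arm (level₁ ≈ 0.89) that are
demethylated under TGF-β + pVC (level₂ ≈ 0.21), exactly the implanted
truth (0.9 vs 0.1 programmed levels; one of them is the TSDR cassette).
`demo_run/suppression_summary.tsv` holds the functional readout:

```
culture      cd4_count  expansion_quotient  cfse_low_fraction
solo         30000.0    1.0000              0.7392
with_gd      18000.0    0.6000              0.5909
with_gd_pvc  7500.0     0.2500              0.3364
```

The solo-cultured CD4 responders normalise to 1.0 by construction;
co-culture with TGF-β-expanded γδ T cells suppresses expansion (0.60),
pVC-expanded γδ T cells suppress more strongly (0.25), and the CFSE-low
(proliferating) fractions recovered by the automatic threshold (74%, 59%,
34%) match the programmed division fractions.

The same stages are scriptable from the shell (`rrbskit --help`):
`rrbskit synth make-genome`, `rrbskit call`, `rrbskit dmr`,
`rrbskit stats pca`, `rrbskit anno enrich`, `rrbskit amplicon heatmap`,
`rrbskit cyto scda`, `rrbskit run pipeline --config run.cfg`.

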