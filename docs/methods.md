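# Methods

This note documents the models implemented in `rrbskit`, the parameters
that matter, the design choices made where several definitions were
defensible, and what the synthetic-data validation does and does not
demonstrate.

## Synthetic genomes and methylation profiles

`synthio.generate_genome` draws i.i.d. bases at a configurable GC
fraction (default 0.5) and then enriches the sequence three ways:

* **CCGG density.** Extra CCGG motifs are implanted at
  `(ccgg_boost − 1) ×` the random-sequence baseline rate, so that MspI
  digestion yields RRBS-like fragment densities (≥ 1 site/kb at boost
  ≥ 2 for GC ≈ 0.5).
* **CpG islands.** Random 300–800 bp intervals receive additional CG
  dinucleotides (~1 per 12 bp) and are annotated as `CGI`.
* **Designed cassettes.** Each implanted differential region (`truth_dmr`)
  and the TSDR-like locus (`tsdr`, ≥ 7 CpGs) is written as
  `CCGG + (s₁s₂ CG s₃s₄)ₖ + CCGG` with random A/T spacers. The flanking
  CCGGs guarantee that the CpG-dense middle falls inside a single MspI
  fragment of 6k + 4 bp — inside the 40–220 bp size-selection window for
  6 ≤ k ≤ 36 — so implanted truth is always observable by the RRBS arm
  of the pipeline. A/T spacers cannot create extra CpGs, CHG contexts or
  CCGG sites, and the per-cassette randomisation keeps distinct cassettes
  unique and mappable. Cassettes are placed inside gene bodies when a
  large-enough gene exists, so that DMR→gene annotation and enrichment
  have signal.

`assign_profile` gives every cytosine on both strands exactly one true
methylation level: CpG sites get `base_cg_level` (default 0.8, typical
for somatic non-CGI CpGs), non-CpG sites `base_noncg_level` (default
0.02), plus Gaussian jitter (SD 0.05, clipped to [0, 1]) so that null
windows are not artificially identical across arms. Inside a listed
feature the CpG sites take the exact level programmed for that condition
arm; non-CpG sites always keep background levels, since the differential
biology modelled (TSDR and DMR methylation) is CpG methylation. The
default pipeline programs the TSDR at 0.85 in all arms except
TGF-β + pVC (0.1), and alternates the remaining implants between
pVC-responsive (medium vs pVC) and TGF-β + pVC-responsive regions.

## Read simulation and calling

The library model is directional single-end sequencing, default 50 bp,
from the 5′ ends of both the original-top (OT) and original-bottom (OB)
strands of each retained fragment; each fragment receives
Poisson(`mean_depth`) reads per strand (default 30). A cytosine is read
as C with probability `level + (1 − level)(1 − conversion_rate)` and as T
otherwise (conversion default 0.995); independent substitution errors are
applied at `error_rate` (default 0.001). No adapters, quality model,
PCR duplicates or indels are simulated. Sites further than one read
length from the informative strand's fragment end receive no coverage —
a deliberate echo of real RRBS coverage concentrating at fragment ends.

Placement is exact collapsed-alphabet search rather than an external
aligner: the read is compared C→T-collapsed against the forward genome
(OT) and its reverse complement G→A-collapsed (OB), seeded by pigeonhole
segments so that any placement with ≤ `max_mismatches` (default 2)
mismatches is found; only a unique best placement is kept, ties and
failures are counted as discards. On error-free simulations ≥ 99% of
reads place at their true origin (measured 100% on the test fixtures).

At a reference cytosine, read base C increments mC, T increments uC, and
any other base is ignored as sequencing error — consistent with reading
"total C" as the number of C/T (bisulfite-informative) observations. The
level is mC/(mC + uC); `min_coverage` defaults to 1 for site tables and
5 wherever two samples are compared (DMR scan, sample matrices), since
level estimates below 5× are dominated by discreteness.

## DMR discovery

The unit of testing is a window of exactly `min_sites` = 5 consecutive
qualifying sites (same context, ≥ `min_cov` = 5 in both samples),
sliding by one site; "at least 5 sites" regions arise by collapsing
overlapping passing windows, which avoids inventing an arbitrary bp
width. Windows have no bp cap: consecutive qualifying sites may be far
apart, which mirrors the region definition exactly and means a strong
region can recruit the nearest background sites at its edges.

A window passes when, on coverage-pooled counts (Σ mC / Σ(mC + uC); an
unweighted-mean mode exists behind a flag):

1. fold change max(L₁, L₂)/min(L₁, L₂) ≥ `fold_min` = 2 — when
   min(L₁, L₂) = 0 and max > 0 the fold is +∞ and the criterion holds;
2. two-sided Fisher exact p < `p_max` = 0.05 on (mC₁, uC₁, mC₂, uC₂);
3. not both samples hypomethylated. "Hypomethylated" is defined as a
   pooled level < `hypo_threshold` = 0.2; the default rule is
   max(L₁, L₂) ≥ 0.2 ("not both"), because demethylation of one sample
   is precisely the biological signal sought; the stricter
   `hypo_rule="neither"` (min ≥ threshold) is available.

The Fisher test sums, in log space (cached log-factorials), the
hypergeometric probabilities of all tables with the observed margins
whose probability is ≤ that of the observed table, with a relative
tolerance of 1e−7 on the comparison (the convention shared by R and
SciPy); an all-zero table returns p = 1, and results are clamped to the
smallest positive float so p ∈ (0, 1] survives extreme tables. It is
validated against an exact-integer enumeration oracle over every 2×2
table with N ≤ 40 (135,751 tables, max |Δp| ≈ 4e−14).

Merging: adjacent putative regions on one chromosome within
`max_gap` = 500 bp are interdependent when the spanning region — pooled
over **all** qualifying sites from the upstream start to the downstream
end, not just member sites — passes all three criteria; merging repeats
to a fixpoint (left-to-right sweeps; the validation oracle sweeps
right-to-left and reaches the same fixpoint on all test corpora). Final
regions are re-checked on their own pooled counts; a collapsed region
that no longer passes is dropped with a warning (this occurs when
opposite-direction windows chain, and matches the brute-force
enumerator's behaviour). Pooled-count testing (rather than per-site) is
an assumption, flagged here and in the run manifest. Single methylomes
are compared; no replicate dispersion model is added, and no
multiple-testing correction is applied in discovery.

## Sample comparison, annotation, amplicon, cytometry

* **Matrices/PCA/correlation.** The site matrix is the intersection of
  context-filtered sites covered ≥ 5× in every sample. PCA mean-centres
  each site, does not scale (levels already share the [0, 1] scale), and
  fixes each component's sign so its first nonzero loading is positive;
  variance-explained fractions sum to 1 over the n−1 available
  components. Zero-variance columns yield NaN correlations, never a
  silent 0. CpG sites are kept per strand, matching the per-cytosine
  level definition; symmetric-pair pooling is a caller option upstream.
* **Annotation/enrichment.** Promoters are TSS −2000/+500 strand-aware
  (not dictated by the underlying study; configurable). The background
  universe is the annotation's full gene set. Enrichment is the upper
  hypergeometric tail P(X ≥ overlap); raw p ≤ 0.05 flags significance,
  and a Benjamini–Hochberg column is emitted for information only.
* **Amplicon.** Per-CpG percent = 100·methylated/total; the per-sample
  average is the unweighted mean over the assay's CpGs (7 by default); a
  CpG with zero observations is excluded from the average with a
  warning. The colour code interpolates linearly yellow (255,255,0) →
  green (0,128,0) on [0, 50] and green → blue (0,0,255) on [50, 100];
  the anchor RGB values are the standard named colours.
* **Cytometry.** Event tables are plain CSV (FCS parsing is out of
  scope); viability is a generator-supplied boolean. SCDA count =
  (target events / standard events) × standards added; the relative
  expansion quotient divides by the solo-culture count (≡ 1.0). CFSE
  intensities halve per division with lognormal noise (σ = 0.1); the
  automatic CFSE-low threshold histograms log₂ intensity
  (Freedman–Diaconis bins), smooths with a 3-bin moving average, and
  takes the minimum between the two largest modes that are ≥ 0.5 log₂
  units apart (guarding against twin peaks inside one generation
  cluster). The default generation distribution puts the divided
  fraction f into generations 1–4 with decaying weights
  (0.4, 0.3, 0.2, 0.1)·f.

## Pipeline and reproducibility

`RunConfig` is a flat INI file (no code execution); every DMR default
(5 sites, 2-fold, p < 0.05, hypo 0.2, gap 500) and the 40–220 bp size
selection are config defaults. Stage seeds derive arithmetically from
the master seed; the manifest records the config hash and a SHA-256 of
every output, and identical config + seed reproduces identical
checksums. Logs carry timestamps and are excluded from checksumming.

## Validation scales and what they show

Validation runs use deliberately small problem sizes chosen so the full
suite exercises every stage end to end: 12–40 kb genomes, 10–30×
simulated depth, 10 implanted regions of 8–10 CpGs, 100 kb direct-count
comparisons against the brute-force enumerator, and 20,000-event
cytometry samples. Passing these shows internal correctness —
formula-level agreement with independent enumeration oracles, unbiased
binomial sampling, exact recovery of programmed truth — not performance
on real RRBS data, which has coverage biases, conversion heterogeneity,
repeats and mapping ambiguity that the generator intentionally omits.

One caveat is worth stating precisely: with conversion 1 and no errors,
per-site observed levels are exact Binomial(n, p) draws, so ~0.3–0.5% of
sites necessarily deviate from truth by more than 3 binomial SE — a
property of the binomial tail, not an implementation bias. Site-level
accuracy is therefore asserted via exact binomial tail probabilities
(the fraction of sites with two-sided tail p < 0.003 stays below 1%),
and the measured maximum deviation in SE units is reported alongside the
fraction of sites within 3 SE.

## Known limitations

* No indel-aware alignment, mapping-quality model or external-aligner
  parity; equivalence is claimed only with the stated level formula.
* No PMD/FMR/UMR/LMR genome segmentation, smoothing, beta-binomial
  dispersion or replicate modelling.
* Enrichment is validated on synthetic gene sets only; no live pathway
  databases are queried.
* The amplicon module carries no pyrogram signal processing or
  bisulfite-PCR bias correction; cytometry has no compensation or gating
  reconstruction.
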